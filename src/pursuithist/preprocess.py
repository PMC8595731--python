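"""Eye-trace preprocessing: velocity/acceleration traces, filtering, saccades.

The fixed pipeline order is: central-difference differentiation -> 30 Hz
zero-phase FIR low-pass -> saccade detection on the filtered acceleration ->
linear interpolation of the velocity over saccadic gaps -> 40 ms moving
average.  No stage changes the time grid or the trace length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

FS_HZ = 1000.0

FIR_ORDER = 80
FIR_CUTOFF_HZ = 30.0
SACCADE_ACCEL_THRESHOLD = 1000.0  # deg/s^2
SACCADE_PAD_MS = 10.0
MOVING_AVERAGE_MS = 40.0


@dataclass
class EyeTrace:
    """Uniform 1 kHz eye-position samples (t in ms, position in deg)."""

    t: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.t.shape != self.position.shape:
            raise ValueError("t and position must have the same length")

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    def check_uniform(self, tol: float = 1e-9) -> None:
        d = np.diff(self.t)
        if len(d) == 0 or np.any(np.abs(d - d[0]) > tol):
            raise ValueError("non-uniform time grid")


@dataclass
class SignalTrace:
    """Velocity (deg/s) or acceleration (deg/s^2) on the same grid.

    ``interpolated`` flags samples that were reconstructed over removed
    saccades.
    """

    t: np.ndarray
    value: np.ndarray
    kind: str  # "velocity" | "acceleration"
    interpolated: np.ndarray = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.t), dtype=bool)

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class SaccadeInterval:
    start: float  # ms
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("saccade interval must have start < end")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def differentiate_central(trace) -> SignalTrace:
    """Central-difference derivative; one-sided differences at the endpoints.

    Accepts an :class:`EyeTrace` (-> velocity) or a velocity
    :class:`SignalTrace` (-> acceleration).  Units convert ms -> s, so an
    input in deg yields deg/s.
    """
    if isinstance(trace, EyeTrace):
        trace.check_uniform()
        y, t, kind, flags = trace.position, trace.t, "velocity", None
    else:
        y, t, kind = trace.value, trace.t, "acceleration"
        flags = trace.interpolated.copy()
    if len(y) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d = np.diff(t)
    if np.any(np.abs(d - d[0]) > 1e-9):
        raise ValueError("non-uniform time grid")
    dt_s = d[0] / 1000.0
    out = np.empty_like(y)
    out[1:-1] = (y[2:] - y[:-2]) / (2.0 * dt_s)
    out[0] = (y[1] - y[0]) / dt_s
    out[-1] = (y[-1] - y[-2]) / dt_s
    return SignalTrace(t=t.copy(), value=out, kind=kind, interpolated=flags)


def design_lowpass(order: int = FIR_ORDER, cutoff_hz: float = FIR_CUTOFF_HZ,
                   fs: float = FS_HZ) -> np.ndarray:
    """Hamming-window linear-phase FIR low-pass taps (order+1 taps)."""
    return signal.firwin(order + 1, cutoff_hz, window="hamming", fs=fs)


def lowpass_fir(trace: SignalTrace, order: int = FIR_ORDER,
                cutoff_hz: float = FIR_CUTOFF_HZ) -> SignalTrace:
    """Zero-phase (forward-backward) FIR low-pass on the same grid.

    Zero-phase filtering is used so detected event times carry no group
    delay.  Rejects traces not longer than 3x the filter order (the padding
    needed by the forward-backward pass).
    """
    taps = design_lowpass(order, cutoff_hz, fs=1000.0 / trace.dt_ms)
    padlen = 3 * order
    if len(trace.value) <= padlen:
        raise ValueError(
            f"trace of {len(trace.value)} samples is too short for an "
            f"order-{order} zero-phase FIR (needs > {padlen})")
    out = signal.filtfilt(taps, [1.0], trace.value, padlen=padlen)
    return SignalTrace(t=trace.t.copy(), value=out, kind=trace.kind,
                       interpolated=trace.interpolated.copy())


def detect_saccades(accel: SignalTrace,
                    threshold: float = SACCADE_ACCEL_THRESHOLD,
                    pad_ms: float = SACCADE_PAD_MS) -> list:
    """Supra-threshold |acceleration| runs, padded and merged.

    Every sample with ``|a| > threshold`` lies inside a returned interval;
    intervals are padded by ``pad_ms`` on each side and merged when they
    overlap or touch.
    """
    if accel.kind != "acceleration":
        raise ValueError("saccade detection expects an acceleration trace")
    mask = np.abs(accel.value) > threshold
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    t0, t1 = accel.t[0], accel.t[-1]
    raw = [(max(accel.t[s] - pad_ms, t0), min(accel.t[e] + pad_ms, t1))
           for s, e in zip(starts, ends)]
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [SaccadeInterval(s, e) for s, e in merged]


def remove_and_interpolate(vel: SignalTrace, saccades) -> SignalTrace:
    """Replace samples inside saccade intervals by linear interpolation.

    Interpolation runs between the last retained sample before and the first
    retained sample after each gap; gaps touching the trace boundary are
    filled with the nearest retained value (with a warning).  Samples outside
    the intervals are unchanged and the ``interpolated`` flags mark exactly
    the replaced samples.
    """
    out = vel.value.copy()
    flags = vel.interpolated.copy()
    gap = np.zeros(len(out), dtype=bool)
    for iv in saccades:
        if iv.start < vel.t[0] or iv.end > vel.t[-1]:
            raise ValueError("saccade interval outside the trace span")
        gap |= (vel.t >= iv.start) & (vel.t <= iv.end)
    if gap.any():
        keep = ~gap
        if not keep.any():
            raise ValueError("saccade intervals cover the whole trace")
        if gap[0] or gap[-1]:
            logger.warning("saccade interval touches the trace boundary; "
                           "filling with the nearest retained value")
        out[gap] = np.interp(vel.t[gap], vel.t[keep], out[keep])
        flags = flags | gap
    return SignalTrace(t=vel.t.copy(), value=out, kind=vel.kind,
                       interpolated=flags)


def moving_average(vel: SignalTrace,
                   window_ms: float = MOVING_AVERAGE_MS) -> SignalTrace:
    """Centered boxcar mean; edges use shrinking windows.

    The window is rounded to an odd sample count (a 40 ms window at 1 kHz
    becomes 41 samples) so the smoother is symmetric and phase-free.
    """
    w = int(round(window_ms / vel.dt_ms))
    if w % 2 == 0:
        w += 1
    if w > len(vel.value):
        raise ValueError("moving-average window longer than the trace")
    kernel = np.ones(w)
    num = np.convolve(vel.value, kernel, mode="same")
    den = np.convolve(np.ones(len(vel.value)), kernel, mode="same")
    return SignalTrace(t=vel.t.copy(), value=num / den, kind=vel.kind,
                       interpolated=vel.interpolated.copy())


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class ProcessedTrial:
    """Outputs of the fixed preprocessing pipeline for one trial."""

    velocity: SignalTrace       # smoothed, saccade-free velocity
    acceleration: SignalTrace   # acceleration of the smoothed velocity
    saccades: list


def preprocess_trace(trace: EyeTrace,
                     fir_order: int = FIR_ORDER,
                     fir_cutoff_hz: float = FIR_CUTOFF_HZ,
                     saccade_threshold: float = SACCADE_ACCEL_THRESHOLD,
                     saccade_pad_ms: float = SACCADE_PAD_MS,
                     moving_average_ms: float = MOVING_AVERAGE_MS) -> ProcessedTrial:
    """Run the full pipeline in its fixed order on one eye-position trace."""
    v_raw = differentiate_central(trace)
    v_filt = lowpass_fir(v_raw, fir_order, fir_cutoff_hz)
    a_filt = lowpass_fir(differentiate_central(v_filt), fir_order,
                         fir_cutoff_hz)
    saccades = detect_saccades(a_filt, saccade_threshold, saccade_pad_ms)
    v_clean = remove_and_interpolate(v_filt, saccades)
    v_smooth = moving_average(v_clean, moving_average_ms)
    a_final = lowpass_fir(differentiate_central(v_smooth), fir_order,
                          fir_cutoff_hz)
    return ProcessedTrial(velocity=v_smooth, acceleration=a_final,
                          saccades=saccades)
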