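"""Per-trial predictive-pursuit event detection and inclusion rules.

Three measures are extracted from each trial, with time zero at the
right-to-left target reversal:

* **deceleration onset** — first time the eye velocity drops below 80% of the
  steady-state mean and stays below it until the eye reverses;
* **eye reversal** — first zero crossing of the eye velocity after onset
  (sub-sample interpolated);
* **mean eye deceleration** — average eye acceleration between the two.

Trials with onset earlier than -300 ms or reversal later than +100 ms are
excluded, as are trials where either event is undetected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import SignalTrace

logger = logging.getLogger(__name__)

STEADY_STATE_WINDOW = (-700.0, -500.0)  # ms relative to target reversal
THRESHOLD_FRACTION = 0.8
ONSET_SEARCH_START = -500.0  # ms; earlier onsets cannot exist by construction
EXCLUSION_ONSET_MS = -300.0
EXCLUSION_REVERSAL_MS = 100.0


@dataclass(frozen=True)
class SteadyStateStats:
    """Pooled steady-state velocity over one observer x condition."""

    mean_velocity: float  # deg/s
    threshold: float      # deg/s
    window: tuple = STEADY_STATE_WINDOW
    n_trials: int = 0


@dataclass
class TrialEvents:
    """Detected events for one trial (times in signed ms, 0 = reversal)."""

    deceleration_onset: float | None
    eye_reversal: float | None
    mean_eye_deceleration: float | None
    included: bool = False
    exclusion_reason: str = "none"  # none|early_onset|late_reversal|undetected


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

def compute_steady_state_threshold(trials,
                                   window=STEADY_STATE_WINDOW,
                                   fraction: float = THRESHOLD_FRACTION,
                                   ) -> SteadyStateStats:
    """Pool the steady-state velocity over all trials of one observer.

    The mean is taken over every sample falling in ``window`` across all
    given velocity traces; the detection threshold is ``fraction`` times it.
    """
    if not trials:
        raise ValueError("cannot compute a steady-state threshold "
                         "from an empty trial list")
    chunks = []
    for tr in trials:
        m = (tr.t >= window[0]) & (tr.t <= window[1])
        if not m.any():
            raise ValueError("a trace does not cover the steady-state window")
        chunks.append(tr.value[m])
    mean_v = float(np.mean(np.concatenate(chunks)))
    return SteadyStateStats(mean_velocity=mean_v,
                            threshold=fraction * mean_v,
                            window=tuple(window), n_trials=len(trials))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_deceleration_onset(vel: SignalTrace, stats: SteadyStateStats,
                              search_start: float = ONSET_SEARCH_START,
                              ) -> float | None:
    """Sustained threshold crossing preceding the eye reversal.

    Returns the earliest time (sample resolution) at which the velocity is
    below the threshold and remains below it continuously until the zero
    crossing; ``None`` when the velocity never crosses zero.  Transient dips
    that recover above threshold before the reversal are ignored.
    """
    t, v = vel.t, vel.value
    win = np.flatnonzero(t >= search_start)
    if len(win) == 0:
        return None
    iz = _first_negative_index(v, win[0])
    if iz is None:
        return None
    i = iz
    while i - 1 >= win[0] and v[i - 1] < stats.threshold:
        i -= 1
    return float(t[i])


def detect_eye_reversal(vel: SignalTrace, onset: float) -> float | None:
    """First zero crossing after onset, sub-sample interpolated.

    Linear interpolation between the bracketing samples gives the time at
    which the velocity reaches exactly 0 deg/s; ``None`` when the velocity
    never goes negative after the onset.
    """
    t, v = vel.t, vel.value
    start = int(np.searchsorted(t, onset, side="left"))
    iz = _first_negative_index(v, start)
    if iz is None:
        return None
    if iz == 0 or v[iz - 1] < 0:
        return float(t[iz])
    v0, v1 = v[iz - 1], v[iz]  # v0 >= 0 > v1: crossing lies in between
    return float(t[iz - 1] + (t[iz] - t[iz - 1]) * v0 / (v0 - v1))


def _first_negative_index(v: np.ndarray, start: int):
    neg = np.flatnonzero(v[start:] < 0)
    return None if len(neg) == 0 else int(start + neg[0])


def mean_deceleration(accel: SignalTrace, onset: float,
                      reversal: float) -> float | None:
    """Arithmetic mean of the acceleration samples in [onset, reversal]."""
    if not onset < reversal:
        raise ValueError("onset must precede the eye reversal")
    m = (accel.t >= onset) & (accel.t <= reversal)
    if m.sum() < 2:
        return None
    return float(np.mean(accel.value[m]))


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------

def apply_exclusion(events: TrialEvents,
                    onset_bound: float = EXCLUSION_ONSET_MS,
                    reversal_bound: float = EXCLUSION_REVERSAL_MS,
                    ) -> TrialEvents:
    """Apply the trial inclusion rules and set the exclusion reason.

    Onsets earlier than ``onset_bound`` (preceding saccades), reversals later
    than ``reversal_bound`` (visual feedback), and undetected events all
    exclude the trial.
    """
    ev = replace(events)
    if (ev.deceleration_onset is None or ev.eye_reversal is None
            or ev.mean_eye_deceleration is None):
        ev.included, ev.exclusion_reason = False, "undetected"
    elif ev.deceleration_onset < onset_bound:
        ev.included, ev.exclusion_reason = False, "early_onset"
    elif ev.eye_reversal > reversal_bound:
        ev.included, ev.exclusion_reason = False, "late_reversal"
    else:
        ev.included, ev.exclusion_reason = True, "none"
    return ev


def inclusion_rate(trials) -> float:
    """Fraction of included trials."""
    if not trials:
        raise ValueError("empty trial list")
    return sum(t.included for t in trials) / len(trials)


def inclusion_summary(per_observer_rates) -> dict:
    """Mean, SD and range of per-observer inclusion rates (as fractions)."""
    r = np.asarray(list(per_observer_rates), dtype=float)
    return {"mean": float(r.mean()), "sd": float(r.std(ddof=1)) if len(r) > 1 else 0.0,
            "min": float(r.min()), "max": float(r.max()), "n": len(r)}


# ---------------------------------------------------------------------------
# per-cohort driver
# ---------------------------------------------------------------------------

def detect_trial_events(processed,
                        steady_window=STEADY_STATE_WINDOW,
                        threshold_fraction: float = THRESHOLD_FRACTION,
                        search_start: float = ONSET_SEARCH_START,
                        onset_bound: float = EXCLUSION_ONSET_MS,
                        reversal_bound: float = EXCLUSION_REVERSAL_MS):
    """Detect events for a list of processed trials of one observer/condition.

    The steady-state threshold is pooled across all given trials; each trial
    is then measured and the inclusion rules applied.  Returns
    ``(list[TrialEvents], SteadyStateStats)``.
    """
    stats = compute_steady_state_threshold(
        [p.velocity for p in processed], window=steady_window,
        fraction=threshold_fraction)
    out = []
    for p in processed:
        onset = detect_deceleration_onset(p.velocity, stats, search_start)
        reversal = None if onset is None else detect_eye_reversal(p.velocity,
                                                                  onset)
        decel = None
        if onset is not None and reversal is not None and onset < reversal:
            decel = mean_deceleration(p.acceleration, onset, reversal)
        ev = TrialEvents(deceleration_onset=onset, eye_reversal=reversal,
                         mean_eye_deceleration=decel)
        out.append(apply_exclusion(ev, onset_bound, reversal_bound))
    return out, stats
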