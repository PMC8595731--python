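"""Synthetic stimulus sequences and eye traces for predictive-pursuit experiments.

The experimental design emulated here is a horizontal triangular-wave tracking
task: the target sweeps rightward at a fixed 16 deg/s over 24 deg, then reverses
and sweeps leftward at one of seven velocities (4..28 deg/s), with no pause
between ramps.  In the *predictable* condition one leftward velocity is repeated
for a whole block; in the *unpredictable* condition the seven velocities are
shuffled within each block.

Eye-reversal timings are generated from a linear trial-history model (lagged
target velocities and lagged eye-reversal timings, plus a per-observer random
intercept), and full 1 kHz eye-position traces are synthesized around those
timings so that the downstream detection pipeline has a recoverable ground
truth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

FS_HZ = 1000.0
DT_MS = 1000.0 / FS_HZ

RIGHTWARD_VELOCITY = 16.0  # deg/s, fixed for every trial
LEFTWARD_VELOCITIES = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0)  # deg/s
TRAVEL_DISTANCE = 24.0  # deg per ramp

PREDICTABLE_BLOCKS = 7
PREDICTABLE_TRIALS_PER_BLOCK = 30
UNPREDICTABLE_BLOCKS = 5
UNPREDICTABLE_REPEATS = 7  # each velocity 7x per block -> 49 trials

#: quiet interval between blocks (target parked at the start position)
BLOCK_GAP_MS = 2000.0
#: visuomotor latency used for the reactive (non-predictive) transitions at
#: ramp starts; the right-to-left reversal itself is predictive and does not
#: use this.
REACTIVE_LATENCY_MS = 100.0
REACTIVE_RAMP_MS = 200.0


# ---------------------------------------------------------------------------
# stimulus sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSequence:
    """Ordered trial list for one observer in one condition.

    ``blocks`` is a tuple of blocks; each block is a tuple of
    ``(rightward_velocity, leftward_velocity)`` pairs in deg/s.
    """

    condition: str
    observer_id: str
    blocks: tuple
    travel_distance: float = TRAVEL_DISTANCE

    def __post_init__(self):
        if self.condition not in ("predictable", "unpredictable"):
            raise ValueError(
                f"unknown condition {self.condition!r}; "
                "valid values are 'predictable' and 'unpredictable'"
            )
        for block in self.blocks:
            for vr, vl in block:
                if vr != RIGHTWARD_VELOCITY:
                    raise ValueError("rightward velocity must be 16 deg/s")
                if vl not in LEFTWARD_VELOCITIES:
                    raise ValueError(
                        f"leftward velocity {vl} not in {LEFTWARD_VELOCITIES}"
                    )

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def trial_rows(self):
        """Yield (block_index, trial_index_in_block, leftward_velocity)."""
        for bi, block in enumerate(self.blocks):
            for ti, (_, vl) in enumerate(block):
                yield bi, ti, vl

    def leftward_velocities(self) -> np.ndarray:
        return np.array([vl for _, _, vl in self.trial_rows()])


def generate_stimulus_sequence(condition: str, observer_id: str,
                               seed) -> StimulusSequence:
    """Draw a block/trial structure for one observer.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  Identical
    seeds give identical sequences.
    """
    if condition not in ("predictable", "unpredictable"):
        raise ValueError(
            f"unknown condition {condition!r}; "
            "valid values are 'predictable' and 'unpredictable'"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vels = np.array(LEFTWARD_VELOCITIES)
    if condition == "predictable":
        order = rng.permutation(vels)
        blocks = tuple(
            tuple((RIGHTWARD_VELOCITY, float(v))
                  for _ in range(PREDICTABLE_TRIALS_PER_BLOCK))
            for v in order
        )
    else:
        blocks = []
        for _ in range(UNPREDICTABLE_BLOCKS):
            pool = np.repeat(vels, UNPREDICTABLE_REPEATS)
            rng.shuffle(pool)
            blocks.append(tuple((RIGHTWARD_VELOCITY, float(v)) for v in pool))
        blocks = tuple(blocks)
    return StimulusSequence(condition=condition, observer_id=observer_id,
                            blocks=blocks)


# ---------------------------------------------------------------------------
# target trajectory
# ---------------------------------------------------------------------------

@dataclass
class TargetTrajectory:
    """Piecewise-linear target trajectory on a 1 kHz grid.

    Times are in ms from session start; positions in deg, rightward positive.
    ``reversal_times`` holds the right-to-left reversal of each trial (one per
    trial, strictly increasing); ``ramp_start_times`` / ``trial_end_times``
    bracket each trial's rightward ramp start and leftward ramp end.
    """

    t: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    reversal_times: np.ndarray
    ramp_start_times: np.ndarray
    trial_end_times: np.ndarray
    trial_block: np.ndarray
    trial_in_block: np.ndarray
    leftward_velocity: np.ndarray
    travel_distance: float = TRAVEL_DISTANCE


def render_target_trajectory(seq: StimulusSequence) -> TargetTrajectory:
    """Render the triangular waveform for a whole session.

    Blocks are separated by a stationary gap of ``BLOCK_GAP_MS``.  Each
    rightward ramp lasts ``24/16`` s; each leftward ramp ``24/v_left`` s, with
    no pause between ramps.
    """
    half = seq.travel_distance / 2.0
    bp_t = [0.0]
    bp_x = [-half]
    reversal_times, ramp_starts, trial_ends = [], [], []
    trial_block, trial_in_block, left_v = [], [], []
    t_cursor = 0.0
    for bi, block in enumerate(seq.blocks):
        for ti, (vr, vl) in enumerate(block):
            ramp_starts.append(t_cursor)
            right_dur = seq.travel_distance / vr * 1000.0
            t_cursor += right_dur
            bp_t.append(t_cursor)
            bp_x.append(half)
            reversal_times.append(t_cursor)
            left_dur = seq.travel_distance / vl * 1000.0
            t_cursor += left_dur
            bp_t.append(t_cursor)
            bp_x.append(-half)
            trial_ends.append(t_cursor)
            trial_block.append(bi)
            trial_in_block.append(ti)
            left_v.append(vl)
        t_cursor += BLOCK_GAP_MS
        bp_t.append(t_cursor)
        bp_x.append(-half)

    if not reversal_times:
        z = np.zeros(0)
        return TargetTrajectory(
            t=z, position=z, velocity=z, reversal_times=z,
            ramp_start_times=z, trial_end_times=z,
            trial_block=np.zeros(0, dtype=int),
            trial_in_block=np.zeros(0, dtype=int), leftward_velocity=z,
            travel_distance=seq.travel_distance)
    n = int(math.floor(t_cursor)) + 1
    t = np.arange(n, dtype=float)
    bp_t = np.asarray(bp_t)
    bp_x = np.asarray(bp_x)
    position = np.interp(t, bp_t, bp_x)
    slopes = np.diff(bp_x) / np.diff(bp_t) * 1000.0  # deg/s per segment
    seg = np.clip(np.searchsorted(bp_t, t, side="right") - 1, 0, len(slopes) - 1)
    velocity = slopes[seg]
    return TargetTrajectory(
        t=t, position=position, velocity=velocity,
        reversal_times=np.asarray(reversal_times),
        ramp_start_times=np.asarray(ramp_starts),
        trial_end_times=np.asarray(trial_ends),
        trial_block=np.asarray(trial_block, dtype=int),
        trial_in_block=np.asarray(trial_in_block, dtype=int),
        leftward_velocity=np.asarray(left_v),
        travel_distance=seq.travel_distance,
    )


# ---------------------------------------------------------------------------
# generative behavioral model
# ---------------------------------------------------------------------------

@dataclass
class SimModel:
    """Generative twin of the trial-history mixed model plus trace parameters.

    The eye-reversal timing of trial *n* within a block is

    ``T_n = beta0 + b_obs + sum_k beta_stim[k] * V_{n-k}
                 + sum_k beta_behav[k] * T_{n-k} + eps_n``

    with ``b_obs ~ N(0, subject_intercept_sd^2)`` drawn once per observer and
    ``eps_n ~ N(0, noise_sd^2)``.  History never crosses block boundaries;
    missing lags at the start of a block contribute zero (truncated sums) and
    those trials are flagged as burn-in.

    Defaults reproduce the study conditions: history weights at the scale of
    the fitted group-level model, residual noise ~30 ms, pursuit gain slightly
    below 1, and sparse catch-up saccades.
    """

    beta0: float = 30.620  # ms
    subject_intercept_sd: float = 10.0  # ms
    beta_stim: tuple = (-0.096, -0.417, -0.215, 0.034, -0.074)  # ms/(deg/s)
    beta_behav: tuple = (0.078, 0.093, 0.029, 0.001, 0.029)  # dimensionless
    noise_sd: float = 30.0  # ms
    pursuit_gain: float = 0.95
    saccade_rate: float = 1.0  # per second of tracking
    saccade_amplitude_range: tuple = (0.5, 2.5)  # deg
    saccade_duration_range: tuple = (20.0, 40.0)  # ms
    position_noise_sd: float = 0.05  # deg
    onset_lead_range: tuple = (100.0, 250.0)  # ms before the eye reversal
    seed: int = 0

    def __post_init__(self):
        if min(self.subject_intercept_sd, self.noise_sd,
               self.position_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 < self.pursuit_gain <= 1.2):
            raise ValueError("pursuit_gain must be in (0, 1.2]")
        if len(self.beta_stim) > 5 or len(self.beta_behav) > 5:
            raise ValueError("at most 5 history lags are supported")
        if sum(abs(b) for b in self.beta_behav) >= 1:
            warnings.warn(
                "sum |beta_behav| >= 1: the behavioral-history recursion "
                "may be nonstationary", RuntimeWarning)


def simulate_reversal_timings(seq: StimulusSequence, model: SimModel,
                              rng=None) -> np.ndarray:
    """Draw one eye-reversal timing (ms, 0 = target reversal) per trial.

    The per-observer random intercept is drawn first from ``rng`` so that one
    generator per observer yields independent intercepts.  History resets at
    every block boundary.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    b_obs = rng.normal(0.0, model.subject_intercept_sd)
    ks, kb = len(model.beta_stim), len(model.beta_behav)
    out = []
    for block in seq.blocks:
        v = [vl for _, vl in block]
        t_hist: list = []
        for j in range(len(block)):
            mu = model.beta0 + b_obs
            for k in range(1, ks + 1):
                if j - k >= 0:
                    mu += model.beta_stim[k - 1] * v[j - k]
            for k in range(1, kb + 1):
                if j - k >= 0:
                    mu += model.beta_behav[k - 1] * t_hist[j - k]
            tj = mu + rng.normal(0.0, model.noise_sd)
            t_hist.append(tj)
        out.extend(t_hist)
    return np.asarray(out)


def burn_in_flags(seq: StimulusSequence, model: SimModel) -> np.ndarray:
    """True for trials whose generating history sums were truncated."""
    k = max(len(model.beta_stim), len(model.beta_behav))
    return np.array([ti < k for _, ti, _ in seq.trial_rows()])


# ---------------------------------------------------------------------------
# eye-trace synthesis
# ---------------------------------------------------------------------------

@dataclass
class SessionTrace:
    """Whole-session eye and target positions on the 1 kHz grid (ms, deg)."""

    t: np.ndarray
    eye_position: np.ndarray
    target_position: np.ndarray


@dataclass
class GroundTruth:
    """Constructed event times for a simulated session.

    ``true_onset_time`` / ``true_reversal_time`` are signed ms relative to
    each trial's target reversal.  ``saccade_intervals`` are absolute
    (start, end) ms.  ``usable`` is False where the requested reversal timing
    could not be embedded in the trial's time span.
    """

    true_reversal_time: np.ndarray
    true_onset_time: np.ndarray
    saccade_intervals: list
    usable: np.ndarray


def min_jerk_step(amplitude: float, duration_ms: float,
                  dt_ms: float = DT_MS) -> np.ndarray:
    """Minimum-jerk position step: smooth, with bounded peak acceleration."""
    n = max(int(round(duration_ms / dt_ms)), 2)
    tau = np.linspace(0.0, 1.0, n + 1)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def _raised_cosine_crossing(v_from: float, v_to: float, t_start: float,
                            t_zero: float) -> float:
    """End time of a raised-cosine ramp v_from -> -v_to crossing 0 at t_zero.

    v(t) = (v_from+v_to)/2 * cos(pi*(t-t_start)/(t_end-t_start))
           + (v_from-v_to)/2, with v_from, v_to > 0.
    """
    theta = math.acos((v_to - v_from) / (v_from + v_to))
    return t_start + (t_zero - t_start) * math.pi / theta


def synthesize_eye_trace(traj: TargetTrajectory, timings,
                         model: SimModel, rng=None):
    """Build a full-session eye trace realizing the given reversal timings.

    Returns ``(SessionTrace, GroundTruth)``.  Steady-state eye velocity is
    ``pursuit_gain`` times target velocity; around each right-to-left target
    reversal the eye velocity follows a single raised-cosine sweep from the
    rightward steady state to the leftward one whose zero crossing falls
    exactly at the trial's requested timing.  Catch-up saccades are injected
    as minimum-jerk position steps and Gaussian position noise is added.
    """
    timings = np.asarray(timings, dtype=float)
    n_trials = len(traj.reversal_times)
    if len(timings) != n_trials:
        raise ValueError("need exactly one reversal timing per trial")
    rng = np.random.default_rng(model.seed + 1) if rng is None else rng

    t = traj.t
    if n_trials == 0:
        empty = np.zeros(0)
        return (SessionTrace(t=empty, eye_position=empty,
                             target_position=empty),
                GroundTruth(true_reversal_time=empty, true_onset_time=empty,
                            saccade_intervals=[], usable=np.zeros(0, bool)))

    g = model.pursuit_gain
    v_right = g * RIGHTWARD_VELOCITY
    vel = np.zeros_like(t)
    usable = np.ones(n_trials, dtype=bool)
    lead = rng.uniform(*model.onset_lead_range, size=n_trials)
    onset_rel = timings - lead

    # breakpoints of the eye-velocity profile, laid down trial by trial
    for i in range(n_trials):
        r = traj.reversal_times[i]
        start = traj.ramp_start_times[i]
        end = traj.trial_end_times[i]
        v_left = g * traj.leftward_velocity[i]
        a_t = r + onset_rel[i]           # true deceleration onset (abs ms)
        z_t = r + timings[i]             # true eye reversal (abs ms)
        b_t = _raised_cosine_crossing(v_right, v_left, a_t, z_t)
        # the sweep must fit between the steady phases of this trial
        if a_t < start + 400.0 or b_t > end - 150.0:
            usable[i] = False
            a_t = r - 150.0
            z_t = r
            b_t = _raised_cosine_crossing(v_right, v_left, a_t, z_t)
        i0, i1 = int(math.ceil(a_t)), int(math.floor(b_t))
        # rightward steady phase: from the reactive ramp of the previous
        # transition (handled below) up to the sweep start
        j0 = int(math.ceil(start))
        vel[j0:i0] = v_right
        phase = np.pi * (t[i0:i1 + 1] - a_t) / (b_t - a_t)
        vel[i0:i1 + 1] = ((v_right + v_left) / 2.0 * np.cos(phase)
                          + (v_right - v_left) / 2.0)
        j1 = int(math.ceil(end))
        vel[i1 + 1:j1] = -v_left

    # reactive transitions at every leftward-ramp end (and block starts):
    # the eye follows the new ramp only after a latency, via a smooth ramp
    for i in range(n_trials):
        end = traj.trial_end_times[i]
        last_in_block = (i == n_trials - 1
                         or traj.trial_block[i + 1] != traj.trial_block[i])
        v_old = -g * traj.leftward_velocity[i]
        v_new = 0.0 if last_in_block else v_right
        _blend_transition(vel, t, end, v_old, v_new)
    for i in range(n_trials):
        if traj.trial_in_block[i] == 0:
            _blend_transition(vel, t, traj.ramp_start_times[i], 0.0, v_right)

    dt_s = DT_MS / 1000.0
    eye = -traj.travel_distance / 2.0 + np.concatenate(
        [[0.0], np.cumsum(vel[:-1] + vel[1:]) / 2.0 * dt_s])

    # catch-up saccades: minimum-jerk steps toward the target
    saccade_intervals = []
    track_time_s = (traj.trial_end_times[-1] - traj.ramp_start_times[0]) / 1000.0
    n_sacc = rng.poisson(model.saccade_rate * track_time_s)
    sacc_t = np.sort(rng.uniform(traj.ramp_start_times[0] + 300.0,
                                 traj.trial_end_times[-1] - 300.0,
                                 size=n_sacc))
    for st in sacc_t:
        dur = rng.uniform(*model.saccade_duration_range)
        amp = rng.uniform(*model.saccade_amplitude_range)
        k = int(round(st))
        sign = np.sign(traj.position[k] - eye[k]) or 1.0
        step = min_jerk_step(sign * amp, dur)
        k1 = min(k + len(step), len(eye))
        eye[k:k1] += step[:k1 - k]
        eye[k1:] += sign * amp if k1 == k + len(step) else step[-1]
        saccade_intervals.append((float(k), float(k) + dur))

    if model.position_noise_sd > 0:
        eye = eye + rng.normal(0.0, model.position_noise_sd, size=len(eye))

    trace = SessionTrace(t=t.copy(), eye_position=eye,
                         target_position=traj.position.copy())
    truth = GroundTruth(true_reversal_time=timings.copy(),
                        true_onset_time=onset_rel,
                        saccade_intervals=saccade_intervals,
                        usable=usable)
    return trace, truth


def _blend_transition(vel: np.ndarray, t: np.ndarray, event_ms: float,
                      v_old: float, v_new: float) -> None:
    """Reactive raised-cosine transition v_old -> v_new after a latency."""
    a = event_ms + REACTIVE_LATENCY_MS
    b = a + REACTIVE_RAMP_MS
    i0, i1 = int(math.ceil(event_ms)), min(int(math.floor(b)), len(vel) - 1)
    if i0 >= len(vel):
        return
    seg_t = t[i0:i1 + 1]
    w = np.clip((seg_t - a) / (b - a), 0.0, 1.0)
    vel[i0:i1 + 1] = v_old + (v_new - v_old) * (1 - np.cos(np.pi * w)) / 2.0


# ---------------------------------------------------------------------------
# per-trial slicing
# ---------------------------------------------------------------------------

def split_into_trials(trace: SessionTrace, traj: TargetTrajectory,
                      pre_ms: float = 800.0, post_ms: float = 400.0):
    """Cut the session into per-trial eye traces aligned at target reversal.

    Returns a list of :class:`pursuithist.preprocess.EyeTrace` whose time axis
    is signed ms relative to the trial's right-to-left target reversal
    (nearest-sample alignment).
    """
    from .preprocess import EyeTrace

    out = []
    for r in traj.reversal_times:
        k = int(round(r))
        i0 = k - int(pre_ms)
        i1 = k + int(post_ms)
        if i0 < 0 or i1 >= len(trace.t):
            raise ValueError("trial window exceeds the session trace")
        out.append(EyeTrace(t=trace.t[i0:i1 + 1] - r,
                            position=trace.eye_position[i0:i1 + 1].copy()))
    return out
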