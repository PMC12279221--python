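"""Forward simulation of block-design fNIRS recordings and game telemetry.

The simulator is the package's ground-truth source: every downstream stage
(preprocessing, GLM, ROI means, connectivity, group statistics) is validated
by recovering parameters that the simulator planted.

Signal model, per channel:

* the ROI's per-condition amplitude (uM*mm) scales a canonical double-gamma
  impulse response convolved with the 30 s block boxcar, normalised so that
  the mean of the single-block response over the 10-35 s analysis window is
  exactly 1 — the amplitude parameter therefore *is* the windowed block mean
  the analysis pipeline estimates;
* structured noise is added in optical-density space: white sensor noise,
  cardiac (~1.1 Hz), respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz)
  sinusoids with random phase, a linear drift, and motion artifacts
  (spike + occasional step);
* the clean concentrations are pushed through the same forward modified
  Beer-Lambert map the pipeline inverts, and intensities are synthesised as
  I = baseline * exp(-OD).

The pinch-force game is simulated as an Ornstein-Uhlenbeck force trace
around the 70% MVC target; leaving the +/-10% MVC window resets the fork and
triggers a new grasp, and each feeding decision is wrong with a configurable
error probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .containers import (
    BlockLog,
    EventSchedule,
    GameLog,
    Montage,
    RecordingBundle,
    ROIS,
    GAMEPLAY_CONDITIONS,
    ValidationError,
    DEFAULT_SAMPLE_RATE,
    DEFAULT_WAVELENGTHS,
)
from .preprocess import MbllParams

__all__ = [
    "HrfShape", "NoiseSpec", "MotionSpec", "SimulationTruth",
    "ForceModelParams",
    "canonical_hrf", "block_response",
    "simulate_recording", "simulate_game_log",
    "default_amplitudes",
]


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfShape:
    """Canonical double-gamma impulse response: gamma(peak_delay) minus
    undershoot_ratio * gamma(undershoot_delay), unit scale in seconds."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise in OD units. Frequencies must stay below Nyquist
    (3.905 Hz at the 7.81 Hz default sampling rate)."""

    white_sd: float = 0.002
    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.010
    respiratory_hz: float = 0.25
    respiratory_amp: float = 0.005
    mayer_hz: float = 0.1
    mayer_amp: float = 0.005
    drift_slope_per_s: float = 1e-5

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        for name, f in (("cardiac", self.cardiac_hz),
                        ("respiratory", self.respiratory_hz),
                        ("mayer", self.mayer_hz)):
            if not 0 < f < nyq:
                raise ValidationError(
                    f"{name} frequency {f} Hz outside (0, Nyquist={nyq})")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(white_sd=0.0, cardiac_amp=0.0, respiratory_amp=0.0,
                   mayer_amp=0.0, drift_slope_per_s=0.0)


@dataclass(frozen=True)
class MotionSpec:
    """Motion artifacts: Poisson spikes (sharp exponential transients) of
    which half leave a persistent baseline step — the artifact classes the
    wavelet stage targets."""

    rate_per_min: float = 0.5
    amplitude: float = 0.02
    spike_decay_s: float = 0.4
    step_fraction: float = 0.5

    @classmethod
    def none(cls) -> "MotionSpec":
        return cls(rate_per_min=0.0, amplitude=0.0)


def default_amplitudes(hbo: float = 40.0) -> pd.DataFrame:
    """Equal HbO response amplitude (uM*mm) for every ROI and condition."""
    return pd.DataFrame(hbo, index=list(ROIS), columns=list(GAMEPLAY_CONDITIONS))


@dataclass
class SimulationTruth:
    """Everything the forward model needs, and hence everything downstream
    recovery can be checked against.

    amp_hbo / amp_hbr are ROI x condition tables in uM*mm; amp_hbr defaults
    to -amp_hbo / 3, the typical physiological HbR:HbO ratio.
    subject_gain_sd is the between-subject multiplicative amplitude spread
    (lognormal sigma) used by study-level simulations; the paper-scale
    tables report group means and SEs only, so this spread is a free,
    documented simulation parameter.
    """

    amp_hbo: pd.DataFrame = field(default_factory=default_amplitudes)
    amp_hbr: pd.DataFrame | None = None
    hrf: HrfShape = HrfShape()
    noise: NoiseSpec = NoiseSpec()
    motion: MotionSpec = MotionSpec()
    subject_gain_sd: float = 0.15
    baseline_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amp_hbr is None:
            self.amp_hbr = -self.amp_hbo / 3.0
        for tbl, name in ((self.amp_hbo, "amp_hbo"), (self.amp_hbr, "amp_hbr")):
            missing = set(ROIS) - set(tbl.index)
            if missing:
                raise ValidationError(f"{name} is missing ROIs: {sorted(missing)}")

    def with_seed(self, seed: int) -> "SimulationTruth":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# Canonical response
# ---------------------------------------------------------------------------

def canonical_hrf(t: np.ndarray, shape: HrfShape = HrfShape()) -> np.ndarray:
    """Double-gamma impulse response evaluated at times t (s), zero for t<0."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, shape.peak_delay_s) \
        - shape.undershoot_ratio * gamma_dist.pdf(t, shape.undershoot_delay_s)
    return np.where(t < 0, 0.0, h)


def block_response(dt: float, block_s: float = 30.0,
                   shape: HrfShape = HrfShape(),
                   window: tuple[float, float] = (10.0, 35.0),
                   kernel_s: float = 45.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-block response b = boxcar(block_s) * hrf on a dt grid.

    Returns (tau, b, norm) where b has been divided by norm = mean of the raw
    response over the analysis window, so mean(b[window]) == 1 and an
    amplitude A planted in the simulator equals the windowed block mean that
    the analysis pipeline reports.
    """
    tk = np.arange(0.0, kernel_s, dt)
    h = canonical_hrf(tk, shape)
    box = np.ones(int(round(block_s / dt)))
    b = np.convolve(box, h) * dt
    tau = np.arange(b.size) * dt
    sel = (tau >= window[0]) & (tau <= window[1])
    norm = float(b[sel].mean())
    if norm == 0:
        raise ValidationError("degenerate canonical response (zero window mean)")
    return tau, b / norm, norm


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _condition_drive(schedule: EventSchedule, timestamps: np.ndarray,
                     condition: str, dt: float, shape: HrfShape) -> np.ndarray:
    """Superposed normalised block responses of one condition on the grid."""
    drive = np.zeros(timestamps.size)
    for ev in schedule.of_condition(condition):
        tau, b, _ = block_response(dt, block_s=ev.duration, shape=shape)
        i0 = int(np.searchsorted(timestamps, ev.onset))
        n = min(b.size, timestamps.size - i0)
        if n > 0:
            drive[i0:i0 + n] += b[:n]
    return drive


def simulate_recording(montage: Montage, schedule: EventSchedule,
                       truth: SimulationTruth,
                       sample_rate: float = DEFAULT_SAMPLE_RATE,
                       duration_s: float | None = None,
                       mbll: MbllParams | None = None,
                       rng: np.random.Generator | None = None) -> RecordingBundle:
    """Forward-simulate a raw-intensity recording.

    Ground-truth HbO/HbR concentration traces (uM*mm) and the truth object
    are stored in ``bundle.meta['truth']`` for recovery tests.
    """
    truth.noise.validate(sample_rate)
    if duration_s is None:
        duration_s = schedule.end
    if schedule.end > duration_s + 1e-9:
        raise ValidationError("schedule does not fit within recording duration")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    mbll = mbll or MbllParams()

    dt = 1.0 / sample_rate
    n = int(round(duration_s / dt))
    t = np.arange(n) * dt

    drives = {c: _condition_drive(schedule, t, c, dt, truth.hrf)
              for c in GAMEPLAY_CONDITIONS
              if len(schedule.of_condition(c)) > 0}

    ids = montage.channel_ids
    conc = np.zeros((n, len(ids), 2))  # (time, channel, [HbO, HbR])
    for ci, cid in enumerate(ids):
        roi = montage.roi_map[cid]
        for cond, drive in drives.items():
            conc[:, ci, 0] += float(truth.amp_hbo.loc[roi, cond]) * drive
            conc[:, ci, 1] += float(truth.amp_hbr.loc[roi, cond]) * drive

    # forward MBLL: OD(lambda) = eps(lambda,:) @ (c * d * ppf); conc already
    # carries the pathlength product, so only eps enters here.
    od_signal = np.einsum("wk,tck->tcw", mbll.extinction, conc)

    od_noise = np.zeros_like(od_signal)
    ns = truth.noise
    for ci in range(len(ids)):
        for wi in range(2):
            col = np.zeros(n)
            if ns.white_sd > 0:
                col += rng.normal(0.0, ns.white_sd, n)
            for f, a in ((ns.cardiac_hz, ns.cardiac_amp),
                         (ns.respiratory_hz, ns.respiratory_amp),
                         (ns.mayer_hz, ns.mayer_amp)):
                if a > 0:
                    col += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            if ns.drift_slope_per_s != 0:
                col += ns.drift_slope_per_s * rng.uniform(-1, 1) * t
            col += _motion_artifacts(n, dt, truth.motion, rng)
            od_noise[:, ci, wi] = col

    intensity = truth.baseline_intensity * np.exp(-(od_signal + od_noise))
    return RecordingBundle(
        timestamps=t, data=intensity, state="intensity",
        component_labels=tuple(float(w) for w in DEFAULT_WAVELENGTHS),
        montage=montage, sample_rate=sample_rate,
        meta={"truth": {"conc": conc, "params": truth, "schedule": schedule}},
    )


def _motion_artifacts(n: int, dt: float, motion: MotionSpec,
                      rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    if motion.rate_per_min <= 0 or motion.amplitude <= 0:
        return out
    expected = motion.rate_per_min * n * dt / 60.0
    for _ in range(rng.poisson(expected)):
        i0 = rng.integers(0, n)
        amp = motion.amplitude * (0.5 + rng.random()) * rng.choice([-1.0, 1.0])
        span = np.arange(n - i0)
        out[i0:] += amp * np.exp(-span * dt / motion.spike_decay_s)
        if rng.random() < motion.step_fraction:
            out[i0:] += 0.5 * amp
    return out


# ---------------------------------------------------------------------------
# Game simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceModelParams:
    """Ornstein-Uhlenbeck pinch-force model around the task target.

    target_fraction/tolerance_fraction define the allowed force window as a
    fraction of the subject's maximum voluntary contraction (MVC); the trace
    mean-reverts with rate ``reversion_rate`` (1/s) and diffuses with
    ``volatility`` (N/sqrt(s)).
    """

    target_fraction: float = 0.70
    tolerance_fraction: float = 0.10
    reversion_rate: float = 1.0
    volatility: float = 3.4
    sample_rate: float = 50.0
    regrasp_delay_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ValidationError("target_fraction must be in (0, 1]")
        if self.tolerance_fraction <= 0:
            raise ValidationError("tolerance_fraction must be positive")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")


def simulate_game_log(params: ForceModelParams, schedule: EventSchedule,
                      mvc: float, seed: int,
                      feeds_per_block: int = 5,
                      feed_error_prob: float = 0.2) -> GameLog:
    """Simulate the pinch-force feeding game over the gameplay blocks.

    In force-control (wFC) blocks the force trace follows an OU process
    around target_fraction * mvc; any excursion outside the +/- tolerance
    window resets the fork (ending the current hold) and a new grasp starts
    after a short delay. Blocks without force control record a single grasp
    and no force-window constraint. Feeding outcomes are Bernoulli with the
    given per-item error probability.
    """
    if mvc <= 0:
        raise ValidationError("mvc must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate
    target = params.target_fraction * mvc
    tol = params.tolerance_fraction * mvc

    blocks: dict[int, BlockLog] = {}
    for bid, ev in enumerate(schedule.gameplay_events):
        t0, t1 = ev.onset, ev.onset + ev.duration
        grasps = [t0]
        ft: list[float] = []
        fn: list[float] = []
        if ev.condition == "wFC":
            t = t0
            force = target
            while t < t1:
                ft.append(t)
                fn.append(max(force, 0.0))
                if abs(force - target) > tol:
                    # window violated: fork resets, re-grasp after a delay
                    t += params.regrasp_delay_s
                    if t >= t1:
                        break
                    grasps.append(t)
                    force = target
                    continue
                force += params.reversion_rate * (target - force) * dt \
                    + params.volatility * np.sqrt(dt) * rng.standard_normal()
                t += dt
        else:
            # no force window: a steady comfortable pinch, sampled sparsely
            tgrid = np.arange(t0, t1, 0.5)
            ft = list(tgrid)
            fn = list(np.full(tgrid.size, 0.3 * mvc))
        expected = rng.integers(0, 5, feeds_per_block)
        feeds = []
        for e in expected:
            if rng.random() < feed_error_prob:
                wrong = (int(e) + int(rng.integers(1, 5))) % 5
                feeds.append((wrong, int(e)))
            else:
                feeds.append((int(e), int(e)))
        blocks[bid] = BlockLog(block_id=bid, condition=ev.condition,
                               t_start=t0, t_end=t1,
                               force_t=np.array(ft), force_n=np.array(fn),
                               grasp_times=np.array(grasps), feeds=feeds)
    return GameLog(mvc=mvc, blocks=blocks)
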