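"""Hemodynamic response estimation by ordinary-least-squares deconvolution.

The response to each gameplay condition is modelled as a linear combination
of Gaussian basis functions (SD 1 s, spaced 1 s apart, centred from -5 s to
+35 s around block onset — 41 basis functions per condition at the
defaults). Each regressor is the superposition of its Gaussian over all
onsets of its condition; rest is the implicit baseline. Low-order Legendre
polynomials absorb residual drift (order 3 by default, set drift_order=0
for an intercept only).

Drift is modelled with a discrete-cosine basis whose cutoff matches the
band-pass high-pass edge (0.01 Hz -> 100 s period, the convention used by
fMRI GLMs). This matters: the band-pass removes the session-scale envelope
of the design (one condition occupies the first half of the session, the
other the second), and a low-order polynomial cannot absorb that removal,
which otherwise biases the recovered amplitudes of the later condition by
2-3%. A Legendre polynomial drift (``drift_basis="poly"``) is available for
Homer-style fits on unfiltered data.

In addition, when the data have been band-pass filtered the design can
carry one *filter-compensation* nuisance column per condition: the part of
the condition's canonical block drive (double-gamma response convolved
with the block boxcars) that the same zero-phase filter removes. Filtered
data are missing exactly this component of the evoked signal, and without
it the fit attributes the in-band attenuation (about 4.5% of the 1/60 Hz
block fundamental) to the task regressors, systematically shrinking the
second condition more than the first. The nuisance coefficient is
discarded after the fit; the response curves are reconstructed from the
task basis only.

Estimated responses are reconstructed from the (unfiltered) basis on an
onset-relative time axis, baseline-normalised by subtracting the mean over
the 5 s before onset, and summarised per ROI over the 10-35 s window where
the movement-induced response plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from .containers import (
    EventSchedule,
    GAMEPLAY_CONDITIONS,
    Montage,
    RecordingBundle,
    ROIS,
    ValidationError,
)

__all__ = ["GlmSpec", "DesignMatrix", "HRFEstimate", "ROIBlockStats",
           "build_design_matrix", "fit_glm", "roi_block_means"]


@dataclass(frozen=True)
class GlmSpec:
    """Gaussian-basis GLM configuration (times in seconds, onset-relative)."""

    t_min: float = -5.0
    t_max: float = 35.0
    basis_sd: float = 1.0
    basis_spacing: float = 1.0
    baseline_window: tuple[float, float] = (-5.0, 0.0)
    mean_window: tuple[float, float] = (10.0, 35.0)
    drift_basis: str = "cosine"
    drift_order: int = 3
    drift_high_pass_hz: float = 0.01
    filter_compensation: bool = True

    def __post_init__(self) -> None:
        if self.drift_basis not in ("cosine", "poly"):
            raise ValidationError("drift_basis must be 'cosine' or 'poly'")
        if self.drift_high_pass_hz <= 0:
            raise ValidationError("drift_high_pass_hz must be positive")
        if not self.t_min < 0 < self.t_max:
            raise ValidationError("require t_min < 0 < t_max")
        if self.basis_sd <= 0 or self.basis_spacing <= 0:
            raise ValidationError("basis_sd and basis_spacing must be positive")
        for w in (self.baseline_window, self.mean_window):
            if not (self.t_min - 1e-9 <= w[0] < w[1] <= self.t_max + 1e-9):
                raise ValidationError(f"window {w} outside [t_min, t_max]")
        if self.drift_order < 0:
            raise ValidationError("drift_order must be >= 0")

    @property
    def basis_centers(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + self.basis_spacing / 2,
                         self.basis_spacing)


@dataclass
class DesignMatrix:
    """OLS design: task columns (condition x basis centre) then drift."""

    X: np.ndarray
    columns: list[tuple]          # ("task", condition, centre) | ("drift", order)
    conditions: tuple[str, ...]
    spec: GlmSpec
    timestamps: np.ndarray
    _pinv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def pinv(self) -> np.ndarray:
        """Cached Moore-Penrose pseudo-inverse (the design is reused across
        the subjects of a study, the SVD is not)."""
        if self._pinv is None:
            self._pinv = np.linalg.pinv(self.X)
        return self._pinv

    @property
    def n_task_columns(self) -> int:
        return sum(1 for c in self.columns if c[0] == "task")

    def task_slice(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.columns)
               if c[0] == "task" and c[1] == condition]
        return np.asarray(idx)


def build_design_matrix(schedule: EventSchedule, spec: GlmSpec,
                        timestamps: np.ndarray,
                        conditions: tuple[str, ...] | None = None,
                        compensate_band: tuple | None = None) -> DesignMatrix:
    """One regressor per (condition, basis centre): the Gaussian summed over
    that condition's onsets, plus drift columns.

    With two conditions there are 2 x 41 task columns at the defaults; the
    polynomial drift mode adds drift_order + 1 columns (86 total at order 3),
    the cosine mode an intercept plus ceil(2 T f_cut) cosines.

    ``compensate_band=(low_hz, high_hz, order, fs)`` adds one
    filter-compensation nuisance column per condition (see module notes);
    pass it when the data to be fitted went through that band-pass.
    """
    t = np.asarray(timestamps, dtype=float)
    if conditions is None:
        conditions = tuple(c for c in GAMEPLAY_CONDITIONS
                           if len(schedule.of_condition(c)) > 0)
    if not conditions:
        raise ValidationError("no gameplay events to model")
    for c in conditions:
        if len(schedule.of_condition(c)) == 0:
            raise ValidationError(f"no events for modelled condition {c!r}")

    centers = spec.basis_centers
    cols: list[np.ndarray] = []
    names: list[tuple] = []
    for cond in conditions:
        onsets = np.array([e.onset for e in schedule.of_condition(cond)])
        # (time, centre) Gaussian bank summed over onsets
        lag = t[:, None, None] - onsets[None, :, None] - centers[None, None, :]
        bank = np.exp(-0.5 * (lag / spec.basis_sd) ** 2).sum(axis=1)
        for k, mu in enumerate(centers):
            cols.append(bank[:, k])
            names.append(("task", cond, float(mu)))
    if compensate_band is not None and spec.filter_compensation:
        from scipy.signal import butter, sosfiltfilt
        from .synth import block_response
        low, high, order, fs = compensate_band
        sos = butter(order, [low, high], btype="bandpass", fs=fs,
                     output="sos")
        dt = float(np.mean(np.diff(t))) if t.size > 1 else 1.0
        for cond in conditions:
            drive = np.zeros(t.size)
            for ev in schedule.of_condition(cond):
                tau_b, b, _ = block_response(dt, block_s=ev.duration)
                i0 = int(np.searchsorted(t, ev.onset))
                nfit = min(b.size, t.size - i0)
                if nfit > 0:
                    drive[i0:i0 + nfit] += b[:nfit]
            removed = drive - sosfiltfilt(sos, drive)
            cols.append(removed)
            names.append(("nuisance", cond))

    span = (t[-1] - t[0]) if t.size > 1 else 1.0
    if spec.drift_basis == "poly":
        # Legendre drift columns on [-1, 1]
        x = 2 * (t - t[0]) / span - 1
        for order in range(spec.drift_order + 1):
            coef = np.zeros(order + 1)
            coef[order] = 1.0
            cols.append(legendre.legval(x, coef))
            names.append(("drift", order))
    else:
        # discrete-cosine drift up to the high-pass cutoff
        n_cos = int(np.ceil(2 * span * spec.drift_high_pass_hz))
        cols.append(np.ones_like(t))
        names.append(("drift", 0))
        for k in range(1, n_cos + 1):
            cols.append(np.cos(np.pi * k * (t - t[0]) / span))
            names.append(("drift", k))

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cond_num = np.linalg.cond(X)
        raise ValidationError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]} "
            f"columns, condition number {cond_num:.3g}); are two conditions "
            f"sharing identical onsets?")
    return DesignMatrix(X=X, columns=names, conditions=conditions,
                        spec=spec, timestamps=t)


@dataclass
class HRFEstimate:
    """Per-channel estimated responses on an onset-relative time axis.

    curves has shape (n_channels, n_conditions, 2 chromophores, n_tau) and is
    baseline-normalised (zero mean over the pre-onset baseline window).
    """

    time_axis: np.ndarray
    curves: np.ndarray
    betas: np.ndarray             # (n_channels, 2, n_columns)
    residual_var: np.ndarray      # (n_channels, 2)
    conditions: tuple[str, ...]
    montage: Montage
    pruned_channels: dict[str, str]
    spec: GlmSpec

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)


def fit_glm(rec: RecordingBundle, design: DesignMatrix) -> HRFEstimate:
    """Least-squares fit per channel and chromophore, then reconstruct the
    onset-relative response curves from the basis coefficients."""
    rec.require_state("concentration", "fit_glm")
    if design.X.shape[0] != rec.n_times:
        raise ValidationError("design matrix rows != number of samples")
    Y = rec.data.reshape(rec.n_times, -1)      # (T, channels*2)
    bad_cols = ~np.isfinite(Y).all(axis=0)
    if bad_cols.any():
        idx = np.where(bad_cols)[0]
        chans = sorted({rec.montage.channel_ids[i // 2] for i in idx})
        raise ValidationError(f"non-finite values in channels {chans}")

    X = design.X
    beta = design.pinv() @ Y
    resid = Y - X @ beta
    dof = max(rec.n_times - X.shape[1], 1)
    residual_var = (resid ** 2).sum(axis=0) / dof

    spec = design.spec
    dt = rec.dt
    tau = np.arange(spec.t_min, spec.t_max + dt / 2, dt)
    centers = spec.basis_centers
    G = np.exp(-0.5 * ((tau[:, None] - centers[None, :]) / spec.basis_sd) ** 2)

    n_ch = rec.n_channels
    curves = np.empty((n_ch, len(design.conditions), 2, tau.size))
    beta_cc = beta.reshape(X.shape[1], n_ch, 2)
    for j, cond in enumerate(design.conditions):
        sl = design.task_slice(cond)
        # (tau, centres) @ (centres, channels, chrom) -> (tau, ch, chrom)
        rec_curve = np.tensordot(G, beta_cc[sl], axes=(1, 0))
        curves[:, j] = np.moveaxis(rec_curve, 0, -1)

    curves = baseline_normalize(curves, tau, spec.baseline_window)
    return HRFEstimate(
        time_axis=tau, curves=curves,
        betas=np.moveaxis(beta_cc, 0, -1),
        residual_var=residual_var.reshape(n_ch, 2),
        conditions=design.conditions, montage=rec.montage,
        pruned_channels=dict(rec.pruned_channels), spec=spec)


def baseline_normalize(curves: np.ndarray, tau: np.ndarray,
                       window: tuple[float, float]) -> np.ndarray:
    """Subtract each curve's mean over the pre-onset window (idempotent)."""
    sel = (tau >= window[0]) & (tau < window[1])
    if not sel.any():
        raise ValidationError("baseline window contains no samples")
    return curves - curves[..., sel].mean(axis=-1, keepdims=True)


@dataclass
class ROIBlockStats:
    """Windowed ROI block means (uM*mm): ROI x condition tables for HbO and
    HbR, with the channel count actually used per ROI. ROIs whose channels
    were all pruned are NaN and listed in ``missing``."""

    mean_hbo: pd.DataFrame
    mean_hbr: pd.DataFrame
    n_channels_used: dict[str, int]
    missing: tuple[str, ...]


def roi_block_means(est: HRFEstimate, montage: Montage | None = None,
                    spec: GlmSpec | None = None) -> ROIBlockStats:
    """Average unpruned channel curves within each ROI, then average over the
    10-35 s analysis window."""
    montage = montage or est.montage
    spec = spec or est.spec
    tau = est.time_axis
    dtau = tau[1] - tau[0] if tau.size > 1 else 0.0
    if tau[-1] < spec.mean_window[1] - dtau - 1e-9:
        raise ValidationError("estimate does not cover the analysis window")
    sel = (tau >= spec.mean_window[0]) & (tau <= spec.mean_window[1])
    pruned = set(est.pruned_channels)
    ids = montage.channel_ids

    hbo = pd.DataFrame(np.nan, index=list(ROIS), columns=list(est.conditions))
    hbr = hbo.copy()
    used: dict[str, int] = {}
    missing: list[str] = []
    for roi in ROIS:
        ch_idx = [ids.index(c) for c in montage.roi_channels(roi)
                  if c not in pruned]
        used[roi] = len(ch_idx)
        if not ch_idx:
            missing.append(roi)
            continue
        roi_curves = est.curves[ch_idx].mean(axis=0)   # (cond, chrom, tau)
        win = roi_curves[..., sel].mean(axis=-1)       # (cond, chrom)
        hbo.loc[roi] = win[:, 0]
        hbr.loc[roi] = win[:, 1]
    return ROIBlockStats(mean_hbo=hbo, mean_hbr=hbr, n_channels_used=used,
                         missing=tuple(missing))
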