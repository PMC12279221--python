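"""ROI-pair functional connectivity and the two network summary features.

For each subject, condition and chromophore, Pearson correlations between
the 8 ROI-averaged concentration series (restricted to that condition's
gameplay samples) give an 8x8 matrix; Fisher's z = atanh(r) stabilises the
distribution. Two scalar features summarise each network over the 28 unique
ROI pairs:

* connection ratio (CR): fraction of pairs with \\|z\\| above a threshold
  (0.7 by default);
* connection strength (CS): mean \\|z\\| over the pairs.

Group-level display matrices are the across-subject mean z mapped back to r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    EventSchedule,
    Montage,
    RecordingBundle,
    ROIS,
    ValidationError,
)

__all__ = ["ConnectivityMatrix", "NetworkFeatures", "roi_timeseries",
           "roi_correlation", "network_features", "group_mean_matrix",
           "Z_CLIP", "DEFAULT_Z_THRESHOLD"]

Z_CLIP = 1.0 - 1e-7
DEFAULT_Z_THRESHOLD = 0.7


@dataclass
class ConnectivityMatrix:
    """8x8 Pearson (r) and Fisher-z matrices for one network.

    Pairs involving a zero-variance (or pruned-empty) ROI are NaN and are
    excluded from the features.
    """

    r: pd.DataFrame
    z: pd.DataFrame
    chromophore: str = ""
    condition: str = ""
    subject: str = ""

    @property
    def offdiag_z(self) -> np.ndarray:
        """Unique off-diagonal z values (upper triangle), NaNs included."""
        m = self.z.to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]


@dataclass(frozen=True)
class NetworkFeatures:
    """Connection strength (mean |z|) and connection ratio (fraction of
    pairs whose |z| exceeds the threshold)."""

    cs: float
    cr: float
    threshold: float = DEFAULT_Z_THRESHOLD
    n_pairs: int = 28

    def __post_init__(self) -> None:
        if not (0 <= self.cr <= 1) or self.cs < 0:
            raise ValidationError("invalid network features")


def roi_timeseries(rec: RecordingBundle, chromophore: str,
                   montage: Montage | None = None) -> pd.DataFrame:
    """Time x ROI table of ROI-averaged concentration, skipping pruned
    channels; ROIs with no usable channel become NaN columns."""
    rec.require_state("concentration", "roi_timeseries")
    montage = montage or rec.montage
    comp = rec.component_index(chromophore)
    ids = montage.channel_ids
    active = rec.active_mask
    out = {}
    for roi in ROIS:
        idx = [ids.index(c) for c in montage.roi_channels(roi)
               if active[ids.index(c)]]
        out[roi] = rec.data[:, idx, comp].mean(axis=1) if idx \
            else np.full(rec.n_times, np.nan)
    return pd.DataFrame(out, index=rec.timestamps)


def roi_correlation(roi_series: pd.DataFrame,
                    condition_mask: np.ndarray | None = None,
                    **labels) -> ConnectivityMatrix:
    """Pearson r over the masked samples for every ROI pair, then Fisher z
    with |r| clipped just below 1 so the transform stays finite."""
    data = roi_series.to_numpy()
    if condition_mask is not None:
        data = data[np.asarray(condition_mask, bool)]
    if data.shape[0] < 8:
        raise ValidationError(
            f"need at least 8 samples per ROI pair, got {data.shape[0]}")
    rois = list(roi_series.columns)
    sd = np.nanstd(data, axis=0)
    valid = np.isfinite(sd) & (sd > 0)
    r = np.full((len(rois), len(rois)), np.nan)
    if valid.any():
        r_valid = np.corrcoef(data[:, valid], rowvar=False)
        r[np.ix_(valid, valid)] = np.atleast_2d(r_valid)
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    idx = pd.Index(rois)
    return ConnectivityMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        z=pd.DataFrame(z, index=idx, columns=idx),
        **labels)


def network_features(m: ConnectivityMatrix,
                     threshold: float = DEFAULT_Z_THRESHOLD) -> NetworkFeatures:
    """CR and CS over the unique off-diagonal pairs.

    Undefined (NaN) pairs are excluded from both numerator and denominator;
    with all 8 ROIs defined the denominator is the standard 28.
    """
    z = m.offdiag_z
    defined = np.isfinite(z)
    if not defined.any():
        raise ValidationError("all ROI pairs undefined — no features")
    zd = np.abs(z[defined])
    return NetworkFeatures(cs=float(zd.mean()),
                           cr=float((zd > threshold).mean()),
                           threshold=threshold, n_pairs=int(defined.sum()))


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Across-subject mean Fisher-z matrix, back-transformed to r for
    display (the group heatmaps)."""
    if not matrices:
        raise ValidationError("no matrices to average")
    z = np.nanmean(np.stack([m.z.to_numpy() for m in matrices]), axis=0)
    idx = matrices[0].z.index
    return ConnectivityMatrix(
        r=pd.DataFrame(np.tanh(z), index=idx, columns=idx),
        z=pd.DataFrame(z, index=idx, columns=idx),
        chromophore=matrices[0].chromophore,
        condition=matrices[0].condition, subject="group-mean")


def condition_connectivity(rec: RecordingBundle, schedule: EventSchedule,
                           condition: str, chromophore: str,
                           subject: str = "") -> ConnectivityMatrix:
    """Convenience: ROI series -> condition-masked correlation matrix for the
    concatenated gameplay blocks of one condition."""
    series = roi_timeseries(rec, chromophore)
    mask = schedule.condition_mask(rec.timestamps, condition)
    return roi_correlation(series, mask, chromophore=chromophore,
                           condition=condition, subject=subject)
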