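"""Group-level report tables and figures.

Mirrors the study's published table structure:

* game performance per group with Mann-Whitney group comparisons;
* one ROI response table per group x chromophore (wFC and woFC means with
  SEs, Wilcoxon signed-rank raw p, BH-adjusted p — the 8 ROI comparisons of
  a table form one BH family);
* network features (CS/CR) per group, condition and chromophore with
  Wilcoxon wFC-vs-woFC comparisons;
* Spearman correlations between game scores and ROI responses.

All tables are plain pandas DataFrames; ``write_tables`` saves them as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GAMEPLAY_CONDITIONS, ROIS, ValidationError
from .connectivity import ConnectivityMatrix
from .stats import (TestResult, adjust_family, mann_whitney, spearman,
                    wilcoxon_signed_rank)
from .study import StudyData

__all__ = ["roi_response_table", "game_performance_table",
           "network_feature_table", "game_roi_correlations",
           "build_reports", "write_tables", "plot_connectivity_heatmap"]

GAME_METRICS = ("grasps", "force_cov", "memory_accuracy")


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else float("nan")
    return float(v.mean()), float(se)


def roi_response_table(study: StudyData, group: str, chromophore: str,
                       q: float = 0.05) -> pd.DataFrame:
    """wFC/woFC mean (SE) per ROI plus Wilcoxon raw and BH-adjusted p.

    Columns are the 8 ROIs; the 8 comparisons form one BH family.
    """
    df = study.roi_means.query(
        "group == @group and chromophore == @chromophore")
    if df.empty:
        raise ValidationError(f"no data for group={group!r}, "
                              f"chromophore={chromophore!r}")
    results: list[TestResult] = []
    out: dict[str, list[float]] = {}
    for roi in ROIS:
        wide = df[df["roi"] == roi].pivot(index="subject",
                                          columns="condition", values="value")
        if not set(GAMEPLAY_CONDITIONS).issubset(wide.columns):
            raise ValidationError(f"both conditions required for ROI {roi}")
        wfc = wide["wFC"].to_numpy()
        wofc = wide["woFC"].to_numpy()
        res = wilcoxon_signed_rank(wfc, wofc)
        results.append(res)
        m1, s1 = _mean_se(wfc)
        m0, s0 = _mean_se(wofc)
        out[roi] = [m1, s1, m0, s0, res.p_raw]
    adjust_family(results, family=f"{group}/{chromophore}", q=q)
    for roi, res in zip(ROIS, results):
        out[roi].append(res.p_adjusted if res.p_adjusted is not None
                        else float("nan"))
    return pd.DataFrame(
        out, index=["wFC mean", "wFC SE", "woFC mean", "woFC SE",
                    "p", "p adjusted"])


def game_performance_table(study: StudyData, q: float = 0.05) -> pd.DataFrame:
    """Per-group mean (SD) of the three game scores with Mann-Whitney
    group-comparison p (requires exactly two groups for the test column)."""
    groups = sorted(study.game["group"].unique())
    rows = []
    results: list[TestResult] = []
    for metric in GAME_METRICS:
        row: dict[str, float | str] = {"metric": metric}
        samples = []
        for g in groups:
            v = study.game.query("group == @g")[metric].to_numpy(float)
            v = v[np.isfinite(v)]
            samples.append(v)
            row[f"{g} mean"] = v.mean() if v.size else float("nan")
            row[f"{g} SD"] = v.std(ddof=1) if v.size > 1 else float("nan")
        if len(groups) == 2 and all(s.size for s in samples):
            res = mann_whitney(samples[0], samples[1])
            results.append(res)
            row["p"] = res.p_raw
        rows.append(row)
    if results:
        adjust_family(results, family="game", q=q)
        for row, res in zip(rows, results):
            row["p adjusted"] = res.p_adjusted
    return pd.DataFrame(rows).set_index("metric")


def network_feature_table(study: StudyData, q: float = 0.05) -> pd.DataFrame:
    """CS/CR mean (SE) per group x condition x chromophore with Wilcoxon
    wFC-vs-woFC p per feature (families: one per group x chromophore)."""
    rows = []
    for group in sorted(study.features["group"].unique()):
        for chrom in sorted(study.features["chromophore"].unique()):
            sub = study.features.query(
                "group == @group and chromophore == @chrom")
            wide = {c: sub[sub["condition"] == c].set_index("subject")
                    for c in GAMEPLAY_CONDITIONS}
            results = []
            row_block = []
            for feat in ("cs", "cr"):
                a = wide["wFC"][feat]
                b = wide["woFC"][feat].reindex(a.index)
                res = wilcoxon_signed_rank(a.to_numpy(), b.to_numpy())
                results.append(res)
                for cond in GAMEPLAY_CONDITIONS:
                    m, se = _mean_se(wide[cond][feat].to_numpy())
                    row_block.append({"group": group, "chromophore": chrom,
                                      "feature": feat, "condition": cond,
                                      "mean": m, "SE": se,
                                      "p": res.p_raw})
            adjust_family(results, family=f"net/{group}/{chrom}", q=q)
            for entry in row_block:
                feat_i = 0 if entry["feature"] == "cs" else 1
                entry["p adjusted"] = results[feat_i].p_adjusted
            rows.extend(row_block)
    return pd.DataFrame(rows)


def game_roi_correlations(study: StudyData, condition: str = "wFC",
                          chromophore: str = "HbO",
                          q: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each game score with each ROI response
    (subjects pooled across groups); one BH family per game metric."""
    roi = study.roi_means.query(
        "condition == @condition and chromophore == @chromophore")
    wide = roi.pivot(index="subject", columns="roi", values="value")
    game = study.game.set_index("subject").reindex(wide.index)
    rows = []
    for metric in GAME_METRICS:
        results = []
        for r in ROIS:
            pair = pd.DataFrame({"g": game[metric], "v": wide[r]}).dropna()
            res = spearman(pair["g"].to_numpy(), pair["v"].to_numpy())
            results.append(res)
        adjust_family(results, family=f"corr/{metric}", q=q)
        for r, res in zip(ROIS, results):
            rows.append({"metric": metric, "roi": r, "rho": res.statistic,
                         "p": res.p_raw, "p adjusted": res.p_adjusted,
                         "n": res.n})
    return pd.DataFrame(rows)


def build_reports(study: StudyData, q: float = 0.05) -> dict[str, pd.DataFrame]:
    """All report tables keyed by a short name; missing inputs leave gaps
    (e.g. no game table when the study carries no game data)."""
    tables: dict[str, pd.DataFrame] = {}
    if not study.game.empty:
        tables["game_performance"] = game_performance_table(study, q=q)
    for group in study.group_names():
        for chrom in ("HbO", "HbR"):
            key = f"roi_{chrom.lower()}_{group}"
            tables[key] = roi_response_table(study, group, chrom, q=q)
    if not study.features.empty:
        tables["network_features"] = network_feature_table(study, q=q)
    if not study.game.empty:
        tables["game_roi_correlations"] = game_roi_correlations(study, q=q)
    return tables


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, tbl in tables.items():
        p = outdir / f"{name}.csv"
        tbl.to_csv(p)
        paths.append(p)
    return paths


def plot_connectivity_heatmap(m: ConnectivityMatrix, ax=None, vmin=-1.0,
                              vmax=1.0):
    """Correlation-matrix heatmap with ROI tick labels (display aid for the
    group-mean matrices)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(m.r.to_numpy(), vmin=vmin, vmax=vmax, cmap="RdBu_r")
    ax.set_xticks(range(len(m.r.columns)), m.r.columns, rotation=45)
    ax.set_yticks(range(len(m.r.index)), m.r.index)
    title = " ".join(s for s in (m.chromophore, m.condition, m.subject) if s)
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
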