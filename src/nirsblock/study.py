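"""Subject-level pipeline orchestration and multi-subject simulation studies.

`analyze_subject` runs one recording through the full chain (prune -> OD ->
wavelet motion correction -> band-pass -> Beer-Lambert -> GLM -> ROI means).
`simulate_group_study` forward-simulates whole groups of subjects with known
ground truth and collects tidy per-subject tables (ROI block means, network
features, game scores) ready for the group statistics and report builders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    EventSchedule,
    GAMEPLAY_CONDITIONS,
    Montage,
    RecordingBundle,
    ROIS,
    default_montage,
    default_paradigm,
)
from .preprocess import MbllParams, PruneCriteria, run_pipeline
from .glm import DesignMatrix, GlmSpec, HRFEstimate, ROIBlockStats, \
    build_design_matrix, fit_glm, roi_block_means
from .connectivity import condition_connectivity, network_features
from .game_metrics import summarize_game
from .synth import ForceModelParams, SimulationTruth, simulate_game_log, \
    simulate_recording

__all__ = ["SubjectAnalysis", "StudyData", "analyze_subject",
           "simulate_subject", "simulate_group_study"]


@dataclass
class SubjectAnalysis:
    concentration: RecordingBundle
    estimate: HRFEstimate
    roi_stats: ROIBlockStats


def analyze_subject(rec: RecordingBundle, schedule: EventSchedule, *,
                    glm_spec: GlmSpec = GlmSpec(),
                    design: DesignMatrix | None = None,
                    prune: PruneCriteria | None = PruneCriteria(),
                    motion_correction: bool = True,
                    band: tuple[float, float] | None = (0.01, 0.1),
                    mbll: MbllParams | None = None) -> SubjectAnalysis:
    """Full single-subject chain from raw intensity to ROI block means.

    Pass a prebuilt ``design`` (shared timestamps and schedule) to avoid
    rebuilding the design matrix for every subject of a simulation study.
    """
    conc = run_pipeline(rec, prune=prune, motion_correction=motion_correction,
                        band=band, mbll=mbll)
    if design is None:
        cb = None
        if band is not None and glm_spec.filter_compensation:
            cb = (band[0], band[1], 3, rec.sample_rate)
        design = build_design_matrix(schedule, glm_spec, conc.timestamps,
                                     compensate_band=cb)
    est = fit_glm(conc, design)
    return SubjectAnalysis(concentration=conc, estimate=est,
                           roi_stats=roi_block_means(est))


def simulate_subject(truth: SimulationTruth, montage: Montage,
                     schedule: EventSchedule,
                     rng: np.random.Generator) -> RecordingBundle:
    """One simulated subject: a lognormal between-subject gain (sigma =
    ``truth.subject_gain_sd``, unit median) scales all response amplitudes,
    then the forward model adds that subject's noise realisation."""
    if truth.subject_gain_sd > 0:
        gain = float(rng.lognormal(0.0, truth.subject_gain_sd))
    else:
        gain = 1.0
    subj_truth = replace(truth, amp_hbo=truth.amp_hbo * gain,
                         amp_hbr=truth.amp_hbr * gain)
    return simulate_recording(montage, schedule, subj_truth, rng=rng)


@dataclass
class StudyData:
    """Tidy per-subject tables of a (simulated or real) group study."""

    roi_means: pd.DataFrame    # subject, group, condition, chromophore, roi, value
    features: pd.DataFrame     # subject, group, condition, chromophore, cs, cr
    game: pd.DataFrame         # subject, group, grasps, force_cov, memory_accuracy

    def group_names(self) -> list[str]:
        return sorted(self.roi_means["group"].unique())


def simulate_group_study(groups: dict[str, SimulationTruth],
                         n_per_group: int, seed: int, *,
                         montage: Montage | None = None,
                         schedule: EventSchedule | None = None,
                         glm_spec: GlmSpec = GlmSpec(),
                         with_connectivity: bool = True,
                         with_game: bool = True,
                         force_params: ForceModelParams = ForceModelParams(),
                         mvc: float = 50.0,
                         feed_error_prob: dict[str, float] | float = 0.2,
                         ) -> StudyData:
    """Simulate and analyse a full multi-group study.

    Each subject gets an independent RNG stream spawned from ``seed``; the
    design matrix is built once and shared across subjects.
    """
    montage = montage or default_montage()
    schedule = schedule or default_paradigm()
    ss = np.random.SeedSequence(seed)
    roi_rows, feat_rows, game_rows = [], [], []
    design: DesignMatrix | None = None
    for group, truth in groups.items():
        err = feed_error_prob.get(group) if isinstance(feed_error_prob, dict) \
            else feed_error_prob
        for i in range(n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            subject = f"{group}-{i:02d}"
            rec = simulate_subject(truth, montage, schedule, rng)
            if design is None:
                cb = (0.01, 0.1, 3, rec.sample_rate) \
                    if glm_spec.filter_compensation else None
                design = build_design_matrix(schedule, glm_spec,
                                             rec.timestamps,
                                             compensate_band=cb)
            ana = analyze_subject(rec, schedule, glm_spec=glm_spec,
                                  design=design)
            tables = {"HbO": ana.roi_stats.mean_hbo,
                      "HbR": ana.roi_stats.mean_hbr}
            for chrom, tbl in tables.items():
                for cond in tbl.columns:
                    for roi in ROIS:
                        roi_rows.append({
                            "subject": subject, "group": group,
                            "condition": cond, "chromophore": chrom,
                            "roi": roi, "value": float(tbl.loc[roi, cond])})
            if with_connectivity:
                for chrom in ("HbO", "HbR"):
                    for cond in GAMEPLAY_CONDITIONS:
                        m = condition_connectivity(
                            ana.concentration, schedule, cond, chrom,
                            subject=subject)
                        f = network_features(m)
                        feat_rows.append({
                            "subject": subject, "group": group,
                            "condition": cond, "chromophore": chrom,
                            "cs": f.cs, "cr": f.cr})
            if with_game:
                game_seed = int(child.generate_state(1, np.uint32)[0] >> 1)
                log = simulate_game_log(force_params, schedule, mvc=mvc,
                                        seed=game_seed,
                                        feed_error_prob=err)
                perf = summarize_game(log, condition="wFC")
                game_rows.append({
                    "subject": subject, "group": group,
                    "grasps": perf.grasps_per_loop,
                    "force_cov": perf.force_cov,
                    "memory_accuracy": perf.memory_accuracy})
    return StudyData(roi_means=pd.DataFrame(roi_rows),
                     features=pd.DataFrame(feat_rows),
                     game=pd.DataFrame(game_rows))
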