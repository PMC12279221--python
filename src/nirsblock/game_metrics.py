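"""Behavioural metrics from the pinch-force feeding game.

Three per-loop scores, aggregated per subject as the mean over loops:

* grasp count — how many times the fork was picked up in a loop (one grasp
  plus one per force-window violation);
* pinch-force coefficient of variation (COV) — sample SD / mean of the force
  trace while the fork is held (N/N, so unit-free);
* memory accuracy — correct feeds / total feeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GameLog, ValidationError

logger = logging.getLogger("nirsblock")

__all__ = ["GamePerformance", "grasp_count", "force_cov", "memory_accuracy",
           "block_metrics", "summarize_game"]


@dataclass(frozen=True)
class GamePerformance:
    """Per-subject aggregate game scores (means over gameplay loops)."""

    grasps_per_loop: float
    force_cov: float
    memory_accuracy: float

    def __post_init__(self) -> None:
        if self.force_cov < 0:
            raise ValidationError("force COV cannot be negative")
        if not 0 <= self.memory_accuracy <= 1:
            raise ValidationError("memory accuracy must be in [0, 1]")


def grasp_count(log: GameLog, loop: int) -> int:
    """Number of grasp initiations within one gameplay loop."""
    bl = log.block(loop)
    n = int(bl.grasp_times.size)
    if n == 0:
        logger.warning("gameplay loop %s has no grasp events "
                       "(possible data-quality problem)", loop)
    return n


def force_cov(log: GameLog, loop: int) -> float:
    """Sample SD (n-1 denominator) divided by mean of the loop's force
    samples; scale-invariant. NaN (flagged) when undefined."""
    bl = log.block(loop)
    f = bl.force_n
    if f.size < 2:
        logger.warning("loop %s: fewer than 2 force samples, COV undefined", loop)
        return float("nan")
    mean = f.mean()
    if mean <= 0:
        logger.warning("loop %s: non-positive mean force, COV undefined", loop)
        return float("nan")
    return float(f.std(ddof=1) / mean)


def memory_accuracy(log: GameLog, loop: int) -> float:
    """Correct feeds / total feeds in one loop; NaN (flagged) if no feeds."""
    bl = log.block(loop)
    if not bl.feeds:
        logger.warning("loop %s: no feed events, accuracy undefined", loop)
        return float("nan")
    correct = sum(1 for delivered, expected in bl.feeds if delivered == expected)
    return correct / len(bl.feeds)


def block_metrics(log: GameLog, condition: str | None = None) -> pd.DataFrame:
    """Tidy per-loop metric table (block, condition, grasps, cov, accuracy)."""
    rows = []
    for bid in log.block_ids(condition):
        rows.append({
            "block": bid,
            "condition": log.blocks[bid].condition,
            "grasps": grasp_count(log, bid),
            "force_cov": force_cov(log, bid),
            "memory_accuracy": memory_accuracy(log, bid),
        })
    return pd.DataFrame(rows)


def summarize_game(log: GameLog, condition: str | None = None) -> GamePerformance:
    """Aggregate across loops: the mean of the per-loop values (NaN-skipping
    for the flagged undefined loops)."""
    tbl = block_metrics(log, condition)
    if tbl.empty:
        raise ValidationError("no gameplay loops to summarise")
    return GamePerformance(
        grasps_per_loop=float(tbl["grasps"].mean()),
        force_cov=float(np.nanmean(tbl["force_cov"])),
        memory_accuracy=float(np.nanmean(tbl["memory_accuracy"])),
    )
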