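"""Core domain containers for block-design fNIRS analysis.

The central object is :class:`RecordingBundle`, a time x channel x component
array that moves through exactly three states::

    intensity  ->  optical_density  ->  concentration

In the first two states the component axis holds the two CW wavelengths
(760 and 850 nm); after the modified Beer-Lambert inversion it holds the two
chromophores (HbO, HbR) in uM*mm (concentration change times pathlength).

:class:`EventSchedule` carries the block paradigm (condition-labelled onsets
and durations), :class:`Montage` the optode/channel geometry and the
channel -> region-of-interest assignment, and :class:`GameLog` the pinch-force
game telemetry from which behavioural metrics are computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np

logger = logging.getLogger("nirsblock")

__all__ = [
    "NirsblockError",
    "ValidationError",
    "StateError",
    "Montage",
    "RecordingBundle",
    "Event",
    "EventSchedule",
    "BlockLog",
    "GameLog",
    "ROIS",
    "CONDITIONS",
    "GAMEPLAY_CONDITIONS",
    "WFC",
    "WOFC",
    "REST",
    "default_montage",
    "default_paradigm",
]


class NirsblockError(Exception):
    """Base class for all package errors."""


class ValidationError(NirsblockError):
    """An input violated a structural precondition."""


class StateError(NirsblockError):
    """An operation was applied to a bundle in the wrong processing state."""


#: The eight regions of interest, left and right prefrontal cortex (PFC),
#: premotor cortex (PMC), supplementary motor area (SMA) and primary motor
#: cortex (M1).
ROIS: tuple[str, ...] = ("lPFC", "lPMC", "lSMA", "lM1", "rPFC", "rPMC", "rSMA", "rM1")

WFC = "wFC"
WOFC = "woFC"
REST = "rest"
GAMEPLAY_CONDITIONS: tuple[str, str] = (WFC, WOFC)
CONDITIONS: tuple[str, ...] = (WFC, WOFC, REST)

STATE_INTENSITY = "intensity"
STATE_OD = "optical_density"
STATE_CONCENTRATION = "concentration"
_STATE_ORDER = (STATE_INTENSITY, STATE_OD, STATE_CONCENTRATION)

DEFAULT_SAMPLE_RATE = 7.81  # Hz
DEFAULT_WAVELENGTHS = (760.0, 850.0)  # nm
CHROMOPHORES = ("HbO", "HbR")


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Optode geometry plus the channel -> ROI assignment.

    A channel is identified by its ``"S#-D#"`` source-detector pair; the two
    wavelengths of a pair are components of the same channel, keeping the
    channel count aligned with the probe design (30 for the default montage).
    """

    sources: dict[str, tuple[float, float, float]]
    detectors: dict[str, tuple[float, float, float]]
    channels: tuple[tuple[str, str], ...]
    roi_map: dict[str, str]
    separation_mm: dict[str, float]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = self.channel_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate channels in montage")
        for src, det in self.channels:
            if src not in self.sources:
                raise ValidationError(f"channel references unknown source {src!r}")
            if det not in self.detectors:
                raise ValidationError(f"channel references unknown detector {det!r}")
        missing = [c for c in ids if c not in self.roi_map]
        if missing:
            raise ValidationError(f"channels without ROI assignment: {missing}")
        bad = {c: r for c, r in self.roi_map.items() if r not in ROIS}
        if bad:
            raise ValidationError(f"unknown ROI labels: {bad}")
        for c in ids:
            if self.separation_mm[c] <= 0:
                raise ValidationError(f"non-positive separation for channel {c}")

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(f"{s}-{d}" for s, d in self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def roi_channels(self, roi: str) -> tuple[str, ...]:
        """Channel ids assigned to one region of interest."""
        if roi not in ROIS:
            raise ValidationError(f"unknown ROI {roi!r}")
        return tuple(c for c in self.channel_ids if self.roi_map[c] == roi)

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise ValidationError(f"unknown channel {channel_id!r}") from None

    @classmethod
    def from_dict(cls, cfg: dict) -> "Montage":
        channels = tuple((s, d) for s, d in cfg["channels"])
        sep = cfg["separation_mm"]
        ids = tuple(f"{s}-{d}" for s, d in channels)
        if isinstance(sep, (int, float)):
            sep = {c: float(sep) for c in ids}
        return cls(
            sources={k: tuple(v) for k, v in cfg["sources"].items()},
            detectors={k: tuple(v) for k, v in cfg["detectors"].items()},
            channels=channels,
            roi_map=dict(cfg["roi_map"]),
            separation_mm=dict(sep),
            version=str(cfg.get("version", "unversioned")),
        )

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_montage() -> Montage:
    """The packaged 8-source / 16-detector / 30-channel bilateral montage."""
    text = resources.files("nirsblock.data").joinpath("default_montage.json").read_text()
    return Montage.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

class Event(NamedTuple):
    onset: float
    duration: float
    condition: str


@dataclass(frozen=True)
class EventSchedule:
    """Sorted, non-overlapping, condition-labelled block events."""

    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for ev in self.events:
            if ev.condition not in CONDITIONS:
                raise ValidationError(f"unknown condition {ev.condition!r}")
            if ev.duration <= 0:
                raise ValidationError(f"non-positive duration in event {ev}")
            if ev.onset < prev_onset:
                raise ValidationError("events not sorted by onset")
            if ev.onset < prev_end - 1e-9:
                raise ValidationError(f"overlapping events near onset {ev.onset}")
            prev_onset = ev.onset
            prev_end = ev.onset + ev.duration

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[float, float, str]]) -> "EventSchedule":
        evs = sorted((Event(float(o), float(d), str(c)) for o, d, c in rows),
                     key=lambda e: e.onset)
        return cls(tuple(evs))

    def __len__(self) -> int:
        return len(self.events)

    @property
    def end(self) -> float:
        return max((e.onset + e.duration for e in self.events), default=0.0)

    def of_condition(self, condition: str) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.condition == condition)

    @property
    def gameplay_events(self) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.condition in GAMEPLAY_CONDITIONS)

    def condition_mask(self, timestamps: np.ndarray, condition: str) -> np.ndarray:
        """Boolean sample mask covering all blocks of one condition."""
        t = np.asarray(timestamps, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for ev in self.of_condition(condition):
            mask |= (t >= ev.onset) & (t < ev.onset + ev.duration)
        return mask


def default_paradigm(n_trials: int = 5, block_s: float = 30.0,
                     rest_s: float = 30.0, lead_in_s: float = 30.0) -> EventSchedule:
    """The study block design: a lead-in rest, five force-control (wFC)
    gameplay blocks each followed by rest, one separating rest, then five
    no-force-control (woFC) blocks each followed by rest. All blocks and
    rests last 30 s by default."""
    rows: list[tuple[float, float, str]] = []
    t = 0.0
    if lead_in_s > 0:
        rows.append((t, lead_in_s, REST))
        t += lead_in_s
    for _ in range(n_trials):
        rows.append((t, block_s, WFC)); t += block_s
        rows.append((t, rest_s, REST)); t += rest_s
    rows.append((t, rest_s, REST)); t += rest_s
    for _ in range(n_trials):
        rows.append((t, block_s, WOFC)); t += block_s
        rows.append((t, rest_s, REST)); t += rest_s
    return EventSchedule.from_rows(rows)


# ---------------------------------------------------------------------------
# Recording bundle
# ---------------------------------------------------------------------------

@dataclass
class RecordingBundle:
    """Time-indexed multichannel recording in one of three processing states.

    data has shape (n_times, n_channels, 2); the component axis is the two
    wavelengths (intensity / optical density) or the two chromophores
    (concentration). ``pruned_channels`` maps channel id -> reason code;
    pruned channels keep their data (so indexing stays aligned with the
    montage) but are masked from every downstream statistic.
    """

    timestamps: np.ndarray
    data: np.ndarray
    state: str
    component_labels: tuple
    montage: Montage
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pruned_channels: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.state not in _STATE_ORDER:
            raise ValidationError(f"unknown state {self.state!r}")
        if self.data.ndim != 3:
            raise ValidationError("data must be (time, channel, component)")
        nt, nc, ncomp = self.data.shape
        if nt != self.timestamps.size:
            raise ValidationError("timestamps/data length mismatch")
        if nc != self.montage.n_channels:
            raise ValidationError(
                f"data has {nc} channels but montage defines {self.montage.n_channels}")
        if ncomp != len(self.component_labels) or ncomp != 2:
            raise ValidationError("exactly two components (wavelengths/chromophores) required")
        if nt >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise ValidationError("non-uniform time base (tolerance 1 ppm)")

    # -- helpers ------------------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def active_mask(self) -> np.ndarray:
        """Boolean per-channel mask, False where the channel is pruned."""
        pruned = set(self.pruned_channels)
        return np.array([c not in pruned for c in self.montage.channel_ids])

    def component_index(self, label) -> int:
        try:
            return list(self.component_labels).index(label)
        except ValueError:
            raise ValidationError(
                f"component {label!r} not in {self.component_labels}") from None

    def evolve(self, *, data: np.ndarray | None = None, state: str | None = None,
               component_labels: tuple | None = None, **meta_updates) -> "RecordingBundle":
        """Return a copy with new data/state; enforces forward-only state moves."""
        new_state = self.state if state is None else state
        if _STATE_ORDER.index(new_state) < _STATE_ORDER.index(self.state):
            raise StateError(f"cannot move from {self.state} back to {new_state}")
        new = replace(
            self,
            data=self.data.copy() if data is None else data,
            state=new_state,
            component_labels=self.component_labels if component_labels is None
            else component_labels,
            pruned_channels=dict(self.pruned_channels),
            meta={**self.meta, **meta_updates},
        )
        return new

    def require_state(self, state: str, op: str) -> None:
        if self.state != state:
            raise StateError(f"{op} requires state={state!r}, got {self.state!r}")


# ---------------------------------------------------------------------------
# Game logs
# ---------------------------------------------------------------------------

@dataclass
class BlockLog:
    """Telemetry of one gameplay loop.

    force samples cover only the periods where the fork is held; each grasp
    time marks a fork pick-up (the first one at block start, later ones after
    force-window violations reset the fork). feeds are (delivered, expected)
    food-id pairs."""

    block_id: int
    condition: str
    t_start: float
    t_end: float
    force_t: np.ndarray
    force_n: np.ndarray
    grasp_times: np.ndarray
    feeds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.force_t = np.asarray(self.force_t, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.grasp_times = np.asarray(self.grasp_times, dtype=float)
        if np.any(self.force_n < 0):
            raise ValidationError(f"negative force sample in block {self.block_id}")
        inside = (self.grasp_times >= self.t_start - 1e-9) & \
                 (self.grasp_times <= self.t_end + 1e-9)
        if not np.all(inside):
            raise ValidationError(
                f"grasp event outside block {self.block_id} time span")


@dataclass
class GameLog:
    """Per-subject game telemetry: one BlockLog per gameplay loop plus the
    subject's maximum voluntary contraction (N) used to scale the force window."""

    mvc: float
    blocks: dict[int, BlockLog]

    def __post_init__(self) -> None:
        if self.mvc <= 0:
            raise ValidationError("MVC must be positive")

    def block(self, block_id: int) -> BlockLog:
        try:
            return self.blocks[block_id]
        except KeyError:
            raise ValidationError(f"unknown gameplay loop {block_id!r}") from None

    def block_ids(self, condition: str | None = None) -> list[int]:
        return [b for b, bl in sorted(self.blocks.items())
                if condition is None or bl.condition == condition]
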