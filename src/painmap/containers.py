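"""Core data containers shared across the pipeline.

Each container is a light dataclass around numpy/pandas structures with
eager validation: invalid data fails at construction, naming the offending
field, so downstream analytics can assume clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container or spec invariant is violated."""


# ---------------------------------------------------------------------------
# Region counts (brain-wide FOS mapping)
# ---------------------------------------------------------------------------

@dataclass
class RegionActivationMatrix:
    """Per-animal FOS+ cell counts across named brain regions.

    Rows are animals, columns are brain regions (Allen-style acronyms).
    ``group_labels`` is a two-level factor (e.g. CON vs MA). ``zscores``
    is filled by :func:`painmap.activation.zscore_regions`; columns with
    zero variance are recorded in ``degenerate_regions``.
    """

    counts: np.ndarray
    region_names: list[str]
    group_labels: np.ndarray
    zscores: Optional[np.ndarray] = None
    degenerate_regions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        self.region_names = list(self.region_names)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D animals x regions array")
        n, m = self.counts.shape
        if m != len(self.region_names):
            raise ValidationError(
                f"region_names length {len(self.region_names)} != {m} count columns"
            )
        if m < 2:
            raise ValidationError("need at least 2 regions (M >= 2)")
        if n < 2:
            raise ValidationError("need at least 2 animals (N >= 2)")
        if len(self.group_labels) != n:
            raise ValidationError("group_labels length must match number of animals")
        if np.isnan(self.counts).any():
            raise ValidationError("counts contain missing cells")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        levels = np.unique(self.group_labels)
        if len(levels) != 2:
            raise ValidationError(
                f"group_labels must have exactly two levels, got {list(levels)}"
            )
        if len(set(self.region_names)) != m:
            raise ValidationError("region_names must be unique")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    @property
    def classes(self) -> tuple[str, str]:
        """The two group levels in sorted order (negative, positive)."""
        a, b = sorted(np.unique(self.group_labels).tolist())
        return str(a), str(b)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.region_names)
        df.insert(0, "group", self.group_labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionActivationMatrix":
        if "group" not in df.columns:
            raise ValidationError("counts table must contain a 'group' column")
        regions = [c for c in df.columns if c != "group"]
        return cls(
            counts=df[regions].to_numpy(dtype=float),
            region_names=regions,
            group_labels=df["group"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Ethograms (labeled behavioral bouts)
# ---------------------------------------------------------------------------

@dataclass
class Ethogram:
    """Ordered sequence of labeled behavioral bouts.

    ``bouts`` holds columns label/start_s/end_s; bouts must be ordered,
    non-overlapping and have positive duration. ``label_set`` fixes the
    action alphabet (labels may be unused but never unknown).
    """

    bouts: pd.DataFrame
    label_set: tuple[str, ...]
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        required = {"label", "start_s", "end_s"}
        if not required.issubset(self.bouts.columns):
            missing = required - set(self.bouts.columns)
            raise ValidationError(f"bouts table missing columns: {sorted(missing)}")
        self.label_set = tuple(self.label_set)
        b = self.bouts
        if len(b):
            starts = b["start_s"].to_numpy(float)
            ends = b["end_s"].to_numpy(float)
            if not (ends > starts).all():
                raise ValidationError("every bout must satisfy start_s < end_s")
            if not (starts[1:] >= ends[:-1] - 1e-9).all():
                raise ValidationError("bouts must be non-overlapping and time-ordered")
            unknown = set(b["label"]) - set(self.label_set)
            if unknown:
                raise ValidationError(f"bout labels not in label_set: {sorted(unknown)}")

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def labels(self) -> np.ndarray:
        return self.bouts["label"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return (self.bouts["end_s"] - self.bouts["start_s"]).to_numpy(float)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


# ---------------------------------------------------------------------------
# Arena geometry + trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareArena:
    """Open-field box; coordinates live in [0, side_cm] x [0, side_cm]."""

    side_cm: float = 50.0

    def __post_init__(self) -> None:
        if self.side_cm <= 0:
            raise ValidationError("side_cm must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        s = self.side_cm
        return (x >= -tol) & (x <= s + tol) & (y >= -tol) & (y <= s + tol)


@dataclass(frozen=True)
class PlusMazeArena:
    """Elevated plus maze centered at the origin.

    Open arms extend along +/-x, closed arms along +/-y; the center
    platform is a ``center_cm`` square. Standard dimensions: 30 x 5 cm
    arms with a 5 x 5 cm center.
    """

    arm_length_cm: float = 30.0
    arm_width_cm: float = 5.0
    center_cm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.arm_length_cm, self.arm_width_cm, self.center_cm) <= 0:
            raise ValidationError("all maze dimensions must be positive")
        if self.arm_width_cm > self.center_cm + 1e-9:
            raise ValidationError("arm_width_cm may not exceed center_cm (overlapping polygons)")

    def zone_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample zone: 'open', 'closed', or 'center'.

        The center square claims its own area; arms start at its edge.
        Points outside the maze polygon raise.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        h = self.center_cm / 2.0
        w = self.arm_width_cm / 2.0
        reach = h + self.arm_length_cm
        tol = 1e-9
        in_center = (np.abs(x) <= h + tol) & (np.abs(y) <= h + tol)
        in_open = (np.abs(x) > h) & (np.abs(x) <= reach + tol) & (np.abs(y) <= w + tol)
        in_closed = (np.abs(y) > h) & (np.abs(y) <= reach + tol) & (np.abs(x) <= w + tol)
        zone = np.full(x.shape, "", dtype=object)
        zone[in_closed] = "closed"
        zone[in_open] = "open"
        zone[in_center] = "center"
        if (zone == "").any():
            raise ValidationError("trajectory contains points outside the plus-maze polygon")
        return zone.astype(str)

    def contains(self, x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        h = self.center_cm / 2.0
        w = self.arm_width_cm / 2.0
        reach = h + self.arm_length_cm
        in_center = (np.abs(x) <= h + tol) & (np.abs(y) <= h + tol)
        in_open = (np.abs(x) <= reach + tol) & (np.abs(y) <= w + tol)
        in_closed = (np.abs(y) <= reach + tol) & (np.abs(x) <= w + tol)
        return in_center | in_open | in_closed


@dataclass
class Trajectory:
    """2-D body-point track sampled at a fixed rate inside an arena."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    sample_rate: float
    arena: object = field(default_factory=SquareArena)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.x_cm = np.asarray(self.x_cm, float)
        self.y_cm = np.asarray(self.y_cm, float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValidationError("t_s, x_cm, y_cm must have equal length")
        if len(self.t_s) and not (np.diff(self.t_s) > 0).all():
            raise ValidationError("t_s must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if len(self.t_s) and not self.arena.contains(self.x_cm, self.y_cm).all():
            raise ValidationError("trajectory contains points outside arena bounds")

    @property
    def n_samples(self) -> int:
        return len(self.t_s)

    @property
    def duration(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) + 1.0 / self.sample_rate if len(self.t_s) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "x_cm": self.x_cm, "y_cm": self.y_cm})


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

@dataclass
class PhotometryRecording:
    """Dual-channel fiber-photometry recording.

    ``f470`` is the calcium-dependent signal channel; ``f410`` is the
    isosbestic control capturing motion/bleaching artifacts.
    """

    t_s: np.ndarray
    f470: np.ndarray
    f410: np.ndarray
    sample_rate: float
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.f470 = np.asarray(self.f470, float)
        self.f410 = np.asarray(self.f410, float)
        self.event_times_s = np.asarray(self.event_times_s, float)
        if not (len(self.t_s) == len(self.f470) == len(self.f410)):
            raise ValidationError("channel lengths must match the timebase")
        if len(self.t_s) > 1 and not (np.diff(self.t_s) > 0).all():
            raise ValidationError("t_s must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "f470": self.f470, "f410": self.f410})


@dataclass
class DFFTrace:
    """Motion/bleaching-corrected ΔF/F trace with the control-fit used."""

    t_s: np.ndarray
    dff: np.ndarray
    sample_rate: float
    fit_params: dict = field(default_factory=dict)
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.dff = np.asarray(self.dff, float)
        if len(self.t_s) != len(self.dff):
            raise ValidationError("dff must be the same length as its timebase")
        if not np.isfinite(self.dff).all():
            raise ValidationError("dff contains non-finite values")


@dataclass(frozen=True)
class PairedPulsePair:
    """Peak current magnitudes from a paired-pulse protocol (pA)."""

    peak1: float
    peak2: float
    interstimulus_interval_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.peak1 <= 0:
            raise ValidationError("peak1 must be a positive magnitude")
        if self.peak2 < 0:
            raise ValidationError("peak2 must be a nonnegative magnitude")


# ---------------------------------------------------------------------------
# von Frey
# ---------------------------------------------------------------------------

#: Filament specification values of the standard orofacial ladder.
VONFREY_LADDER: tuple[float, ...] = (1.65, 2.36, 2.44, 2.83, 3.22, 3.61)


@dataclass
class VonFreyAssay:
    """Positive-response counts along an ascending von Frey filament ladder."""

    filaments: Sequence[float]
    positives: Sequence[int]
    trials: int = 10

    def __post_init__(self) -> None:
        self.filaments = tuple(float(f) for f in self.filaments)
        self.positives = tuple(int(p) for p in self.positives)
        if len(self.filaments) == 0:
            raise ValidationError("filament ladder is empty")
        if len(self.positives) != len(self.filaments):
            raise ValidationError("positives must align with the filament ladder")
        if not all(b > a for a, b in zip(self.filaments, self.filaments[1:])):
            raise ValidationError("filaments must be strictly increasing")
        if self.trials < 1:
            raise ValidationError("trials must be >= 1")
        if any(p < 0 or p > self.trials for p in self.positives):
            raise ValidationError("positives must lie in [0, trials]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filament": self.filaments,
                "positives": self.positives,
                "trials": [self.trials] * len(self.filaments),
            }
        )
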