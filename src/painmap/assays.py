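"""Deterministic scoring of classical pain/anxiety assays.

von Frey mechanical thresholds and response-frequency curves, and
trajectory-based zone metrics for the open field (center zone) and the
elevated plus maze (open/closed arms, center platform).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    PlusMazeArena,
    SquareArena,
    Trajectory,
    ValidationError,
    VonFreyAssay,
)

__all__ = [
    "VonFreyThreshold",
    "ZoneMetrics",
    "vonfrey_threshold",
    "response_frequency",
    "openfield_metrics",
    "epm_metrics",
]


@dataclass(frozen=True)
class VonFreyThreshold:
    """Mechanical threshold; ``censored`` marks a never-responding animal.

    ``value`` is the filament specification value; for censored results
    it is NaN and ``label`` reads e.g. '> 3.61' (above the ladder).
    ``sentinel`` is a numeric stand-in (max filament) usable by rank
    statistics downstream.
    """

    value: float
    censored: bool
    label: str
    sentinel: float


@dataclass
class ZoneMetrics:
    """Occupancy/entry/path metrics for one zone of an arena."""

    time_in_zone_s: float
    entries: int
    distance_in_zone_cm: float
    total_distance_cm: float
    zone_fraction_of_path: float
    total_time_s: float

    def to_dict(self) -> dict:
        return {
            "time_in_zone_s": self.time_in_zone_s,
            "entries": self.entries,
            "distance_in_zone_cm": self.distance_in_zone_cm,
            "total_distance_cm": self.total_distance_cm,
            "zone_fraction_of_path": self.zone_fraction_of_path,
            "total_time_s": self.total_time_s,
        }


# ---------------------------------------------------------------------------
# von Frey
# ---------------------------------------------------------------------------

def vonfrey_threshold(assay: VonFreyAssay) -> VonFreyThreshold:
    """Smallest filament evoking positives on more than 60% of trials.

    With the standard 10-trial protocol this is the smallest filament
    with more than six positive responses. An animal never reaching the
    criterion returns a censored marker above the ladder rather than an
    error.
    """
    crit = 0.6 * assay.trials
    for f, pos in zip(assay.filaments, assay.positives):
        if pos > crit:
            return VonFreyThreshold(value=float(f), censored=False,
                                    label=f"{f:g}", sentinel=float(f))
    top = assay.filaments[-1]
    return VonFreyThreshold(value=float("nan"), censored=True,
                            label=f"> {top:g}", sentinel=float(top))


def response_frequency(assay: VonFreyAssay) -> pd.Series:
    """Percentage of positive responses per filament (0-100)."""
    if assay.trials == 0:
        raise ValidationError("trials must be positive")
    return pd.Series(
        [100.0 * p / assay.trials for p in assay.positives],
        index=list(assay.filaments),
        name="response_pct",
    )


# ---------------------------------------------------------------------------
# Zone metrics
# ---------------------------------------------------------------------------

def _zone_metrics_from_mask(traj: Trajectory, inside: np.ndarray) -> ZoneMetrics:
    """Shared zone accounting from a per-sample membership mask.

    Time = samples inside / sample_rate. An entry is a strict
    outside->inside transition; a session starting inside counts as one
    entry. Each path segment is attributed to the zone of its start
    point.
    """
    dt = 1.0 / traj.sample_rate
    time_in = float(inside.sum()) * dt
    entries = int(inside[0]) + int((inside[1:] & ~inside[:-1]).sum())
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    seg = np.hypot(dx, dy)
    dist_in = float(seg[inside[:-1]].sum()) if len(seg) else 0.0
    total = float(seg.sum()) if len(seg) else 0.0
    frac = dist_in / total if total > 0 else 0.0
    return ZoneMetrics(
        time_in_zone_s=time_in,
        entries=entries,
        distance_in_zone_cm=dist_in,
        total_distance_cm=total,
        zone_fraction_of_path=frac,
        total_time_s=len(inside) * dt,
    )


def openfield_metrics(traj: Trajectory, center_fraction: float = 0.5) -> ZoneMetrics:
    """Center-zone metrics for a square open field.

    The center zone is the concentric square whose side is
    ``center_fraction`` times the arena side (default half, the common
    open-field convention).
    """
    if not isinstance(traj.arena, SquareArena):
        raise ValidationError("openfield_metrics requires a square arena")
    if not 0 < center_fraction < 1:
        raise ValidationError("center_fraction must be in (0, 1)")
    side = traj.arena.side_cm
    half_gap = side * (1 - center_fraction) / 2.0
    lo, hi = half_gap, side - half_gap
    inside = (
        (traj.x_cm >= lo) & (traj.x_cm <= hi) & (traj.y_cm >= lo) & (traj.y_cm <= hi)
    )
    return _zone_metrics_from_mask(traj, inside)


def epm_metrics(traj: Trajectory) -> dict[str, ZoneMetrics]:
    """Per-zone metrics (open arms, closed arms, center) on a plus maze."""
    if not isinstance(traj.arena, PlusMazeArena):
        raise ValidationError("epm_metrics requires a plus-maze arena")
    zone = traj.arena.zone_of(traj.x_cm, traj.y_cm)
    return {
        name: _zone_metrics_from_mask(traj, zone == name)
        for name in ("open", "closed", "center")
    }
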