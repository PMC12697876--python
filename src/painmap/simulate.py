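"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the pipeline has a matching generator here so
that recovery and calibration tests never depend on external data. Each
generator takes a validated spec, draws from a fixed-seed RNG
(bit-identical reruns), and returns the data container together with a
JSON-serializable ground-truth dict describing exactly what was
injected (group effects, transition matrices, thresholds, transient
amplitudes).

Models, briefly:

* region counts — negative binomial per region (mean/dispersion
  parameterization); a chosen subset of regions has its second-group
  mean multiplied by exp(effect_log_fold);
* ethograms — first-order Markov chain over the action alphabet with
  exponential bout durations, truncated at the session end;
* trajectories — reflected random walk with an outward radial drift
  controlled by ``center_avoidance`` (0 = unbiased);
* photometry — shared baseline + linear drift + Gaussian noise on both
  channels; the 470-nm channel additionally carries exponentially
  decaying transients at the event times;
* von Frey — binomial responses under a logistic psychometric curve
  centered on the true threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import (
    Ethogram,
    PhotometryRecording,
    PlusMazeArena,
    RegionActivationMatrix,
    SquareArena,
    Trajectory,
    ValidationError,
    VonFreyAssay,
    VONFREY_LADDER,
)

__all__ = [
    "ACTION_LABELS",
    "RegionCountSpec",
    "EthogramSpec",
    "TrajectorySpec",
    "PhotometrySpec",
    "VonFreySpec",
    "gen_region_counts",
    "gen_ethogram",
    "gen_trajectory",
    "gen_photometry",
    "gen_vonfrey",
]

#: The 10-action repertoire used for naturalistic mouse behavior.
ACTION_LABELS: tuple[str, ...] = (
    "running",
    "trotting",
    "stepping",
    "walking",
    "rearing",
    "hunching",
    "right turning",
    "curling-up",
    "sniffing",
    "self-grooming",
)


def _default_regions(m: int) -> list[str]:
    return [f"R{i:03d}" for i in range(1, m + 1)]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class RegionCountSpec:
    """Two-group overdispersed region-count design with planted effects."""

    n_per_group: int = 3
    region_names: Sequence[str] = field(default_factory=lambda: _default_regions(129))
    baseline_mean: float = 200.0
    dispersion: float = 10.0
    effect_regions: Sequence[int] = ()  # 0-based region indices
    effect_log_fold: float = 0.0
    seed: int = 0
    group_names: tuple[str, str] = ("CON", "MA")

    def __post_init__(self) -> None:
        self.region_names = list(self.region_names)
        m = len(self.region_names)
        if m < 2:
            raise ValidationError("region_names: need M >= 2 regions")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group: must be >= 1")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean: must be > 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion: must be > 0")
        self.effect_regions = tuple(int(i) for i in self.effect_regions)
        if any(i < 0 or i >= m for i in self.effect_regions):
            raise ValidationError("effect_regions: indices must lie in [0, M)")


@dataclass
class EthogramSpec:
    """Markov bout-sequence design over an action alphabet."""

    action_labels: Sequence[str] = ACTION_LABELS
    transition_matrix: Optional[np.ndarray] = None  # K x K row-stochastic
    mean_bout_duration: Union[float, Sequence[float]] = 2.0
    total_duration: float = 600.0
    seed: int = 0
    start_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.action_labels = tuple(self.action_labels)
        k = len(self.action_labels)
        if k < 1:
            raise ValidationError("action_labels: need at least one label")
        if self.transition_matrix is None:
            self.transition_matrix = np.full((k, k), 1.0 / k)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        if self.transition_matrix.shape != (k, k):
            raise ValidationError("transition_matrix: shape must be K x K")
        if (self.transition_matrix < 0).any():
            raise ValidationError("transition_matrix: probabilities must be >= 0")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition_matrix: every row must sum to 1")
        durs = np.atleast_1d(np.asarray(self.mean_bout_duration, float))
        if len(durs) == 1:
            durs = np.full(k, durs[0])
        if len(durs) != k:
            raise ValidationError("mean_bout_duration: scalar or one value per action")
        if (durs <= 0).any():
            raise ValidationError("mean_bout_duration: durations must be > 0")
        self._mean_durations = durs
        if self.total_duration <= 0:
            raise ValidationError("total_duration: must be > 0")
        if self.start_label is not None and self.start_label not in self.action_labels:
            raise ValidationError("start_label: not in action_labels")


@dataclass
class TrajectorySpec:
    """Reflected-random-walk trajectory design inside an arena."""

    arena: object = field(default_factory=SquareArena)
    center_avoidance: float = 0.0
    speed_scale: float = 8.0  # cm/s
    duration: float = 600.0
    sample_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_avoidance < 0:
            raise ValidationError("center_avoidance: must be >= 0")
        if self.speed_scale < 0:
            raise ValidationError("speed_scale: must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration: must be > 0")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate: must be > 0")


@dataclass
class PhotometrySpec:
    """Dual-channel photometry design with injected calcium transients."""

    sample_rate: float = 50.0
    duration: float = 120.0
    event_times: Sequence[float] = ()
    transient_amplitude: float = 0.2  # ΔF/F units
    transient_tau: float = 1.0  # s
    drift_slope: float = 0.0  # fluorescence units / s
    noise_sd: float = 0.5
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate: must be > 0")
        if self.duration <= 0:
            raise ValidationError("duration: must be > 0")
        self.event_times = tuple(float(t) for t in self.event_times)
        if any(t < 0 or t > self.duration for t in self.event_times):
            raise ValidationError("event_times: must lie within [0, duration]")
        if self.transient_tau <= 0:
            raise ValidationError("transient_tau: must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if self.baseline <= 0:
            raise ValidationError("baseline: must be > 0")


@dataclass
class VonFreySpec:
    """Binomial psychometric design on a filament ladder."""

    true_threshold: float = 2.6
    slope: float = 10.0
    filaments: Sequence[float] = VONFREY_LADDER
    trials_per_filament: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.filaments = tuple(float(f) for f in self.filaments)
        if len(self.filaments) == 0:
            raise ValidationError("filaments: ladder is empty")
        if not all(b > a for a, b in zip(self.filaments, self.filaments[1:])):
            raise ValidationError("filaments: must be strictly increasing")
        if self.trials_per_filament < 1:
            raise ValidationError("trials_per_filament: must be >= 1")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_region_counts(spec: RegionCountSpec) -> tuple[RegionActivationMatrix, dict]:
    """Draw the two-group count table; returns (data, ground_truth).

    Counts are negative binomial with mean mu and variance
    mu + mu²/dispersion. Effect regions have the second group's mean
    multiplied by exp(effect_log_fold).
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.region_names)
    n = spec.n_per_group
    mu = np.full((2, m), spec.baseline_mean, dtype=float)
    mu[1, list(spec.effect_regions)] *= np.exp(spec.effect_log_fold)
    theta = spec.dispersion
    counts = np.empty((2 * n, m))
    groups = np.empty(2 * n, dtype=object)
    for g, gname in enumerate(spec.group_names):
        p = theta / (theta + mu[g])
        counts[g * n : (g + 1) * n] = rng.negative_binomial(theta, p, size=(n, m))
        groups[g * n : (g + 1) * n] = gname
    data = RegionActivationMatrix(
        counts=counts, region_names=list(spec.region_names), group_labels=groups
    )
    truth = {
        "kind": "region_counts",
        "effect_regions": [spec.region_names[i] for i in spec.effect_regions],
        "effect_region_indices": list(spec.effect_regions),
        "effect_log_fold": spec.effect_log_fold,
        "baseline_mean": spec.baseline_mean,
        "dispersion": spec.dispersion,
        "group_names": list(spec.group_names),
        "n_per_group": n,
        "seed": spec.seed,
    }
    return data, truth


def gen_ethogram(spec: EthogramSpec, animal_id: str = "", group: str = "") -> tuple[Ethogram, dict]:
    """Sample a Markov bout sequence truncated at the session end."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.action_labels
    k = len(labels)
    p = spec.transition_matrix
    means = spec._mean_durations
    if spec.start_label is not None:
        state = labels.index(spec.start_label)
    else:
        state = int(rng.integers(k))
    t = 0.0
    rows = []
    while t < spec.total_duration:
        dur = rng.exponential(means[state])
        end = min(t + dur, spec.total_duration)
        if end > t:
            rows.append((labels[state], t, end))
        t = end
        state = int(rng.choice(k, p=p[state]))
    bouts = pd.DataFrame(rows, columns=["label", "start_s", "end_s"])
    e = Ethogram(bouts=bouts, label_set=labels, animal_id=animal_id, group=group)
    truth = {
        "kind": "ethogram",
        "transition_matrix": p.tolist(),
        "action_labels": list(labels),
        "mean_bout_duration": means.tolist(),
        "total_duration": spec.total_duration,
        "seed": spec.seed,
    }
    return e, truth


def _arena_center(arena) -> tuple[float, float]:
    if isinstance(arena, SquareArena):
        return arena.side_cm / 2.0, arena.side_cm / 2.0
    return 0.0, 0.0


def gen_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, dict]:
    """Reflected biased random walk; higher center_avoidance pushes the
    walker away from the arena center."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate
    cx, cy = _arena_center(spec.arena)
    arena = spec.arena
    if isinstance(arena, SquareArena):
        pos = np.array([cx, cy])
        side = arena.side_cm
        xs = np.empty(n)
        ys = np.empty(n)
        step_sd = spec.speed_scale * dt
        for i in range(n):
            xs[i], ys[i] = pos
            r = pos - np.array([cx, cy])
            norm = np.hypot(*r)
            u = r / norm if norm > 1e-9 else np.zeros(2)
            step = step_sd * (rng.standard_normal(2) + spec.center_avoidance * u)
            pos = pos + step
            # reflect at walls
            for d in range(2):
                if pos[d] < 0:
                    pos[d] = -pos[d]
                if pos[d] > side:
                    pos[d] = 2 * side - pos[d]
                pos[d] = min(max(pos[d], 0.0), side)
    elif isinstance(arena, PlusMazeArena):
        pos = np.array([0.0, 0.0])
        xs = np.empty(n)
        ys = np.empty(n)
        step_sd = spec.speed_scale * dt
        for i in range(n):
            xs[i], ys[i] = pos
            r = pos
            norm = np.hypot(*r)
            u = r / norm if norm > 1e-9 else np.zeros(2)
            step = step_sd * (rng.standard_normal(2) + spec.center_avoidance * u)
            cand = pos + step
            # reject moves that leave the maze polygon
            if arena.contains(np.array([cand[0]]), np.array([cand[1]]))[0]:
                pos = cand
    else:
        raise ValidationError(f"arena: unsupported geometry {type(arena).__name__}")
    t = np.arange(n) * dt
    traj = Trajectory(t_s=t, x_cm=xs, y_cm=ys, sample_rate=spec.sample_rate, arena=arena)
    truth = {
        "kind": "trajectory",
        "center_avoidance": spec.center_avoidance,
        "speed_scale": spec.speed_scale,
        "duration": spec.duration,
        "sample_rate": spec.sample_rate,
        "arena": type(arena).__name__,
        "seed": spec.seed,
    }
    return traj, truth


def gen_photometry(spec: PhotometrySpec) -> tuple[PhotometryRecording, dict]:
    """Two-channel recording with exponentially decaying 470-nm transients."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    base = spec.baseline + spec.drift_slope * t
    f410 = base + spec.noise_sd * rng.standard_normal(n)
    signal = np.zeros(n)
    for ev in spec.event_times:
        mask = t >= ev
        signal[mask] += spec.transient_amplitude * np.exp(-(t[mask] - ev) / spec.transient_tau)
    f470 = base * (1.0 + signal) + spec.noise_sd * rng.standard_normal(n)
    rec = PhotometryRecording(
        t_s=t,
        f470=f470,
        f410=f410,
        sample_rate=spec.sample_rate,
        event_times_s=np.asarray(spec.event_times, float),
    )
    truth = {
        "kind": "photometry",
        "transient_amplitude": spec.transient_amplitude,
        "transient_tau": spec.transient_tau,
        "event_times": list(spec.event_times),
        "drift_slope": spec.drift_slope,
        "noise_sd": spec.noise_sd,
        "baseline": spec.baseline,
        "seed": spec.seed,
    }
    return rec, truth


def gen_vonfrey(spec: VonFreySpec) -> tuple[VonFreyAssay, dict]:
    """Binomial positives under a logistic psychometric function."""
    rng = np.random.default_rng(spec.seed)
    f = np.asarray(spec.filaments)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-(f - spec.true_threshold) * spec.slope))
    positives = rng.binomial(spec.trials_per_filament, prob)
    assay = VonFreyAssay(
        filaments=spec.filaments,
        positives=positives.tolist(),
        trials=spec.trials_per_filament,
    )
    truth = {
        "kind": "vonfrey",
        "true_threshold": spec.true_threshold,
        "slope": spec.slope,
        "filaments": list(spec.filaments),
        "response_probabilities": prob.tolist(),
        "trials_per_filament": spec.trials_per_filament,
        "seed": spec.seed,
    }
    return assay, truth
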