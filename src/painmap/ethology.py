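"""Computational-ethology analytics on labeled behavioral bouts.

Given per-animal ethograms (ordered bouts drawn from a fixed action
alphabet), this module computes action proportions, bout-level Markov
transition matrices, chord/flow summaries, hierarchical clustering of
repertoires, a t-SNE embedding with a descriptive linear boundary, and
per-action differential statistics with FDR control.

Transitions are counted at the bout level, self-transitions included:
two consecutive bouts of the same label are a legal self-transition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .containers import Ethogram, Trajectory, ValidationError
from .stats import auto_two_group_test, bh_adjust

__all__ = [
    "TransitionMatrix",
    "action_proportions",
    "proportion_table",
    "transition_matrix",
    "summarize_transitions",
    "cluster_proportions",
    "EmbedClassifier",
    "embed_and_classify",
    "differential_actions",
    "speed_map",
]


@dataclass
class TransitionMatrix:
    """Bout-to-bout transition probabilities over an action alphabet."""

    probabilities: pd.DataFrame  # K x K, rows sum to 1 (or 0 if unobserved)
    counts: pd.DataFrame  # K x K integer counts
    pseudocount: float
    unobserved_rows: pd.Series  # bool per label: no outgoing transition observed

    @property
    def labels(self) -> list[str]:
        return list(self.probabilities.index)


def action_proportions(e: Ethogram, weighting: str = "time") -> pd.Series:
    """Per-label behavioral proportions, time- or bout-weighted.

    Time weighting divides summed bout durations per label by the total
    recorded time; bout weighting divides bout counts by total bouts.
    """
    if e.n_bouts == 0:
        raise ValidationError("cannot compute proportions of an empty ethogram")
    if weighting == "time":
        w = pd.Series(e.durations, index=e.labels).groupby(level=0).sum()
    elif weighting == "bout":
        w = pd.Series(1.0, index=e.labels).groupby(level=0).sum()
    else:
        raise ValidationError(f"unknown weighting {weighting!r} (use 'time' or 'bout')")
    props = w.reindex(e.label_set, fill_value=0.0)
    return props / props.sum()


def proportion_table(
    ethograms: Sequence[Ethogram], weighting: str = "time"
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack per-animal proportion vectors; returns (table, group labels)."""
    if not ethograms:
        raise ValidationError("no ethograms given")
    rows, groups, index = [], [], []
    for i, e in enumerate(ethograms):
        rows.append(action_proportions(e, weighting))
        groups.append(e.group)
        index.append(e.animal_id or f"animal{i+1}")
    table = pd.DataFrame(rows, index=index)
    return table, pd.Series(groups, index=index, name="group")


def transition_matrix(e: Ethogram, pseudocount: float = 0.0) -> TransitionMatrix:
    """Row-stochastic bout-transition matrix with optional pseudocount.

    The pseudocount is added to every cell before row normalization.
    With pseudocount 0, labels that never start a transition produce an
    all-zero row flagged in ``unobserved_rows`` (not a uniform row).
    """
    if e.n_bouts < 2:
        raise ValidationError("transition matrix needs >= 2 bouts")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    labels = list(e.label_set)
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((k, k), dtype=int)
    seq = e.labels
    for a, b in zip(seq[:-1], seq[1:]):
        counts[idx[a], idx[b]] += 1
    smoothed = counts + pseudocount
    row_sums = smoothed.sum(axis=1)
    unobserved = row_sums == 0
    probs = np.zeros_like(smoothed, dtype=float)
    nz = ~unobserved
    probs[nz] = smoothed[nz] / row_sums[nz, None]
    return TransitionMatrix(
        probabilities=pd.DataFrame(probs, index=labels, columns=labels),
        counts=pd.DataFrame(counts, index=labels, columns=labels),
        pseudocount=pseudocount,
        unobserved_rows=pd.Series(unobserved, index=labels),
    )


def summarize_transitions(
    tm: TransitionMatrix,
    proportions: Optional[pd.Series] = None,
    floor: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format flow table for chord/heatmap rendering.

    Emits one row per (from, to) cell with probability >= ``floor``
    (floor 0 keeps all K² cells), carrying the source label's average
    proportion when given. Also returns the per-label self-transition
    share P(label -> label).
    """
    labels = tm.labels
    rows = []
    for a in labels:
        for b in labels:
            p = float(tm.probabilities.loc[a, b])
            if p < floor:
                continue
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "probability": p,
                    "from_proportion": float(proportions[a]) if proportions is not None else np.nan,
                    "self": a == b,
                }
            )
    flows = pd.DataFrame(rows, columns=["from", "to", "probability", "from_proportion", "self"])
    self_share = pd.Series(
        np.diag(tm.probabilities.to_numpy()), index=labels, name="self_transition_share"
    )
    return flows, self_share


def cluster_proportions(
    table: pd.DataFrame, k: int = 2, linkage: str = "ward"
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering of repertoire vectors (Euclidean distance).

    Returns per-animal cluster assignments (1..k) and the dendrogram
    leaf order. The default cut at k = 2 separates two behavioral
    phenotypes.
    """
    n = len(table)
    if k > n:
        raise ValidationError(f"k = {k} clusters exceeds N = {n} animals")
    if k < 1:
        raise ValidationError("k must be >= 1")
    z = scipy_linkage(table.to_numpy(float), method=linkage, metric="euclidean")
    assignments = fcluster(z, t=k, criterion="maxclust")
    order = [table.index[i] for i in leaves_list(z)]
    return pd.Series(assignments, index=table.index, name="cluster"), order


class EmbedClassifier(BaseEstimator):
    """t-SNE embedding with a linear SVM boundary in the 2-D plane.

    The embedding is descriptive: t-SNE is fit on the pooled feature
    vectors (action proportions or flattened transition probabilities)
    and a linear SVM is then trained on the 2-D coordinates. The
    reported ``accuracy_`` is training accuracy in embedding space and
    must not be read as an out-of-sample estimate.

    Parameters
    ----------
    perplexity : float or None
        t-SNE perplexity; None selects min(5, (N-1)/3) for small cohorts.
    random_state : int
        Fixed seed; identical inputs reproduce identical coordinates.
    """

    def __init__(self, perplexity: Optional[float] = None, random_state: int = 0,
                 C: float = 1.0):
        self.perplexity = perplexity
        self.random_state = random_state
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        n = X.shape[0]
        if n < 4:
            raise ValidationError("embedding needs N >= 4 samples")
        perp = self.perplexity
        if perp is None:
            perp = min(5.0, max(1.0, (n - 1) // 3))
        if perp >= n:
            raise ValidationError(f"perplexity {perp} infeasible for N = {n}")
        tsne = TSNE(
            n_components=2,
            perplexity=perp,
            random_state=self.random_state,
            init="pca",
        )
        self.embedding_ = tsne.fit_transform(X)
        self.perplexity_ = perp
        svm = SVC(kernel="linear", C=self.C, random_state=self.random_state)
        svm.fit(self.embedding_, y)
        self._svc_ = svm
        self.classes_ = svm.classes_
        self.boundary_coef_ = svm.coef_.ravel()
        self.boundary_intercept_ = float(svm.intercept_[0])
        self.accuracy_ = float(svm.score(self.embedding_, y))
        return self


def embed_and_classify(
    features: Union[pd.DataFrame, np.ndarray],
    labels: Sequence,
    perplexity: Optional[float] = None,
    seed: int = 0,
) -> tuple[np.ndarray, EmbedClassifier, float]:
    """Convenience wrapper: returns (coordinates, fitted model, accuracy)."""
    x = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    model = EmbedClassifier(perplexity=perplexity, random_state=seed).fit(x, np.asarray(labels))
    return model.embedding_, model, model.accuracy_


def differential_actions(
    table: pd.DataFrame,
    groups: pd.Series,
    fdr_q: float = 0.05,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Per-action two-group comparison with Benjamini-Hochberg control.

    One automatically selected two-sample test per action column; p
    values are BH-adjusted across the action family and thresholded at
    ``fdr_q``. Effect direction is reported relative to the two group
    labels in sorted order (positive = higher in the later label).
    """
    groups = pd.Series(np.asarray(groups), index=table.index)
    levels = sorted(groups.unique().tolist())
    if len(levels) != 2:
        raise ValidationError("differential testing needs exactly two groups")
    ga, gb = levels
    a_rows = table.loc[groups == ga]
    b_rows = table.loc[groups == gb]
    if len(a_rows) < 2 or len(b_rows) < 2:
        raise ValidationError("each group needs >= 2 animals")
    records = []
    for action in table.columns:
        res = auto_two_group_test(a_rows[action], b_rows[action], alpha_gate=alpha_gate)
        diff = float(b_rows[action].mean() - a_rows[action].mean())
        records.append(
            {
                "action": action,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_raw": res.p_raw,
                "mean_diff": diff,
                "direction": f"{gb}>{ga}" if diff > 0 else (f"{ga}>{gb}" if diff < 0 else "none"),
            }
        )
    out = pd.DataFrame(records).set_index("action")
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] <= fdr_q
    return out


def speed_map(traj: Trajectory, grid_cm: float = 5.0) -> tuple[np.ndarray, dict]:
    """Spatial map of mean locomotion speed plus path summaries.

    Speed at each step is the finite-difference displacement times the
    sample rate, assigned to the grid cell of the step's start point.
    Unvisited cells are NaN. Returns ``(grid, summary)`` with summary
    keys total_distance_cm, mean_speed_cms, max_speed_cms.
    """
    if traj.n_samples < 2:
        raise ValidationError("speed map needs >= 2 trajectory samples")
    if grid_cm <= 0:
        raise ValidationError("grid_cm must be positive")
    x, y = traj.x_cm, traj.y_cm
    dx, dy = np.diff(x), np.diff(y)
    step = np.hypot(dx, dy)
    speed = step * traj.sample_rate
    # grid over the arena bounding box
    if hasattr(traj.arena, "side_cm"):
        x0 = y0 = 0.0
        x1 = y1 = traj.arena.side_cm
    else:
        reach = traj.arena.center_cm / 2 + traj.arena.arm_length_cm
        x0 = y0 = -reach
        x1 = y1 = reach
    nx = max(1, int(np.ceil((x1 - x0) / grid_cm)))
    ny = max(1, int(np.ceil((y1 - y0) / grid_cm)))
    ix = np.clip(((x[:-1] - x0) / grid_cm).astype(int), 0, nx - 1)
    iy = np.clip(((y[:-1] - y0) / grid_cm).astype(int), 0, ny - 1)
    total = np.zeros((ny, nx))
    hits = np.zeros((ny, nx))
    np.add.at(total, (iy, ix), speed)
    np.add.at(hits, (iy, ix), 1)
    with np.errstate(invalid="ignore"):
        grid = np.where(hits > 0, total / np.where(hits > 0, hits, 1), np.nan)
    summary = {
        "total_distance_cm": float(step.sum()),
        "mean_speed_cms": float(speed.mean()),
        "max_speed_cms": float(speed.max()),
    }
    return grid, summary
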