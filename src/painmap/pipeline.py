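"""Config-driven pipeline runner with reproducible manifests.

A run configuration (YAML/JSON) names the stages to execute and their
parameters; stages execute in dependency order and every run writes a
``manifest.json`` recording inputs, parameters, seeds, package version
and a SHA-256 digest of each output file. Manifests contain no
timestamps, so re-running an identical seeded config reproduces an
identical manifest byte for byte.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import __version__
from .activation import cross_validate, map_activation
from .assays import openfield_metrics, response_frequency, vonfrey_threshold
from .containers import SquareArena, ValidationError
from .ethology import (
    action_proportions,
    cluster_proportions,
    differential_actions,
    embed_and_classify,
    proportion_table,
    summarize_transitions,
    transition_matrix,
)
from .io import (
    read_counts,
    read_ethogram,
    read_photometry,
    read_trajectory,
    read_vonfrey,
    write_counts,
    write_ethogram,
    write_json,
    write_photometry,
    write_trajectory,
    write_vonfrey,
)
from .physiology import auc, compute_dff, peri_event
from .simulate import (
    ACTION_LABELS,
    EthogramSpec,
    PhotometrySpec,
    RegionCountSpec,
    TrajectorySpec,
    VonFreySpec,
    gen_ethogram,
    gen_photometry,
    gen_region_counts,
    gen_trajectory,
    gen_vonfrey,
)

log = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "map_activation", "ethology", "assays", "photometry")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sticky_transition_matrix(k: int, stay: float, rng: np.random.Generator) -> np.ndarray:
    """Row-stochastic matrix with diagonal mass ``stay`` and Dirichlet rest."""
    m = np.zeros((k, k))
    for i in range(k):
        off = rng.dirichlet(np.ones(k - 1)) * (1 - stay)
        m[i] = np.insert(off, i, stay)
    return m


def _simulate_stage(cfg: dict, out: Path, seed: int) -> dict:
    """Generate the configured synthetic inputs; returns output registry."""
    outputs: dict[str, str] = {}
    sim = cfg.get("simulate", {})
    rng = np.random.default_rng(seed)

    cc = sim.get("region_counts", {})
    spec = RegionCountSpec(
        n_per_group=int(cc.get("n_per_group", 3)),
        region_names=[f"R{i:03d}" for i in range(1, int(cc.get("n_regions", 129)) + 1)],
        baseline_mean=float(cc.get("baseline_mean", 200.0)),
        dispersion=float(cc.get("dispersion", 10.0)),
        effect_regions=cc.get("effect_regions", [0, 1, 2, 3, 4]),
        effect_log_fold=float(cc.get("effect_log_fold", 0.7)),
        seed=int(rng.integers(2**31)),
    )
    data, truth = gen_region_counts(spec)
    write_counts(data, out / "counts.csv")
    write_json(truth, out / "counts.truth.json")
    outputs["counts"] = "counts.csv"

    ec = sim.get("ethograms", {})
    n_con = int(ec.get("n_con", 11))
    n_ma = int(ec.get("n_ma", 6))
    stay_con = float(ec.get("self_transition_con", 0.3))
    stay_ma = float(ec.get("self_transition_ma", 0.6))
    duration = float(ec.get("total_duration", 600.0))
    k = len(ACTION_LABELS)
    tm_con = _sticky_transition_matrix(k, stay_con, rng)
    tm_ma = _sticky_transition_matrix(k, stay_ma, rng)
    groups_file = []
    (out / "ethograms").mkdir(exist_ok=True)
    for group, n_animals, tm in (("CON", n_con, tm_con), ("MA", n_ma, tm_ma)):
        for i in range(n_animals):
            espec = EthogramSpec(
                transition_matrix=tm,
                total_duration=duration,
                seed=int(rng.integers(2**31)),
            )
            animal = f"{group.lower()}{i+1:02d}"
            e, etruth = gen_ethogram(espec, animal_id=animal, group=group)
            write_ethogram(e, out / "ethograms" / f"{animal}.csv")
            groups_file.append({"animal_id": animal, "group": group})
    pd.DataFrame(groups_file).to_csv(out / "ethograms" / "groups.csv", index=False)
    write_json(
        {"CON": tm_con.tolist(), "MA": tm_ma.tolist(), "labels": list(ACTION_LABELS)},
        out / "ethograms" / "transition.truth.json",
    )
    outputs["ethograms"] = "ethograms/"

    tc = sim.get("trajectories", {})
    for group, avoid in (("CON", float(tc.get("center_avoidance_con", 0.5))),
                         ("MA", float(tc.get("center_avoidance_ma", 2.0)))):
        tspec = TrajectorySpec(
            arena=SquareArena(side_cm=float(tc.get("side_cm", 50.0))),
            center_avoidance=avoid,
            duration=float(tc.get("duration", 600.0)),
            sample_rate=float(tc.get("sample_rate", 25.0)),
            seed=int(rng.integers(2**31)),
        )
        traj, _ = gen_trajectory(tspec)
        write_trajectory(traj, out / f"openfield_{group.lower()}.csv")
        outputs[f"trajectory_{group}"] = f"openfield_{group.lower()}.csv"

    pc = sim.get("photometry", {})
    pspec = PhotometrySpec(
        duration=float(pc.get("duration", 120.0)),
        event_times=pc.get("event_times", [20, 40, 60, 80, 100]),
        transient_amplitude=float(pc.get("transient_amplitude", 0.2)),
        noise_sd=float(pc.get("noise_sd", 0.2)),
        seed=int(rng.integers(2**31)),
    )
    rec, ptruth = gen_photometry(pspec)
    write_photometry(rec, out / "photometry.csv")
    write_json(ptruth, out / "photometry.truth.json")
    outputs["photometry"] = "photometry.csv"

    vc = sim.get("vonfrey", {})
    vspec = VonFreySpec(
        true_threshold=float(vc.get("true_threshold", 2.6)),
        slope=float(vc.get("slope", 10.0)),
        seed=int(rng.integers(2**31)),
    )
    assay, vtruth = gen_vonfrey(vspec)
    write_vonfrey(assay, out / "vonfrey.csv")
    write_json(vtruth, out / "vonfrey.truth.json")
    outputs["vonfrey"] = "vonfrey.csv"
    return outputs


def _map_activation_stage(cfg: dict, out: Path, seed: int) -> dict:
    params = cfg.get("map_activation", {})
    data = read_counts(out / "counts.csv", validate_acronyms=False)
    z, model, pattern, curve = map_activation(
        data,
        shrinkage=params.get("shrinkage", "auto"),
        regularization=float(params.get("regularization", 1.0)),
        seed=seed,
    )
    rank = {name: i + 1 for i, name in enumerate(curve.ordered_regions)}
    cum = dict(zip(curve.ordered_regions, curve.cumulative_fraction))
    table = pd.DataFrame(
        {
            "region": data.region_names,
            "weight": model.weights[:, 0],
            "pattern": pattern.A[:, 0],
            "abs_rank": [rank[r] for r in data.region_names],
            "cum_fraction": [cum[r] for r in data.region_names],
        }
    )
    table.to_csv(out / "activation_pattern.csv", index=False)
    pd.DataFrame(pattern.sigma_x, index=data.region_names,
                 columns=data.region_names).to_csv(out / "feature_covariance.csv")
    cv = None
    counts = np.unique(data.group_labels, return_counts=True)[1]
    if counts.min() >= 2:
        cv = cross_validate(z, scheme="leave-one-out", seed=seed)
    write_json(
        {
            "training_accuracy": model.training_accuracy,
            "shrinkage_used": pattern.shrinkage_used,
            "classes": list(model.classes),
            "cross_validation": cv,
            "seed": seed,
        },
        out / "activation_meta.json",
    )
    return {
        "activation_pattern": "activation_pattern.csv",
        "feature_covariance": "feature_covariance.csv",
        "activation_meta": "activation_meta.json",
    }


def _ethology_stage(cfg: dict, out: Path, seed: int) -> dict:
    params = cfg.get("ethology", {})
    edir = out / "ethograms"
    groups = pd.read_csv(edir / "groups.csv")
    ethograms = []
    for _, row in groups.iterrows():
        e = read_ethogram(edir / f"{row.animal_id}.csv", label_set=ACTION_LABELS,
                          animal_id=row.animal_id, group=row.group)
        ethograms.append(e)
    table, grp = proportion_table(ethograms, weighting=params.get("weighting", "time"))
    table.assign(group=grp).to_csv(out / "action_proportions.csv")

    long_rows = []
    for e in ethograms:
        tm = transition_matrix(e, pseudocount=float(params.get("pseudocount", 0.0)))
        props = action_proportions(e, weighting=params.get("weighting", "time"))
        flows, _ = summarize_transitions(tm, props)
        flows.insert(0, "animal_id", e.animal_id)
        flows.insert(1, "group", e.group)
        long_rows.append(flows)
    pd.concat(long_rows, ignore_index=True).to_csv(out / "transition_flows.csv", index=False)

    clusters, order = cluster_proportions(table, k=int(params.get("clusters", 2)))
    clusters.to_frame().assign(group=grp).to_csv(out / "clusters.csv")

    coords, emodel, acc = embed_and_classify(table, grp, seed=seed)
    pd.DataFrame(coords, index=table.index, columns=["tsne1", "tsne2"]).assign(
        group=grp
    ).to_csv(out / "embedding.csv")

    diff = differential_actions(table, grp, fdr_q=float(params.get("fdr_q", 0.05)))
    diff.to_csv(out / "differential_actions.csv")
    write_json({"embedding_accuracy": acc, "dendrogram_order": order, "seed": seed},
               out / "ethology_meta.json")
    return {
        "action_proportions": "action_proportions.csv",
        "transition_flows": "transition_flows.csv",
        "clusters": "clusters.csv",
        "embedding": "embedding.csv",
        "differential_actions": "differential_actions.csv",
        "ethology_meta": "ethology_meta.json",
    }


def _assays_stage(cfg: dict, out: Path, seed: int) -> dict:
    params = cfg.get("assays", {})
    outputs = {}
    assay = read_vonfrey(out / "vonfrey.csv")
    thr = vonfrey_threshold(assay)
    freq = response_frequency(assay)
    write_json(
        {
            "threshold": None if thr.censored else thr.value,
            "censored": thr.censored,
            "label": thr.label,
            "sentinel": thr.sentinel,
            "response_pct": {f"{f:g}": v for f, v in freq.items()},
        },
        out / "vonfrey_metrics.json",
    )
    outputs["vonfrey_metrics"] = "vonfrey_metrics.json"
    for group in ("CON", "MA"):
        p = out / f"openfield_{group.lower()}.csv"
        if p.exists():
            traj = read_trajectory(p)
            zm = openfield_metrics(traj, center_fraction=float(params.get("center_fraction", 0.5)))
            write_json(zm.to_dict(), out / f"openfield_metrics_{group.lower()}.json")
            outputs[f"openfield_metrics_{group}"] = f"openfield_metrics_{group.lower()}.json"
    return outputs


def _photometry_stage(cfg: dict, out: Path, seed: int) -> dict:
    params = cfg.get("photometry", {})
    rec = read_photometry(out / "photometry.csv")
    dff = compute_dff(rec)
    peri = peri_event(dff, window_pre_s=float(params.get("window_pre_s", 2.0)),
                      window_post_s=float(params.get("window_post_s", 5.0)))
    trial_auc = auc(peri)
    pd.DataFrame(peri.traces, columns=[f"{t:.3f}" for t in peri.time_s]).to_csv(
        out / "peri_event.csv", index=False
    )
    write_json(
        {
            "fit_params": dff.fit_params,
            "n_trials": peri.n_trials,
            "n_dropped": peri.n_dropped,
            "auc_per_trial": trial_auc.tolist(),
            "auc_mean": float(trial_auc.mean()),
        },
        out / "photometry_metrics.json",
    )
    return {"peri_event": "peri_event.csv", "photometry_metrics": "photometry_metrics.json"}


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "map_activation": _map_activation_stage,
    "ethology": _ethology_stage,
    "assays": _assays_stage,
    "photometry": _photometry_stage,
}


def run_pipeline(config: dict, out_dir: Union[str, Path]) -> dict:
    """Execute the configured stages and write a deterministic manifest."""
    stages = config.get("stages", list(KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValidationError(f"unknown pipeline stage(s): {unknown}")
    seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    for stage in KNOWN_STAGES:  # dependency order
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            outputs.update(_STAGE_FUNCS[stage](config, out, seed))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest = {
        "package": "painmap",
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [s for s in KNOWN_STAGES if s in stages],
        "outputs": {
            name: {"path": rel, "sha256": _sha256(out / rel)}
            for name, rel in sorted(outputs.items())
            if (out / rel).is_file()
        },
    }
    write_json(manifest, out / "manifest.json")
    return manifest
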