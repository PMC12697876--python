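"""CSV/JSON readers and writers for every pipeline input and output.

All tabular I/O is plain CSV with JSON sidecars for ground truth and
run metadata; desk-scale data never justifies binary formats. Readers
are schema-checked and raise distinct messages for a missing file, an
empty file, missing columns, and non-numeric cells.
"""
from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .containers import (
    Ethogram,
    PhotometryRecording,
    PlusMazeArena,
    RegionActivationMatrix,
    SquareArena,
    Trajectory,
    ValidationError,
    VonFreyAssay,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_table",
    "read_counts",
    "write_counts",
    "read_ethogram",
    "write_ethogram",
    "read_trajectory",
    "write_trajectory",
    "read_photometry",
    "write_photometry",
    "read_vonfrey",
    "write_vonfrey",
    "load_config",
    "load_allen_acronyms",
    "write_json",
]


def load_allen_acronyms() -> frozenset[str]:
    """Bundled list of common Allen Atlas structure acronyms."""
    text = resources.files("painmap.data").joinpath("allen_acronyms.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def read_table(
    path: Union[str, Path],
    required_columns: Sequence[str],
    numeric_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read a CSV with schema validation and distinct error messages."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"input file is empty: {path}") from None
    if df.empty:
        raise ValidationError(f"input file has no data rows: {path}")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing}")
    for col in numeric_columns or []:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise ValidationError(f"{path.name}: non-numeric cells in column '{col}'")
        df[col] = coerced
    log.info("read %s: %d rows x %d columns", path.name, *df.shape)
    return df


# ---------------------------------------------------------------------------
# Region counts
# ---------------------------------------------------------------------------

def read_counts(path: Union[str, Path], validate_acronyms: bool = True) -> RegionActivationMatrix:
    """Counts CSV: one row per animal, a ``group`` column plus region columns.

    Region names are checked against the bundled Allen-acronym list;
    unknown names warn but never fail (custom parcellations are legal).
    """
    df = read_table(path, required_columns=["group"])
    ram = RegionActivationMatrix.from_frame(df)
    if validate_acronyms:
        known = load_allen_acronyms()
        unknown = [r for r in ram.region_names if r not in known]
        if unknown and len(unknown) < len(ram.region_names):
            warnings.warn(
                f"{len(unknown)} region names not in the bundled Allen acronym list "
                f"(e.g. {unknown[:5]})",
                UserWarning,
                stacklevel=2,
            )
    return ram


def write_counts(data: RegionActivationMatrix, path: Union[str, Path]) -> None:
    data.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ethograms
# ---------------------------------------------------------------------------

def read_ethogram(
    path: Union[str, Path],
    label_set: Optional[Sequence[str]] = None,
    animal_id: str = "",
    group: str = "",
) -> Ethogram:
    df = read_table(path, required_columns=["label", "start_s", "end_s"],
                    numeric_columns=["start_s", "end_s"])
    labels = tuple(label_set) if label_set is not None else tuple(sorted(df["label"].unique()))
    return Ethogram(bouts=df[["label", "start_s", "end_s"]], label_set=labels,
                    animal_id=animal_id, group=group)


def write_ethogram(e: Ethogram, path: Union[str, Path]) -> None:
    e.bouts.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _arena_to_dict(arena) -> dict:
    if isinstance(arena, SquareArena):
        return {"type": "square", "side_cm": arena.side_cm}
    if isinstance(arena, PlusMazeArena):
        return {
            "type": "plus_maze",
            "arm_length_cm": arena.arm_length_cm,
            "arm_width_cm": arena.arm_width_cm,
            "center_cm": arena.center_cm,
        }
    raise ValidationError(f"unsupported arena type: {type(arena).__name__}")


def arena_from_dict(cfg: dict):
    kind = cfg.get("type")
    if kind == "square":
        return SquareArena(side_cm=float(cfg.get("side_cm", 50.0)))
    if kind == "plus_maze":
        return PlusMazeArena(
            arm_length_cm=float(cfg.get("arm_length_cm", 30.0)),
            arm_width_cm=float(cfg.get("arm_width_cm", 5.0)),
            center_cm=float(cfg.get("center_cm", 5.0)),
        )
    raise ValidationError(f"unknown arena type in config: {kind!r}")


def read_trajectory(path: Union[str, Path], arena=None,
                    sample_rate: Optional[float] = None) -> Trajectory:
    """Trajectory CSV (t_s,x_cm,y_cm) + optional JSON arena sidecar.

    If ``arena`` is None, a sidecar ``<stem>.arena.json`` next to the
    CSV is loaded; failing that, a 50-cm square arena is assumed.
    """
    path = Path(path)
    df = read_table(path, required_columns=["t_s", "x_cm", "y_cm"],
                    numeric_columns=["t_s", "x_cm", "y_cm"])
    if arena is None:
        sidecar = path.with_suffix("").with_suffix(".arena.json")
        if sidecar.exists():
            arena = arena_from_dict(json.loads(sidecar.read_text()))
        else:
            arena = SquareArena()
    t = df["t_s"].to_numpy()
    if sample_rate is None:
        dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
        sample_rate = 1.0 / dt
    return Trajectory(t_s=t, x_cm=df["x_cm"].to_numpy(), y_cm=df["y_cm"].to_numpy(),
                      sample_rate=sample_rate, arena=arena)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix("").with_suffix(".arena.json")
    sidecar.write_text(json.dumps(_arena_to_dict(traj.arena), indent=2))


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def read_photometry(path: Union[str, Path],
                    event_times: Optional[Sequence[float]] = None) -> PhotometryRecording:
    """Photometry CSV (t_s,f470,f410) + optional ``<stem>.events.json``."""
    path = Path(path)
    df = read_table(path, required_columns=["t_s", "f470", "f410"],
                    numeric_columns=["t_s", "f470", "f410"])
    if event_times is None:
        sidecar = path.with_suffix("").with_suffix(".events.json")
        event_times = json.loads(sidecar.read_text()) if sidecar.exists() else []
    t = df["t_s"].to_numpy()
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    return PhotometryRecording(
        t_s=t, f470=df["f470"].to_numpy(), f410=df["f410"].to_numpy(),
        sample_rate=1.0 / dt, event_times_s=np.asarray(event_times, float),
    )


def write_photometry(rec: PhotometryRecording, path: Union[str, Path]) -> None:
    path = Path(path)
    rec.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix("").with_suffix(".events.json")
    sidecar.write_text(json.dumps(list(map(float, rec.event_times_s))))


# ---------------------------------------------------------------------------
# von Frey
# ---------------------------------------------------------------------------

def read_vonfrey(path: Union[str, Path]) -> VonFreyAssay:
    df = read_table(path, required_columns=["filament", "positives", "trials"],
                    numeric_columns=["filament", "positives", "trials"])
    trials = df["trials"].unique()
    if len(trials) != 1:
        raise ValidationError("von Frey table must use a single trial count per ladder")
    return VonFreyAssay(filaments=df["filament"].tolist(),
                        positives=df["positives"].astype(int).tolist(),
                        trials=int(trials[0]))


def write_vonfrey(assay: VonFreyAssay, path: Union[str, Path]) -> None:
    assay.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config / JSON helpers
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file does not exist: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config must be a mapping, got {type(cfg).__name__}")
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
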