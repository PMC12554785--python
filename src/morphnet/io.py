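"""Readers, writers and shared spatial containers.

Tabular data travel as TSV (tab-delimited, UTF-8, header row, '.' decimal);
volumes as NIfTI-1.  Subject/parcel alignment is always validated by id and
name, never by position alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LabelVolume",
    "PipelineConfig",
    "DEFAULT_PARCELS",
    "default_atlas",
    "read_gmv_matrix",
    "write_gmv_matrix",
    "read_subjects",
    "write_subjects",
    "read_nifti_stack",
    "extract_parcel_means",
    "write_reports",
]

#: Default parcel label set: a small bilateral selection of basal-ganglia,
#: parietal, temporal and motor regions commonly implicated in parkinsonian
#: morphometry (pallidum, precuneus, fusiform, inferior/middle temporal,
#: supplementary motor, precentral, hippocampus).
DEFAULT_PARCELS = [
    "PAL.L", "PAL.R",
    "PCUN.L", "PCUN.R",
    "FFG.L", "FFG.R",
    "ITG.L", "ITG.R",
    "MTG.R", "SMA.R",
    "PreCG.L", "HIP.L",
]


@dataclass
class LabelVolume:
    """Integer-labelled 3-D atlas volume.

    ``0`` is background; ``labels`` maps each positive integer to a parcel
    name.  Voxel indices are 0-based; world coordinates come from ``affine``.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("atlas volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("atlas volume must hold integer labels")

    @property
    def names(self) -> list[str]:
        return [self.labels[k] for k in sorted(self.labels)]

    def label_of(self, name: str) -> int:
        for k, v in self.labels.items():
            if v == name:
                return k
        raise KeyError(f"unknown parcel name: {name!r}")

    def empty_labels(self) -> list[str]:
        """Names whose label has no voxel in the grid (flagged, not fatal)."""
        present = set(np.unique(self.data))
        return [v for k, v in self.labels.items() if k not in present]

    def centroids(self) -> dict[str, np.ndarray]:
        """World-coordinate centroid of each non-empty parcel."""
        out: dict[str, np.ndarray] = {}
        for k, name in self.labels.items():
            idx = np.argwhere(self.data == k)
            if idx.size == 0:
                continue
            vox = idx.mean(axis=0)
            world = self.affine @ np.append(vox, 1.0)
            out[name] = world[:3]
        return out

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        nib.save(img, str(path))
        Path(str(path) + ".labels.json").write_text(
            json.dumps({str(k): v for k, v in self.labels.items()}, indent=1)
        )

    @classmethod
    def from_nifti(cls, path: str | Path,
                   labels: Mapping[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int32)
        if labels is None:
            side = Path(str(path) + ".labels.json")
            if side.exists():
                labels = {int(k): v for k, v in json.loads(side.read_text()).items()}
            else:
                labels = {int(k): f"label{int(k)}" for k in np.unique(data) if k != 0}
        return cls(data=data, affine=np.asarray(img.affine), labels=dict(labels))


def default_atlas(parcels: Sequence[str] = DEFAULT_PARCELS,
                  shape: tuple[int, int, int] = (24, 24, 24),
                  block: int = 4) -> LabelVolume:
    """Desk-scale atlas: each parcel a ``block``³ cube on a small grid.

    Cubes are laid out on a regular lattice with one-voxel gaps so that
    clusters from different parcels never touch under 26-connectivity.
    """
    data = np.zeros(shape, dtype=np.int32)
    labels: dict[int, str] = {}
    per_axis = [s // (block + 1) for s in shape]
    capacity = int(np.prod(per_axis))
    if len(parcels) > capacity:
        raise ValueError(f"grid {shape} holds at most {capacity} parcels")
    for i, name in enumerate(parcels):
        ix = i % per_axis[0]
        iy = (i // per_axis[0]) % per_axis[1]
        iz = i // (per_axis[0] * per_axis[1])
        x0, y0, z0 = ix * (block + 1), iy * (block + 1), iz * (block + 1)
        data[x0:x0 + block, y0:y0 + block, z0:z0 + block] = i + 1
        labels[i + 1] = name
    affine = np.eye(4)
    affine[:3, 3] = -np.asarray(shape) / 2.0
    return LabelVolume(data=data, affine=affine, labels=labels)


# ---------------------------------------------------------------------------
# tabular IO

_FLOAT_FMT = "%.17g"


def write_gmv_matrix(gmv: pd.DataFrame, path: str | Path) -> None:
    gmv.to_csv(path, sep="\t", index_label="id", float_format=_FLOAT_FMT)


def read_gmv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate subject id in GMV matrix: {dup!r}")
    if len(set(df.columns)) != len(df.columns):
        raise ValueError("duplicate parcel names in GMV matrix header")
    return df.astype(float)


def write_subjects(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "group", "age", "sex", "tiv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate subject id: {dup!r}")
    bad_group = set(df["group"]) - {"patient", "control"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    if (df["age"] <= 0).any() or (df["tiv"] <= 0).any():
        raise ValueError("age and TIV must be positive")
    return df


def read_nifti_stack(paths: Sequence[str | Path]) -> tuple[np.ndarray, np.ndarray]:
    """Load per-subject volumes into an (n, x, y, z) stack.

    All images must share shape and affine; a mismatch is an error naming
    the offending file.
    """
    if not paths:
        raise ValueError("empty NIfTI stack")
    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        a = np.asarray(img.affine)
        d = np.asanyarray(img.dataobj).astype(float)
        if affine is None:
            affine, shape = a, d.shape
        else:
            if d.shape != shape:
                raise ValueError(f"shape mismatch in NIfTI stack: {p}")
            if not np.allclose(a, affine, atol=1e-6):
                raise ValueError(f"affine mismatch in NIfTI stack: {p}")
        vols.append(d)
    return np.stack(vols), affine


def extract_parcel_means(stack: np.ndarray, atlas: LabelVolume,
                         subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean voxel value per atlas label per subject.

    Parcels whose label has no voxel are absent from the result and flagged
    with a warning.
    """
    if stack.shape[1:] != atlas.data.shape:
        raise ValueError("stack grid does not match atlas grid")
    empty = atlas.empty_labels()
    if empty:
        warnings.warn(f"atlas labels with no voxels skipped: {empty}")
    cols, names = [], []
    for k in sorted(atlas.labels):
        mask = atlas.data == k
        if not mask.any():
            continue
        names.append(atlas.labels[k])
        cols.append(stack[:, mask].mean(axis=1))
    idx = list(subject_ids) if subject_ids is not None else list(range(stack.shape[0]))
    return pd.DataFrame(np.column_stack(cols), index=idx, columns=names)


def write_reports(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write a mapping of name -> DataFrame/dict/ndarray as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        elif isinstance(obj, np.ndarray):
            p = out / f"{name}.tsv"
            np.savetxt(p, obj, delimiter="\t", fmt=_FLOAT_FMT)
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, default=_json_default))
        written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one serializable record.

    Every stochastic stage derives its seed from ``seed`` so a run is a
    deterministic function of (inputs, config).
    """

    seed: int = 0
    out_dir: str = "morphnet_out"
    # simulation
    n_patient: int = 61
    n_control: int = 61
    # morphometry
    forming_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    fwhm: float = 8.0
    # scn / cascn
    scn_seed_parcel: str = "PAL.L"
    q: float = 0.05
    lag: int = 1
    # dfnc
    window_length: int = 22
    window_step: int = 1
    taper_sd: float = 3.0
    k_states: int = 5
    n_init: int = 20
    n_timepoints: int = 160
    # prediction
    n_iterations: int = 1000
    n_lasso_repeats: int = 1000
    retain_fraction: float = 0.30
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "clinical": True, "morphometry": True,
        "scn": True, "cascn": True, "dfnc": True, "predict": True,
    })

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
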