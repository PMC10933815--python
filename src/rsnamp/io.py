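"""Readers and writers for the pipeline's on-disk formats.

Group maps and BOLD runs travel either as delimited matrices (CSV, voxels in
rows) or as 4-D NIfTI (flattened in C order over a 3-D box); measure tables,
netmats and linkage tables are CSV; configs and manifests are YAML/JSON.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decompose import BoldRun, GroupMaps

__all__ = [
    "save_group_maps_csv",
    "load_group_maps_csv",
    "save_group_maps_nifti",
    "load_group_maps_nifti",
    "save_run_nifti",
    "load_run_nifti",
    "save_measure_table",
    "load_measure_table",
    "save_netmat",
    "load_netmat",
    "save_linkage",
    "config_to_yaml",
    "config_from_yaml",
]


def _box_shape(n_voxels: int) -> tuple[int, int, int]:
    """Smallest 3-D box (x, y, 1) holding n_voxels in C order."""
    side = int(np.ceil(np.sqrt(n_voxels)))
    ny = int(np.ceil(n_voxels / side))
    return (side, ny, 1)


def save_group_maps_csv(maps: GroupMaps, path: str | Path) -> None:
    pd.DataFrame(maps.weights, columns=maps.network_labels).to_csv(path, index=False)


def load_group_maps_csv(path: str | Path) -> GroupMaps:
    df = pd.read_csv(path)
    return GroupMaps(weights=df.to_numpy(dtype=float),
                     network_labels=list(df.columns))


def save_group_maps_nifti(maps: GroupMaps, path: str | Path) -> None:
    """One 3-D volume per network, voxels padded into a flat box."""
    import nibabel as nib

    shape = maps.shape or _box_shape(maps.n_voxels)
    vol = np.zeros((int(np.prod(shape)), maps.n_networks))
    vol[: maps.n_voxels] = maps.weights
    img = nib.Nifti1Image(
        vol.reshape(*shape, maps.n_networks, order="C"),
        maps.affine if maps.affine is not None else np.eye(4),
    )
    img.header["descrip"] = f"nvox={maps.n_voxels}".encode()
    nib.save(img, str(path))


def load_group_maps_nifti(path: str | Path, n_voxels: int | None = None) -> GroupMaps:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as err:
        raise IOError(f"cannot read NIfTI group maps from {path}: {err}") from err
    if data.ndim != 4:
        raise IOError(f"{path}: expected a 4-D image, got shape {data.shape}")
    flat = data.reshape(-1, data.shape[3], order="C")
    if n_voxels is None:
        desc = img.header["descrip"].item().decode(errors="ignore")
        n_voxels = (
            int(desc.split("=", 1)[1]) if desc.startswith("nvox=") else flat.shape[0]
        )
    return GroupMaps(
        weights=flat[:n_voxels],
        shape=tuple(data.shape[:3]),
        affine=np.asarray(img.affine),
    )


def save_run_nifti(run: BoldRun, path: str | Path) -> None:
    import nibabel as nib

    shape = run.shape or _box_shape(run.n_voxels)
    vol = np.zeros((int(np.prod(shape)), run.n_timepoints))
    vol[: run.n_voxels] = run.data
    img = nib.Nifti1Image(
        vol.reshape(*shape, run.n_timepoints, order="C"),
        run.affine if run.affine is not None else np.eye(4),
    )
    img.header["descrip"] = f"nvox={run.n_voxels}".encode()
    nib.save(img, str(path))


def load_run_nifti(path: str | Path, n_voxels: int | None = None,
                   subject_id: str | int = 0) -> BoldRun:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as err:
        raise IOError(f"cannot read NIfTI run from {path}: {err}") from err
    if data.ndim != 4:
        raise IOError(f"{path}: expected a 4-D image, got shape {data.shape}")
    flat = data.reshape(-1, data.shape[3], order="C")
    if n_voxels is None:
        desc = img.header["descrip"].item().decode(errors="ignore")
        n_voxels = (
            int(desc.split("=", 1)[1]) if desc.startswith("nvox=") else flat.shape[0]
        )
    return BoldRun(
        data=flat[:n_voxels],
        subject_id=subject_id,
        shape=tuple(data.shape[:3]),
        affine=np.asarray(img.affine),
    )


def save_measure_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_measure_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_netmat(c: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(c, index=labels, columns=labels).to_csv(path)


def load_netmat(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def save_linkage(linkage: np.ndarray, path: str | Path) -> None:
    """Standard 4-column merge table (left, right, height, count)."""
    pd.DataFrame(
        linkage, columns=["left", "right", "height", "count"]
    ).to_csv(path, index=False)


def config_to_yaml(cfg, path: str | Path) -> None:
    payload = dataclasses.asdict(cfg)
    for key, val in payload.items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
        elif isinstance(val, tuple):
            payload[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path: str | Path):
    from .synthcohort import ConfoundSpec, PhenotypeSpec, SimConfig

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["phenotype_spec"] = tuple(
        PhenotypeSpec(**p) if isinstance(p, dict) else PhenotypeSpec(*p)
        for p in payload.get("phenotype_spec", ())
    )
    payload["confound_spec"] = tuple(
        ConfoundSpec(**c) if isinstance(c, dict) else ConfoundSpec(*c)
        for c in payload.get("confound_spec", ())
    )
    for key in ("synchrony_range", "voxel_sd_range"):
        if key in payload:
            payload[key] = tuple(payload[key])
    if isinstance(payload.get("between_net_corr"), list):
        payload["between_net_corr"] = np.asarray(payload["between_net_corr"])
    return SimConfig(**payload)
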