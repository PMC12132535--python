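"""Reading and writing threshold tables and neuroimaging volumes.

Threshold tables are plain columnar text (CSV/TSV autodetected by pandas)
with the long-format columns participant, condition, hemifield,
session_order, threshold — the layout the deposited study data uses and
the one every analysis function consumes. Volumes are single-image NIfTI-1
read through nibabel; a pair used for the overlap analysis must agree in
shape and affine, and the shared mask is the intersection of both
finite-value supports (optionally intersected with an explicit mask image).
Voxel indices are 0-based internally; world coordinates are MNI mm through
the affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import CONDITIONS, HEMIFIELDS, VolumePair

__all__ = [
    "read_threshold_table",
    "write_threshold_table",
    "read_volume",
    "read_volume_pair",
    "write_volume",
]

TABLE_COLUMNS = ["participant", "condition", "hemifield", "session_order", "threshold"]


def read_threshold_table(path) -> pd.DataFrame:
    """Load and validate a long-format threshold table.

    Raises ``ValueError`` listing every offending row/column: missing
    columns, unknown condition or hemifield labels, and thresholds outside
    [0, 100].
    """
    df = pd.read_csv(path, sep=None, engine="python")
    problems = []
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_cond = df.index[~df["condition"].isin(CONDITIONS)]
    for i in bad_cond:
        problems.append(f"row {i + 2}: unknown condition {df.loc[i, 'condition']!r}")
    bad_hemi = df.index[~df["hemifield"].isin(HEMIFIELDS)]
    for i in bad_hemi:
        problems.append(f"row {i + 2}: unknown hemifield {df.loc[i, 'hemifield']!r}")
    thr = pd.to_numeric(df["threshold"], errors="coerce")
    bad_thr = df.index[~((thr >= 0.0) & (thr <= 100.0))]
    for i in bad_thr:
        problems.append(f"row {i + 2}: threshold {df.loc[i, 'threshold']!r} outside [0, 100]")
    if problems:
        raise ValueError(f"{path}: invalid threshold table:\n" + "\n".join(problems))
    df["threshold"] = thr
    df["session_order"] = df["session_order"].astype(int)
    return df[TABLE_COLUMNS]


def write_threshold_table(table: pd.DataFrame, path) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_volume(path) -> tuple:
    """Read a single 3-D NIfTI volume; returns (data, affine, voxel_size)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), voxel_size


def read_volume_pair(tmap_path, efield_path, mask_path=None) -> VolumePair:
    """Read a co-registered t-map / e-field pair, rejecting mismatches."""
    tmap, aff_t, vox = read_volume(tmap_path)
    efield, aff_e, _ = read_volume(efield_path)
    if tmap.shape != efield.shape:
        raise ValueError(
            f"shape mismatch: {tmap_path} {tmap.shape} vs {efield_path} {efield.shape}"
        )
    if not np.allclose(aff_t, aff_e, atol=1e-4):
        raise ValueError(f"affine mismatch between {tmap_path} and {efield_path}")
    mask = np.isfinite(tmap) & np.isfinite(efield)
    if mask_path is not None:
        m, aff_m, _ = read_volume(mask_path)
        if m.shape != tmap.shape or not np.allclose(aff_m, aff_t, atol=1e-4):
            raise ValueError(f"mask {mask_path} does not match the volume pair")
        mask &= m > 0
    return VolumePair(tmap=tmap, efield=efield, mask=mask, voxel_size=vox, affine=aff_t)


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
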