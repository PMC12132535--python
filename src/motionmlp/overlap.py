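"""Rank-based mutual information between co-registered brain volumes.

The exploratory overlap analysis asks how strongly a functional-contrast
t-map and a simulated stimulation e-field co-localize, without assuming any
functional form for their relationship. Both volumes are rank-transformed
within the shared brain mask (descending, average ranks for ties), the
ranks are discretized into equal-count bins, and the mutual information of
the joint bin histogram is computed in nats and normalized by the smaller
marginal entropy — so identical maps score 100% and independent maps score
near 0%. Because only ranks enter, the score is invariant to any strictly
monotone rescaling of either volume. No voxelwise threshold is applied:
every finite in-mask voxel participates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import VolumePair

__all__ = [
    "OverlapResult",
    "rank_transform",
    "mutual_information_percent",
    "correlate_overlap_behavior",
    "voxel_rank_correlation",
    "mni_distance",
]


@dataclass(frozen=True)
class OverlapResult:
    """Normalized mutual information of one volume pair."""

    mi_percent: float
    n_voxels: int
    bins: int
    mi_nats: float = float("nan")
    h_min: float = float("nan")


def rank_transform(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Descending average ranks of in-mask voxels (1 = highest value).

    Returns a flat array over ``mask == True`` voxels. A constant volume
    has no ordering and raises ``ValueError``.
    """
    values = np.asarray(volume, dtype=float)[np.asarray(mask, dtype=bool)]
    if values.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    if np.ptp(values) == 0.0:
        raise ValueError("constant volume: ranking is undefined")
    return stats.rankdata(-values, method="average")


def _equal_count_bins(ranks: np.ndarray, bins: int) -> np.ndarray:
    """Assign each rank to one of ``bins`` equal-count bins (0-based)."""
    n = ranks.size
    # rank r in [1, n] -> bin floor((r - 1) * bins / n); ties share a bin
    idx = np.floor((ranks - 1.0) * bins / n).astype(int)
    return np.clip(idx, 0, bins - 1)


def mutual_information_percent(pair: VolumePair, bins: int = 10) -> OverlapResult:
    """MI of binned ranks as a percent of the smaller marginal entropy.

    The normalization ceiling min(H(A), H(B)) is the largest MI the binned
    marginals admit, so the score is the attained fraction of the maximum
    possible overlap for this particular pair (tie structure and voxel
    count make the ceiling participant-specific).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mask = np.asarray(pair.mask, dtype=bool)
    finite = np.isfinite(pair.tmap) & np.isfinite(pair.efield)
    mask = mask & finite
    n_vox = int(mask.sum())
    if n_vox < 4 * bins:
        raise ValueError(f"too few in-mask voxels ({n_vox}) for {bins} bins")

    ra = rank_transform(pair.tmap, mask)
    rb = rank_transform(pair.efield, mask)
    a = _equal_count_bins(ra, bins)
    b = _equal_count_bins(rb, bins)

    joint = np.zeros((bins, bins))
    np.add.at(joint, (a, b), 1.0)
    joint /= n_vox
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)

    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())
    h = lambda p: float(-(p[p > 0] * np.log(p[p > 0])).sum())
    h_min = min(h(pa), h(pb))
    mi = min(max(mi, 0.0), h_min)  # clamp numerical round-off at the bounds
    return OverlapResult(
        mi_percent=100.0 * mi / h_min,
        n_voxels=n_vox,
        bins=bins,
        mi_nats=mi,
        h_min=h_min,
    )


def correlate_overlap_behavior(mi_values, behavior) -> tuple:
    """Pearson correlation (r, two-sided p) of overlap vs behavioral shift."""
    x = np.asarray(mi_values, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.size != y.size:
        raise ValueError("mi_values and behavior must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 participants")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def voxel_rank_correlation(pair: VolumePair) -> float:
    """Correlation of the two in-mask rank fields (a Spearman rho of raw maps)."""
    mask = np.asarray(pair.mask, dtype=bool) & np.isfinite(pair.tmap) & np.isfinite(pair.efield)
    ra = rank_transform(pair.tmap, mask)
    rb = rank_transform(pair.efield, mask)
    r, _ = stats.pearsonr(ra, rb)
    return float(r)


def mni_distance(a, b) -> float:
    """Euclidean distance in mm between two MNI coordinate triplets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("coordinates must be length-3 triplets")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))
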