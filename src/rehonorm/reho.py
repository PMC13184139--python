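"""Regional homogeneity (ReHo) via Kendall's coefficient of concordance.

ReHo scores the temporal synchrony of a voxel with its spatial neighbors:
Kendall's W of the K time series (voxel + neighbors) over n time points,
a rank statistic in [0, 1].  Voxel-wise maps are reduced to regional means
through an integer label atlas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import nibabel as nib
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

#: neighborhood size -> list of (dx, dy, dz) offsets, center included
_NEIGHBORHOODS = {
    7: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ],
}


def kendalls_w(series_set: np.ndarray, tie_policy: str = "midrank") -> float:
    """Kendall's coefficient of concordance W of K series over n time points.

    Ranks are computed within each series (midranks for ties, no tie
    correction factor), R_i is the rank sum across series at time i, and

        W = (sum_i R_i**2 - n * Rbar**2) / ((1/12) * K**2 * (n**3 - n))

    Fully tied (constant) series contribute flat midranks; if all rank sums
    are equal the numerator is 0 and W = 0.
    """
    if tie_policy != "midrank":
        raise ValueError(f"unsupported tie_policy {tie_policy!r}")
    series = np.asarray(series_set, dtype=float)
    if series.ndim != 2:
        raise ValueError("series_set must be 2-D (K series x n time points)")
    k, n = series.shape
    if k < 2:
        raise ValueError("need at least K=2 series")
    if n < 2:
        raise ValueError("need at least n=2 time points")
    ranks = rankdata(series, axis=1)
    r = ranks.sum(axis=0)
    num = float(np.sum(r**2) - n * r.mean() ** 2)
    den = (k**2 * (n**3 - n)) / 12.0
    return num / den


@dataclass
class ReHoMap:
    """Voxel-wise ReHo values (NaN where undefined / out of mask)."""

    values: np.ndarray  # 3-D float array
    neighborhood_size: int

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def reho_map(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    neighborhood_size: int = 27,
) -> ReHoMap:
    """Voxel-wise Kendall's W over each voxel's in-mask neighborhood.

    Vectorized: each voxel's series is ranked once over time; neighbor rank
    sums are accumulated by shifting the rank volume per neighborhood
    offset.  Voxels with fewer than 2 in-mask neighbors get NaN.
    """
    if neighborhood_size not in _NEIGHBORHOODS:
        raise ValueError("neighborhood_size must be one of {7, 19, 27}")
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, t)")
    n_t = data.shape[3]
    if n_t < 10:
        raise ValueError("need at least 10 time points")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match spatial shape")

    ranks = rankdata(data, axis=3)
    ranks[~mask] = 0.0

    shape = data.shape[:3]
    rank_sum = np.zeros(shape + (n_t,))
    k_count = np.zeros(shape, dtype=int)
    for dx, dy, dz in _NEIGHBORHOODS[neighborhood_size]:
        src = tuple(
            slice(max(-d, 0), s - max(d, 0)) for d, s in zip((dx, dy, dz), shape)
        )
        dst = tuple(
            slice(max(d, 0), s - max(-d, 0)) for d, s in zip((dx, dy, dz), shape)
        )
        rank_sum[dst] += ranks[src]
        k_count[dst] += mask[src]

    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = rank_sum.mean(axis=3)
        num = (rank_sum**2).sum(axis=3) - n_t * rbar**2
        den = (k_count.astype(float) ** 2 * (n_t**3 - n_t)) / 12.0
        w = num / den

    # require the voxel itself plus >= 2 neighbors
    valid = mask & (k_count >= 3)
    w[~valid] = np.nan
    n_dropped = int(mask.sum() - valid.sum())
    if n_dropped:
        log.info("reho_map: %d in-mask voxels had < 2 in-mask neighbors", n_dropped)
    return ReHoMap(values=w, neighborhood_size=neighborhood_size)


def parcellate(
    reho: ReHoMap | np.ndarray,
    labels: np.ndarray,
    n_regions: int = 246,
) -> pd.Series:
    """Regional means of a voxel map under an integer label atlas.

    Returns a length-``n_regions`` Series indexed ``region_001`` ...; a
    region with no valid voxel gets NaN and a warning.
    """
    values = reho.values if isinstance(reho, ReHoMap) else np.asarray(reho, float)
    labels = np.asarray(labels)
    if labels.shape != values.shape:
        raise ValueError("atlas shape must match map shape")
    if labels.min() < 0 or labels.max() > n_regions:
        raise ValueError(f"labels must lie in 0..{n_regions}")

    valid = np.isfinite(values) & (labels > 0)
    lab = labels[valid].ravel()
    val = values[valid].ravel()
    sums = np.bincount(lab, weights=val, minlength=n_regions + 1)[1:]
    counts = np.bincount(lab, minlength=n_regions + 1)[1:]
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    empty = int((counts == 0).sum())
    if empty:
        warnings.warn(f"{empty} regions had no valid voxels", stacklevel=2)
    return pd.Series(
        means, index=[f"region_{r:03d}" for r in range(1, n_regions + 1)]
    )


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_nifti(array: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)
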