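"""Point-by-point comparison of registered grid maps.

Once expression maps are registered into a common reference frame and
resampled onto a shared grid, similarity is quantified by the sample Pearson
correlation of the point-by-point matched expression levels, restricted to the
common mask of the comparison set (any pixel not present in every submitted
pattern is excluded). Group summaries report the mean ± SD of the pairwise r
values, the convention used for developmental and between-species contrasts;
significance testing on the r values is left to standard statistics routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, UndefinedCorrelationError
from .mapmath import GridMap, common_mask

__all__ = ["ComparisonResult", "pearson", "pairwise_correlations"]

MIN_PIXELS = 3


@dataclass
class ComparisonResult:
    """Pairwise correlation matrix over a comparison set's common mask."""

    r: np.ndarray  # (|A|, |B|)
    ids_a: list
    ids_b: list
    n_pixels: int
    mask_fraction: float
    within_group: bool

    def summary(self) -> dict:
        """Mean ± SD of pairwise r (self-pairs excluded within a group)."""
        if self.within_group:
            iu = np.triu_indices_from(self.r, k=1)
            vals = self.r[iu]
        else:
            vals = self.r.ravel()
        if vals.size == 0:
            raise InsufficientDataError("no map pairs to summarize")
        return {
            "r_mean": float(np.mean(vals)),
            "r_sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "n_pairs": int(vals.size),
            "n_pixels": self.n_pixels,
            "mask_fraction": self.mask_fraction,
        }


def pearson(grid_a: GridMap, grid_b: GridMap, mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation over masked pixels of two matched grids."""
    if not grid_a.same_geometry(grid_b):
        raise InvalidInputError("grids do not share geometry")
    if mask is None:
        mask = common_mask([grid_a, grid_b])
    a = grid_a.values[mask]
    b = grid_b.values[mask]
    if a.size < MIN_PIXELS:
        raise InsufficientDataError(f"only {a.size} masked pixels (need >= {MIN_PIXELS})")
    da = a - a.mean()
    db = b - b.mean()
    va = np.sum(da * da)
    vb = np.sum(db * db)
    if va == 0.0 or vb == 0.0:
        raise UndefinedCorrelationError("zero variance over the mask")
    # sqrt of the product keeps r(A, A) exactly 1 and r symmetric bit-for-bit
    r = float(np.sum(da * db) / np.sqrt(va * vb))
    return min(1.0, max(-1.0, r))


def pairwise_correlations(group_a, group_b=None, ids_a=None, ids_b=None) -> ComparisonResult:
    """All pairwise correlations over the comparison set's common mask.

    With ``group_b`` omitted the comparison is within-group: the matrix is
    |A| x |A| and :meth:`ComparisonResult.summary` excludes self-pairs. The
    common mask is taken over *all* grids submitted to the set, not per pair.
    """
    group_a = list(group_a)
    within = group_b is None
    group_b = group_a if within else list(group_b)
    if not group_a or not group_b:
        raise InvalidInputError("empty comparison group")
    mask = common_mask(group_a + ([] if within else group_b))
    n_pix = int(mask.sum())
    r = np.empty((len(group_a), len(group_b)))
    for i, ga in enumerate(group_a):
        for j, gb in enumerate(group_b):
            if within and j < i:
                r[i, j] = r[j, i]  # symmetric, computed once
            else:
                r[i, j] = pearson(ga, gb, mask)
    return ComparisonResult(
        r=r,
        ids_a=list(ids_a) if ids_a is not None else list(range(len(group_a))),
        ids_b=list(ids_b) if ids_b is not None else list(range(len(group_b))),
        n_pixels=n_pix,
        mask_fraction=float(mask.mean()),
        within_group=within,
    )
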