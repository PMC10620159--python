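"""Niche breadth and overlap statistics on suitability surfaces.

Suitability maps are normalized to probability distributions over the cell
set shared by the species being compared (cells nodata in either map are
excluded from both). Breadth follows Levins: B1 is the standardized inverse
concentration ((1/sum p^2) - 1)/(n - 1) and B2 the standardized Shannon
uncertainty -sum p ln p / ln n, both 1 for a uniform distribution and 0 for
a point mass. Overlap uses Schoener's D = 1 - 0.5 sum|pA - pB| and the
Hellinger-based I = 1 - 0.5 sum (sqrt pA - sqrt pB)^2; the overlapping
degree is the fraction of the two species' occurrence records that fall in
their joint (moderate-or-better) suitable region.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet
from .raster import RasterGrid


def _shared_valid(*grids: RasterGrid) -> np.ndarray:
    base = grids[0]
    for g in grids[1:]:
        if not g.aligned_with(base):
            raise ValueError("grids are not aligned")
    mask = np.ones(base.shape, dtype=bool)
    for g in grids:
        mask &= np.isfinite(g.values)
    return mask


def normalize_suitability(grid: RasterGrid, mask: np.ndarray | None = None) -> np.ndarray:
    """Flatten the map over ``mask`` (default: its valid cells) and divide
    by the total, yielding p_i >= 0 with sum 1."""
    if mask is None:
        mask = np.isfinite(grid.values)
    vals = grid.values[mask]
    if np.any(vals < 0):
        raise ValueError("suitability must be non-negative")
    total = vals.sum()
    if not total > 0:
        raise ValueError("suitability map sums to zero")
    return vals / total


def schoener_d(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |pA - pB|, in [0, 1]."""
    p_a, p_b = np.asarray(p_a, float), np.asarray(p_b, float)
    if p_a.shape != p_b.shape:
        raise ValueError("distributions must share a grid")
    return float(1 - 0.5 * np.abs(p_a - p_b).sum())


def hellinger_i(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Warren's I = 1 - 0.5 * sum (sqrt pA - sqrt pB)^2, in [0, 1]."""
    p_a, p_b = np.asarray(p_a, float), np.asarray(p_b, float)
    if p_a.shape != p_b.shape:
        raise ValueError("distributions must share a grid")
    return float(1 - 0.5 * ((np.sqrt(p_a) - np.sqrt(p_b)) ** 2).sum())


def levins_breadth(p: np.ndarray) -> tuple[float, float]:
    """Levins B1 (inverse concentration) and B2 (uncertainty), both
    standardized to [0, 1]; 0 ln 0 reads as 0."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    b1 = (1.0 / np.sum(p * p) - 1.0) / (n - 1)
    nz = p[p > 0]
    b2 = float(-(nz * np.log(nz)).sum() / np.log(n))
    return float(b1), b2


def niche_overlap(map_a: RasterGrid, map_b: RasterGrid) -> tuple[float, float]:
    """(D, I) between two suitability maps, normalized over their shared
    valid cells."""
    mask = _shared_valid(map_a, map_b)
    p_a = normalize_suitability(map_a, mask)
    p_b = normalize_suitability(map_b, mask)
    return schoener_d(p_a, p_b), hellinger_i(p_a, p_b)


def overlap_region(grades_a: RasterGrid, grades_b: RasterGrid,
                   min_grade: int = 2) -> RasterGrid:
    """Mask (1/0) of cells where both species grade moderate or better."""
    mask = _shared_valid(grades_a, grades_b)
    out = np.where(mask & (grades_a.values >= min_grade)
                   & (grades_b.values >= min_grade), 1.0, 0.0)
    out[~mask & ~np.isfinite(grades_a.values) & ~np.isfinite(grades_b.values)] = np.nan
    return grades_a.like(out, name="overlap_region")


def species_specific_habitat(grades_focal: RasterGrid,
                             grades_others: list[RasterGrid],
                             min_grade: int = 2) -> RasterGrid:
    """Mask of cells where the focal species grades moderate or better and
    no other species does."""
    mask = _shared_valid(grades_focal, *grades_others) if grades_others \
        else np.isfinite(grades_focal.values)
    ok = mask & (grades_focal.values >= min_grade)
    for other in grades_others:
        ok &= ~(other.values >= min_grade)
    return grades_focal.like(np.where(ok, 1.0, 0.0), name="species_specific")


def _records_in_mask(occ: OccurrenceSet, mask: RasterGrid) -> int:
    row, col, inside = mask.index_of(occ.frame["lon"].to_numpy(),
                                     occ.frame["lat"].to_numpy())
    vals = mask.values[row[inside], col[inside]]
    return int(np.nansum(vals > 0))


def overlapping_degree(occ_a: OccurrenceSet, occ_b: OccurrenceSet,
                       mask: RasterGrid) -> float:
    """(A_overlap + B_overlap) / (A_total + B_total): the share of both
    species' records falling in the overlap region."""
    if len(occ_a) == 0 or len(occ_b) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    a_in = _records_in_mask(occ_a, mask)
    b_in = _records_in_mask(occ_b, mask)
    return (a_in + b_in) / (len(occ_a) + len(occ_b))


def compute_niche_stats(
    suitability: dict[str, RasterGrid],
    grades: dict[str, RasterGrid],
    occurrences: dict[str, OccurrenceSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species breadth table (B1, B2) and per-pair overlap table
    (D, I, overlapping degree)."""
    species = list(suitability)
    breadth_rows = []
    for sp in species:
        p = normalize_suitability(suitability[sp])
        b1, b2 = levins_breadth(p)
        breadth_rows.append({"species": sp, "B1": b1, "B2": b2})
    pair_rows = []
    for a, b in combinations(species, 2):
        d, i = niche_overlap(suitability[a], suitability[b])
        mask = overlap_region(grades[a], grades[b])
        deg = overlapping_degree(occurrences[a], occurrences[b], mask)
        pair_rows.append({"species_a": a, "species_b": b, "D": d, "I": i,
                          "overlapping_degree": deg})
    return pd.DataFrame(breadth_rows), pd.DataFrame(pair_rows)
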