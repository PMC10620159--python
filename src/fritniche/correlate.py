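"""Pearson correlation of niche overlap against chemical or genetic
(dis)similarity.

For species pairs, the x variable is a niche-overlap index (Schoener's D or
Hellinger-based I) and the y variable a plant-plant chemical dissimilarity
(1 - Jaccard similarity of metabolite-group profiles) or a pairwise
evolutionary distance. The report mirrors the conventional four-row layout
(CPD, CPI, CCD, CCI: chloroplast-phylogeny or chemical-composition feature
against D or I), with R^2 = r^2, a two-sided P from the t distribution on
n - 2 degrees of freedom, and an OLS trend line. With n = 3 pairs
(df = 1) the t tail has the closed form P = 2 (1/2 - arctan|t| / pi); the
implementation agrees with it exactly, and the report flags such tiny n as
low-powered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PearsonResult:
    r: float
    r2: float
    p: float
    t: float
    n: int


def pearson_test(x, y) -> PearsonResult:
    """Sample Pearson r with a two-sided P from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; |r| = 1 gives
    P = 0 exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an input")
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return PearsonResult(r, 1.0, 0.0, math.inf, n)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return PearsonResult(r, r * r, p, t, n)


def pearson_p_df1_closed_form(t: float) -> float:
    """Two-sided t-tail for df = 1 (standard Cauchy):
    P = 2 (1/2 - arctan|t| / pi)."""
    return 2 * (0.5 - math.atan(abs(t)) / math.pi)


def fit_trendline(x, y) -> tuple[float, float]:
    """Ordinary least squares line; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def correlate_overlap(
    overlaps: pd.DataFrame,
    features: pd.DataFrame,
    overlap_kinds=("D", "I"),
    feature_kinds=("genetic", "chemical"),
) -> pd.DataFrame:
    """Four-row correlation report (one row per overlap x feature
    combination).

    ``overlaps`` indexes species pairs with columns D and I; ``features``
    indexes the same pairs with a column per feature kind (dissimilarity or
    distance). Pair labels must align exactly. Row types follow the CP/CC
    naming: genetic-D = CPD, genetic-I = CPI, chemical-D = CCD,
    chemical-I = CCI.
    """
    mismatch = set(overlaps.index).symmetric_difference(features.index)
    if mismatch:
        raise ValueError(f"pair labels do not align: {sorted(map(str, mismatch))}")
    features = features.loc[overlaps.index]
    n = len(overlaps)
    if n < 5:
        warnings.warn(f"only n={n} species pairs: the Pearson test has very "
                      "little power at this size")
    prefix = {"genetic": "CP", "chemical": "CC"}
    rows = []
    for fk in feature_kinds:
        if fk not in features.columns:
            raise ValueError(f"features table lacks column {fk!r}")
        for ok in overlap_kinds:
            x = overlaps[ok].to_numpy(dtype=float)
            y = features[fk].to_numpy(dtype=float)
            res = pearson_test(x, y)
            slope, intercept = fit_trendline(x, y)
            row = {"type": prefix.get(fk, fk.upper()) + ok, "overlap": ok,
                   "feature": fk, "R2": res.r2, "P": res.p, "r": res.r,
                   "n": res.n, "slope": slope, "intercept": intercept,
                   "low_power": res.n < 5}
            for pair, val in zip(overlaps.index, x):
                row[f"overlap[{pair}]"] = val
            rows.append(row)
    return pd.DataFrame(rows)
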