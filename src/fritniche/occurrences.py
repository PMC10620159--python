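"""Occurrence records: thinning, environmental extraction, variable selection.

Records are species-tagged lon/lat points flagged ``presence`` or
``pseudo_absence``. Thinning keeps one record per 20 km x 20 km cell of an
equirectangular grid centred on the records' mean latitude; the
environmental table pairs each surviving record with the raster values at
its cell, ready for presence/absence modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster import RasterStack

logger = logging.getLogger(__name__)

KM_PER_DEGREE = 111.195  # spherical degree of latitude

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"

_COLUMNS = ["species", "lon", "lat", "kind"]


@dataclass
class OccurrenceSet:
    """Species-tagged lon/lat records with a presence/pseudo-absence flag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        if "kind" not in df.columns:
            df = df.assign(kind=PRESENCE)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        if len(df) and (
            df["lon"].abs().max() > 180 or df["lat"].abs().max() > 90
        ):
            raise ValueError("coordinates outside WGS84 bounds")
        self.frame = df[_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species"]))

    def subset(self, species: str | None = None, kind: str | None = None) -> "OccurrenceSet":
        df = self.frame
        if species is not None:
            df = df[df["species"] == species]
        if kind is not None:
            df = df[df["kind"] == kind]
        return OccurrenceSet(df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records) -> "OccurrenceSet":
        return cls(pd.DataFrame(records, columns=_COLUMNS))

    @classmethod
    def concat(cls, sets) -> "OccurrenceSet":
        return cls(pd.concat([s.frame for s in sets], ignore_index=True))

    @classmethod
    def read_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _thinning_cells(lon, lat, cell_km: float, mean_lat: float):
    """Integer (ix, iy) thinning-grid cell per record, grid in km via
    equirectangular scaling about ``mean_lat``."""
    kx = KM_PER_DEGREE * np.cos(np.deg2rad(mean_lat))
    ix = np.floor(np.asarray(lon) * kx / cell_km).astype(int)
    iy = np.floor(np.asarray(lat) * KM_PER_DEGREE / cell_km).astype(int)
    return ix, iy


def thin_occurrences(occ: OccurrenceSet, cell_km: float = 20.0,
                     ref_lat: float | None = None) -> tuple[OccurrenceSet, int]:
    """Keep one record per species per ``cell_km`` grid cell.

    The grid is equirectangular about ``ref_lat`` — by default the records'
    mean latitude (1 deg lat = 111.195 km, 1 deg lon = 111.195 *
    cos(ref lat) km); the first record per cell in input order is kept.
    Returns the thinned set and the number of removed records. Thinning is
    exactly idempotent for a fixed ``ref_lat``; re-deriving the reference
    from an already-thinned set can shift the longitude scale slightly.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    df = occ.frame
    if df.empty:
        return OccurrenceSet(df.copy()), 0
    mean_lat = float(df["lat"].mean()) if ref_lat is None else float(ref_lat)
    ix, iy = _thinning_cells(df["lon"].to_numpy(), df["lat"].to_numpy(), cell_km, mean_lat)
    key = pd.DataFrame({"species": df["species"], "ix": ix, "iy": iy})
    keep = ~key.duplicated()
    n_removed = int((~keep).sum())
    return OccurrenceSet(df[keep].reset_index(drop=True)), n_removed


def extract_env(stack: RasterStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Environmental table at each record's raster cell (nearest cell).

    Records outside the raster extent or on a nodata cell in any layer are
    dropped; the dropped count is logged and stored in
    ``result.attrs["n_dropped"]``. The returned frame carries the record
    columns, one column per layer, and ``label`` (1 presence,
    0 pseudo-absence).
    """
    df = occ.frame
    tmpl = stack.grid_template()
    row, col, inside = tmpl.index_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    n_outside = int((~inside).sum())
    row, col = row[inside], col[inside]
    sub = df[inside].reset_index(drop=True)
    values = stack.data[:, row, col].T  # (n_records, n_layers)
    ok = np.all(np.isfinite(values), axis=1)
    n_nodata = int((~ok).sum())
    out = sub[ok].reset_index(drop=True)
    env = pd.DataFrame(values[ok], columns=stack.names)
    table = pd.concat([out, env], axis=1)
    table["label"] = (table["kind"] == PRESENCE).astype(int)
    table.attrs["n_dropped"] = n_outside + n_nodata
    if n_outside or n_nodata:
        logger.info("extract_env dropped %d records (%d outside extent, %d on nodata)",
                    n_outside + n_nodata, n_outside, n_nodata)
    return table


def env_columns(table: pd.DataFrame) -> list[str]:
    """Environmental variable columns of an extracted table."""
    return [c for c in table.columns if c not in _COLUMNS + ["label"]]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mean ranks).

    Undefined (NaN) when either argument has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def univariate_contributions(table: pd.DataFrame) -> dict[str, float]:
    """Default contribution score per variable: discriminative power of the
    variable alone, measured as the rank AUC against the presence labels
    folded about 0.5 (so direction does not matter)."""
    from .metrics import auc_score

    labels = table["label"].to_numpy()
    out = {}
    for var in env_columns(table):
        if np.unique(labels).size < 2:
            out[var] = 0.0
            continue
        a = auc_score(table[var].to_numpy(), labels)
        out[var] = abs(a - 0.5) * 2
    return out


def select_variables(
    table: pd.DataFrame,
    contributions: dict[str, float] | None = None,
    threshold: float = 0.8,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop, from every pair with |Spearman rho| > ``threshold``, the
    lower-contribution variable.

    Removal is greedy in ascending contribution order (ties broken by
    variable name); returns the retained variable list (original column
    order) and a removal log of (removed, correlated_with, rho).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    variables = env_columns(table)
    if contributions is None:
        contributions = univariate_contributions(table)
    missing = [v for v in variables if v not in contributions]
    if missing:
        raise ValueError(f"contributions missing for {missing}")

    rho = pd.DataFrame(index=variables, columns=variables, dtype=float)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = spearman_rho(table[a].to_numpy(), table[b].to_numpy())
            rho.loc[a, b] = rho.loc[b, a] = r

    retained = set(variables)
    removal_log: list[tuple[str, str, float]] = []
    for var in sorted(variables, key=lambda v: (contributions[v], v)):
        if var not in retained:
            continue
        partners = [
            v for v in retained
            if v != var and np.isfinite(rho.loc[var, v]) and abs(rho.loc[var, v]) > threshold
        ]
        if partners:
            worst = max(partners, key=lambda v: abs(rho.loc[var, v]))
            retained.discard(var)
            removal_log.append((var, worst, float(rho.loc[var, worst])))
            logger.info("select_variables removed %s (|rho|=%.3f with %s)",
                        var, abs(rho.loc[var, worst]), worst)
    return [v for v in variables if v in retained], removal_log
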