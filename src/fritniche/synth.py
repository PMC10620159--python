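"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate, statistically, the inputs of a montane-plant niche
study: spatially autocorrelated environmental layers (bioclim-like), a
virtual species with per-variable Gaussian responses and
suitability-weighted presence sampling, planted metabolite fingerprint
clusters with controlled Tanimoto structure, and nucleotide alignments
evolved under the TN93 model at a known branch length. Every generator
takes an explicit seed and is bit-reproducible; no global random state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter

from .chem import N_BITS, FingerprintSet
from .occurrences import PRESENCE, OccurrenceSet
from .raster import RasterGrid, RasterStack


@dataclass
class VirtualSpeciesTruth:
    """Known response surface of a simulated species.

    ``optima``/``widths`` are the per-variable Gaussian response centres
    mu_k and widths sigma_k (layer units); ``weights`` in [0, 1] scale each
    variable's influence (0 = ignored). ``true_suitability`` is the product
    of the weighted Gaussian responses, in [0, 1] cellwise.
    """

    optima: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    true_suitability: RasterGrid

    def __post_init__(self) -> None:
        if np.any(self.widths <= 0):
            raise ValueError("all response widths must be positive")
        vals = self.true_suitability.values
        if not np.nanmax(vals) > 0:
            raise ValueError("true suitability is zero everywhere")


@dataclass
class FingerprintTruth:
    """Planted cluster label per metabolite."""

    labels: dict[str, int]
    n_bits: int = N_BITS


def gen_env_stack(
    n_rows: int,
    n_cols: int,
    n_layers: int,
    corr_length: float,
    means: list[float],
    sds: list[float],
    seed: int,
    west: float = 95.0,
    north: float = 35.0,
    cellsize: float = 0.1,
    names: list[str] | None = None,
) -> RasterStack:
    """Spatially autocorrelated environmental layers.

    Each layer is Gaussian white noise smoothed with a Gaussian kernel of
    scale ``corr_length`` (in cells; 0 disables smoothing), then affinely
    rescaled so its sample mean and standard deviation equal the requested
    values exactly.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    if len(means) != n_layers or len(sds) != n_layers:
        raise ValueError("means and sds must have one entry per layer")
    if any(s <= 0 for s in sds):
        raise ValueError("layer standard deviations must be positive")
    rng = np.random.default_rng(seed)
    layers = np.empty((n_layers, n_rows, n_cols))
    for k in range(n_layers):
        z = rng.standard_normal((n_rows, n_cols))
        if corr_length > 0:
            z = gaussian_filter(z, sigma=corr_length, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers[k] = means[k] + sds[k] * z
    if names is None:
        names = [f"bio{k + 1:02d}" for k in range(n_layers)]
    return RasterStack(list(names), layers, west=west, north=north,
                       dx=cellsize, dy=cellsize)


def gen_virtual_species(
    stack: RasterStack,
    optima: list[float],
    widths: list[float],
    weights: list[float],
) -> VirtualSpeciesTruth:
    """Virtual species with product-Gaussian suitability
    s(x) = prod_k exp(-w_k (z_k(x) - mu_k)^2 / (2 sigma_k^2))."""
    optima = np.asarray(optima, dtype=float)
    widths = np.asarray(widths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(optima) == len(widths) == len(weights) == stack.n_layers):
        raise ValueError("parameter lists must match the stack layer count")
    if np.any(widths <= 0):
        raise ValueError("all response widths must be positive")
    log_s = np.zeros(stack.shape)
    for k in range(stack.n_layers):
        log_s -= weights[k] * (stack.data[k] - optima[k]) ** 2 / (2 * widths[k] ** 2)
    suit = np.exp(log_s)
    suit[~stack.valid] = np.nan
    grid = RasterGrid(suit, stack.west, stack.north, stack.dx, stack.dy,
                      name="true_suitability")
    return VirtualSpeciesTruth(optima, widths, weights, grid)


def sample_occurrences(
    truth: VirtualSpeciesTruth,
    n: int,
    duplicate_rate: float = 0.0,
    seed: int = 0,
    species: str = "virtual",
) -> OccurrenceSet:
    """Presence records drawn with probability proportional to suitability.

    Each record takes its cell-centre lon/lat jittered uniformly within the
    cell. A ``duplicate_rate`` fraction of the n records are near-copies
    (offset ~1e-6 degrees) of earlier records, guaranteed to share the
    source's 20-km thinning cell, so thinning ground truth is exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= duplicate_rate < 1:
        raise ValueError("duplicate_rate must be in [0, 1)")
    grid = truth.true_suitability
    vals = grid.values
    valid = np.isfinite(vals) & (vals > 0)
    total = np.nansum(np.where(valid, vals, 0.0))
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(valid)
    p = vals[rows, cols] / total

    n_dup = int(round(n * duplicate_rate))
    n_base = n - n_dup
    picks = rng.choice(rows.size, size=n_base, p=p)
    lon_c, lat_c = grid.cell_center(rows[picks], cols[picks])
    lon = lon_c + (rng.uniform(-0.5, 0.5, n_base)) * grid.dx
    lat = lat_c + (rng.uniform(-0.5, 0.5, n_base)) * grid.dy
    records = pd.DataFrame({"species": species, "lon": lon, "lat": lat,
                            "kind": PRESENCE})
    if n_dup:
        src = rng.integers(0, n_base, size=n_dup)
        # nudge ~0.1 m towards the source's cell centre: same raster cell,
        # same 20-km cell
        eps = 1e-6
        dlon = np.sign(lon_c[src] - lon[src]) * eps
        dlat = np.sign(lat_c[src] - lat[src]) * eps
        dups = pd.DataFrame({"species": species, "lon": lon[src] + dlon,
                             "lat": lat[src] + dlat, "kind": PRESENCE})
        records = pd.concat([records, dups], ignore_index=True)
    return OccurrenceSet(records)


def gen_fingerprint_clusters(
    k_clusters: int = 4,
    per_cluster: int = 8,
    flip_bits: int = 4,
    seed: int = 0,
    density: float = 0.1,
    max_center_tanimoto: float = 0.5,
) -> tuple[FingerprintSet, FingerprintTruth]:
    """Planted fingerprint clusters with controlled Tanimoto structure.

    Cluster centres are random 881-bit vectors with ``density`` on-bits and
    pairwise Tanimoto below ``max_center_tanimoto``; members are centres
    with ``flip_bits`` random bits flipped. ``flip_bits`` must keep the
    expected within-cluster Tanimoto, roughly (m - f)/(m + f) at
    m = density * 881 on-bits, above the 0.85 network threshold.
    """
    from .chem import tanimoto

    if k_clusters < 1 or per_cluster < 1:
        raise ValueError("k_clusters and per_cluster must be >= 1")
    m = int(round(density * N_BITS))
    expected = (m - flip_bits) / (m + flip_bits)
    if flip_bits < 0 or expected <= 0.85:
        raise ValueError(
            f"flip_bits={flip_bits} gives expected within-cluster Tanimoto "
            f"~{max(expected, 0):.3f} <= 0.85 at ~{m} on-bits; use flip_bits "
            f"<= {int(m * 0.15 / 1.85)} to keep planted clusters connected"
        )
    rng = np.random.default_rng(seed)
    centers = []
    for _ in range(k_clusters):
        for _attempt in range(100):
            c = np.zeros(N_BITS, dtype=np.uint8)
            c[rng.choice(N_BITS, size=m, replace=False)] = 1
            if all(tanimoto(c, prev) < max_center_tanimoto for prev in centers):
                centers.append(c)
                break
        else:  # pragma: no cover - practically unreachable at 881 bits
            raise RuntimeError("could not place a sufficiently distinct cluster centre")

    rows, labels = {}, {}
    for ci, center in enumerate(centers):
        for j in range(per_cluster):
            fp = center.copy()
            if flip_bits:
                flip = rng.choice(N_BITS, size=flip_bits, replace=False)
                fp[flip] ^= 1
            name = f"M{ci + 1:02d}_{j + 1:02d}"
            rows[name] = fp
            labels[name] = ci
    fps = FingerprintSet(pd.DataFrame(rows).T)
    return fps, FingerprintTruth(labels)


def gen_plant_profiles(
    fps: FingerprintSet,
    truth: FingerprintTruth,
    plant_clusters: dict[str, set[int]],
    seed: int = 0,
    take_fraction: float = 0.6,
) -> FingerprintSet:
    """Assign plants metabolite sets drawn from chosen planted clusters.

    ``plant_clusters`` maps plant id -> set of planted cluster ids; each
    plant receives a random ``take_fraction`` share (at least one) of every
    chosen cluster's metabolites. Returns a new FingerprintSet with the
    plant table filled.
    """
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for met, lab in truth.labels.items():
        by_cluster.setdefault(lab, []).append(met)
    plants: dict[str, set[str]] = {}
    for plant, clusters in plant_clusters.items():
        mets: set[str] = set()
        for ci in sorted(clusters):
            members = sorted(by_cluster[ci])
            k = max(1, int(round(take_fraction * len(members))))
            mets |= set(rng.choice(members, size=k, replace=False))
        plants[plant] = mets
    return FingerprintSet(fps.fingerprints.copy(), plants)


# ---------------------------------------------------------------------------
# TN93 sequence simulation

def _tn93_rate_matrix(freqs: np.ndarray, kappa1: float, kappa2: float) -> np.ndarray:
    """TN93 rate matrix (order A, C, G, T) normalized to one expected
    substitution per site per unit time."""
    pa, pc, pg, pt = freqs
    beta = 1.0
    a1 = kappa1 * beta  # A<->G
    a2 = kappa2 * beta  # C<->T
    q = np.zeros((4, 4))
    rates = {
        (0, 2): a1, (2, 0): a1,   # purine transitions
        (1, 3): a2, (3, 1): a2,   # pyrimidine transitions
    }
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = rates.get((i, j), beta)
            q[i, j] = rate * freqs[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.sum(freqs * np.diag(q))
    return q / mu


def gen_alignment_tn93(
    n_sites: int,
    branch_length: float,
    freqs=(0.25, 0.25, 0.25, 0.25),
    kappa1: float = 2.0,
    kappa2: float = 2.0,
    seed: int = 0,
    taxa: tuple[str, str] = ("ancestor", "descendant"),
) -> dict[str, str]:
    """Two aligned sequences separated by ``branch_length`` expected
    substitutions/site under TN93; transition probabilities via the matrix
    exponential of the scaled rate matrix (exact at any branch length)."""
    freqs = np.asarray(freqs, dtype=float)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if freqs.shape != (4,) or np.any(freqs <= 0) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("freqs must be four positive values summing to 1")
    rng = np.random.default_rng(seed)
    q = _tn93_rate_matrix(freqs, kappa1, kappa2)
    p = expm(q * branch_length)
    anc = rng.choice(4, size=n_sites, p=freqs)
    bases = np.array(list("ACGT"))
    dec = np.array([rng.choice(4, p=p[i]) for i in anc])
    return {taxa[0]: "".join(bases[anc]), taxa[1]: "".join(bases[dec])}


def gen_star_alignment(
    n_sites: int,
    branch_lengths: dict[str, float],
    freqs=(0.25, 0.25, 0.25, 0.25),
    kappa1: float = 2.0,
    kappa2: float = 2.0,
    seed: int = 0,
) -> dict[str, str]:
    """Taxa evolved independently from one ancestor on a star tree; the
    expected pairwise TN93 distance is the sum of the two branch lengths."""
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    q = _tn93_rate_matrix(freqs, kappa1, kappa2)
    anc = rng.choice(4, size=n_sites, p=freqs)
    bases = np.array(list("ACGT"))
    out = {}
    for taxon, bl in branch_lengths.items():
        p = expm(q * bl)
        out[taxon] = "".join(bases[[rng.choice(4, p=p[i]) for i in anc]])
    return out


# ---------------------------------------------------------------------------
# Default study conditions

def default_virtual_study(seed: int = 0):
    """The default synthetic study: a 100x100 four-layer stack (two
    informative variables, two nuisance), a virtual species with Gaussian
    responses on the informative pair, and 200 presence records with a 20%
    near-duplicate fraction (mirroring a raw-to-thinned record ratio typical
    of herbarium compilations).

    Returns (stack, truth, occurrences).
    """
    rng_seed = int(seed)
    stack = gen_env_stack(
        n_rows=100, n_cols=100, n_layers=4, corr_length=5.0,
        means=[12.0, 800.0, 45.0, 3000.0], sds=[4.0, 250.0, 8.0, 900.0],
        seed=rng_seed, names=["bio01", "bio12", "bio03", "elev"],
    )
    truth = gen_virtual_species(
        stack,
        optima=[14.0, 900.0, 45.0, 3000.0],
        widths=[2.0, 120.0, 8.0, 900.0],
        weights=[1.0, 1.0, 0.0, 0.0],
    )
    occ = sample_occurrences(truth, n=200, duplicate_rate=0.2,
                             seed=rng_seed + 1, species="virtual")
    return stack, truth, occ
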