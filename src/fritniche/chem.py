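"""Metabolite fingerprint similarity, clustering, and plant-level trees.

Metabolites carry 881-bit PubChem-style binary fingerprints. Pairs with a
Tanimoto coefficient strictly greater than a threshold (0.85 by default)
are linked in a similarity network; network clusters become
"metabolite-groups"; plants are then compared through the binary
plant x group incidence matrix with Jaccard or Simpson set similarity and
clustered agglomeratively (UPGMA by default) with bootstrap support from
resampled group columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

N_BITS = 881  # PubChem fingerprint length


@dataclass
class FingerprintSet:
    """Metabolite -> binary fingerprint plus plant -> metabolite membership."""

    fingerprints: pd.DataFrame  # metabolites x bits, 0/1
    plants: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fp = pd.DataFrame(self.fingerprints).astype(np.uint8)
        if fp.shape[1] != N_BITS:
            raise ValueError(f"fingerprints must have {N_BITS} bits, got {fp.shape[1]}")
        if not fp.isin([0, 1]).all().all():
            raise ValueError("fingerprints must be binary")
        self.fingerprints = fp
        known = set(fp.index)
        for plant, mets in self.plants.items():
            unknown = set(mets) - known
            if unknown:
                raise ValueError(f"plant {plant!r} references unknown metabolites {sorted(unknown)}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.fingerprints.index)

    @classmethod
    def read_csv(cls, fingerprint_csv, plant_csv=None) -> "FingerprintSet":
        fp = pd.read_csv(fingerprint_csv, index_col=0)
        plants: dict[str, set[str]] = {}
        if plant_csv is not None:
            pm = pd.read_csv(plant_csv)
            for plant, grp in pm.groupby("plant"):
                plants[plant] = set(grp["metabolite"])
        return cls(fp, plants)

    def to_csv(self, fingerprint_csv, plant_csv=None) -> None:
        self.fingerprints.to_csv(fingerprint_csv, index_label="metabolite")
        if plant_csv is not None:
            rows = [(p, m) for p, mets in self.plants.items() for m in sorted(mets)]
            pd.DataFrame(rows, columns=["plant", "metabolite"]).to_csv(plant_csv, index=False)


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b| for binary vectors; 0 when both are all-zero."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.sum(a | b)
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def tanimoto_matrix(fps: FingerprintSet) -> pd.DataFrame:
    X = fps.fingerprints.to_numpy(dtype=np.int64)
    inter = X @ X.T
    counts = X.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=fps.metabolites, columns=fps.metabolites)


def build_network(fps: FingerprintSet, threshold: float = 0.85) -> nx.Graph:
    """Similarity network: edge iff Tanimoto strictly exceeds ``threshold``."""
    if len(fps.metabolites) < 1:
        raise ValueError("need at least one metabolite")
    sim = tanimoto_matrix(fps)
    g = nx.Graph()
    g.add_nodes_from(fps.metabolites)
    mets = fps.metabolites
    for i, a in enumerate(mets):
        for b in mets[i + 1:]:
            s = sim.loc[a, b]
            if s > threshold:
                g.add_edge(a, b, weight=float(s))
    return g


def _density(g: nx.Graph, nodes: set) -> float:
    k = len(nodes)
    if k < 2:
        return 1.0
    e = g.subgraph(nodes).number_of_edges()
    return 2 * e / (k * (k - 1))


def cluster_metabolites(g: nx.Graph, mode: str = "components",
                        density_threshold: float = 0.5) -> dict[str, set]:
    """Metabolite-groups from the similarity network.

    ``components`` (default): connected components. ``ipca``: seed-and-extend
    dense-subgraph mining — repeatedly seed at the highest-degree unassigned
    node and greedily add neighbouring unassigned nodes while the subgraph
    density stays >= ``density_threshold``. Isolated nodes become singleton
    groups. Group ids are ``G1, G2, ...`` in deterministic (sorted-seed)
    order.
    """
    if mode == "components":
        comps = [set(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: sorted(c)[0])
    elif mode == "ipca":
        unassigned = set(g.nodes)
        comps = []
        while unassigned:
            seed = max(sorted(unassigned), key=lambda n: g.degree(n))
            cluster = {seed}
            grown = True
            while grown:
                grown = False
                frontier = sorted(
                    {nb for n in cluster for nb in g.neighbors(n)} & unassigned - cluster
                )
                frontier.sort(key=lambda n: -sum(1 for nb in g.neighbors(n) if nb in cluster))
                for cand in frontier:
                    if _density(g, cluster | {cand}) >= density_threshold:
                        cluster.add(cand)
                        grown = True
                        break
            comps.append(cluster)
            unassigned -= cluster
        comps.sort(key=lambda c: sorted(c)[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {f"G{i + 1}": c for i, c in enumerate(comps)}


def plant_group_matrix(groups: dict[str, set], plants: dict[str, set]) -> pd.DataFrame:
    """Binary plants x metabolite-groups incidence matrix (1 iff the plant
    holds at least one metabolite of the group)."""
    grouped = {m for mets in groups.values() for m in mets}
    for plant, mets in plants.items():
        missing = set(mets) - grouped
        if missing:
            raise ValueError(f"plant {plant!r} has ungrouped metabolites {sorted(missing)}")
    gids = sorted(groups, key=lambda gid: int(gid[1:]) if gid[1:].isdigit() else gid)
    mat = pd.DataFrame(0, index=sorted(plants), columns=gids, dtype=int)
    for plant, mets in plants.items():
        for gid in gids:
            if groups[gid] & set(mets):
                mat.loc[plant, gid] = 1
    return mat


def set_similarity(row_a, row_b, index: str = "jaccard") -> float:
    """Jaccard (|A&B|/|A|B|) or Simpson (|A&B|/min(|A|,|B|)) similarity of two
    binary membership rows."""
    a = np.asarray(row_a).astype(bool)
    b = np.asarray(row_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("row length mismatch")
    inter = int(np.sum(a & b))
    if index == "jaccard":
        union = int(np.sum(a | b))
        return inter / union if union else 1.0
    if index == "simpson":
        m = min(int(a.sum()), int(b.sum()))
        if m == 0:
            raise ValueError("Simpson similarity undefined for an empty set")
        return inter / m
    raise ValueError(f"unknown index {index!r}")


def dissimilarity_matrix(matrix: pd.DataFrame, index: str = "jaccard") -> pd.DataFrame:
    """Plant-plant dissimilarity (1 - similarity) from a plant x group
    binary matrix."""
    plants = list(matrix.index)
    out = pd.DataFrame(0.0, index=plants, columns=plants)
    for i, a in enumerate(plants):
        for b in plants[i + 1:]:
            d = 1.0 - set_similarity(matrix.loc[a], matrix.loc[b], index=index)
            out.loc[a, b] = out.loc[b, a] = d
    return out


_LINKAGE = {"upgma": "average", "average": "average", "single": "single",
            "complete": "complete", "ward": "ward"}


@dataclass
class PlantTree:
    """Rooted agglomerative tree over plants with optional bootstrap support
    (percent of resampled trees containing the same leaf cluster)."""

    labels: list[str]
    linkage_matrix: np.ndarray
    support: dict[frozenset, float] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Leaf set of every internal node, smallest first."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            clade = members[int(a)] | members[int(b)]
            members[n + i] = clade
            out.append(clade)
        return out

    def newick(self) -> str:
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        reps: dict[int, str] = {i: self.labels[i] for i in range(n)}
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            node = n + i
            members[node] = members[a] | members[b]
            bl_a = h - heights[a]
            bl_b = h - heights[b]
            sup = self.support.get(members[node])
            label = "" if sup is None else f"{sup:.0f}"
            reps[node] = f"({reps[a]}:{bl_a:.6g},{reps[b]}:{bl_b:.6g}){label}"
            heights[node] = h
        root = n + len(self.linkage_matrix) - 1
        return reps[root] + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def _tree_from_dissimilarity(dmat: pd.DataFrame, linkage: str) -> PlantTree:
    labels = list(dmat.index)
    arr = dmat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    condensed = squareform(arr, checks=False)
    z = hierarchy.linkage(condensed, method=_LINKAGE[linkage])
    return PlantTree(labels, z)


def cluster_plants(
    dmat: pd.DataFrame,
    linkage: str = "upgma",
    n_boot: int = 0,
    seed: int = 0,
    matrix: pd.DataFrame | None = None,
    index: str = "jaccard",
) -> PlantTree:
    """Agglomerative plant tree from a dissimilarity matrix.

    With ``n_boot`` > 0 the plant x group ``matrix`` must be supplied:
    group columns are resampled with replacement, the dissimilarity and tree
    rebuilt per replicate, and each internal node annotated with the percent
    of replicates containing the same leaf cluster.
    """
    tree = _tree_from_dissimilarity(dmat, linkage)
    if n_boot > 0:
        if matrix is None:
            raise ValueError("bootstrap requires the plant x group matrix")
        rng = np.random.default_rng(seed)
        counts = {clade: 0 for clade in tree.clades()}
        n_cols = matrix.shape[1]
        for _ in range(n_boot):
            cols = rng.integers(0, n_cols, size=n_cols)
            boot = matrix.iloc[:, cols]
            bdm = dissimilarity_matrix(boot, index=index)
            btree = _tree_from_dissimilarity(bdm, linkage)
            bclades = set(btree.clades())
            for clade in counts:
                if clade in bclades:
                    counts[clade] += 1
        tree.support = {c: 100.0 * k / n_boot for c, k in counts.items()}
    return tree
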