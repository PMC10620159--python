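"""Tamura-Nei (TN93) pairwise evolutionary distances.

TN93 corrects the observed proportion of differing sites for unequal base
frequencies and for the two transition classes (A<->G within purines,
C<->T within pyrimidines) evolving at their own rates. With pooled
empirical frequencies pi, purine/pyrimidine sums piR/piY, observed
proportions P1 (A<->G), P2 (C<->T) and Q (transversions):

    d = -k1 * ln(1 - P1/(2 k1') - Q/(2 piR))
        -k2 * ln(1 - P2/(2 k2') - Q/(2 piY))
        -k3 * ln(1 - Q/(2 piR piY))

with k1 = 2 piA piG / piR, k2 = 2 piT piC / piY and
k3 = 2 (piR piY - piA piG piY/piR - piT piC piR/piY). Sites with a gap or
ambiguity in either sequence are excluded (pairwise deletion; complete
deletion optional at the matrix level). Saturated pairs (a log argument
<= 0) are undefined and reported as NaN with a warning.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}


def read_fasta_alignment(path) -> dict[str, str]:
    """Taxon -> sequence for an aligned FASTA file (equal lengths enforced)."""
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len(aln) < 2:
        raise ValueError("alignment needs at least two taxa")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return aln


def write_fasta_alignment(aln: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.items():
            fh.write(f">{taxon}\n{seq}\n")


def _usable_sites(seq_a: str, seq_b: str) -> np.ndarray:
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    if a.size != b.size:
        raise ValueError("sequences must be equal length")
    letters = np.array([c.encode() for c in _BASES])
    ok = np.isin(a, letters) & np.isin(b, letters)
    return np.nonzero(ok)[0]


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Closed-form TN93 distance between two aligned sequences.

    Base frequencies are pooled empirical frequencies over both sequences
    at usable (ungapped, unambiguous) sites. Returns NaN with a warning
    when the correction saturates.
    """
    sites = _usable_sites(seq_a, seq_b)
    if sites.size == 0:
        raise ValueError("no usable (ungapped ACGT) sites")
    a = np.array([_INDEX[seq_a.upper()[i]] for i in sites])
    b = np.array([_INDEX[seq_b.upper()[i]] for i in sites])
    n = sites.size

    counts = np.bincount(np.concatenate([a, b]), minlength=4).astype(float)
    pi = counts / counts.sum()
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t

    diff = a != b
    transition_ag = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    transition_ct = diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    p1 = transition_ag.sum() / n
    p2 = transition_ct.sum() / n
    q = (diff.sum() - transition_ag.sum() - transition_ct.sum()) / n

    if not diff.any():
        return 0.0
    if (p1 > 0 and (pi_a == 0 or pi_g == 0)) or (p2 > 0 and (pi_t == 0 or pi_c == 0)):
        raise ValueError("zero frequency for a base required by an observed substitution")

    k1 = 2 * pi_a * pi_g / pi_r if pi_r > 0 else 0.0
    k2 = 2 * pi_t * pi_c / pi_y if pi_y > 0 else 0.0
    arg1 = 1 - (pi_r * p1 / (2 * pi_a * pi_g) if k1 > 0 else 0.0) - q / (2 * pi_r)
    arg2 = 1 - (pi_y * p2 / (2 * pi_t * pi_c) if k2 > 0 else 0.0) - q / (2 * pi_y)
    arg3 = 1 - q / (2 * pi_r * pi_y)
    if min(arg1, arg2, arg3) <= 0:
        warnings.warn("TN93 distance saturated (log argument <= 0); returning NaN")
        return float("nan")
    k3 = 2 * (pi_r * pi_y - pi_a * pi_g * pi_y / pi_r - pi_t * pi_c * pi_r / pi_y)
    d = -(k1 * np.log(arg1) if k1 > 0 else 0.0) \
        - (k2 * np.log(arg2) if k2 > 0 else 0.0) \
        - k3 * np.log(arg3)
    return float(d)


def distance_matrix(aln: dict[str, str], deletion: str = "pairwise") -> pd.DataFrame:
    """Symmetric TN93 distance matrix over all taxon pairs.

    ``deletion='complete'`` first drops every column containing a gap or
    ambiguity in any taxon; the default is pairwise deletion. Undefined
    (saturated) pairs stay NaN.
    """
    taxa = list(aln)
    if len(taxa) < 2:
        raise ValueError("alignment needs at least two taxa")
    seqs = dict(aln)
    if deletion == "complete":
        arr = np.array([list(s.upper()) for s in seqs.values()])
        keep = np.all(np.isin(arr, list(_BASES)), axis=0)
        seqs = {t: "".join(np.array(list(s.upper()))[keep]) for t, s in seqs.items()}
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for t1, t2 in combinations(taxa, 2):
        d = tn93_distance(seqs[t1], seqs[t2])
        out.loc[t1, t2] = out.loc[t2, t1] = d
    return out
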