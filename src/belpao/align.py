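"""Progressive multiple alignment of amino-acid sequences.

A deliberately compact aligner for the desk-scale alignments this package
needs (family domains, cross-family consensus rows, reference panels):
pairwise k-mer distances feed an average-linkage guide tree, and profiles are
merged bottom-up by global profile-profile alignment with affine gaps and
BLOSUM62 column scores.  The dynamic program is vectorised row-by-row with
numpy; gap opening is only allowed out of the match state, the standard
simplification.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .constants import AA_INDEX, AMINO_ACIDS

_NEG = -1e9

_blosum = substitution_matrices.load("BLOSUM62")
#: 21x21 substitution scores: 20 amino acids + neutral row/col for X/unknown
BLOSUM62 = np.zeros((21, 21))
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        BLOSUM62[_i, _j] = _blosum[_a][_b]


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 21) residue frequencies; gaps carry no weight (columns are
    normalised by the number of rows, so gappy columns score weakly)."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for r in rows:
        for j, c in enumerate(r):
            if c == "-":
                continue
            prof[j, AA_INDEX.get(c, 20)] += 1
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    gap_open: float, gap_extend: float) -> list[str]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    La, Lb = pa.shape[0], pb.shape[0]
    col = pa @ BLOSUM62 @ pb.T  # (La, Lb) expected column-pair scores

    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)  # gap in B (consume A)
    Y = np.full((La + 1, Lb + 1), _NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, Lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, La + 1):
        X[i, 1:] = np.maximum(M[i - 1, 1:] - gap_open, X[i - 1, 1:] - gap_extend)
        M[i, 1:] = col[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        # Y along the row has an in-row dependency; since gaps only open out
        # of M/X, it collapses to a prefix running maximum:
        #   Y[i,j] = max_{k<j} (max(M[i,k], X[i,k]) - open - (j-1-k)*ext)
        t = np.maximum(M[i, :-1], X[i, :-1]) - gap_open
        idx = np.arange(Lb)
        run = np.maximum.accumulate(t + idx * gap_extend)
        Y[i, 1:] = run - idx * gap_extend

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("col")
            out_b.append("col")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            out_a.append("col")
            out_b.append("gap")
            if abs(X[i, j] - (M[i - 1, j] - gap_open)) < 1e-6:
                state = 0
            i -= 1
        elif state == 2 and j > 0:
            out_a.append("gap")
            out_b.append("col")
            prev_m = max(M[i, j - 1], X[i, j - 1]) - gap_open
            if abs(Y[i, j] - prev_m) < 1e-6:
                state = 0 if M[i, j - 1] >= X[i, j - 1] else 1
            j -= 1
        else:  # boundary
            if i > 0:
                out_a.append("col")
                out_b.append("gap")
                i -= 1
            else:
                out_a.append("gap")
                out_b.append("col")
                j -= 1
    out_a.reverse()
    out_b.reverse()

    merged: list[str] = []
    for rows, ops in ((rows_a, out_a), (rows_b, out_b)):
        for r in rows:
            it = iter(r)
            merged.append("".join(next(it) if op == "col" else "-" for op in ops))
    return merged


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = []
    for s in seqs:
        sets.append({s[i: i + k] for i in range(max(1, len(s) - k + 1))})
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return d


def align_msa(seqs: list[str], gap_open: float = 11.0, gap_extend: float = 1.0) -> list[str]:
    """Progressive multiple alignment; deterministic, single sequence returned
    ungapped; raises on empty input."""
    if not seqs:
        raise ValueError("cannot align an empty sequence set")
    if len(seqs) == 1:
        return [seqs[0]]
    d = _kmer_distance(seqs)
    Z = linkage(squareform(d, checks=False), method="average")
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(seqs))}
    aligned: dict[int, list[str]] = {i: [seqs[i]] for i in range(len(seqs))}
    nxt = len(seqs)
    for a, b, _, _ in Z:
        a, b = int(a), int(b)
        merged = _align_profiles(aligned[a], aligned[b], gap_open, gap_extend)
        clusters[nxt] = clusters[a] + clusters[b]
        aligned[nxt] = merged
        del aligned[a], aligned[b]
        nxt += 1
    rows = aligned[nxt - 1]
    order = clusters[nxt - 1]
    # restore input order
    out = [""] * len(seqs)
    for row, src in zip(rows, order):
        out[src] = row
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both rows are
    non-gap; 0 if no comparable columns."""
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)
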