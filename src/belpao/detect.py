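"""De novo structural detection of LTR-retrotransposon candidates.

An LTR element leaves a characteristic footprint: two similar direct repeats
(the LTRs, 0.2-1.2 kb) whose starts are 2-15 kb apart.  The detector finds
such repeat pairs by exact k-mer seeding between positions at plausible
spacing, clusters co-diagonal seed pairs into repeat-pair candidates, and
validates each candidate by a gapped alignment of the two repeat copies.
Detection is deterministic; overlapping and nested candidates are all
reported and resolved later by the merge stage.

Both strands are covered implicitly: an element inserted in reverse
orientation still presents a direct repeat pair on the forward strand, so
candidates carry no strand call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np


@dataclass
class Contig:
    contig_id: str
    species_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LTRParams:
    min_ltr: int = 200
    max_ltr: int = 1200
    min_dist: int = 2000
    max_dist: int = 15000
    min_ltr_identity: float = 0.8
    seed_kmer: int = 16
    #: spacing tolerance when clustering seed pairs on nearby diagonals
    diagonal_band: int = 25
    #: k-mers occurring more often than this on a contig are ignored as repeats
    max_kmer_occurrence: int = 64


@dataclass
class LTRCandidate:
    candidate_id: str
    contig_id: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    detector_tag: str = "A"
    class_label: str = "unclassified"
    species_id: str = ""
    seq: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def element(self) -> tuple[int, int]:
        return (self.ltr5[0], self.ltr3[1])

    @property
    def start(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_genome(contigs: list[Contig], min_contig: int = 10000,
                  min_genome: int = 1_500_000) -> tuple[list[Contig], bool]:
    """Drop contigs below ``min_contig`` bp; flag the genome excluded when the
    retained total is below ``min_genome`` bp.  Returns (retained, excluded)."""
    retained = [c for c in contigs if len(c) >= min_contig]
    total = sum(len(c) for c in retained)
    excluded = total < min_genome
    return retained, excluded


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers and a validity mask (False where any N)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    invalid = arr < 0
    vals = np.where(invalid, 0, arr)
    kernel = 4 ** np.arange(k, dtype=np.int64)
    codes = np.convolve(vals, kernel, mode="valid")
    bad = np.convolve(invalid.astype(np.int64), np.ones(k, dtype=np.int64), mode="valid") > 0
    return codes, ~bad


def _seed_pairs(codes: np.ndarray, valid: np.ndarray, min_d: int, max_d: int,
                max_occ: int) -> list[tuple[int, int]]:
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.nonzero(np.diff(sorted_codes))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(sorted_codes)]])
    pairs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        n = e - s
        if n < 2 or n > max_occ:
            continue
        pos = np.sort(order[s:e])
        pos = pos[valid[pos]]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = pos[j] - pos[i]
                if d > max_d:
                    break
                if d >= min_d:
                    pairs.append((int(pos[i]), int(d)))
    return pairs


def _cluster_pairs(pairs: list[tuple[int, int]], band: int, max_ltr: int) -> list[list[tuple[int, int]]]:
    """Group seed pairs lying on nearby diagonals into repeat-pair clusters.

    Pairs are chained by spacing (within ``band`` of the previous pair, which
    tolerates small indel drift between the two repeat copies) and then split
    wherever consecutive seed positions are further apart than ``max_ltr``.
    """
    import bisect

    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    buckets: dict[int, list[tuple[int, int]]] = {}
    for idx, (p, d) in enumerate(pairs):
        buckets.setdefault(d // band, []).append((p, idx))
    for b in buckets.values():
        b.sort()
    for idx, (p, d) in enumerate(pairs):
        key = d // band
        for kb in (key - 1, key, key + 1):
            b = buckets.get(kb)
            if not b:
                continue
            lo = bisect.bisect_left(b, (p - max_ltr, -1))
            hi = bisect.bisect_right(b, (p + max_ltr, n + 1))
            for q, jdx in b[lo:hi]:
                if jdx > idx and abs(pairs[jdx][1] - d) <= band:
                    union(idx, jdx)

    groups: dict[int, list[tuple[int, int]]] = {}
    for idx in range(n):
        groups.setdefault(find(idx), []).append(pairs[idx])
    return list(groups.values())


def _extend_right(seq: str, i: int, j: int, limit: int, xdrop: int = 12) -> int:
    """X-drop ungapped extension: number of positions the repeat pair extends
    right of exclusive ends (i, j), scoring +1/-2 per match/mismatch."""
    best, best_t, score = 0, 0, 0
    n = len(seq)
    for t in range(limit):
        if i + t >= n or j + t >= n:
            break
        score += 1 if seq[i + t] == seq[j + t] else -2
        if score > best:
            best, best_t = score, t + 1
        elif score < best - xdrop:
            break
    return best_t


def _extend_left(seq: str, i: int, j: int, limit: int, xdrop: int = 12) -> int:
    """Mirror of :func:`_extend_right` for extension left of starts (i, j)."""
    best, best_t, score = 0, 0, 0
    for t in range(1, limit + 1):
        if i - t < 0 or j - t < 0:
            break
        score += 1 if seq[i - t] == seq[j - t] else -2
        if score > best:
            best, best_t = score, t
        elif score < best - xdrop:
            break
    return best_t


def _alignment_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def find_ltr_pairs(contig: Contig, params: LTRParams | None = None) -> list[LTRCandidate]:
    """Report all direct-repeat pair candidates on a contig.

    A candidate is a pair of sub-intervals of length in [min_ltr, max_ltr],
    with start-to-start spacing in [min_dist, max_dist] and alignment identity
    >= min_ltr_identity.  Overlapping/nested candidates are all reported.
    """
    params = params or LTRParams()
    k = params.seed_kmer
    if len(contig) < params.min_dist + params.min_ltr:
        return []
    codes, valid = _kmer_codes(contig.seq, k)
    pairs = _seed_pairs(codes, valid, params.min_dist - params.diagonal_band,
                        params.max_dist + params.diagonal_band, params.max_kmer_occurrence)
    if not pairs:
        return []
    out: list[LTRCandidate] = []
    n = 0
    for cl in _cluster_pairs(pairs, params.diagonal_band, params.max_ltr):
        p5 = [p for p, _ in cl]
        s5, e5 = min(p5), max(p5) + k
        p3 = [p + d for p, d in cl]
        s3, e3 = min(p3), max(p3) + k
        # seed cover underestimates the repeat ends; extend by X-drop alignment
        room = max(0, params.max_ltr - (e5 - s5))
        ext = _extend_left(contig.seq, s5, s3, room)
        s5, s3 = s5 - ext, s3 - ext
        room = max(0, min(params.max_ltr - (e5 - s5), s3 - e5))
        ext = _extend_right(contig.seq, e5, e3, room)
        e5, e3 = e5 + ext, e3 + ext
        len5, len3 = e5 - s5, e3 - s3
        if not (params.min_ltr <= len5 <= params.max_ltr and params.min_ltr <= len3 <= params.max_ltr):
            continue
        spacing = s3 - s5
        if not params.min_dist <= spacing <= params.max_dist:
            continue
        if e5 > s3:  # repeat copies themselves must not overlap
            continue
        identity = _alignment_identity(contig.seq[s5:e5], contig.seq[s3:e3])
        if identity < params.min_ltr_identity:
            continue
        n += 1
        out.append(LTRCandidate(
            candidate_id=f"{contig.contig_id}:cand{n}",
            contig_id=contig.contig_id,
            ltr5=(s5, e5), ltr3=(s3, e3),
            ltr_identity=identity,
            species_id=contig.species_id,
            seq=contig.seq[s5:e3],
        ))
    out.sort(key=lambda c: (c.start, c.end))
    return out


#: default parameterizations of the two detector passes; the stricter pass B
#: plays the role the higher-precision reference detector plays in the merge.
DEFAULT_PARAMS_A = LTRParams(seed_kmer=16, min_ltr_identity=0.75)
DEFAULT_PARAMS_B = LTRParams(seed_kmer=20, min_ltr_identity=0.85)


def run_detectors(contigs: list[Contig], params_a: LTRParams | None = None,
                  params_b: LTRParams | None = None) -> tuple[list[LTRCandidate], list[LTRCandidate]]:
    """Run two independently parameterized detector passes (tags A and B)."""
    params_a = params_a or DEFAULT_PARAMS_A
    params_b = params_b or DEFAULT_PARAMS_B
    if params_a == params_b:
        raise ValueError("the two detector parameterizations must differ")
    set_a: list[LTRCandidate] = []
    set_b: list[LTRCandidate] = []
    for contig in contigs:
        for cand in find_ltr_pairs(contig, params_a):
            cand.detector_tag = "A"
            cand.candidate_id += ":A"
            set_a.append(cand)
        for cand in find_ltr_pairs(contig, params_b):
            cand.detector_tag = "B"
            cand.candidate_id += ":B"
            set_b.append(cand)
    return set_a, set_b
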