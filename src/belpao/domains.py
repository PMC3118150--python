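"""ORF finding, position-specific domain scoring, and class assignment.

Candidate elements are validated by protein evidence: a candidate is kept only
if it has at least one open reading frame longer than 300 bp and at least one
protein-domain hit with E-value below 0.01.  Validated elements are then
assigned to one of the four LTR classes (Ty1/Copia, Ty3/Gypsy, BEL/Pao, DIRS)
by the most significant E-value against class-specific domain profiles; an
element whose best E-value is not below 1e-20 stays unclassified.

Domains are modelled as ungapped log-odds position-specific scoring matrices
(PSSMs) built from reference alignments, with E-values calibrated against an
extreme-value (Gumbel) fit to the score distribution of shuffled decoys:
E(S) = n_windows * exp(-lambda * (S - mu)).  This keeps the decision logic of
profile-HMM searches (thresholds 0.01, 1e-4, 1e-20) with a transparent,
seedable scorer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ._rng import as_generator
from .align import align_msa
from .constants import AA_INDEX, CLASSES, DOMAINS, revcomp

_EULER = 0.5772156649015329
_MIN_E = 1e-300


from .constants import AA_BACKGROUND as BACKGROUND_AA  # noqa: E402


# ---------------------------------------------------------------------------
# open reading frames
# ---------------------------------------------------------------------------

@dataclass
class ORF:
    frame: int  # +1..+3 forward, -1..-3 reverse
    start: int  # nucleotide coords on the forward strand, 0-based half-open
    end: int
    aa_seq: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _frame_orfs(seq: str, offset: int, min_codons: int) -> list[tuple[int, int, str]]:
    """Maximal stop-free codon runs (in frame-local nucleotide coords)."""
    aa = str(Seq(seq[offset:offset + 3 * ((len(seq) - offset) // 3)]).translate())
    out = []
    start = 0
    for i, c in enumerate(aa + "*"):
        if c == "*":
            if i - start >= min_codons:
                out.append((offset + 3 * start, offset + 3 * i, aa[start:i]))
            start = i + 1
    return out


def find_orfs(seq: str, min_len: int = 300) -> list[ORF]:
    """All maximal stop-to-stop ORFs of length > ``min_len`` bp in 6 frames.

    Coordinates are reported on the forward strand (0-based half-open).
    """
    min_codons = min_len // 3 + 1
    orfs: list[ORF] = []
    for off in range(3):
        for s, e, aa in _frame_orfs(seq, off, min_codons):
            orfs.append(ORF(frame=off + 1, start=s, end=e, aa_seq=aa))
    rc = revcomp(seq)
    n = len(seq)
    for off in range(3):
        for s, e, aa in _frame_orfs(rc, off, min_codons):
            orfs.append(ORF(frame=-(off + 1), start=n - e, end=n - s, aa_seq=aa))
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


def translation_pieces(seq: str, min_aa: int = 60) -> list[str]:
    """Six-frame translations (>= ``min_aa`` residues), the search space for
    domain scans.

    Stop codons are kept as neutral 'X' positions rather than splitting the
    translation: the scan is a local similarity search, and an isolated
    nonsense mutation inside a real domain should cost one column, not the
    whole window.  Frameshifts still split the signal across frames.
    """
    frames = []
    rc = revcomp(seq)
    for src in (seq, rc):
        for off in range(3):
            aa = str(Seq(src[off: off + 3 * ((len(src) - off) // 3)]).translate())
            frames.append(aa.replace("*", "X"))
    return [f for f in frames if len(f) >= min_aa]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class DomainProfile:
    domain_name: str
    class_label: str  # one of CLASSES or "generic"
    matrix: np.ndarray  # (length, 21): 20 aa log2-odds columns + zero column for X
    background: np.ndarray  # length-20 background amino-acid frequencies
    mu: float
    lam: float
    n_calibration_decoys: int

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def null_col_mean(self) -> np.ndarray:
        """Expected null score per column (background composition)."""
        return self.matrix[:, :20] @ self.background

    def e_value(self, score: float, n_effective: int) -> float:
        e = n_effective * math.exp(max(-600.0, min(600.0, -self.lam * (score - self.mu))))
        return max(e, _MIN_E)


@dataclass
class DomainHit:
    element_id: str
    domain_name: str
    class_label: str
    interval: tuple[int, int]  # aa coords within the scanned piece
    score: float
    e_value: float


def _encode_aa(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


def _window_scores(profile: DomainProfile, piece: np.ndarray) -> np.ndarray:
    """Scores of every window against the full profile.

    If the piece is shorter than the profile, the piece slides along the
    profile and the columns it does not cover contribute their expected null
    score, so that partial-coverage scores stay comparable with the
    full-length decoy calibration.
    """
    L = profile.length
    m = profile.matrix
    n = piece.size
    if n >= L:
        # per-position column scores, then summed along diagonals via strides
        R = np.ascontiguousarray(m[:, piece])  # (L, n)
        s0, s1 = R.strides
        windows = np.lib.stride_tricks.as_strided(
            R, shape=(L, n - L + 1), strides=(s0 + s1, s1))
        return windows.sum(axis=0)
    offsets = np.arange(L - n + 1)
    scores = np.zeros(L - n + 1)
    for j in range(n):
        scores += m[offsets + j, piece[j]]
    null = profile.null_col_mean
    cum = np.concatenate([[0.0], np.cumsum(null)])
    uncovered = cum[-1] - (cum[offsets + n] - cum[offsets])
    return scores + uncovered


def build_domain_profile(aligned: list[str], domain_name: str = "generic",
                         class_label: str = "generic", decoy_count: int = 500,
                         seed=0) -> DomainProfile:
    """Compile an aligned set of amino-acid sequences into a calibrated PSSM.

    Column scores are log2 of (column frequency with pseudocount 1/20) over
    the codon-usage background; the null score distribution is a Gumbel
    fitted by the method of moments to ``decoy_count`` shuffled decoys drawn
    from the training-sequence residue composition, which keeps E-values
    calibrated both for translated genomic windows and for shuffles of real
    domain sequences.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned sequences")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValueError("aligned sequences must have equal lengths")
    counts = np.zeros((L, 20))
    for s in aligned:
        for j, c in enumerate(s):
            i = AA_INDEX.get(c)
            if i is not None:
                counts[j, i] += 1
    n_eff = counts.sum(axis=1, keepdims=True)
    freq = (counts + 1 / 20) / (n_eff + 1)
    scores = np.log2(freq / BACKGROUND_AA[None, :])
    matrix = np.zeros((L, 21))
    matrix[:, :20] = scores

    rng = as_generator(seed)
    residues = np.concatenate([_encode_aa(s.replace("-", "")) for s in aligned])
    residues = residues[residues < 20]
    decoys = rng.choice(residues, size=(decoy_count, L))
    prof = DomainProfile(domain_name, class_label, matrix, BACKGROUND_AA.copy(),
                         0.0, 1.0, decoy_count)
    dscores = np.zeros(decoy_count)
    for j in range(L):
        dscores += matrix[j, decoys[:, j]]
    std = float(dscores.std())
    if std <= 0:
        std = 1.0
    lam = math.pi / (math.sqrt(6) * std)
    mu = float(dscores.mean()) - _EULER / lam
    prof.mu, prof.lam = mu, lam
    return prof


def scan_domains(query: str, profiles: list[DomainProfile],
                 element_id: str = "") -> list[DomainHit]:
    """Best-scoring window of ``query`` per profile, with calibrated E-values
    (n_effective = number of scanned windows); sorted by E-value."""
    enc = _encode_aa(query)
    hits: list[DomainHit] = []
    for prof in profiles:
        scores = _window_scores(prof, enc)
        if scores.size == 0:
            continue
        best = int(np.argmax(scores))
        n_eff = int(scores.size)
        s = float(scores[best])
        if enc.size >= prof.length:
            interval = (best, best + prof.length)
        else:
            interval = (0, enc.size)
        hits.append(DomainHit(element_id, prof.domain_name, prof.class_label,
                              interval, s, prof.e_value(s, n_eff)))
    hits.sort(key=lambda h: h.e_value)
    return hits


def scan_element(seq_nt: str, profiles: list[DomainProfile], element_id: str = "",
                 min_piece_aa: int = 60) -> list[DomainHit]:
    """Scan all 6-frame translated stretches of a nucleotide sequence and keep
    the single best hit per profile, with n_effective aggregated over every
    window scanned for that profile."""
    pieces = [_encode_aa(p) for p in translation_pieces(seq_nt, min_piece_aa)]
    best: dict[int, tuple[float, int, tuple[int, int]]] = {}
    for pi, prof in enumerate(profiles):
        tot_windows = 0
        top: tuple[float, tuple[int, int]] | None = None
        for enc in pieces:
            scores = _window_scores(prof, enc)
            if scores.size == 0:
                continue
            tot_windows += int(scores.size)
            b = int(np.argmax(scores))
            s = float(scores[b])
            if top is None or s > top[0]:
                iv = (b, b + prof.length) if enc.size >= prof.length else (0, enc.size)
                top = (s, iv)
        if top is not None:
            best[pi] = (top[0], tot_windows, top[1])
    hits = []
    for pi, (s, n_eff, iv) in best.items():
        prof = profiles[pi]
        hits.append(DomainHit(element_id, prof.domain_name, prof.class_label,
                              iv, s, prof.e_value(s, max(1, n_eff))))
    hits.sort(key=lambda h: h.e_value)
    return hits


# ---------------------------------------------------------------------------
# class profile library
# ---------------------------------------------------------------------------

@dataclass
class ClassProfileLibrary:
    generic: dict[str, DomainProfile]  # domain -> pooled profile
    by_class: dict[str, list[DomainProfile]]  # class -> lineage subprofiles
    metadata: dict = field(default_factory=dict)

    @property
    def generic_profiles(self) -> list[DomainProfile]:
        return list(self.generic.values())

    @property
    def all_profiles(self) -> list[DomainProfile]:
        """Pooled-generic plus every class subprofile — the domain-library
        scan used for candidate validation."""
        out = list(self.generic.values())
        for profs in self.by_class.values():
            out.extend(profs)
        return out

    def class_profiles(self, class_label: str) -> list[DomainProfile]:
        return list(self.by_class[class_label])


def _identity_clusters(seqs: list[str], threshold: float = 0.8) -> list[list[str]]:
    """Greedy single-representative clustering by ungapped identity."""
    reps: list[str] = []
    clusters: list[list[str]] = []
    for s in seqs:
        for rep, cl in zip(reps, clusters):
            n = min(len(rep), len(s))
            ident = sum(a == b for a, b in zip(rep[:n], s[:n])) / n
            if ident >= threshold:
                cl.append(s)
                break
        else:
            reps.append(s)
            clusters.append([s])
    return clusters


def build_class_profiles(panels: dict[str, dict[str, list[tuple[str, str]]]],
                         build_e: float = 1e-4, decoy_count: int = 400,
                         seed=0) -> ClassProfileLibrary:
    """Build generic per-domain profiles from the pooled panels, then
    class-specific profiles from the members that pass the generic scan at
    E < ``build_e``.

    Because a class can contain deeply diverged lineages, its surviving
    members are first grouped by sequence identity and one subprofile is
    compiled per lineage group; the class E-value of a query is the best over
    the class's subprofiles.
    """
    if len(panels) < 2:
        raise ValueError("need panels for at least 2 classes")
    rng = as_generator(seed)
    generic: dict[str, DomainProfile] = {}
    for d in DOMAINS:
        pooled = [s for cls in panels for _, s in panels[cls].get(d, [])]
        if len(pooled) < 2:
            continue
        msa = align_msa(pooled)
        generic[d] = build_domain_profile(msa, d, "generic", decoy_count,
                                          rng.integers(2 ** 31))
    by_class: dict[str, list[DomainProfile]] = {}
    excluded: list[str] = []
    for cls in panels:
        by_class[cls] = []
        for d in DOMAINS:
            members = panels[cls].get(d, [])
            if d not in generic or len(members) < 2:
                continue
            surviving = []
            for name, s in members:
                hit = scan_domains(s, [generic[d]])[0]
                if hit.e_value < build_e:
                    surviving.append(s)
                else:
                    excluded.append(name)
            if len(surviving) < 2:
                continue
            for group in _identity_clusters(surviving):
                rows = group if len(group) >= 2 else [group[0], group[0]]
                msa = align_msa(rows) if len(set(rows)) > 1 else list(rows)
                by_class[cls].append(build_domain_profile(
                    msa, d, cls, decoy_count, rng.integers(2 ** 31)))
        if not by_class[cls]:
            raise ValueError(f"class {cls!r}: fewer than 2 surviving members for every domain")
    return ClassProfileLibrary(generic, by_class,
                               metadata={"build_e": build_e, "excluded": excluded,
                                         "decoy_count": decoy_count})


# ---------------------------------------------------------------------------
# validation and classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedElement:
    element_id: str
    best_e: dict[str, float]
    class_label: str  # one of CLASSES or "unclassified"; obeys the 1e-20 rule
    #: best-supported class at a softer evidence level (E < 1e-4) — used for
    #: family-level majority votes, never as the element's assignment
    class_vote: str | None = None


def validate_candidate(seq_nt: str, library: ClassProfileLibrary,
                       min_orf: int = 300, keep_e: float = 0.01,
                       element_id: str = "", min_piece_aa: int = 60) -> tuple[bool, dict]:
    """Keep a candidate iff it has an ORF > ``min_orf`` bp and at least one
    domain hit with E-value < ``keep_e`` against the full domain library
    (pooled-generic and class subprofiles)."""
    orfs = find_orfs(seq_nt, min_len=min_orf)
    hits = scan_element(seq_nt, library.all_profiles, element_id,
                        min_piece_aa=min_piece_aa) if orfs else []
    keep = bool(orfs) and any(h.e_value < keep_e for h in hits)
    return keep, {"n_orfs": len(orfs), "hits": hits}


def classify_element(seq_nt: str, library: ClassProfileLibrary,
                     classify_e: float = 1e-20, element_id: str = "") -> ClassifiedElement:
    """Assign the class with the smallest best E-value, if below ``classify_e``.

    Ties are broken by the fixed class order; elements whose best E-value does
    not reach the threshold remain unclassified.
    """
    best_e: dict[str, float] = {}
    for cls in CLASSES:
        if cls not in library.by_class:
            continue
        hits = scan_element(seq_nt, library.class_profiles(cls), element_id)
        if hits:
            best_e[cls] = min(h.e_value for h in hits)
    label = "unclassified"
    if best_e:
        winner = min(best_e, key=lambda c: (best_e[c], CLASSES.index(c)))
        if best_e[winner] < classify_e:
            label = winner
    return ClassifiedElement(element_id, best_e, label)


def validate_and_classify(seq_nt: str, library: ClassProfileLibrary,
                          min_orf: int = 300, keep_e: float = 0.01,
                          classify_e: float = 1e-20,
                          element_id: str = "") -> tuple[bool, ClassifiedElement]:
    """Single-pass validation + classification over the whole profile library.

    Equivalent to :func:`validate_candidate` followed by
    :func:`classify_element` (the scan returns the best hit per profile, so
    per-class minima are identical), but scans the element only once.
    """
    orfs = find_orfs(seq_nt, min_len=min_orf)
    if not orfs:
        return False, ClassifiedElement(element_id, {}, "unclassified")
    hits = scan_element(seq_nt, library.all_profiles, element_id)
    keep = any(h.e_value < keep_e for h in hits)
    best_e: dict[str, float] = {}
    for h in hits:
        if h.class_label in CLASSES:
            best_e[h.class_label] = min(best_e.get(h.class_label, np.inf), h.e_value)
    label = "unclassified"
    vote = None
    if best_e:
        winner = min(best_e, key=lambda c: (best_e[c], CLASSES.index(c)))
        if best_e[winner] < classify_e:
            label = winner
        if best_e[winner] < 1e-4:
            vote = winner
    return keep, ClassifiedElement(element_id, best_e, label, vote)
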