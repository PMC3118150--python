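"""Horizontal-transfer candidate screen and abundance statistics.

Vertically inherited elements should not be highly similar across distant
taxa; the screen flags cross-species element pairs with at least 80%
nucleotide identity over at least 20% of the (shorter) element's length and
at least 300 bp, annotated with the taxonomic rank at which the two species
diverge.  Same-genus pairs are expected and serve as the positive control;
cross-phylum pairs are horizontal-transfer candidates.

Abundance summaries report element counts and densities (copies per Mbp) per
species plus per-class fractions of classified elements, and a Spearman rank
correlation (exact permutation p-value at small n) relates total copy number
to density across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import edlib
import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist


@dataclass
class TaxonomyMap:
    species: dict[str, dict[str, str]]  # species_id -> {genus, phylum, subkingdom}

    def rank_of_divergence(self, sp_a: str, sp_b: str) -> str:
        a, b = self.species[sp_a], self.species[sp_b]
        if a.get("genus") == b.get("genus"):
            return "same_genus"
        if a.get("phylum") == b.get("phylum"):
            return "same_phylum"
        return "cross_phylum"


@dataclass
class HTCandidatePair:
    id_a: str
    id_b: str
    species_a: str
    species_b: str
    rank: str  # same_genus | same_phylum | cross_phylum
    identity: float
    span: int


def _local_match(sa: str, sb: str, kmer: int = 14, min_shared: int = 10) -> tuple[float, int]:
    """Best conserved-region match between two sequences: shared k-mer
    diagonal clustering delimits the candidate region, which is then aligned.
    Returns (identity, aligned span); (0.0, 0) when nothing matches."""
    pos_a: dict[str, list[int]] = {}
    for i in range(len(sa) - kmer + 1):
        pos_a.setdefault(sa[i:i + kmer], []).append(i)
    hits = []
    for j in range(len(sb) - kmer + 1):
        for i in pos_a.get(sb[j:j + kmer], ()):
            hits.append((i, j))
    if len(hits) < min_shared:
        return 0.0, 0
    # cluster by diagonal
    hits.sort(key=lambda ij: (ij[0] - ij[1], ij[0]))
    best_cluster: list[tuple[int, int]] = []
    current: list[tuple[int, int]] = []
    for i, j in hits:
        if current and abs((i - j) - (current[-1][0] - current[-1][1])) <= 50 \
                and i - current[-1][0] <= 1000:
            current.append((i, j))
        else:
            if len(current) > len(best_cluster):
                best_cluster = current
            current = [(i, j)]
    if len(current) > len(best_cluster):
        best_cluster = current
    if len(best_cluster) < min_shared:
        return 0.0, 0
    ia, ib = min(p[0] for p in best_cluster), max(p[0] for p in best_cluster) + kmer
    ja, jb = min(p[1] for p in best_cluster), max(p[1] for p in best_cluster) + kmer
    pad = 30
    ra = sa[max(0, ia - pad): min(len(sa), ib + pad)]
    rb = sb[max(0, ja - pad): min(len(sb), jb + pad)]
    res = edlib.align(ra, rb, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, ra, rb)
    cols = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return (matches / cols if cols else 0.0), cols


def ht_screen(elements: list, taxonomy: TaxonomyMap, min_identity: float = 0.80,
              min_fraction: float = 0.20, min_span: int = 300) -> list[HTCandidatePair]:
    """All cross-species element pairs whose best conserved region has
    identity >= ``min_identity`` over >= max(min_fraction * shorter element,
    ``min_span``) aligned bp, annotated with divergence rank.

    The fraction threshold is anchored to the shorter element of the pair
    (the conservative reading: it flags more candidates).
    """
    from .constants import revcomp

    out: list[HTCandidatePair] = []
    rcs = [revcomp(a.seq) for a in elements]
    fwd = [{a.seq[i:i + 14] for i in range(0, max(1, len(a.seq) - 13), 2)}
           for a in elements]
    rev = [{s[i:i + 14] for i in range(0, max(1, len(s) - 13), 2)} for s in rcs]
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            a, b = elements[i], elements[j]
            if a.species_id == b.species_id:
                continue
            shared_f = len(fwd[i] & fwd[j])
            shared_r = len(fwd[i] & rev[j])
            if max(shared_f, shared_r) < 5:
                continue
            sb = b.seq if shared_f >= shared_r else rcs[j]
            identity, span = _local_match(a.seq, sb)
            need = max(int(min_fraction * min(len(a.seq), len(b.seq))), min_span)
            if identity >= min_identity and span >= need:
                out.append(HTCandidatePair(
                    id_a=a.element_id, id_b=b.element_id,
                    species_a=a.species_id, species_b=b.species_id,
                    rank=taxonomy.rank_of_divergence(a.species_id, b.species_id),
                    identity=identity, span=span,
                ))
    return out


def summarize_abundance(elements: list, genome_sizes: dict[str, int]) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-species counts/densities and per-class fractions.

    Returns (per_species, per_class, warnings); species with missing genome
    size are skipped with a warning.  Density is copies per Mbp; class
    fractions are taken over classified elements only.
    """
    warnings = []
    counts: dict[str, int] = {}
    class_counts: dict[tuple[str, str], int] = {}
    for e in elements:
        counts[e.species_id] = counts.get(e.species_id, 0) + 1
        class_counts[(e.species_id, e.class_label)] = class_counts.get(
            (e.species_id, e.class_label), 0) + 1
    rows = []
    for sp in sorted(set(counts) | set(genome_sizes)):
        if sp not in genome_sizes:
            warnings.append(f"no genome size for {sp}; skipped")
            continue
        size = genome_sizes[sp]
        if size <= 0:
            warnings.append(f"non-positive genome size for {sp}; skipped")
            continue
        n = counts.get(sp, 0)
        rows.append({"species_id": sp, "count": n, "genome_mbp": size / 1e6,
                     "density_per_mbp": n / (size / 1e6)})
    per_species = pd.DataFrame(rows)

    cls_rows = []
    for (sp, cls), n in sorted(class_counts.items()):
        classified = sum(v for (s, c), v in class_counts.items()
                         if s == sp and c != "unclassified")
        cls_rows.append({"species_id": sp, "class_label": cls, "count": n,
                         "fraction_of_classified":
                             (n / classified if cls != "unclassified" and classified else np.nan)})
    per_class = pd.DataFrame(cls_rows)
    return per_species, per_class, warnings


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value (two-sided) is exact (full permutation enumeration) for
    n <= 10 and a t-approximation otherwise.  Raises on constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rx, ry = rankdata(x), rankdata(y)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = rho_of(rx, ry)
    n = x.size
    if n <= 10:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = rho_of(rx, ry[list(perm)])
            total += 1
            if abs(r) >= target:
                count += 1
        p = count / total
    else:
        tt = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
        p = float(2 * t_dist.sf(abs(tt), df=n - 2))
    return rho, min(p, 1.0)
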