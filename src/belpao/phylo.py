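"""Family consensus sequences, the concatenated-domain phylogeny, and
superfamily assignment.

Per family and per pol domain (protease, reverse transcriptase, integrase), a
majority-rule consensus is built from the aligned member sequences: the most
common residue per column wins (seeded random tie-break), but it must occur
in at least one third of the rows and in at least two rows, otherwise the
column becomes 'X'.  Alignments with mean pairwise similarity below 70% or
consensuses with more than five 'X' positions are flagged for review.

Families with all three domain consensuses enter a supermatrix: one
cross-family alignment per domain, concatenated in the order the domains
occur in the element (protease - RT - integrase).  A neighbor-joining tree on
Poisson-corrected distances, rooted between the outgroup pair, with
nonparametric bootstrap support over columns, is cut at deep, well-supported
branches to define superfamilies; a within/between average-percent-similarity
matrix summarizes the partition.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._rng import as_generator
from .align import align_msa
from .constants import POL_DOMAINS


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class FamilyConsensus:
    family_id: str
    consensus: dict[str, str] = field(default_factory=dict)  # domain -> aa
    mean_similarity: dict[str, float] = field(default_factory=dict)  # percent
    flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def has_all_pol_domains(self) -> bool:
        return all(d in self.consensus for d in POL_DOMAINS)


def mean_pairwise_similarity(msa: list[str]) -> float:
    """Mean percent identity over all row pairs, counting only columns where
    both rows are non-gap.  100.0 for a single row."""
    n = len(msa)
    if n < 2:
        return 100.0
    vals = []
    arrs = [np.frombuffer(r.encode(), np.uint8) for r in msa]
    gap = ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            tot = int(both.sum())
            vals.append(100.0 * float((arrs[i][both] == arrs[j][both]).sum()) / tot if tot else 0.0)
    return float(np.mean(vals))


def build_consensus(msa: list[str], seed=0, min_frac: float = 1 / 3,
                    min_count: int = 2, flag_similarity: float = 70.0,
                    flag_x: int = 5) -> tuple[str, dict]:
    """Majority-rule consensus of one domain alignment.

    Per column the most common non-gap residue is chosen (ties broken by a
    seeded uniform draw) provided it occurs in at least ceil(n * min_frac)
    and at least ``min_count`` rows; otherwise the column is 'X'.
    """
    if not msa:
        raise ValueError("empty alignment")
    rng = as_generator(seed)
    n = len(msa)
    need = max(math.ceil(n * min_frac), min_count) if n > 1 else 1
    cols = len(msa[0])
    out = []
    for j in range(cols):
        counts: dict[str, int] = {}
        for r in msa:
            c = r[j]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("X")
            continue
        top = max(counts.values())
        winners = sorted(c for c, v in counts.items() if v == top)
        pick = winners[int(rng.integers(len(winners)))] if len(winners) > 1 else winners[0]
        if n == 1:
            out.append(pick)
        else:
            out.append(pick if top >= need else "X")
    consensus = "".join(out)
    sim = mean_pairwise_similarity(msa)
    flags = {"low_similarity": sim < flag_similarity,
             "many_x": consensus.count("X") > flag_x}
    return consensus, {"mean_similarity": sim, "flags": flags}


def family_consensuses(domain_seqs: dict[str, dict[str, list[str]]], seed=0,
                       **consensus_kwargs) -> dict[str, FamilyConsensus]:
    """Align members and build consensuses for every family and domain.

    ``domain_seqs`` maps family_id -> domain -> member amino-acid sequences.
    Domains with no members are skipped; singleton families use the member
    sequence itself.
    """
    rng = as_generator(seed)
    out: dict[str, FamilyConsensus] = {}
    for fam in sorted(domain_seqs):
        fc = FamilyConsensus(fam)
        for dom in sorted(domain_seqs[fam]):
            seqs = [s for s in domain_seqs[fam][dom] if s]
            if not seqs:
                continue
            msa = align_msa(seqs) if len(seqs) > 1 else list(seqs)
            cons, info = build_consensus(msa, seed=rng.integers(2 ** 31), **consensus_kwargs)
            fc.consensus[dom] = cons
            fc.mean_similarity[dom] = info["mean_similarity"]
            fc.flags[dom] = info["flags"]
        out[fam] = fc
    return out


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    row_ids: list[str]  # families + outgroups
    rows: list[str]  # concatenated aligned aa strings
    blocks: dict[str, tuple[int, int]]  # domain -> column range
    outgroup_ids: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def build_supermatrix(consensuses: dict[str, FamilyConsensus],
                      outgroups: dict[str, dict[str, str]]) -> Supermatrix:
    """Concatenated cross-family domain alignments (protease-RT-integrase).

    Only families with a consensus for all three pol domains are included;
    others are recorded in ``excluded``.  Requires >= 3 eligible families and
    exactly 2 outgroups.
    """
    if len(outgroups) != 2:
        raise ValueError("need exactly 2 outgroups")
    eligible = []
    excluded = []
    for fam in sorted(consensuses):
        fc = consensuses[fam]
        if fc.has_all_pol_domains():
            eligible.append(fam)
        else:
            missing = [d for d in POL_DOMAINS if d not in fc.consensus]
            excluded.append((fam, "missing:" + ",".join(missing)))
    if len(eligible) < 3:
        raise ValueError(f"only {len(eligible)} families with all three domains (need >= 3)")
    out_ids = sorted(outgroups)
    row_ids = eligible + out_ids
    blocks: dict[str, tuple[int, int]] = {}
    parts: dict[str, list[str]] = {r: [] for r in row_ids}
    col = 0
    for dom in POL_DOMAINS:
        seqs = [consensuses[f].consensus[dom] for f in eligible]
        seqs += [outgroups[o][dom] for o in out_ids]
        msa = align_msa(seqs)
        width = len(msa[0])
        blocks[dom] = (col, col + width)
        col += width
        for rid, row in zip(row_ids, msa):
            parts[rid].append(row)
    rows = ["".join(parts[r]) for r in row_ids]
    return Supermatrix(row_ids=row_ids, rows=rows, blocks=blocks,
                       outgroup_ids=out_ids, excluded=excluded)


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def _pairwise_p_distance(rows: list[np.ndarray], i: int, j: int) -> float:
    gap, x = ord("-"), ord("X")
    a, b = rows[i], rows[j]
    ok = (a != gap) & (b != gap) & (a != x) & (b != x)
    tot = int(ok.sum())
    if tot == 0:
        raise ValueError(f"no comparable columns between rows {i} and {j}")
    return float((a[ok] != b[ok]).sum()) / tot


def distance_matrix(rows: list[str], labels: list[str] | None = None) -> np.ndarray:
    """Poisson-corrected distances, -ln(1 - p), on pairwise-deletion
    p-distances (gap and 'X' columns excluded per pair, p capped at 0.98)."""
    arrs = [np.frombuffer(r.encode(), np.uint8) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p = _pairwise_p_distance(arrs, i, j)
            except ValueError:
                name = f"{labels[i]} / {labels[j]}" if labels else f"{i} / {j}"
                raise ValueError(f"undefined distance (no comparable columns): {name}") from None
            d[i, j] = d[j, i] = -math.log(1.0 - min(p, 0.98))
    return d


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree (dendropy) from a distance matrix."""
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, dist):
        buf.write(lab + "," + ",".join(f"{v:.10f}" for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, taxon_namespace=dendropy.TaxonNamespace(labels))
    tree = pdm.nj_tree()
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


@dataclass
class PhyloTree:
    tree: dendropy.Tree
    labels: list[str]
    outgroup_ids: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)
    n_bootstrap: int = 0

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _ingroup_bipartitions(tree: dendropy.Tree, ingroup: set) -> dict[frozenset, object]:
    """Map clade leaf-sets (restricted to the ingroup, canonicalised against
    their complement) to tree nodes."""
    out: dict[frozenset, object] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = {lf.taxon.label for lf in node.leaf_iter()} & ingroup
        if not leaves or leaves == ingroup:
            continue
        comp = frozenset(ingroup - leaves)
        key = min(frozenset(leaves), comp, key=lambda s: (len(s), sorted(s)))
        out[key] = node
    return out


def _root_on_outgroups(tree: dendropy.Tree, outgroup_ids: list[str]) -> dendropy.Tree:
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(o) for o in outgroup_ids]
    mrca = tree.mrca(taxa=taxa)
    if mrca is tree.seed_node or mrca is None:
        # outgroups straddle the current root; reroot at one outgroup first
        leaf = tree.find_node_with_taxon_label(outgroup_ids[0])
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
        mrca = tree.mrca(taxa=taxa)
    if mrca is not tree.seed_node and mrca.edge.tail_node is not None:
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return tree


def build_tree(supermatrix: Supermatrix, n_bootstrap: int = 100, seed=0) -> PhyloTree:
    """NJ tree on the supermatrix, rooted between the outgroup pair, with
    seeded nonparametric bootstrap (column resampling) support in [0, 1]."""
    if len(supermatrix.row_ids) < 4:
        raise ValueError("need >= 4 rows for a tree")
    rng = as_generator(seed)
    labels = supermatrix.row_ids
    d = distance_matrix(supermatrix.rows, labels)
    tree = _root_on_outgroups(neighbor_joining(d, labels), supermatrix.outgroup_ids)

    ingroup = set(labels) - set(supermatrix.outgroup_ids)
    main_bips = _ingroup_bipartitions(tree, ingroup)
    counts = {k: 0 for k in main_bips}
    ncol = supermatrix.n_columns
    arr = np.array([list(r) for r in supermatrix.rows])
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r) for r in arr[:, cols]]
        try:
            db = distance_matrix(rows, labels)
        except ValueError:
            continue
        tb = _root_on_outgroups(neighbor_joining(db, labels), supermatrix.outgroup_ids)
        bips = set(_ingroup_bipartitions(tb, ingroup))
        for k in counts:
            if k in bips:
                counts[k] += 1
    support = {k: (v / n_bootstrap if n_bootstrap else 1.0) for k, v in counts.items()}
    pt = PhyloTree(tree=tree, labels=labels, outgroup_ids=supermatrix.outgroup_ids,
                   support=support, n_bootstrap=n_bootstrap)
    for key, node in main_bips.items():
        node.label = f"{support[key]:.2f}"
    return pt


# ---------------------------------------------------------------------------
# superfamilies
# ---------------------------------------------------------------------------

@dataclass
class SuperfamilyAssignment:
    assignment: dict[str, str]  # family_id -> superfamily label
    cut_edges: int = 0
    threshold: float = 0.0

    def members(self, label: str) -> list[str]:
        return sorted(f for f, l in self.assignment.items() if l == label)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def cut_superfamilies(phylo: PhyloTree, stem_quantile: float = 0.95,
                      min_support: float = 0.5,
                      min_stem_length: float = 0.1) -> SuperfamilyAssignment:
    """Cut deep, well-supported branches of the ingroup tree into
    superfamilies.

    A branch is deep when its length reaches the ``stem_quantile`` of
    internal ingroup branch lengths AND at least twice their median AND at
    least ``min_stem_length`` substitutions/site (so a star-like tree with
    uniformly short branches yields a single superfamily), and its bootstrap
    support is >= ``min_support``.  Each resulting subtree is a superfamily
    named by its smallest member family id.
    """
    tree = dendropy.Tree(phylo.tree)
    ingroup = set(phylo.labels) - set(phylo.outgroup_ids)
    bips = _ingroup_bipartitions(tree, ingroup)
    internal = []
    for key, node in bips.items():
        if node.edge.length is not None:
            internal.append((key, node, node.edge.length))
    if not internal:
        assignment = {f: f"SF_{min(ingroup)}" for f in ingroup}
        return SuperfamilyAssignment(assignment=assignment)
    lengths = np.array([l for _, _, l in internal])
    # order statistic ("lower") so the threshold is an attained branch length
    # and the deepest ~(1 - stem_quantile) of branches are all cut
    thr = float(np.quantile(lengths, stem_quantile, method="lower"))
    floor = max(2.0 * float(np.median(lengths)), min_stem_length)
    cut_nodes = []
    for key, node, l in internal:
        if l >= thr and l >= floor and phylo.support.get(key, 1.0) >= min_support:
            cut_nodes.append(node)

    # assign each ingroup leaf to the closest cut ancestor (deepest cut below
    # which it falls); leaves under no cut form the residual root group
    group_of: dict[str, int] = {}
    counter = [0]
    ids = {id(n) for n in cut_nodes}

    def walk(node, group):
        if id(node) in ids:
            counter[0] += 1
            group = counter[0]
        if node.is_leaf():
            if node.taxon.label in ingroup:
                group_of[node.taxon.label] = group
            return
        for ch in node.child_nodes():
            walk(ch, group)

    walk(tree.seed_node, 0)
    members: dict[int, list[str]] = {}
    for leaf, g in group_of.items():
        members.setdefault(g, []).append(leaf)
    assignment: dict[str, str] = {}
    for g, mem in members.items():
        label = f"SF_{min(mem)}"
        for m in mem:
            assignment[m] = label
    return SuperfamilyAssignment(assignment=assignment, cut_edges=len(cut_nodes),
                                 threshold=thr)


# ---------------------------------------------------------------------------
# similarity matrix
# ---------------------------------------------------------------------------

def similarity_matrix(supermatrix: Supermatrix,
                      assignment: SuperfamilyAssignment):
    """Average percent similarity of row pairs within and between
    superfamilies (outgroups excluded).

    Returns (labels, matrix) where the diagonal holds within-superfamily
    averages (NaN for singleton superfamilies) and off-diagonal cells hold
    between-superfamily averages.
    """
    import pandas as pd

    fams = [r for r in supermatrix.row_ids if r in assignment.assignment]
    arrs = {r: np.frombuffer(supermatrix.rows[supermatrix.row_ids.index(r)].encode(), np.uint8)
            for r in fams}
    gap, x = ord("-"), ord("X")

    def pct(i, j):
        a, b = arrs[i], arrs[j]
        ok = (a != gap) & (b != gap) & (a != x) & (b != x)
        tot = int(ok.sum())
        return 100.0 * float((a[ok] == b[ok]).sum()) / tot if tot else np.nan

    labels = assignment.labels
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for ii, la in enumerate(labels):
        for lb in labels[ii:]:
            ma = [f for f in fams if assignment.assignment[f] == la]
            mb = [f for f in fams if assignment.assignment[f] == lb]
            vals = []
            if la == lb:
                for i in range(len(ma)):
                    for j in range(i + 1, len(ma)):
                        vals.append(pct(ma[i], ma[j]))
            else:
                for a in ma:
                    for b in mb:
                        vals.append(pct(a, b))
            if vals:
                v = float(np.nanmean(vals))
                mat.loc[la, lb] = v
                mat.loc[lb, la] = v
    return mat
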