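"""Alignment, consensus rules, supermatrix bookkeeping, neighbor joining
(against a least-squares oracle), superfamily cuts and similarity matrices."""

import itertools

import numpy as np
import pytest

from belpao.align import align_msa, pairwise_identity
from belpao.metrics import adjusted_rand_index
from belpao.phylo import (FamilyConsensus, build_consensus, build_supermatrix,
                          build_tree, cut_superfamilies, distance_matrix,
                          mean_pairwise_similarity, neighbor_joining,
                          similarity_matrix)
from belpao.simulate import mutate_aa, random_aa


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def nw_oracle(a, b, match=1, mismatch=-1, gap=-1):
    """Plain Needleman-Wunsch, maximizing matches; returns aligned pair."""
    la, lb = len(a), len(b)
    S = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        S[i, 0] = i * gap
    for j in range(1, lb + 1):
        S[0, j] = j * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            S[i, j] = max(S[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch),
                          S[i - 1, j] + gap, S[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def best_topology_by_least_squares(d):
    """Brute-force over the 3 unrooted 4-taxon topologies, least-squares
    branch fit (non-negative), returns the split {x, y} grouped together."""
    from scipy.optimize import nnls
    taxa = range(4)
    pairs = list(itertools.combinations(taxa, 2))
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for split in (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))):
        # edges: 4 pendant + 1 internal
        X = np.zeros((6, 5))
        for r, (i, j) in enumerate(pairs):
            X[r, i] = 1
            X[r, j] = 1
            same = any(i in g and j in g for g in split)
            if not same:
                X[r, 4] = 1
        coef, resid = nnls(X, y)
        if best is None or resid < best[0]:
            best = (resid, split)
    return frozenset(best[1][0])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

class TestAlignMsa:
    def test_identical_pair_gap_free(self):
        msa = align_msa(["MKVLAW", "MKVLAW"])
        assert msa == ["MKVLAW", "MKVLAW"]
        assert pairwise_identity(*msa) == 1.0

    def test_single_deletion_matches_nw_oracle(self):
        msa = align_msa(["ACDEFG", "ACEFG"])
        oa, ob = nw_oracle("ACDEFG", "ACEFG")
        assert len(msa[0]) == len(msa[1]) == 6
        n_gap_cols = sum("-" in col for col in zip(*msa))
        matches = sum(x == y != "-" for x, y in zip(*msa))
        assert n_gap_cols == 1 and matches == 5
        assert sum(x == y != "-" for x, y in zip(oa, ob)) == 5

    def test_family_alignment_similarity(self):
        rng = np.random.default_rng(6)
        base = random_aa(rng, 120)
        seqs = [mutate_aa(base, 0.05, rng) for _ in range(5)]
        msa = align_msa(seqs)
        assert mean_pairwise_similarity(msa) >= 90.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_msa([])

    def test_single_sequence_returned_ungapped(self):
        assert align_msa(["MKWQ"]) == ["MKWQ"]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_unanimous_column(self):
        assert build_consensus(["A", "A", "A"])[0] == "A"

    def test_two_singletons_give_x(self):
        # each residue occurs in only one sequence (< 2 required)
        assert build_consensus(["A", "C"])[0] == "X"

    def test_majority_with_thresholds(self):
        assert build_consensus(["A", "A", "C", "C", "C", "G"])[0] == "C"

    def test_consensus_of_identical_rows_is_unflagged_copy(self):
        rows = ["MKVLAWCH"] * 4
        cons, info = build_consensus(rows)
        assert cons == "MKVLAWCH"
        assert "X" not in cons
        assert not info["flags"]["low_similarity"] and not info["flags"]["many_x"]

    def test_low_similarity_flag(self):
        rng = np.random.default_rng(7)
        rows = align_msa([random_aa(rng, 60) for _ in range(4)])
        cons, info = build_consensus(rows)
        assert info["mean_similarity"] < 70.0
        assert info["flags"]["low_similarity"]

    def test_many_x_flag(self):
        # 2 rows with disagreement at > 5 columns -> > 5 'X'
        a = "AAAAAAAAAA"
        b = "CCCCCCCCCC"
        cons, info = build_consensus([a, b])
        assert cons.count("X") == 10
        assert info["flags"]["many_x"]

    def test_tie_break_is_seeded(self):
        rows = ["AA", "AA", "CC", "CC"]
        c1 = build_consensus(rows, seed=3)[0]
        c2 = build_consensus(rows, seed=3)[0]
        assert c1 == c2
        assert set(c1) <= {"A", "C"}


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------

def _consensuses(n=4, seqs=None):
    out = {}
    for i in range(n):
        fc = FamilyConsensus(f"fam{i}")
        for d in ("protease", "reverse_transcriptase", "integrase"):
            fc.consensus[d] = (seqs or {}).get((i, d), "MKVLAW" * 10)
        out[f"fam{i}"] = fc
    return out


def _outgroups(rng=None):
    rng = rng or np.random.default_rng(77)
    base = {d: random_aa(rng, 60) for d in
            ("protease", "reverse_transcriptase", "integrase")}
    return {"out1": base,
            "out2": {d: mutate_aa(s, 0.2, rng) for d, s in base.items()}}


class TestSupermatrix:
    def test_identical_families(self):
        sm = build_supermatrix(_consensuses(4), _outgroups())
        assert len(sm.row_ids) == 6
        ingroup_rows = sm.rows[:4]
        assert len(set(ingroup_rows)) == 1

    def test_family_missing_domain_excluded(self):
        cons = _consensuses(4)
        del cons["fam2"].consensus["integrase"]
        sm = build_supermatrix(cons, _outgroups())
        assert "fam2" not in sm.row_ids
        assert ("fam2", "missing:integrase") in sm.excluded

    def test_block_boundaries_partition_columns(self):
        sm = build_supermatrix(_consensuses(5), _outgroups())
        spans = sorted(sm.blocks.values())
        assert spans[0][0] == 0 and spans[-1][1] == sm.n_columns
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError):
            build_supermatrix(_consensuses(2), _outgroups())


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

class TestTree:
    def test_distance_matrix_properties(self):
        rows = ["MKVLAW" * 5, "MKVLAW" * 5, "MKVCAW" * 5]
        d = distance_matrix(rows)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d[0, 1] == 0.0 and d[0, 2] > 0

    def test_nj_recovers_additive_topologies(self):
        """All three 4-taxon topologies, scored against a brute-force
        least-squares oracle."""
        labels = ["t0", "t1", "t2", "t3"]
        for split in (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))):
            # additive distances: pendant 0.1, internal 0.6
            d = np.zeros((4, 4))
            for i in range(4):
                for j in range(i + 1, 4):
                    same = any(i in g and j in g for g in split)
                    d[i, j] = d[j, i] = 0.2 + (0.0 if same else 0.6)
            tree = neighbor_joining(d, labels)
            want = frozenset(split[0])
            got = None
            for node in tree.preorder_node_iter():
                leaves = {lf.taxon.label for lf in node.leaf_iter()}
                if len(leaves) == 2:
                    got = frozenset(int(l[1]) for l in leaves)
                    break
            assert got in (want, frozenset({0, 1, 2, 3}) - want)
            assert best_topology_by_least_squares(d) == want

    def test_identical_ingroup_zero_branches(self):
        cons = _consensuses(3)
        sm = build_supermatrix(cons, _outgroups())
        pt = build_tree(sm, n_bootstrap=10, seed=2)
        for leaf in pt.tree.leaf_node_iter():
            if leaf.taxon.label.startswith("fam"):
                assert leaf.edge.length == pytest.approx(0.0, abs=1e-9)

    def test_planted_superfamilies_recovered(self, template_set):
        cons = {}
        for t in template_set.templates:
            if t.class_label != "BEL/Pao":
                continue
            fc = FamilyConsensus(t.family_id)
            for d in ("protease", "reverse_transcriptase", "integrase"):
                fc.consensus[d] = t.domain_aa[d]
            cons[t.family_id] = fc
        sm = build_supermatrix(cons, template_set.outgroup_domains)
        pt = build_tree(sm, n_bootstrap=100, seed=4)
        sf = cut_superfamilies(pt)
        fams = sorted(sf.assignment)
        ari = adjusted_rand_index(
            [template_set.superfamily_of[f] for f in fams],
            [sf.assignment[f] for f in fams])
        assert ari == 1.0
        # support of the superfamily stems is high
        mat = similarity_matrix(sm, sf)
        diag = np.diag(mat.values)
        off = mat.values[~np.eye(len(diag), dtype=bool)]
        assert diag.min() > off.max()


class TestCutSuperfamilies:
    def _uniform_tree(self):
        cons = _consensuses(5)
        rng = np.random.default_rng(3)
        base = "MKVLAW" * 10
        for i, fc in enumerate(cons.values()):
            for d in fc.consensus:
                fc.consensus[d] = mutate_aa(base, 0.05, rng)
        sm = build_supermatrix(cons, _outgroups())
        return build_tree(sm, n_bootstrap=20, seed=5)

    def test_star_like_tree_single_superfamily(self):
        pt = self._uniform_tree()
        sf = cut_superfamilies(pt)
        assert len(sf.labels) == 1
        assert set(sf.assignment) == {f"fam{i}" for i in range(5)}

    def test_raising_quantile_never_increases_count(self, template_set):
        cons = {}
        for t in template_set.templates:
            if t.class_label != "BEL/Pao":
                continue
            fc = FamilyConsensus(t.family_id)
            for d in ("protease", "reverse_transcriptase", "integrase"):
                fc.consensus[d] = t.domain_aa[d]
            cons[t.family_id] = fc
        sm = build_supermatrix(cons, template_set.outgroup_domains)
        pt = build_tree(sm, n_bootstrap=20, seed=6)
        counts = [len(cut_superfamilies(pt, stem_quantile=q).labels)
                  for q in (0.5, 0.75, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)


class TestSimilarityMatrix:
    def test_identical_rows_100(self):
        cons = _consensuses(3)
        sm = build_supermatrix(cons, _outgroups())
        pt = build_tree(sm, n_bootstrap=5, seed=7)
        sf = cut_superfamilies(pt)
        mat = similarity_matrix(sm, sf)
        assert mat.values[0, 0] == pytest.approx(100.0)

    def test_half_identity_pair(self):
        from belpao.phylo import Supermatrix, SuperfamilyAssignment
        sm = Supermatrix(row_ids=["a", "b"], rows=["AAAA", "AACC"],
                         blocks={"protease": (0, 4)}, outgroup_ids=[])
        sf = SuperfamilyAssignment(assignment={"a": "S", "b": "S"})
        mat = similarity_matrix(sm, sf)
        assert mat.loc["S", "S"] == pytest.approx(50.0)

    def test_singleton_superfamily_diagonal_absent(self):
        from belpao.phylo import Supermatrix, SuperfamilyAssignment
        sm = Supermatrix(row_ids=["a"], rows=["AAAA"],
                         blocks={"protease": (0, 4)}, outgroup_ids=[])
        sf = SuperfamilyAssignment(assignment={"a": "S"})
        mat = similarity_matrix(sm, sf)
        assert np.isnan(mat.loc["S", "S"])
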