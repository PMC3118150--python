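"""Similarity scores, the E-value -> weight transform, and Markov clustering
(including agreement with an independent flow-simulation oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from belpao.cluster import (all_vs_all_similarity, build_edges, cluster_families,
                            evalue_to_score, mcl_cluster)
from belpao.metrics import adjusted_rand_index
from belpao.simulate import mutate_sequence, random_nt


# ---------------------------------------------------------------------------
# independent MCL oracle: plain dense flow simulation, no pruning
# ---------------------------------------------------------------------------

def mcl_oracle(nodes, edges, inflation=4.0, pre_inflation=3.0, iters=300):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for a, b, w in edges:
        i, j = idx[a], idx[b]
        W[i, j] = W[j, i] = w ** pre_inflation
    loops = W.max(axis=0)
    loops[loops == 0] = 1.0
    W[np.diag_indices(n)] = loops
    M = W / W.sum(axis=0)
    for _ in range(iters):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
    M[M < 1e-9] = 0.0
    clusters = []
    for a in np.nonzero(np.diag(M) > 1e-9)[0]:
        members = set(np.nonzero(M[a, :] > 0)[0]) | {int(a)}
        merged = False
        for cl in clusters:
            if cl & members:
                cl |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    changed = True
    while changed:
        changed = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if clusters[x] & clusters[y]:
                    clusters[x] |= clusters.pop(y)
                    changed = True
                    break
            if changed:
                break
    labels = {}
    for ci, cl in enumerate(sorted(clusters, key=min)):
        for m in cl:
            labels.setdefault(m, ci)
    nxt = len(clusters)
    for i in range(n):
        if i not in labels:
            labels[i] = nxt
            nxt += 1
    return [labels[i] for i in range(n)]


class TestEvalueToScore:
    def test_printed_anchor_values(self):
        assert evalue_to_score(1.0) == 0.0
        assert evalue_to_score(1e-250) == 1.0
        assert evalue_to_score(1e-100) == pytest.approx(0.5)

    def test_invalid_evalue(self):
        with pytest.raises(ValueError):
            evalue_to_score(0.0)
        with pytest.raises(ValueError):
            evalue_to_score(-1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(min_value=-250, max_value=10),
           st.floats(min_value=0, max_value=20))
    def test_monotone_nonincreasing_and_bounded(self, log_e, delta):
        s1 = evalue_to_score(10.0 ** log_e)
        s2 = evalue_to_score(10.0 ** min(log_e + delta, 10))
        assert 0.0 <= s2 <= s1 <= 1.0


class TestAllVsAll:
    def test_identical_elements_maximal_match(self):
        seq = random_nt(np.random.default_rng(0), 5000, 0.42)
        (m,) = all_vs_all_similarity([("a", seq), ("b", seq)])
        assert m.identity == 1.0
        assert m.length == 5000
        assert m.e_value <= 1e-200 and m.score == 1.0

    def test_no_self_match(self):
        seq = random_nt(np.random.default_rng(1), 5000, 0.42)
        assert all(m.id_a != m.id_b for m in all_vs_all_similarity([("a", seq)]))

    def test_unrelated_sequences_no_match(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pair = [("a", random_nt(rng, 5000, 0.42)),
                    ("b", random_nt(rng, 5000, 0.42))]
            assert all_vs_all_similarity(pair) == []

    def test_reverse_complement_pair_matches(self):
        from belpao.constants import revcomp
        seq = random_nt(np.random.default_rng(2), 5000, 0.42)
        (m,) = all_vs_all_similarity([("a", seq), ("b", revcomp(seq))])
        assert m.identity == 1.0

    def test_raising_span_threshold_never_reduces_singletons(self):
        rng = np.random.default_rng(3)
        base = random_nt(rng, 3000, 0.42)
        elems = [("e%d" % i, mutate_sequence(base, 0.08, 0.0, i)[0])
                 for i in range(6)]
        elems += [("r%d" % i, random_nt(rng, 3000, 0.42)) for i in range(3)]
        singletons = []
        for span in (500, 1500, 2900):
            matches = all_vs_all_similarity(elems, min_span=span)
            part = mcl_cluster([e[0] for e in elems], build_edges(matches))
            singletons.append(sum(len(v) == 1 for v in part.families.values()))
        assert singletons == sorted(singletons)


class TestMCL:
    def test_disjoint_cliques(self):
        nodes = list("abcdef")
        edges = [(x, y, 1.0) for g in ("abc", "def")
                 for i, x in enumerate(g) for y in g[i + 1:]]
        part = mcl_cluster(nodes, edges)
        assert sorted(sorted(v) for v in part.families.values()) == \
               [["a", "b", "c"], ["d", "e", "f"]]

    def test_single_node_singleton(self):
        part = mcl_cluster(["x"], [])
        assert list(part.families.values()) == [["x"]]

    def test_barbell_splits_at_weak_bridge(self):
        nodes = list("abcdefgh")
        edges = [(x, y, 1.0) for g in ("abcd", "efgh")
                 for i, x in enumerate(g) for y in g[i + 1:]]
        edges.append(("d", "e", 0.1))
        part = mcl_cluster(nodes, edges, inflation=4.0)
        got = sorted(sorted(v) for v in part.families.values())
        assert got == [list("abcd"), list("efgh")]
        oracle = mcl_oracle(nodes, edges)
        assert adjusted_rand_index(oracle, [part.family_of(n) for n in nodes]) == 1.0

    def test_partition_covers_all_nodes(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(30)]
        edges = [(nodes[i], nodes[j], float(rng.uniform(0.1, 1)))
                 for i in range(30) for j in range(i + 1, 30)
                 if rng.random() < 0.1]
        part = mcl_cluster(nodes, edges)
        members = sorted(m for v in part.families.values() for m in v)
        assert members == sorted(nodes)

    def test_matches_oracle_on_small_graphs(self):
        """MCL equals the independent flow-simulation oracle on a seeded
        ensemble of 100 random graphs with up to 8 nodes."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(2, 9))
            nodes = [f"v{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.45:
                        edges.append((nodes[i], nodes[j],
                                      float(rng.uniform(0.05, 1.0))))
            part = mcl_cluster(nodes, edges)
            got = [part.family_of(v) for v in nodes]
            want = mcl_oracle(nodes, edges)
            assert adjusted_rand_index(got, want) == pytest.approx(1.0), \
                f"trial {trial}: {edges}"

    def test_uniform_cliques_equal_connected_components(self):
        rng = np.random.default_rng(9)
        nodes, edges, want = [], [], []
        for ci, size in enumerate((3, 5, 4)):
            grp = [f"c{ci}_{i}" for i in range(size)]
            nodes += grp
            want += [ci] * size
            edges += [(a, b, 1.0) for i, a in enumerate(grp) for b in grp[i + 1:]]
        part = mcl_cluster(nodes, edges)
        assert adjusted_rand_index(want, [part.family_of(v) for v in nodes]) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mcl_cluster(["a", "b"], [("a", "b", 1.5)])
        with pytest.raises(ValueError):
            mcl_cluster(["a"], [], inflation=1.0)


class _El:
    def __init__(self, eid, sp, seq):
        self.element_id, self.species_id, self.seq = eid, sp, seq


class TestClusterFamilies:
    def _elements(self):
        rng = np.random.default_rng(12)
        out = []
        for f in range(3):
            base = random_nt(rng, 4000, 0.42)
            for sp in ("s1", "s2"):
                for c in range(2):
                    seq, _ = mutate_sequence(base, 0.04, 0.0, 100 * f + 10 * c + ord(sp[1]))
                    out.append(_El(f"f{f}_{sp}_{c}", sp, seq))
        return out

    def test_modes_agree_without_cross_species_matches(self):
        rng = np.random.default_rng(13)
        els = [_El(f"e{i}", f"s{i % 2}", random_nt(rng, 4000, 0.42))
               for i in range(6)]
        g = cluster_families(els, "global")
        p = cluster_families(els, "per_species")
        ids = [e.element_id for e in els]
        assert adjusted_rand_index([g.family_of(i) for i in ids],
                                   [p.family_of(i) for i in ids]) == 1.0

    def test_planted_families_recovered(self):
        els = self._elements()
        part = cluster_families(els, "global")
        ids = [e.element_id for e in els]
        truth = [i.split("_")[0] for i in ids]
        got = [part.family_of(i) for i in ids]
        assert adjusted_rand_index(truth, got) >= 0.9
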