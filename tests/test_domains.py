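"""ORF finding, profile scoring/calibration, candidate validation and class
assignment."""

import numpy as np
import pytest

from belpao.constants import CLASSES
from belpao.domains import (build_domain_profile, classify_element, find_orfs,
                            scan_domains, validate_candidate,
                            validate_and_classify)
from belpao.simulate import mutate_sequence, random_aa, random_nt


class TestFindOrfs:
    def test_all_stops_in_register_frame_empty(self):
        # the in-register reading of a TAA repeat is all stops; the shifted
        # and reverse-complement frames are genuine homopolymer ORFs (N, I,
        # L) and are legitimately reported by a 6-frame finder
        assert [o for o in find_orfs("TAA" * 200) if o.frame == 1] == []

    def test_stop_free_insert_reported(self):
        rng = np.random.default_rng(2)
        insert = "ATG" + "GCT" * 133  # 402 bp stop-free
        seq = "TAA" + insert + "TAA"
        orfs = find_orfs(seq, min_len=300)
        plus = [o for o in orfs if o.frame == 1]
        assert plus and max(o.length_nt for o in plus) >= 402

    def test_template_orfs_cover_domains(self, template_set):
        tpl = template_set.templates[0]
        orfs = find_orfs(tpl.internal_seq, min_len=300)
        for d, (s, e) in tpl.domain_spans.items():
            assert any(o.start <= s and e <= o.end for o in orfs), d

    def test_reverse_strand_coordinates(self):
        from belpao.constants import revcomp
        insert = "ATG" + "GCT" * 150
        fwd = "TAA" + insert + "TAA"
        seq = revcomp(fwd)
        orfs = [o for o in find_orfs(seq, 300) if o.frame < 0]
        assert orfs
        assert all(0 <= o.start < o.end <= len(seq) for o in orfs)


class TestDomainProfile:
    def test_identical_rows_consensus_is_column_max(self):
        rng = np.random.default_rng(0)
        s = random_aa(rng, 80)
        prof = build_domain_profile([s, s], "gag", seed=1)
        for j, c in enumerate(s):
            col = prof.matrix[j, :20]
            from belpao.constants import AA_INDEX
            assert col[AA_INDEX[c]] == pytest.approx(col.max())

    def test_training_beats_shuffle(self):
        """A profile scores its own training sequence strictly above a
        shuffle of it, across seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = random_aa(rng, 100)
            t = "".join(rng.permutation(list(s)))
            prof = build_domain_profile([s, s], seed=seed)
            h_train = scan_domains(s, [prof])[0]
            h_shuf = scan_domains(t, [prof])[0]
            assert h_train.score > h_shuf.score

    def test_decoy_evalue_order_one(self):
        """Median E-value of fresh background decoys is of order 1."""
        rng = np.random.default_rng(4)
        train = [random_aa(np.random.default_rng(9), 120)] * 2
        prof = build_domain_profile(train, decoy_count=500, seed=7)
        es = []
        for _ in range(101):
            decoy = random_aa(rng, 120)
            es.append(scan_domains(decoy, [prof])[0].e_value)
        assert 0.1 <= float(np.median(es)) <= 10.0

    def test_evalue_monotone_in_score(self):
        prof = build_domain_profile([random_aa(np.random.default_rng(1), 60)] * 2,
                                    seed=3)
        es = [prof.e_value(s, 10) for s in (0.0, 10.0, 50.0, 200.0)]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert all(e > 0 for e in es)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_domain_profile(["AAA", "AAAA"])


class TestScanDomains:
    def test_self_recovery(self, panels, library):
        name, seq = panels["BEL/Pao"]["reverse_transcriptase"][0]
        hits = scan_domains(seq, library.class_profiles("BEL/Pao"))
        assert hits[0].domain_name == "reverse_transcriptase"
        assert hits[0].e_value < 1e-20

    def test_shuffled_training_not_significant(self, panels, library):
        rng = np.random.default_rng(8)
        _, seq = panels["BEL/Pao"]["protease"][0]
        prof = [p for p in library.class_profiles("BEL/Pao")
                if p.domain_name == "protease"]
        n_bad = sum(
            scan_domains("".join(rng.permutation(list(seq))), prof)[0].e_value < 0.01
            for _ in range(100))
        assert n_bad <= 5

    def test_empty_library(self):
        assert scan_domains("MKVLA" * 30, []) == []


class TestValidateCandidate:
    def test_background_discarded(self, library):
        rng = np.random.default_rng(12)
        for _ in range(5):
            keep, _ = validate_candidate(random_nt(rng, 6000, 0.42), library)
            assert not keep

    def test_planted_element_kept(self, template_set, library):
        for tpl in template_set.templates[:4]:
            keep, ev = validate_candidate(tpl.element_seq, library)
            assert keep and ev["n_orfs"] >= 1

    def test_orf_without_domain_discarded(self, library):
        rng = np.random.default_rng(13)
        # a long random ORF provides the ORF criterion but no domain evidence
        orf = "ATG" + "".join(np.random.default_rng(14).choice(
            ["GCT", "GGA", "TTA", "CCA", "ACG"], size=400))
        seq = random_nt(rng, 2000, 0.42) + orf + random_nt(rng, 2000, 0.42)
        keep, ev = validate_candidate(seq, library)
        assert not keep
        assert ev["n_orfs"] >= 1  # discarded by the domain rule, not the ORF rule


class TestClassifyElement:
    def test_zero_divergence_accuracy(self, template_set, library):
        correct = sum(
            classify_element(t.element_seq, library).class_label == t.class_label
            for t in template_set.templates)
        assert correct / len(template_set.templates) >= 0.95

    def test_threshold_rule(self, library):
        """Elements without strong evidence stay unclassified."""
        rng = np.random.default_rng(21)
        ce = classify_element(random_nt(rng, 5000, 0.42), library)
        assert ce.class_label == "unclassified"
        assert all(e >= 1e-20 for e in ce.best_e.values())

    def test_assigned_class_is_argmin(self, template_set, library):
        for tpl in template_set.templates[:6]:
            ce = classify_element(tpl.element_seq, library)
            if ce.class_label != "unclassified":
                assert ce.best_e[ce.class_label] == min(ce.best_e.values())
                assert ce.best_e[ce.class_label] < 1e-20

    def test_combined_path_matches_two_step(self, template_set, library):
        for tpl in template_set.templates[:4]:
            keep1, _ = validate_candidate(tpl.element_seq, library,
                                          min_piece_aa=60)
            ce1 = classify_element(tpl.element_seq, library)
            keep2, ce2 = validate_and_classify(tpl.element_seq, library)
            assert keep1 == keep2
            assert ce1.class_label == ce2.class_label

    def test_accuracy_degrades_with_divergence(self, template_set, library):
        """Classification rate is non-increasing in copy divergence."""
        bp = [t for t in template_set.templates if t.class_label == "BEL/Pao"]
        rates = []
        for div in (0.0, 0.05, 0.15):
            ok = 0
            for i, t in enumerate(bp):
                seq, _ = mutate_sequence(t.element_seq, div, div / 25, 50 + i)
                ok += classify_element(seq, library).class_label == t.class_label
            rates.append(ok / len(bp))
        assert rates[0] >= rates[1] >= rates[2]
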