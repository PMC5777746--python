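"""EASE enrichment and PWM scanning against enumeration oracles."""

import math

import numpy as np
import pytest

import oracles
from lncarray import enrichment as enr
from lncarray.errors import SchemaError, ValidationError


class TestEaseP:
    def test_single_hit_never_significant(self):
        assert enr.ease_p(1, 10, 50, 1000) == 1.0

    def test_tiny_worked_example(self):
        # 2 hits of a 2-gene list on a 2-gene term in a 4-gene background:
        # removing one hit leaves P(X >= 1) = 1 - C(2,2)/C(4,2) = 5/6
        assert enr.ease_p(2, 2, 2, 4) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("k,n,K,N", [(2, 5, 4, 12), (3, 6, 5, 11),
                                         (4, 4, 6, 10)])
    def test_matches_enumeration_with_one_hit_removed(self, k, n, K, N):
        expected = oracles.hypergeom_tail_enumeration(k - 1, n, K, N)
        assert enr.ease_p(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k,n,K,N", [(2, 5, 4, 12), (3, 6, 5, 11),
                                         (2, 3, 8, 12)])
    def test_at_least_plain_hypergeometric_tail(self, k, n, K, N):
        plain = oracles.hypergeom_tail_enumeration(k, n, K, N)
        assert enr.ease_p(k, n, K, N) >= plain - 1e-12

    def test_monotone_non_increasing_in_k(self):
        values = [enr.ease_p(k, 8, 10, 40) for k in range(0, 9)]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            enr.ease_p(5, 3, 10, 20)


class TestFoldEnrichment:
    def test_ratio_arithmetic(self):
        assert enr.fold_enrichment(2, 10, 20, 1000) == pytest.approx(10.0)

    def test_zero_hits_give_zero(self):
        assert enr.fold_enrichment(0, 10, 20, 1000) == 0.0

    def test_proportional_representation_gives_one(self):
        assert enr.fold_enrichment(2, 10, 200, 1000) == pytest.approx(1.0)

    def test_empty_term_flagged_nan(self):
        assert math.isnan(enr.fold_enrichment(0, 10, 0, 1000))


def gene_sets(defs):
    return [enr.GeneSet(tid, tid.lower(), frozenset(members))
            for tid, members in defs.items()]


class TestEnrich:
    def test_single_gene_overlap_filtered(self):
        sets = gene_sets({"T1": {"A", "B", "C"}})
        table = enr.enrich(["A", "X"], ["A", "B", "C", "X", "Y"], sets)
        assert table.empty

    def test_weak_term_filtered_by_ease(self):
        # 2 of 3 query genes hit a 6-gene term in a background of 10:
        # EASE = P(X >= 1) is far above 0.1
        sets = gene_sets({f"T{i}": {"A", "B", "C", "D", "E", "F"}
                          for i in range(1)})
        bg = [chr(ord("A") + i) for i in range(10)]
        table = enr.enrich(["A", "B", "H"], bg, sets)
        assert table.empty

    def test_planted_term_top_ranked_with_oracle_ease(self):
        bg = [f"g{i}" for i in range(500)]
        term = set(bg[:12])
        query = bg[:10] + bg[100:110]          # 10 of 12 members in the query
        sets = gene_sets({"PLANTED": term, "OTHER": set(bg[200:230])})
        table = enr.enrich(query, bg, sets)
        assert table.iloc[0]["term_id"] == "PLANTED"
        from scipy.stats import hypergeom
        expected = float(hypergeom.sf(9 - 1, 500, 12, 20))
        assert table.iloc[0]["ease_p"] == pytest.approx(expected, rel=1e-10)
        assert table.iloc[0]["fold_enrichment"] == pytest.approx(
            (10 / 20) / (12 / 500))

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            enr.enrich(["A"], ["B"], gene_sets({"T": {"A", "B"}}))


class TestSharedTerms:
    def _table(self, term_ids):
        import pandas as pd
        return pd.DataFrame({
            "term_id": term_ids,
            "term_name": [t.lower() for t in term_ids],
            "count": range(2, 2 + len(term_ids)),
            "list_size": 10, "term_size": 20, "background_size": 100,
            "ease_p": np.linspace(0.01, 0.09, len(term_ids)),
            "fold_enrichment": np.linspace(2, 4, len(term_ids)),
        })

    def test_disjoint_terms_give_empty_join(self):
        out = enr.shared_terms(self._table(["A", "B"]), self._table(["C"]))
        assert out.empty

    def test_identical_tables_pair_equal_statistics(self):
        t = self._table(["A", "B", "C"])
        out = enr.shared_terms(t, t)
        assert len(out) == 3
        assert np.allclose(out["fold_enrichment_a"], out["fold_enrichment_b"])

    def test_partial_overlap_keeps_both_scores(self):
        a = self._table(["A", "B", "C", "D"])
        b = self._table(["B", "C", "D", "E"])
        out = enr.shared_terms(a, b)
        assert list(out["term_id"]) == ["B", "C", "D"]
        assert {"count_a", "count_b", "fold_enrichment_a",
                "fold_enrichment_b"} <= set(out.columns)


class TestPwmRelativeScore:
    TWO_POS = enr.PWM("toy", np.array([[1.0, 0, 0, 0], [0, 2.0, 0, 0]]))

    def test_consensus_scores_one_and_anticonsensus_zero(self):
        assert enr.pwm_relative_score(self.TWO_POS, "AC") == pytest.approx(1.0)
        assert enr.pwm_relative_score(self.TWO_POS, "GG") == pytest.approx(0.0)

    def test_mixed_window_worked_value(self):
        assert enr.pwm_relative_score(self.TWO_POS, "AA") == pytest.approx(1 / 3)

    def test_all_sixteen_windows_match_naive_formula(self):
        for c1 in "ACGU":
            for c2 in "ACGU":
                w = c1 + c2
                assert enr.pwm_relative_score(self.TWO_POS, w) == pytest.approx(
                    oracles.pwm_relative_score_naive(self.TWO_POS.weights, w))

    def test_thymine_read_as_uracil(self):
        pwm = enr.PWM("u", np.array([[0.0, 0, 0, 1.0]]))
        assert enr.pwm_relative_score(pwm, "T") == pytest.approx(1.0)

    def test_invalid_letter_names_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            enr.pwm_relative_score(self.TWO_POS, "AN")

    def test_degenerate_matrix_rejected(self):
        flat = enr.PWM("flat", np.ones((2, 4)))
        with pytest.raises(ValidationError, match="degenerate"):
            enr.pwm_relative_score(flat, "AC")


class TestScanRbp:
    def test_window_scoring_exactly_at_threshold_emitted(self):
        # five positions rewarding A only: 4 of 5 consensus letters = 0.8
        pwm = enr.PWM("A5", np.array([[1.0, 0, 0, 0]] * 5))
        hits, _, _ = enr.scan_rbp([pwm], [("s", "AAAAC")], threshold=0.8)
        assert len(hits) == 1
        assert hits.iloc[0]["relative_score"] == pytest.approx(0.8)

    def test_sequence_shorter_than_matrix_yields_no_hits(self):
        pwm = enr.PWM("A5", np.array([[1.0, 0, 0, 0]] * 5))
        hits, per_seq, _ = enr.scan_rbp([pwm], [("s", "AAA")], threshold=0.5)
        assert hits.empty
        assert per_seq["s"] == set()

    def test_planted_consensus_found_at_recorded_offset(self):
        rng = np.random.default_rng(17)
        pwm = enr.PWM.from_counts(
            "M", np.array([[90, 3, 3, 4], [2, 91, 4, 3], [3, 2, 92, 3],
                           [4, 3, 2, 91]], dtype=float))
        background = "".join(rng.choice(list("ACGU"), size=60))
        seq = background[:16] + pwm.consensus + background[20:]
        hits, _, _ = enr.scan_rbp([pwm], [("lnc", seq)], threshold=0.8)
        exact = hits[hits["relative_score"] >= 1.0 - 1e-9]
        assert 17 in set(exact["offset"])

    def test_hit_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        pwm = enr.PWM.from_counts("M", rng.uniform(1, 20, size=(6, 4)))
        seq = "".join(rng.choice(list("ACGU"), size=300))
        counts = [len(enr.scan_rbp([pwm], [("s", seq)], threshold=t)[0])
                  for t in (0.5, 0.7, 0.9)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_shared_proteins_are_intersection(self):
        a5 = enr.PWM("A3", np.array([[1.0, 0, 0, 0]] * 3))
        c5 = enr.PWM("C3", np.array([[0, 1.0, 0, 0]] * 3))
        hits, per_seq, shared = enr.scan_rbp(
            [a5, c5], [("s1", "AAACCC"), ("s2", "GGGAAA")], threshold=0.95)
        assert per_seq["s1"] == {"A3", "C3"}
        assert per_seq["s2"] == {"A3"}
        assert shared == {"A3"}


class TestFileFormats:
    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("GO:1\tfirst term\tA\tB\tC\nKEGG:2\tsecond\tD\tE\n")
        sets = enr.parse_gmt(path)
        assert [s.term_id for s in sets] == ["GO:1", "KEGG:2"]
        assert sets[0].members == frozenset({"A", "B", "C"})

    def test_gmt_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GO:1\tonly-description\n")
        with pytest.raises(SchemaError):
            enr.parse_gmt(path)

    def test_pwm_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        pwms = [enr.PWM("P1", rng.normal(size=(4, 4))),
                enr.PWM("P2", rng.normal(size=(6, 4)))]
        enr.write_pwm_file(pwms, tmp_path / "m.txt")
        back = enr.parse_pwm_file(tmp_path / "m.txt")
        assert [p.protein_name for p in back] == ["P1", "P2"]
        for orig, rec in zip(pwms, back):
            assert np.allclose(orig.weights, rec.weights, atol=1e-6)

    def test_count_matrix_converted_to_log_odds(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("NA  M1\nP0  A C G U\n01  97 1 1 1\n02  1 97 1 1\n//\n")
        (pwm,) = enr.parse_pwm_file(path)
        assert pwm.consensus == "AC"
        assert pwm.weights[0, 0] > 0 > pwm.weights[0, 1]

    def test_fasta_reader(self, tmp_path):
        path = tmp_path / "s.fasta"
        path.write_text(">seq1\nACGU\nACGU\n>seq2\nGGCC\n")
        assert enr.read_fasta(path) == [("seq1", "ACGUACGU"), ("seq2", "GGCC")]
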