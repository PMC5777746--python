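"""The synthetic-data generator: determinism, planted structure, round-trips."""

import dataclasses
import json

import pytest
from scipy import stats as sps

from lncarray import annotation as ann
from lncarray import cis as cis_mod
from lncarray import enrichment as enr
from lncarray import preprocess as pre
from lncarray import simulate as sim
from lncarray.errors import ValidationError


def cfg_with(**kw):
    return sim.SimulationConfig(**kw)


class TestAnnotationGenerator:
    def test_same_seed_byte_identical_csv(self, tmp_path):
        c = cfg_with(seed=3, n_probesets=200)
        sim.simulate_annotation(c, tmp_path / "a.csv")
        sim.simulate_annotation(c, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_classifier_recovers_planted_classes(self, tmp_path):
        c = cfg_with(seed=5, n_probesets=400)
        truth = sim.simulate_annotation(c, tmp_path / "a.csv")
        anns = ann.parse_annotation_csv(tmp_path / "a.csv")
        for record in anns:
            cls = ann.classify_probe(record)
            assert cls.status == truth.probe_classes[record.probe_set_id]
            if cls.status == ann.LNCRNA:
                assert cls.source == truth.probe_sources[record.probe_set_id]

    def test_conflict_fraction_within_binomial_bounds(self, tmp_path):
        c = cfg_with(seed=11, n_probesets=1000, fraction_conflict=0.1)
        truth = sim.simulate_annotation(c, tmp_path / "a.csv")
        n_conflict = sum(1 for s in truth.probe_classes.values()
                         if s == "excluded_conflict")
        lo, hi = sps.binom.interval(0.99, 1000, 0.1)
        assert lo <= n_conflict <= hi

    def test_zero_lncrna_fraction_gives_empty_catalog(self, tmp_path):
        c = cfg_with(seed=2, n_probesets=150, fraction_lncrna=0.0)
        sim.simulate_annotation(c, tmp_path / "a.csv")
        catalog, _ = ann.catalog_from_csv(tmp_path / "a.csv")
        assert catalog.entries == []

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValidationError):
            cfg_with(fraction_lncrna=0.8, fraction_conflict=0.2,
                     fraction_short=0.1)


class TestExperimentGenerator:
    def test_same_seed_byte_identical_tsvs(self, tmp_path):
        c = cfg_with(seed=4, n_probesets=40, probes_per_set=3, n_case=3,
                     n_control=3, n_de=4, n_trans_pairs=2, n_outlier_arrays=0)
        sim.simulate_experiment(c, tmp_path / "p1.tsv", tmp_path / "d1.tsv")
        sim.simulate_experiment(c, tmp_path / "p2.tsv", tmp_path / "d2.tsv")
        assert (tmp_path / "p1.tsv").read_bytes() == (tmp_path / "p2.tsv").read_bytes()
        assert (tmp_path / "d1.tsv").read_bytes() == (tmp_path / "d2.tsv").read_bytes()

    def test_emitted_files_parse_and_match_config(self, small_study):
        m = small_study["matrix"]
        cfg = small_study["cfg"]
        assert m.values.shape == (cfg.n_probesets * cfg.probes_per_set,
                                  cfg.n_case + cfg.n_control)
        assert m.group_labels.count("case") == cfg.n_case

    def test_planted_ids_exist_in_emitted_files(self, small_study):
        truth, m = small_study["truth"], small_study["matrix"]
        sets = set(m.probe_sets)
        assert set(truth.de_probesets) <= sets
        for pair in truth.trans_pairs:
            assert pair["lnc_probeset"] in sets
            assert pair["gene_probeset"] in sets
        assert set(truth.outlier_arrays) <= set(m.sample_ids)

    def test_planted_trans_pairs_hit_target_rho_in_signal(self, small_study):
        """The planted signal realises the target rank correlation within
        the ±0.05 contract, and the noisy measured expression still agrees
        in sign and roughly in magnitude (this small fixture keeps its
        corrupted array, so measured ranks are degraded on purpose)."""
        truth, cfg = small_study["truth"], small_study["cfg"]
        expr, _ = pre.rma(small_study["matrix"])
        frame = expr.to_frame()
        for pair in truth.trans_pairs:
            assert abs(pair["signal_abs_rho"] - cfg.trans_rho_target) <= 0.05
            rho = sps.spearmanr(frame.loc[pair["lnc_probeset"]],
                                frame.loc[pair["gene_probeset"]]).statistic
            assert (rho > 0) == (pair["sign"] == "positive")
            assert abs(rho) >= cfg.trans_rho_target - 0.2

    def test_too_few_arrays_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            sim.simulate_experiment(cfg_with(n_case=1, n_control=4),
                                    tmp_path / "p.tsv", tmp_path / "d.tsv")

    def test_ground_truth_json_round_trip(self, small_study, tmp_path):
        truth = small_study["truth"]
        truth.write_json(tmp_path / "t.json")
        loaded = json.loads((tmp_path / "t.json").read_text())
        assert loaded["de_probesets"] == truth.de_probesets
        assert loaded["outlier_arrays"] == truth.outlier_arrays


class TestGenomeGenerator:
    def test_cis_search_recovers_exactly_the_planted_pairs(self, tmp_path):
        for seed in range(5):
            c = cfg_with(seed=seed)
            truth = sim.simulate_genome(c, tmp_path / "l.tsv", tmp_path / "g.tsv")
            lncs = cis_mod.read_interval_tsv(tmp_path / "l.tsv")
            genes = cis_mod.read_interval_tsv(tmp_path / "g.tsv")
            table = cis_mod.find_cis_targets(
                lncs, genes, cis_mod.CisConfig(c.genome.window))
            hits = table[table["gene_name"] != ""]
            got = {(r.lncrna_name, r.gene_name, r.relation)
                   for r in hits.itertuples(index=False)}
            want = {(p["lncrna_name"], p["gene_name"], p["relation"])
                    for p in truth.cis_pairs}
            assert got == want

    def test_all_intervals_valid_and_names_unique(self, tmp_path):
        c = cfg_with(seed=8)
        sim.simulate_genome(c, tmp_path / "l.tsv", tmp_path / "g.tsv")
        intervals = (cis_mod.read_interval_tsv(tmp_path / "l.tsv")
                     + cis_mod.read_interval_tsv(tmp_path / "g.tsv"))
        names = [i.name for i in intervals]
        assert len(set(names)) == len(names)
        for i in intervals:
            assert 1 <= i.start <= i.end

    def test_boundary_gap_equal_to_window_included(self, tmp_path):
        # a tiny window makes gap == window draws likely, so the generator
        # plants boundary pairs that the classifier must keep
        c = dataclasses.replace(
            cfg_with(seed=13), genome=sim.GenomeConfig(window=3))
        truth = sim.simulate_genome(c, tmp_path / "l.tsv", tmp_path / "g.tsv")
        exact = [p for p in truth.cis_pairs if p["gap_bp"] == 3]
        assert exact, "expected at least one boundary pair among 8 planted genes"
        lncs = {i.name: i for i in cis_mod.read_interval_tsv(tmp_path / "l.tsv")}
        genes = {i.name: i for i in cis_mod.read_interval_tsv(tmp_path / "g.tsv")}
        for p in exact:
            t = cis_mod.classify_relation(lncs[p["lncrna_name"]],
                                          genes[p["gene_name"]],
                                          cis_mod.CisConfig(3))
            assert t is not None and t.gap_bp == 3

    def test_infeasible_layout_rejected(self, tmp_path):
        tiny = dataclasses.replace(
            cfg_with(), genome=sim.GenomeConfig(
                chrom_sizes=(("chr1", 100_000),), n_lncs=10))
        with pytest.raises(ValidationError):
            sim.simulate_genome(tiny, tmp_path / "l.tsv", tmp_path / "g.tsv")


class TestSequenceGenerator:
    def test_scan_finds_every_planted_consensus(self, tmp_path):
        c = cfg_with(seed=21)
        truth = sim.simulate_sequences_pwms(c, tmp_path / "s.fasta",
                                            tmp_path / "m.txt")
        pwms = enr.parse_pwm_file(tmp_path / "m.txt")
        seqs = enr.read_fasta(tmp_path / "s.fasta")
        hits, _, _ = enr.scan_rbp(pwms, seqs, threshold=0.8)
        found = set(zip(hits["protein_name"], hits["sequence_name"],
                        hits["offset"]))
        for p in truth.motif_placements:
            assert (p["protein_name"], p["sequence_name"], p["offset"]) in found

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        c = cfg_with(seed=6)
        sim.simulate_sequences_pwms(c, tmp_path / "a.fasta", tmp_path / "a.txt")
        sim.simulate_sequences_pwms(c, tmp_path / "b.fasta", tmp_path / "b.txt")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_background_hit_rate_bounded_without_planting(self, tmp_path):
        """With no planted motifs, perfect-score windows appear at roughly
        the (1/4)^width chance level — bounded well above by 3x."""
        width, total_windows, hits = 6, 0, 0
        for seed in range(30):
            c = cfg_with(seed=seed, n_planted_motifs=0, n_pwms=2,
                         pwm_width=width, n_sequences=2, sequence_length=400)
            sim.simulate_sequences_pwms(c, tmp_path / "s.fasta", tmp_path / "m.txt")
            pwms = enr.parse_pwm_file(tmp_path / "m.txt")
            seqs = enr.read_fasta(tmp_path / "s.fasta")
            table, _, _ = enr.scan_rbp(pwms, seqs, threshold=1.0)
            hits += len(table)
            total_windows += sum(len(s) - width + 1 for _, s in seqs) * len(pwms)
        assert hits <= 3 * total_windows * 0.25 ** width + 5

    def test_sequences_shorter_than_motif_rejected(self):
        with pytest.raises(ValidationError):
            cfg_with(sequence_length=5, pwm_width=7)


class TestStreamIndependence:
    def test_sequence_config_does_not_perturb_annotation(self, tmp_path):
        a = cfg_with(seed=9, n_probesets=100)
        b = dataclasses.replace(a, n_pwms=12, n_sequences=9)
        sim.simulate_annotation(a, tmp_path / "a.csv")
        sim.simulate_annotation(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
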