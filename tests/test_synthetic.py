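"""Synthetic-data generators: determinism, planted-truth recovery, fixtures."""

import numpy as np
import pytest

from cotton_mapk import datasets
from cotton_mapk.classify import classify_subfamily
from cotton_mapk.expression import call_induction_table, induction_matrix
from cotton_mapk.synthetic import (
    PlantedEffect,
    SimulationConfig,
    gen_codon_pairs,
    gen_fpkm,
    gen_proteins,
    gen_qpcr,
)


class TestConfigValidation:
    def test_timepoints_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SimulationConfig(seed=1, timepoints=(0.0, 2.0, 1.0))

    def test_replicates_minimum(self):
        with pytest.raises(ValueError, match="replicates"):
            SimulationConfig(seed=1, qpcr_replicates=1)

    def test_protein_length_floor(self):
        with pytest.raises(ValueError, match="protein_length"):
            SimulationConfig(seed=1, protein_length=5)

    def test_codon_spec_overflow(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(seed=1, codon_pair_spec=((10, 8, 5),))


class TestGenProteins:
    def test_counts_per_subfamily(self):
        records, truth = gen_proteins(SimulationConfig(seed=1, n_per_subfamily=5))
        assert len(records) == 15
        labels = list(truth.protein_labels.values())
        assert {labels.count(f) for f in ("MEKK", "Raf", "ZIK")} == {5}

    def test_zero_per_subfamily_is_empty(self):
        records, truth = gen_proteins(SimulationConfig(seed=1, n_per_subfamily=0))
        assert records == [] and truth.protein_labels == {}

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_classifier_recovers_all_planted_labels(self, seed):
        """100% label recovery: the classifier returns the planted subfamily
        and the planted match position for every generated protein."""
        records, truth = gen_proteins(SimulationConfig(seed=seed, n_per_subfamily=4))
        for record in records:
            call = classify_subfamily(record)
            assert call.subfamily == truth.protein_labels[record.id]
            assert call.match_start == truth.protein_positions[record.id]

    def test_determinism(self):
        a, _ = gen_proteins(SimulationConfig(seed=42))
        b, _ = gen_proteins(SimulationConfig(seed=42))
        assert a == b


class TestGenCodonPairs:
    def test_zero_changes_identical_pair(self):
        pairs, _ = gen_codon_pairs(SimulationConfig(seed=1, codon_pair_spec=((100, 0, 0),)))
        assert pairs[0].seq_a == pairs[0].seq_b

    def test_determinism(self):
        spec = ((50, 2, 1), (80, 4, 0))
        a, _ = gen_codon_pairs(SimulationConfig(seed=9, codon_pair_spec=spec))
        b, _ = gen_codon_pairs(SimulationConfig(seed=9, codon_pair_spec=spec))
        assert a == b

    def test_planted_changes_at_distinct_codons(self):
        pairs, truth = gen_codon_pairs(SimulationConfig(seed=3, codon_pair_spec=((60, 5, 3),)))
        pair = pairs[0]
        diff_codons = [
            i
            for i in range(0, len(pair.seq_a), 3)
            if pair.seq_a[i : i + 3] != pair.seq_b[i : i + 3]
        ]
        assert len(diff_codons) == sum(truth.codon_truth[pair.pair_id])
        for i in diff_codons:  # exactly one nucleotide change per hit codon
            assert sum(x != y for x, y in zip(pair.seq_a[i : i + 3], pair.seq_b[i : i + 3])) == 1


class TestGenFpkm:
    def test_shape_and_nonnegative(self):
        m = gen_fpkm(SimulationConfig(seed=1), n_genes=10)
        assert m.shape == (10, 8)
        assert (m.to_numpy() >= 0).all()

    def test_determinism(self):
        a = gen_fpkm(SimulationConfig(seed=5), n_genes=6)
        b = gen_fpkm(SimulationConfig(seed=5), n_genes=6)
        assert a.equals(b)

    def test_rows_zscore_cleanly(self):
        from cotton_mapk.expression import zscore_normalize

        z = zscore_normalize(gen_fpkm(SimulationConfig(seed=2), n_genes=12))
        assert z.degenerate_genes == ()
        assert np.abs(z.values.to_numpy().mean(axis=1)).max() < 1e-12


class TestGenQpcr:
    def test_flat_design_yields_no_inductions(self):
        design = {(f"g{i}", "JA"): PlantedEffect(1.0) for i in range(5)}
        ct = gen_qpcr(design, SimulationConfig(seed=21, qpcr_noise_sd=0.05))
        matrix = induction_matrix(call_induction_table(ct))
        assert matrix.per_treatment_up == {"JA": 0}

    def test_design_matrix_recovered_exactly(self):
        """Fold >= 4 (or <= 0.25) at sd <= 0.1 Ct and n = 3 is always called
        in the planted direction, across a battery of seeds."""
        design = {
            ("up1", "NaCl"): PlantedEffect(4.0, 12.0),
            ("up2", "NaCl"): PlantedEffect(6.0, 8.0),
            ("flat", "NaCl"): PlantedEffect(1.0),
            ("down1", "NaCl"): PlantedEffect(0.25, 12.0),
        }
        for seed in (1, 7, 13, 99):
            ct = gen_qpcr(design, SimulationConfig(seed=seed, qpcr_noise_sd=0.1))
            status = {c.gene: c.status for c in call_induction_table(ct)}
            assert status == {"up1": "up", "up2": "up", "flat": "none", "down1": "down"}

    def test_peak_time_recovered(self):
        for peak in (0.5, 8.0, 24.0):
            ct = gen_qpcr(
                {("g", "JA"): PlantedEffect(8.0, peak)},
                SimulationConfig(seed=4, qpcr_noise_sd=0.05),
            )
            (call,) = call_induction_table(ct)
            assert call.peak_time_h == peak

    def test_mock_arm_present_at_every_timepoint(self):
        config = SimulationConfig(seed=1)
        ct = gen_qpcr({("g", "JA"): PlantedEffect(4.0)}, config)
        mock_times = set(ct[ct["arm"] == "mock"]["time_h"])
        assert mock_times == set(config.timepoints)

    def test_determinism(self):
        design = {("g", "JA"): PlantedEffect(4.0)}
        a = gen_qpcr(design, SimulationConfig(seed=8))
        b = gen_qpcr(design, SimulationConfig(seed=8))
        assert a.equals(b)


class TestFixtures:
    def test_edge_counts(self, y2h_edges, kkk_kk_edges):
        assert len(kkk_kk_edges) == 18
        assert len(y2h_edges) - len(kkk_kk_edges) == 16

    def test_exclusion_set(self, exclusions):
        assert exclusions == {"MKK10_1", "MEKK19", "RAF17_2"}

    def test_induced_gene_counts(self):
        lists = datasets.load_induced_gene_lists()
        counts = {t: len(v.genes) for t, v in lists.items()}
        assert counts["JA"] == 10
        assert counts["H2O2"] == 7
        assert counts["NaCl"] == 11
        assert counts["PEG"] == 4
        assert counts["cold_4C"] == 5
        assert counts["wounding"] == 9
        assert lists["ABA"].ambiguous and lists["SA"].ambiguous

    def test_panel_membership(self):
        panel = datasets.investigated_genes()
        assert len(panel) == 12
        lists = datasets.load_induced_gene_lists()
        for entry in lists.values():
            assert set(entry.genes) <= set(panel)

    def test_checksums_cover_all_files(self):
        sums = datasets.checksums()
        assert set(sums) == {
            "interactions.tsv",
            "induced_genes.json",
            "exclusions.json",
            "response_profiles.json",
        }
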