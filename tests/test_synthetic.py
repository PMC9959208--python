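"""Generator determinism, ground-truth bookkeeping, zero-noise fidelity."""

import random

import pytest

from venomest.annotate import translate
from venomest.catalog import family_templates
from venomest.synthetic import (
    GeneratorConfig,
    generate_library,
    make_toxin_precursor,
    reverse_translate_and_package,
    simulate_peak_lists,
)


class TestMakeToxinPrecursor:
    def test_family_e_has_eight_cys_with_adjacent_pair_and_terminal_g(self):
        rng = random.Random(1)
        gene = make_toxin_precursor("E", rng)
        assert gene.mature_processed.count("C") == 8
        assert "C3C4" in gene.framework
        assert gene.amidated and gene.amid_tail.startswith("G")
        # the raw precursor still carries the amidation glycine
        assert gene.precursor.endswith("G")

    def test_family_i_has_fourteen_cysteines(self):
        gene = make_toxin_precursor("I", random.Random(2))
        assert gene.mature_processed.count("C") == 14

    def test_same_seed_same_sequence(self):
        a = make_toxin_precursor("F", random.Random(42))
        b = make_toxin_precursor("F", random.Random(42))
        assert a == b

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            make_toxin_precursor("Z", random.Random(0))


class TestReverseTranslate:
    def test_round_trip_translation(self):
        cfg = GeneratorConfig()
        gene = make_toxin_precursor("A", random.Random(3))
        cdna = reverse_translate_and_package(gene.precursor, random.Random(4), cfg)
        cds_len = 3 * len(gene.precursor)
        assert translate(cdna[:cds_len]) == gene.precursor
        assert translate(cdna[cds_len : cds_len + 3]) == "*"

    def test_polya_tail_present(self):
        cfg = GeneratorConfig()
        gene = make_toxin_precursor("B", random.Random(5))
        cdna = reverse_translate_and_package(gene.precursor, random.Random(6), cfg)
        assert cdna.endswith("A" * cfg.polya_len[0])

    def test_zero_length_utr(self):
        cfg = GeneratorConfig(utr_len=(0, 0))
        gene = make_toxin_precursor("C", random.Random(7))
        cdna = reverse_translate_and_package(gene.precursor, random.Random(8), cfg)
        cds_stop = 3 * (len(gene.precursor) + 1)
        assert set(cdna[cds_stop:]) == {"A"}


class TestGenerateLibrary:
    def test_determinism(self, small_config, small_library):
        records2, truth2 = generate_library(small_config)
        records1, truth1 = small_library
        assert [(r.id, r.seq) for r in records1] == [(r.id, r.seq) for r in records2]
        assert truth1.equals(truth2)

    def test_one_truth_row_per_est(self, small_library):
        records, truth = small_library
        assert len(truth) == len(records)
        assert set(truth["est_id"]) == {r.id for r in records}

    def test_zero_noise_ests_encode_their_precursor(self, small_library):
        records, truth = small_library
        toxin = truth[truth["category"] == "toxin-like"].set_index("est_id")
        by_id = {r.id: r.seq for r in records}
        checked = 0
        for est_id, row in toxin.iterrows():
            prec_len = 3 * row["mature_end"]
            assert translate(by_id[est_id][:prec_len]).count("*") == 0
            checked += 1
        assert checked > 0

    def test_copy_counts_monotone_in_rank(self, small_library):
        records, truth = small_library
        per_rank = truth[truth["category"] == "toxin-like"].groupby("gene_id").size()
        ordered = per_rank.sort_index().tolist()
        assert ordered == sorted(ordered, reverse=True)

    def test_family_weights_peaked_on_e_dominate(self):
        weights = {f: 0.01 for f in "ABCDFGHIJK"}
        weights["E"] = 1.0 - sum(weights.values())
        cfg = GeneratorConfig(
            n_toxin_genes=20, n_cellular_genes=5, n_random_genes=3,
            n_toxin_ests=120, n_cellular_ests=25, n_random_ests=10,
            family_weights=weights, sub_rate=0.0, trunc_prob=0.0, seed=13,
        )
        _, truth = generate_library(cfg)
        tox = truth[truth["category"] == "toxin-like"]
        biggest_gene = tox.groupby("gene_id").size().idxmax()
        assert tox[tox["gene_id"] == biggest_gene]["family"].iloc[0] == "E"

    def test_empty_library_rejected(self):
        cfg = GeneratorConfig(
            n_toxin_genes=0, n_cellular_genes=0, n_random_genes=0,
            n_toxin_ests=0, n_cellular_ests=0, n_random_ests=0,
        )
        with pytest.raises(ValueError, match="empty library"):
            generate_library(cfg)

    def test_bad_family_weights_rejected(self):
        cfg = GeneratorConfig(family_weights={"E": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            generate_library(cfg)


class TestPeakSimulation:
    def test_peaks_cover_all_species(self, small_library):
        _, truth = small_library
        df = simulate_peak_lists(truth, seed=3)
        n_species = truth[truth["category"] == "toxin-like"]["mature_processed"].nunique()
        assert df["mz"].nunique() <= len(df)
        assert len(df) >= n_species

    def test_seed_determinism(self, small_library):
        _, truth = small_library
        assert simulate_peak_lists(truth, seed=5).equals(simulate_peak_lists(truth, seed=5))
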