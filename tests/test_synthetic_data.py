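import json

import numpy as np
import pytest

from setsig.enrich import contingency_table, odds_ratio, run_ora
from setsig.genesets import GeneSetLibrary, read_gmt
from setsig.synthetic_data import (
    PlantedDesign,
    make_disease_and_test_sets,
    make_histone_libraries,
    make_peaks,
    make_regulator_library,
    make_signature_benchmark,
    make_universe,
    planting_probability,
    simulate_all,
)
from setsig.peakmap import overlap_peaks
from setsig.ues import build_ues


class TestUniverse:
    def test_size_and_uniqueness(self):
        uni = make_universe(20438)
        assert len(uni.genes) == 20438

    def test_deterministic(self):
        assert make_universe(50, seed=1).genes == make_universe(50, seed=1).genes

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            make_universe(0)


class TestPlantingProbability:
    def test_or_one_recovers_baseline(self):
        assert planting_probability(1.0, 0.3) == pytest.approx(0.3)

    def test_odds_multiplied(self):
        q = planting_probability(4.0, 0.2)
        assert (q / (1 - q)) / (0.2 / 0.8) == pytest.approx(4.0)


class TestDiseaseAndTestSets:
    def test_planted_overlap_exact(self, small_design):
        disease, test, truth = make_disease_and_test_sets(small_design)
        assert len(disease) == small_design.disease_set_size
        assert len(test) == small_design.test_set_size
        assert len(disease.genes & test.genes) == small_design.planted_overlap

    def test_design_or_matches_observed_table(self, small_design):
        disease, test, truth = make_disease_and_test_sets(small_design)
        tbl = contingency_table(test, disease, small_design.universe_size)
        assert odds_ratio(tbl) == pytest.approx(truth["design_odds_ratio"])

    def test_no_planting_or_near_one(self):
        # with planted_overlap at the null expectation, observed OR over seeds ~ 1
        ors = []
        for seed in range(30):
            d = PlantedDesign(
                universe_size=2000, disease_set_size=200, test_set_size=300,
                planted_overlap=30, seed=seed,
            )  # 300*200/2000 = 30 = null expectation
            disease, test, _ = make_disease_and_test_sets(d)
            ors.append(odds_ratio(contingency_table(test, disease, 2000)))
        assert float(np.mean(ors)) == pytest.approx(1.0, abs=0.1)

    def test_full_overlap_maximal(self):
        d = PlantedDesign(
            universe_size=500, disease_set_size=50, test_set_size=50,
            planted_overlap=50, seed=0,
        )
        disease, test, _ = make_disease_and_test_sets(d)
        assert disease.genes == test.genes

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            PlantedDesign(universe_size=100, disease_set_size=50,
                          test_set_size=60, planted_overlap=55)

    def test_default_scale_or_recovered_by_ora(self):
        d = PlantedDesign(seed=4)  # defaults: 20438 / 1000 / 5044 / 390
        disease, test, truth = make_disease_and_test_sets(d)
        lib = GeneSetLibrary("L", [disease])
        (res,) = run_ora(test, lib, d.universe_size)
        assert res.odds_ratio == pytest.approx(truth["design_odds_ratio"], rel=0.2)
        assert res.odds_ratio == pytest.approx(2.0, rel=0.2)


class TestRegulatorLibrary:
    def test_deterministic_under_seed(self, small_design):
        lib1, t1 = make_regulator_library(small_design)
        lib2, t2 = make_regulator_library(small_design)
        assert [s.genes for s in lib1] == [s.genes for s in lib2]
        assert t1["planted_regulators"] == t2["planted_regulators"]

    def test_planted_regulators_recovered_in_ues(self, small_design):
        lib, truth = make_regulator_library(small_design)
        disease, _, _ = make_disease_and_test_sets(small_design)
        u = build_ues(disease, lib, small_design.universe_size)
        for reg in truth["planted_regulators"]:
            assert u[reg] > 0.0

    def test_no_planting_gives_mostly_empty_ues(self):
        empties = 0
        for seed in range(20):
            d = PlantedDesign(
                universe_size=2000, disease_set_size=200, test_set_size=300,
                planted_overlap=30, n_regulators=20, targets_per_regulator=100,
                shared_regulators=0, seed=seed,
            )
            lib, _ = make_regulator_library(d)
            disease, _, _ = make_disease_and_test_sets(d)
            if len(build_ues(disease, lib, d.universe_size)) == 0:
                empties += 1
        assert empties >= 18  # >=90% of seeds


class TestHistoneLibraries:
    def test_names_parse_and_truth_mark_present(self, small_design):
        hm1, hm2, truth = make_histone_libraries(small_design, sets_per_mark=2)
        from setsig.epimark import default_mark_tokenizer

        marks = {default_mark_tokenizer(s.name) for s in hm1}
        assert truth["target_mark"].upper() in marks
        assert len(hm1) == len(hm2)

    def test_no_planting_scores_near_zero(self):
        from setsig.epimark import combined_h3k27me3_score, count_mark_enrichment

        d = PlantedDesign(
            universe_size=2000, disease_set_size=200, test_set_size=300,
            planted_overlap=30, planting_or=1.0, seed=3,
        )
        hm1, hm2, _ = make_histone_libraries(d, sets_per_mark=3, genes_per_set=80)
        disease, _, _ = make_disease_and_test_sets(d)
        s1 = count_mark_enrichment(disease, hm1, d.universe_size)
        s2 = count_mark_enrichment(disease, hm2, d.universe_size)
        assert combined_h3k27me3_score(s1, s2) <= 0.25


class TestPeaks:
    def test_full_colocalization(self, small_design):
        d = PlantedDesign(**{**small_design.to_dict(), "colocalization_fraction": 1.0})
        a, b, _, _ = make_peaks(d, n_peaks=200, n_genes=1500)
        assert overlap_peaks(a, b).fraction_overlapping == 1.0

    def test_zero_colocalization(self, small_design):
        d = PlantedDesign(**{**small_design.to_dict(), "colocalization_fraction": 0.0})
        a, b, _, _ = make_peaks(d, n_peaks=200, n_genes=1500)
        assert overlap_peaks(a, b).fraction_overlapping < 0.02

    def test_fraction_matches_truth(self, small_design):
        a, b, _, truth = make_peaks(small_design, n_peaks=400, n_genes=2000)
        assert overlap_peaks(a, b).fraction_overlapping == pytest.approx(
            truth["colocalization_fraction"]
        )

    def test_infeasible_packing_rejected(self, small_design):
        with pytest.raises(ValueError):
            make_peaks(small_design, genome_length=10_000, n_peaks=50, n_genes=50)


class TestSimulateAll:
    def test_writes_fixtures_and_manifest(self, tmp_path, small_design):
        manifest = simulate_all(small_design, tmp_path / "fix")
        out = tmp_path / "fix"
        for fname in (
            "disease_genes.txt", "test_genes.txt", "regulators.gmt",
            "encode_hm.gmt", "roadmap_hm.gmt", "factor_a.bed", "factor_b.bed",
            "genes.bed", "trajectory.csv", "arena.yaml", "ground_truth.json",
        ):
            assert (out / fname).exists(), fname
        on_disk = json.loads((out / "ground_truth.json").read_text())
        assert on_disk["design"]["seed"] == small_design.seed
        lib = read_gmt(out / "regulators.gmt")
        assert len(lib) == small_design.n_regulators


class TestSignatureBenchmark:
    def test_structure_and_determinism(self):
        d = PlantedDesign(
            universe_size=3000, disease_set_size=300, test_set_size=300,
            planted_overlap=50, n_regulators=20, targets_per_regulator=100,
            shared_regulators=3, seed=5,
        )
        b1 = make_signature_benchmark(d, n_decoys=8, set_size=150)
        b2 = make_signature_benchmark(d, n_decoys=8, set_size=150)
        assert b1["sibling"].genes == b2["sibling"].genes
        assert len(b1["decoys"]) == 8
        assert len(b1["truth"]["planted_regulators"]) == 3
        # decoy groups avoid the planted regulators
        planted = set(b1["truth"]["planted_regulators"])
        for group in b1["truth"]["decoy_groups"].values():
            assert planted.isdisjoint(group)
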