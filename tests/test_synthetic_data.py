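"""Determinism, distributional fidelity and parameter recovery of the
synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from ralascope.burden_stats import binom_upper_tail
from ralascope.regional_constraint import build_depletion_table
from ralascope.structure_contacts import RegionAnnotation, contact_residues, read_structure
from ralascope.synthetic_data import (
    SimulationConfig,
    default_region,
    simulate_assay,
    simulate_cohort,
    simulate_population_variants,
    simulate_structure,
)


class TestDeterminism:
    def test_structure_bytes_identical_across_reruns(self, tmp_path):
        cfg = SimulationConfig(seed=123)
        p1, _ = simulate_structure(cfg, 8, {2, 5}, 2.0, tmp_path / "a.pdb")
        p2, _ = simulate_structure(cfg, 8, {2, 5}, 2.0, tmp_path / "b.pdb")
        assert p1.read_bytes() == p2.read_bytes()

    def test_cohort_reproducible(self):
        cfg = SimulationConfig(seed=9, n_probands=5000, denovo_rate=1e-3)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert c1.variants == c2.variants

    def test_population_reproducible_and_seed_sensitive(self):
        a = simulate_population_variants(SimulationConfig(seed=1, depletion_factor=1.0))
        b = simulate_population_variants(SimulationConfig(seed=1, depletion_factor=1.0))
        c = simulate_population_variants(SimulationConfig(seed=2, depletion_factor=1.0))
        assert a == b
        assert a != c

    def test_assay_reproducible(self):
        cfg = SimulationConfig(seed=4)
        w1 = simulate_assay(cfg).wells
        w2 = simulate_assay(cfg).wells
        assert w1 == w2


class TestCohortGenerator:
    def test_zero_rate_means_zero_variants(self):
        cfg = SimulationConfig(seed=0, n_probands=10_000, denovo_rate=0.0)
        assert simulate_cohort(cfg).variants == []

    def test_mean_count_matches_null_expectation(self):
        """Across replicates the mean simulated count sits within 3 SE of
        2 * N * rate (study scale: 0.198)."""
        n_reps, n, rate = 3000, 16_086, 6.16e-6
        counts = [
            len(simulate_cohort(
                SimulationConfig(seed=s, n_probands=n, denovo_rate=rate)
            ).variants)
            for s in range(n_reps)
        ]
        expected = 2 * n * rate
        se = np.sqrt(expected / n_reps)  # binomial var ~ mean at this rate
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_counts_fit_binomial_null(self):
        """Chi-square goodness of fit of simulated counts vs
        Binomial(2N, rate), seeded."""
        n_reps, n, rate = 4000, 2000, 5e-5
        counts = np.array([
            len(simulate_cohort(
                SimulationConfig(seed=s, n_probands=n, denovo_rate=rate)
            ).variants)
            for s in range(n_reps)
        ])
        kmax = 4
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.binom.pmf(np.arange(kmax), 2 * n, rate)
        probs = np.append(pmf, 1 - pmf.sum())
        chi = stats.chisquare(observed, n_reps * probs)
        assert chi.pvalue > 0.01

    def test_hotspot_concentration(self):
        cfg = SimulationConfig(seed=2, n_probands=50_000, denovo_rate=1e-3,
                               hotspot_codons=(25, 128), hotspot_prob=0.6)
        cohort = simulate_cohort(cfg)
        at_hotspots = sum(
            1 for v in cohort.variants if v.codon_index in (25, 128))
        assert at_hotspots / len(cohort.variants) > 0.4

    def test_monozygotic_injection(self):
        from ralascope.cohort_io import collapse_families

        cfg = SimulationConfig(seed=3, n_probands=20_000, denovo_rate=1e-3,
                               n_monozygotic_sets=2)
        cohort = simulate_cohort(cfg)
        families = collapse_families(cohort)
        assert len(cohort.probands) == len(families) + 2


class TestPopulationGenerator:
    def test_absolute_depletion_avoids_region(self):
        cfg = SimulationConfig(seed=6, depletion_factor=0.0)
        region = default_region(cfg)
        assert simulate_population_variants(cfg) & region == set()

    def test_saturated_uniform_covers_protein(self):
        cfg = SimulationConfig(seed=6, depletion_factor=1.0,
                               n_population_variant_residues=206)
        assert simulate_population_variants(cfg) == set(range(1, 207))

    def test_depleted_simulations_mostly_reject(self):
        """With absolute depletion at in-study-sized counts the Fisher
        pipeline rejects in the majority of replicates."""
        rejections = 0
        n_reps = 200
        for s in range(n_reps):
            cfg = SimulationConfig(seed=s, depletion_factor=0.0)
            region = RegionAnnotation(cfg.protein_length,
                                      frozenset(default_region(cfg)))
            table = build_depletion_table(region, simulate_population_variants(cfg))
            rejections += table.p_fisher_two_sided < 0.05
        assert rejections / n_reps > 0.5

    def test_uniform_null_is_calibrated(self):
        """With factor 1 (no depletion) the two-sided rejection rate at
        alpha = 0.05 stays at or below alpha."""
        rejections = 0
        n_reps = 2000
        for s in range(n_reps):
            cfg = SimulationConfig(seed=s, depletion_factor=1.0)
            region = RegionAnnotation(cfg.protein_length,
                                      frozenset(default_region(cfg)))
            table = build_depletion_table(region, simulate_population_variants(cfg))
            rejections += table.p_fisher_two_sided < 0.05
        # allow 2 SE of Monte Carlo noise above the conservative bound
        assert rejections / n_reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_reps)


class TestStructureGenerator:
    def test_declared_contacts_recovered_exactly(self, tmp_path):
        cfg = SimulationConfig(seed=8)
        path, truth = simulate_structure(cfg, 15, {1, 8, 15}, 2.5,
                                         tmp_path / "s.pdb")
        model = read_structure(path)
        region = contact_residues(model, "GDP", 2.5, protein_length=15)
        assert set(region.residues) == set(truth)

    def test_empty_declared_set(self, tmp_path):
        from ralascope.structure_contacts import LigandAbsentError

        cfg = SimulationConfig(seed=8)
        path, truth = simulate_structure(cfg, 5, set(), 2.0, tmp_path / "s.pdb")
        assert truth == frozenset()
        model = read_structure(path)
        with pytest.raises(LigandAbsentError):
            contact_residues(model, "GDP", 2.0)

    def test_infeasible_geometry_rejected(self, tmp_path):
        cfg = SimulationConfig(seed=8)
        with pytest.raises(ValueError, match="overlap"):
            simulate_structure(cfg, 5, {2}, 0.9, tmp_path / "s.pdb")

    def test_spacing_must_exceed_threshold(self, tmp_path):
        cfg = SimulationConfig(seed=8, residue_spacing=1.5)
        with pytest.raises(ValueError, match="spacing"):
            simulate_structure(cfg, 5, {2}, 2.0, tmp_path / "s.pdb")


class TestAssayGenerator:
    def test_zero_sd_gives_exact_means(self):
        cfg = SimulationConfig(
            seed=0, gtpase_groups={"NTC": (100.0, 0.0), "WT": (20.0, 0.0)})
        plate = simulate_assay(cfg)
        for w in plate.wells:
            assert w.signal == {"NTC": 100.0, "WT": 20.0}[w.construct]

    def test_separated_groups_strongly_significant(self):
        from ralascope.assay_norm import compare_groups, normalize_gtpase, significance_tier

        cfg = SimulationConfig(
            seed=1,
            gtpase_groups={"NTC": (100.0, 1.0), "WT": (20.0, 1.0),
                           "MUT": (95.0, 1.0)})
        rows = compare_groups(normalize_gtpase(simulate_assay(cfg)), "WT")
        mut = next(r for r in rows if r["construct"] == "MUT")
        assert mut["p"] < 0.001
        assert mut["tier"] == significance_tier(mut["p"])
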