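"""Generator contracts: degenerate-noise exactness, determinism, cohort
frequencies and genotype simulation."""

import numpy as np
import pytest

from ycnv import defaults, synthetic
from ycnv.synthetic import (
    CNVEvent,
    CohortConfig,
    IntensityModel,
    default_cohort_config,
    events_for_signature,
    simulate_cohort,
    simulate_genotypes,
    simulate_sample,
)


class TestSimulateSample:
    def test_zero_noise_male_is_flat_at_one_copy_mean(self, manifest):
        model = IntensityModel(sigma=0.0)
        profile = simulate_sample(manifest, model, "male", (), seed=0)
        assert np.allclose(profile, model.mu_one_copy)

    def test_zero_noise_duplication_lifts_exactly_its_probes(self, manifest):
        model = IntensityModel(sigma=0.0)
        start, stop = int(manifest.positions[10]), int(manifest.positions[30])
        ev = CNVEvent("duplication", start, stop)
        profile = simulate_sample(manifest, model, "male", [ev], seed=0)
        assert np.allclose(profile[10:31], model.mu_two_copy)
        assert np.allclose(profile[:10], model.mu_one_copy)
        assert np.allclose(profile[31:], model.mu_one_copy)

    def test_female_background_with_hot_regions(self, manifest):
        model = IntensityModel(sigma=0.0)
        profile = simulate_sample(manifest, model, "female", (), seed=0)
        hot = np.zeros(len(manifest), dtype=bool)
        for lo, hi in model.background_hot_regions:
            hot |= (manifest.positions >= lo) & (manifest.positions <= hi)
        assert hot.any()
        assert np.allclose(profile[hot], model.hot_mean)
        assert np.allclose(profile[~hot], model.mu_zero_copy)

    def test_event_outside_span_rejected(self, manifest):
        ev = CNVEvent("deletion", 1, 1000)
        with pytest.raises(ValueError, match="span"):
            simulate_sample(manifest, IntensityModel(), "male", [ev], seed=0)

    def test_same_seed_identical_output(self, manifest):
        a = simulate_sample(manifest, IntensityModel(), "male", (), seed=7)
        b = simulate_sample(manifest, IntensityModel(), "male", (), seed=7)
        assert np.array_equal(a, b)

    def test_male_mean_calibrated(self, manifest_real):
        """Mean of a default male profile sits within Monte-Carlo error of
        the one-copy anchor (-0.47)."""
        model = IntensityModel()
        profile = simulate_sample(manifest_real, model, "male", (), seed=11)
        se = model.sigma / np.sqrt(len(manifest_real))
        assert abs(profile.mean() - model.mu_one_copy) < 3 * se


class TestEventsForSignature:
    def test_single_region_signature_covers_exactly_its_probes(
        self, manifest, annotation, catalog, regions
    ):
        sig = next(s for s in catalog if s.name == "P6 dupl")
        (ev,) = events_for_signature(sig, annotation, manifest)
        idx = annotation.probes_in("P6")
        assert ev.kind == "duplication"
        assert ev.start == manifest.positions[idx[0]]
        assert ev.stop == manifest.positions[idx[-1]]

    def test_mixed_signature_produces_both_kinds(
        self, manifest, annotation, catalog
    ):
        sig = next(s for s in catalog if s.name == "blue-grey like dupl")
        events = events_for_signature(sig, annotation, manifest)
        kinds = {e.kind for e in events}
        assert kinds == {"deletion", "duplication"}

    def test_jitter_stays_within_bounds_and_no_overlap(
        self, manifest, annotation, catalog, rng
    ):
        sig = next(s for s in catalog if s.name == "blue-grey like dupl")
        for _ in range(20):
            events = sorted(
                events_for_signature(
                    sig, annotation, manifest, jitter_probes=2, rng=rng
                ),
                key=lambda e: e.start,
            )
            for a, b in zip(events, events[1:]):
                assert a.stop < b.start


class TestSimulateGenotypes:
    def test_root_is_all_ancestral(self, tree):
        g = simulate_genotypes(tree, "Root")
        assert all(g[s] == tree.snp_alleles[s][0] for s in g)

    def test_derived_exactly_on_root_path(self, tree):
        g = simulate_genotypes(tree, "E-M96")
        path = {n.name for n in tree.path_to_root("E-M96")}
        for snp, allele in g.items():
            anc, der = tree.snp_alleles[snp]
            expected = der if tree.snp_to_node[snp].name in path else anc
            assert allele == expected

    def test_internal_target_leaves_child_snps_ancestral(self, tree):
        g = simulate_genotypes(tree, "NO-M214")
        anc, _der = tree.snp_alleles["M175"]
        assert g["M175"] == anc

    def test_unknown_node_rejected(self, tree):
        with pytest.raises(ValueError, match="nope"):
            simulate_genotypes(tree, "nope")

    def test_missing_rate_masks_calls(self, tree, rng):
        g = simulate_genotypes(tree, "R-M207", missing_rate=0.5, rng=rng)
        n_missing = sum(1 for v in g.values() if v == ".")
        assert 0 < n_missing < len(g)


class TestSimulateCohort:
    def test_pattern_probability_one_marks_every_truth(self):
        cfg = CohortConfig(
            haplogroup_counts={"NO-M214(xM175)": 40},
            pattern_probs={"NO-M214(xM175)": {"b2/b3 del (c35)": 1.0}},
            n_females=0,
        )
        cohort = simulate_cohort(cfg, seed=1, intensities=False)
        assert (cohort.truth["patterns"] == "b2/b3 del (c35)").all()

    def test_probabilities_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(
                haplogroup_counts={"R-M207": 5},
                pattern_probs={"R-M207": {"P6 dupl": 0.7, "P5 dupl": 0.6}},
            )

    def test_same_seed_bit_identical_truth(self):
        cfg = default_cohort_config(scale=0.05)
        a = simulate_cohort(cfg, seed=9, intensities=False)
        b = simulate_cohort(cfg, seed=9, intensities=False)
        assert a.truth.equals(b.truth)
        assert a.genotypes.equals(b.genotypes)

    def test_b2b3_frequency_matches_reference_rate(self):
        """Empirical b2/b3-del fraction in a large simulated NO-M214(xM175)
        cohort stays within binomial 99% bounds of the 27/40 reference."""
        p0 = 27 / 40
        n = 4000
        cfg = default_cohort_config()
        cfg = CohortConfig(
            haplogroup_counts={"NO-M214(xM175)": n},
            pattern_probs={
                "NO-M214(xM175)": cfg.pattern_probs["NO-M214(xM175)"]
            },
            n_females=0,
        )
        cohort = simulate_cohort(cfg, seed=13, intensities=False)
        k = (
            cohort.truth["patterns"].str.contains("b2/b3 del", regex=False).sum()
        )
        half = 2.576 * np.sqrt(p0 * (1 - p0) / n)
        assert abs(k / n - p0) < half

    def test_default_config_matches_reference_cohort_totals(self):
        cfg = default_cohort_config(scale=1.0)
        t2 = defaults.load_table2_counts()
        assert sum(cfg.haplogroup_counts.values()) == int(t2["n"].sum())
        expected_carriers = sum(
            cfg.haplogroup_counts[hg] * sum(probs.values())
            for hg, probs in cfg.pattern_probs.items()
        )
        assert expected_carriers == pytest.approx(int(t2["carriers"].sum()), abs=1e-6)
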