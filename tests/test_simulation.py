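import numpy as np
import pytest
from scipy.stats import binom

from getmap.fragment_partition import aggregate_methylation
from getmap.reference_panel import CpGSite, select_informative_cpgs
from getmap.simulation import (
    ScenarioConfig,
    build_panel_and_mask,
    mix_and_recover,
    run_accuracy_experiment,
    sample_fragments,
    synthesize_reference_panel,
)


class TestSynthesizeReferencePanel:
    def test_same_seed_identical_panels(self):
        a = synthesize_reference_panel(n_sites=300, seed=5)
        b = synthesize_reference_panel(n_sites=300, seed=5)
        assert [m.tissue for m in a] == [m.tissue for m in b]
        for ma, mb in zip(a, b):
            assert ma.sites == mb.sites

    def test_different_seed_differs(self):
        a = synthesize_reference_panel(n_sites=300, seed=5)
        b = synthesize_reference_panel(n_sites=300, seed=6)
        assert any(ma.sites != mb.sites for ma, mb in zip(a, b))

    def test_all_marker_sites_pass_selection_when_fraction_is_one(self):
        methylomes = synthesize_reference_panel(
            n_sites=400, marker_fraction=1.0, seed=3
        )
        selected = select_informative_cpgs(methylomes)
        assert len(selected) == 400

    def test_selected_count_tracks_marker_fraction(self):
        methylomes = synthesize_reference_panel(
            n_sites=20_000, marker_fraction=0.2, seed=11
        )
        selected = select_informative_cpgs(methylomes)
        assert 0.95 * 4000 <= len(selected) <= 1.05 * 4000

    def test_invalid_marker_fraction(self):
        with pytest.raises(ValueError, match="marker_fraction"):
            synthesize_reference_panel(n_sites=10, marker_fraction=0.0)


class TestSampleFragments:
    def setup_method(self):
        self.sites = [CpGSite("chr1", 100 + 2 * i) for i in range(50)]

    def test_extreme_densities_give_deterministic_states(self):
        ones = {s: 1.0 for s in self.sites}
        zeros = {s: 0.0 for s in self.sites}
        for density_map, expected in ((ones, True), (zeros, False)):
            frags = sample_fragments(density_map, 200, seed=1)
            states = [o.methylated for f in frags for o in f.cpg_observations]
            assert states and all(s is expected for s in states)

    def test_half_density_within_binomial_interval(self):
        density_map = {s: 0.5 for s in self.sites}
        frags = sample_fragments(density_map, 5_000, seed=2)
        states = [o.methylated for f in frags for o in f.cpg_observations]
        n = len(states)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= sum(states) <= hi

    def test_deterministic_under_seed(self):
        density_map = {s: 0.3 for s in self.sites}
        a = sample_fragments(density_map, 100, seed=9)
        b = sample_fragments(density_map, 100, seed=9)
        assert a == b

    def test_fragment_cpg_counts_bounded(self):
        density_map = {s: 0.5 for s in self.sites}
        frags = sample_fragments(density_map, 500, mean_cpgs=2.0, max_cpgs=4, seed=3)
        counts = [len(f.cpg_observations) for f in frags]
        assert min(counts) >= 1 and max(counts) <= 4

    def test_mixture_uses_only_listed_sites(self):
        methylomes = synthesize_reference_panel(n_sites=100, seed=4)
        subset = sorted(methylomes[0].sites)[:20]
        frags = sample_fragments(
            (np.full(5, 0.2), methylomes), 300, sites=subset, seed=5
        )
        seen = {o.site for f in frags for o in f.cpg_observations}
        assert seen <= set(subset)

    def test_invalid_mixture_proportions(self):
        methylomes = synthesize_reference_panel(n_sites=20, seed=4)
        with pytest.raises(ValueError, match="simplex"):
            sample_fragments(([0.5, 0.6, 0.1, 0.1, 0.1], methylomes), 10)

    def test_empty_site_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sample_fragments({}, 10)


@pytest.fixture(scope="module")
def table():
    methylomes, mask = build_panel_and_mask(
        n_sites=2_000, marker_fraction=0.3, seed=7
    )
    config = ScenarioConfig(
        name="mini", n_fragments=2_000, n_cpg_sites=600,
        n_replicates=4, seed=7,
    )
    return run_accuracy_experiment(methylomes, mask, config)


class TestAccuracyExperiment:
    def test_mean_rows_sum_to_100(self, table):
        # medians are not linear, so only the mean table carries the
        # exact row-sum constraint inherited from the QP
        np.testing.assert_allclose(table.mean_percent.sum(axis=1), 100.0, atol=0.1)

    def test_diagonal_dominates(self, table):
        diag = table.diagonal("mean")
        assert diag.min() > 90.0

    def test_replicate_frame_is_complete(self, table):
        assert len(table.replicates) == 5 * 4 * 5  # tissues x reps x entries

    def test_deterministic(self, table):
        methylomes, mask = build_panel_and_mask(
            n_sites=2_000, marker_fraction=0.3, seed=7
        )
        config = ScenarioConfig(
            name="mini", n_fragments=2_000, n_cpg_sites=600,
            n_replicates=4, seed=7,
        )
        again = run_accuracy_experiment(methylomes, mask, config)
        np.testing.assert_array_equal(again.mean_percent, table.mean_percent)

    def test_noise_free_densities_give_perfect_accuracy(self, small_panel):
        # bypass sampling: feed each tissue's exact densities as the vector
        from getmap.deconvolution import deconvolve
        from getmap.fragment_partition import MethylationVector
        from getmap.reference_panel import build_reference_matrix

        methylomes, mask = small_panel
        panel = build_reference_matrix(methylomes, mask, mask)
        denom = 10**9
        for k in range(len(methylomes)):
            vec = MethylationVector(
                "pure", list(panel.sites),
                np.round(panel.matrix[:, k] * denom).astype(np.int64),
                np.full(panel.n_sites, denom, dtype=np.int64),
            )
            contrib = deconvolve(vec, panel)
            assert contrib.percent[k] == pytest.approx(100.0, abs=1e-4)


class TestMixAndRecover:
    def test_pure_vertex_reduces_to_self_deconvolution(self, small_panel):
        methylomes, mask = small_panel
        config = ScenarioConfig(
            name="mini", n_fragments=3_000, n_cpg_sites=600, seed=3
        )
        contrib, err = mix_and_recover(
            [0, 0, 0, 0, 1.0], methylomes, mask, config
        )
        assert contrib.percent[-1] > 95.0
        assert err[-1] == pytest.approx(1 - contrib.proportions[-1])

    def test_uniform_mixture_recovered(self, small_panel):
        methylomes, mask = small_panel
        config = ScenarioConfig(
            name="mini", n_fragments=20_000, n_cpg_sites=600, seed=5
        )
        contrib, err = mix_and_recover(
            np.full(5, 0.2), methylomes, mask, config
        )
        assert err.max() < 0.02

    def test_error_shrinks_with_more_fragments(self, small_panel):
        methylomes, mask = small_panel
        errors = []
        for n in (300, 30_000):
            per_seed = []
            for seed in range(3):
                config = ScenarioConfig(
                    name="mini", n_fragments=n, n_cpg_sites=600, seed=seed
                )
                _, err = mix_and_recover(
                    np.full(5, 0.2), methylomes, mask, config
                )
                per_seed.append(err.mean())
            errors.append(np.mean(per_seed))
        assert errors[1] < errors[0]

    def test_off_simplex_proportions_rejected(self, small_panel):
        methylomes, mask = small_panel
        config = ScenarioConfig(name="x", n_fragments=10, n_cpg_sites=10)
        with pytest.raises(ValueError, match="simplex"):
            mix_and_recover([0.5, 0.5, 0.5, 0, 0], methylomes, mask, config)


class TestScenarioConfig:
    def test_preset_scaling(self):
        full = ScenarioConfig.preset("cancer")
        scaled = ScenarioConfig.preset("cancer", scale_down=10)
        assert scaled.n_fragments == full.n_fragments // 10
        assert scaled.n_cpg_sites == full.n_cpg_sites // 10

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioConfig.preset("metagenomics")

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ScenarioConfig(name="x", n_fragments=0, n_cpg_sites=5)
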