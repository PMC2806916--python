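import numpy as np
import pandas as pd
import pytest

from seepscape import (
    CoreScenario,
    DepthGrid,
    RateProfile,
    TransportSystem,
    ValidationError,
    chao1,
    concordance_check,
    make_community,
    make_concentration_profile,
    make_otu_abundances,
    make_rate_profile,
    simulate_transect,
    solve_forward,
)


@pytest.fixture
def grid():
    return DepthGrid.uniform(20.0, 0.1)


class TestRateGenerator:
    def test_zero_amplitude_all_zero(self, grid):
        scn = CoreScenario("mat", rate_amplitude=0.0)
        assert not make_rate_profile(scn, grid).rate.any()

    def test_exponential_shape(self, grid):
        scn = CoreScenario("mat", rate_amplitude=500.0, decay_length_cm=2.0)
        r = make_rate_profile(scn, grid).rate
        assert r[0] == 500.0
        at_lambda = r[np.searchsorted(grid.x, 2.0)]
        assert at_lambda / 500.0 == pytest.approx(np.e**-1, rel=1e-9)

    def test_outside_scenario_scaled_down(self, grid):
        inside = make_rate_profile(CoreScenario("mat"), grid).rate
        outside = make_rate_profile(CoreScenario("outside"), grid).rate
        np.testing.assert_allclose(outside, 0.1 * inside)


class TestConcentrationGenerator:
    def test_noise_free_matches_forward_solution(self, grid):
        scn = CoreScenario("mat", noise_fraction=0.0)
        sys = TransportSystem(grid)
        rates = make_rate_profile(CoreScenario("mat", rate_amplitude=100.0), grid)
        prof = make_concentration_profile(scn, sys, rates)
        np.testing.assert_array_equal(prof.concentration, solve_forward(sys, rates).concentration)

    def test_same_seed_identical_different_seed_not(self, grid):
        sys = TransportSystem(grid)
        rates = make_rate_profile(CoreScenario("mat", rate_amplitude=100.0), grid)
        a = make_concentration_profile(CoreScenario("mat", seed=5), sys, rates)
        b = make_concentration_profile(CoreScenario("mat", seed=5), sys, rates)
        c = make_concentration_profile(CoreScenario("mat", seed=6), sys, rates)
        np.testing.assert_array_equal(a.concentration, b.concentration)
        assert not np.array_equal(a.concentration, c.concentration)

    def test_noise_level_matches_stated_precision(self):
        """Sample sd of C_noisy/C_true at 3% noise lies in [0.027, 0.033] over 1000 depths."""
        grid = DepthGrid.uniform(100.0, 0.1)  # 1001 depths
        sys = TransportSystem(grid)
        rates = RateProfile(grid, np.zeros(len(grid)))  # C_true = 28 everywhere
        prof = make_concentration_profile(CoreScenario("mat", seed=17, noise_fraction=0.03), sys, rates)
        ratio = prof.concentration / 28.0
        assert 0.027 <= ratio.std(ddof=1) <= 0.033

    def test_truncation_keeps_zero_at_zero(self, grid):
        sys = TransportSystem(grid, overlying_concentration=0.0)
        rates = RateProfile(grid, np.zeros(len(grid)))
        prof = make_concentration_profile(CoreScenario("mat", seed=1), sys, rates)
        assert np.all(prof.concentration == 0.0)


class TestCommunityGenerator:
    def test_degenerate_profile_puts_every_clone_in_one_group(self):
        counts, _ = make_community(CoreScenario("mat", seed=3), 60, {"Eel-2": 1.0})
        assert counts["taxon_id"].tolist() == ["Eel-2"]
        assert counts["count"].sum() == 60

    def test_mean_srb_fraction_tracks_design(self):
        """n=60 clones at SRB fraction 0.5: mean pct within 50 +/- 3 over 200 draws."""
        profile = {"Eel-2": 0.5, "Chloroflexi": 0.5}
        scn = CoreScenario("mat")
        pcts = []
        for s in range(200):
            counts, _ = make_community(scn, 60, profile, seed=s)
            srb = counts.loc[counts["taxon_id"] == "Eel-2", "count"].sum()
            pcts.append(100.0 * srb / counts["count"].sum())
        assert abs(np.mean(pcts) - 50.0) < 3.0

    def test_same_seed_identical_table(self):
        profile = {"Eel-2": 0.6, "ANME-2a": 0.4}
        a, _ = make_community(CoreScenario("edge"), 50, profile, seed=9)
        b, _ = make_community(CoreScenario("edge"), 50, profile, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            make_community(CoreScenario("mat"), 10, {"Eel-2": 0.5, "ANME-2a": 0.4})

    def test_exact_mode_is_largest_remainder(self):
        counts, _ = make_community(CoreScenario("mat"), 60,
                                   {"Eel-2": 0.4, "SEEP-SRB1": 0.35, "Chloroflexi": 0.25},
                                   exact=True)
        assert dict(zip(counts["taxon_id"], counts["count"])) == {
            "Eel-2": 24, "SEEP-SRB1": 21, "Chloroflexi": 15}


class TestOtuAbundances:
    def test_exhaustive_sampling_recovers_richness(self):
        """Uniform pool sampled at 100x richness sees every OTU (coupon collector)."""
        for seed in range(100):
            sizes = make_otu_abundances(8, "uniform", sample_size=800, seed=seed)
            assert len(sizes) == 8

    def test_single_draw(self):
        sizes = make_otu_abundances(10, "uniform", sample_size=1, seed=0)
        assert sizes == [1]
        est = chao1(sizes)
        assert est.S_obs == est.n1 == 1

    def test_chao1_on_outputs_never_below_observed(self):
        for seed in range(50):
            sizes = make_otu_abundances(30, "log_series", sample_size=60, seed=seed)
            est = chao1(sizes)
            assert est.S_chao1 >= est.S_obs


class TestTransect:
    def test_deterministic_given_seed(self):
        a = simulate_transect(seed=4, noise_fraction=0.03)
        b = simulate_transect(seed=4, noise_fraction=0.03)
        np.testing.assert_array_equal(a.cores["mat"].sulfate.concentration,
                                      b.cores["mat"].sulfate.concentration)
        assert [r.pct_SRB_clones for r in a.rows] == [r.pct_SRB_clones for r in b.rows]

    def test_qualitative_architecture(self):
        """Sub-mat sulfate depletes near-surface, the outside core does not;
        flux magnitude and SRB fraction collapse together outside the mat."""
        t = simulate_transect(seed=0)
        mat, outside = t.cores["mat"], t.cores["outside"]
        assert mat.sulfate.concentration[np.searchsorted(mat.sulfate.grid.x, 8.0)] < 3.0
        assert outside.sulfate.concentration.min() > 20.0
        surface = {r.sample_id: r for r in t.rows if r.layer == "surface"}
        assert surface["mat"].abs_sulfate_flux > surface["edge"].abs_sulfate_flux \
            > surface["outside"].abs_sulfate_flux
        assert surface["mat"].pct_SRB_clones > surface["edge"].pct_SRB_clones \
            > surface["outside"].pct_SRB_clones
        assert surface["outside"].dsrAB_present == 0 and surface["mat"].dsrAB_present == 100
        deep = [r for r in t.rows if r.layer == "deep"]
        spread = max(r.pct_SRB_clones for r in deep) - min(r.pct_SRB_clones for r in deep)
        assert spread < 1e-9  # deep communities converge

    def test_noise_free_transect_concordance_is_perfect(self):
        t = simulate_transect(seed=0, noise_fraction=0.0)
        res = {(r.layer, r.pairing): r for r in concordance_check(t.rows)}
        sulf = res[("surface", "abs_sulfate_flux ~ pct_SRB_clones")]
        meth = res[("surface", "methane_flux_x10 ~ pct_ANME_clones")]
        assert sulf.concordant_fraction == 1.0
        assert meth.concordant_fraction == 1.0

    def test_deep_methane_under_mat_is_saturation_censored(self):
        t = simulate_transect(seed=0)
        deep = {r.sample_id: r for r in t.rows if r.layer == "deep"}
        assert deep["mat"].methane_flux_x10 is None
        assert deep["edge"].methane_flux_x10 is None
        assert deep["outside"].methane_flux_x10 is not None
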