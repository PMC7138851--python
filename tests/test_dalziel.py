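"""Blank correction, MM fits, linearizations, Dalziel fit and comparisons."""

import numpy as np
import pandas as pd
import pytest

from grxtools.kinetics import PingPongParameters, dalziel_rate
from grxtools.dalziel import (
    RateGrid, blank_correct, MichaelisMentenModel, fit_apparent_mm,
    linearize, DalzielModel, fit_dalziel, compare_variants,
)
from grxtools.synth import (
    load_variant, generate_rate_grid, NoiseModel,
    DEFAULT_GSH_LEVELS, DEFAULT_GSSCYS_LEVELS,
)

E0 = 10e-9


def make_grid(rates_fn, gssr=DEFAULT_GSSCYS_LEVELS, gsh=DEFAULT_GSH_LEVELS,
              enzyme0=E0, **kw):
    rows = [
        {"gssr_M": a, "gsh_M": b, "enzyme_M": enzyme0,
         "rate_M_per_s": rates_fn(a, b), "replicate": 0}
        for a in gssr for b in gsh
    ]
    return RateGrid(pd.DataFrame(rows), **kw)


@pytest.fixture(scope="module")
def pingpong_grid():
    params = PingPongParameters(phi0=0.02, phi1=1.0 / 2e5, phi2=1.0 / 5e4)
    grid = make_grid(lambda a, b: dalziel_rate(params, E0, a, b))
    return params, grid


class TestBlankCorrect:
    def test_zero_reference_is_identity(self, pingpong_grid):
        _, grid = pingpong_grid
        ref = RateGrid(grid.data.assign(rate_M_per_s=0.0))
        out = blank_correct(grid, ref)
        assert np.allclose(out.data["rate_M_per_s"], grid.data["rate_M_per_s"])
        assert not out.data["clipped"].any()

    def test_equal_reference_gives_flagged_zeros(self, pingpong_grid):
        _, grid = pingpong_grid
        out = blank_correct(grid, grid)
        assert np.all(out.data["rate_M_per_s"] == 0.0)
        assert out.data["clipped"].all()

    def test_simple_subtraction(self):
        raw = make_grid(lambda a, b: 1e-7, gssr=[1e-4] * 1,
                        gsh=np.geomspace(1e-4, 1e-3, 4))
        ref = RateGrid(raw.data.assign(rate_M_per_s=2e-8))
        out = blank_correct(raw, ref)
        assert np.allclose(out.data["rate_M_per_s"], 8e-8)

    def test_unmatched_conditions_raise(self, pingpong_grid):
        _, grid = pingpong_grid
        ref = RateGrid(grid.data.iloc[:-2].copy())
        with pytest.raises(ValueError, match="missing conditions"):
            blank_correct(grid, ref)


class TestMichaelisMenten:
    def test_round_trip_recovery(self):
        kcat, km = 10.0, 200e-6
        s = np.geomspace(20e-6, 2e-3, 8)
        v = E0 * kcat * s / (km + s)
        fit = MichaelisMentenModel(s, v, np.full_like(s, E0)).fit()
        assert fit.kcat_app == pytest.approx(kcat, rel=1e-3)
        assert fit.km_app == pytest.approx(km, rel=1e-3)
        assert not fit.degenerate

    def test_ridge_line_identifiability(self):
        # km >> [S]: only kcat/km identified; the ratio must survive
        kcat, km = 10.0, 1.0
        s = np.geomspace(20e-6, 2e-3, 8)
        v = E0 * kcat * s / (km + s)
        fit = MichaelisMentenModel(s, v, np.full_like(s, E0)).fit()
        assert fit.unidentifiable
        assert fit.efficiency == pytest.approx(kcat / km, rel=0.01)

    def test_constant_rates_flagged_degenerate(self):
        s = np.geomspace(20e-6, 2e-3, 8)
        v = np.full_like(s, 1e-7)
        fit = MichaelisMentenModel(s, v, np.full_like(s, E0)).fit()
        assert fit.degenerate

    def test_apparent_kcat_varies_with_fixed_cosubstrate_as_dalziel(
            self, pingpong_grid):
        """kcat_app at fixed [GSSR] equals 1/(phi0 + phi1/[GSSR])."""
        params, grid = pingpong_grid
        fits = fit_apparent_mm(grid, varied="gsh")
        for gssr, fit in fits.items():
            expected = 1.0 / (params.phi0 + params.phi1 / gssr)
            assert fit.kcat_app == pytest.approx(expected, rel=1e-4)

    def test_efficiency_independent_of_fixed_level(self, pingpong_grid):
        """Ping-pong signature: kcat_app/Km_app for GSH does not depend on
        the fixed GSSCys level (parallel Lineweaver-Burk lines)."""
        _, grid = pingpong_grid
        fits = fit_apparent_mm(grid, varied="gsh")
        effs = [f.efficiency for f in fits.values()]
        assert np.allclose(effs, effs[0], rtol=1e-4)


class TestLinearize:
    def test_all_transforms_match_nonlinear_fit_on_noiseless_data(self):
        kcat, km = 10.0, 200e-6
        s = np.geomspace(20e-6, 2e-3, 8)
        vmax = E0 * kcat
        v = vmax * s / (km + s)
        for method in ("lineweaver_burk", "eadie_hofstee", "hanes"):
            res = linearize(s, v, method)
            assert res.vmax == pytest.approx(vmax, rel=1e-6), method
            assert res.km == pytest.approx(km, rel=1e-6), method

    def test_hanes_slope_is_inverse_vmax(self):
        kcat, km = 10.0, 200e-6
        s = np.geomspace(20e-6, 2e-3, 8)
        vmax = E0 * kcat
        v = vmax * s / (km + s)
        res = linearize(s, v, "hanes")
        assert res.slope == pytest.approx(1.0 / vmax, rel=1e-9)

    def test_lineweaver_burk_horizontal_when_saturated(self):
        s = np.geomspace(1e-5, 1e-3, 6)
        v = np.full_like(s, 2e-7)  # v = Vmax exactly (km = 0)
        res = linearize(s, v, "lineweaver_burk")
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_excluded_with_warning(self):
        s = np.array([1e-5, 2e-5, 4e-5, 8e-5])
        v = np.array([0.0, 1e-8, 2e-8, 3e-8])
        with pytest.warns(UserWarning, match="excluding"):
            res = linearize(s, v, "hanes")
        assert res.n_excluded == 1


class TestDalzielFit:
    def test_exact_recovery_on_noiseless_grid(self, pingpong_grid):
        params, grid = pingpong_grid
        res = fit_dalziel(grid)
        assert res.params.phi0 == pytest.approx(params.phi0, rel=1e-9)
        assert res.params.phi1 == pytest.approx(params.phi1, rel=1e-9)
        assert res.params.phi2 == pytest.approx(params.phi2, rel=1e-9)

    def test_hsgrx5_loop_reciprocals_recovered(self):
        grid = generate_rate_grid(load_variant("HsGrx5-loop"))
        res = fit_dalziel(grid)
        assert res.params.k_ox == pytest.approx(2e3, rel=1e-3)
        assert res.params.k_red == pytest.approx(5e3, rel=1e-3)

    def test_one_stage_equals_two_stage_on_noiseless_data(self, pingpong_grid):
        _, grid = pingpong_grid
        one = fit_dalziel(grid).phi
        two = DalzielModel(grid).fit(method="two_stage").phi
        assert np.allclose(one, two, rtol=1e-8)

    def test_gsh_independent_generator_gives_vanishing_phi2(self):
        params = PingPongParameters(phi0=0.02, phi1=1.0 / 2e5, phi2=1e-12)
        grid = make_grid(lambda a, b: dalziel_rate(params, E0, a, b))
        res = fit_dalziel(grid)
        # phi2 indistinguishable from zero relative to the other terms
        assert abs(res.params.phi2) / res.params.phi0 < 1e-6

    def test_rank_deficient_design_raises(self):
        params = PingPongParameters(phi0=0.02, phi1=1.0 / 2e5, phi2=1.0 / 5e4)
        grid = make_grid(lambda a, b: dalziel_rate(params, E0, a, b),
                         gssr=[1e-4])
        with pytest.raises(ValueError, match="rank-deficient"):
            DalzielModel(grid)

    def test_median_relative_error_under_2pct_noise(self):
        """Parameter-recovery simulation study: 2% multiplicative noise."""
        vset = load_variant("WT")
        true = vset.kinetic.parameters()
        errs = []
        for seed in range(200):
            grid = generate_rate_grid(
                vset, noise=NoiseModel("multiplicative_gaussian", 0.02, seed))
            res = fit_dalziel(grid)
            errs.append(max(
                abs(res.params.k_ox / true.k_ox - 1),
                abs(res.params.k_red / true.k_red - 1),
            ))
        assert np.median(errs) < 0.05


class TestCompareVariants:
    def test_identity_and_reciprocity(self, pingpong_grid):
        _, grid = pingpong_grid
        wt = fit_dalziel(grid)
        cmp_self = compare_variants(wt, wt)
        assert all(r == pytest.approx(1.0) for r in cmp_self.ratios.values())

        mut_grid = generate_rate_grid(load_variant("E147K"))
        wt_grid = generate_rate_grid(load_variant("WT"))
        a = fit_dalziel(wt_grid)
        b = fit_dalziel(mut_grid)
        fwd = compare_variants(a, b).ratios
        rev = compare_variants(b, a).ratios
        for key in fwd:
            assert fwd[key] * rev[key] == pytest.approx(1.0, rel=1e-9)

    def test_reductive_gain_of_function_ratio(self):
        """E147K-like 2.5x faster reductive half-reaction is reported as 2.50."""
        wt = fit_dalziel(generate_rate_grid(load_variant("WT")))
        mut = fit_dalziel(generate_rate_grid(load_variant("E147K")))
        cmp = compare_variants(wt, mut)
        assert cmp.ratios["k_red"] == pytest.approx(2.5, rel=1e-6)

    def test_oxidative_reduction_percent(self):
        """R153A-like 0.40x oxidative coefficient reads as 60% reduction."""
        wt = fit_dalziel(generate_rate_grid(load_variant("WT")))
        mut = fit_dalziel(generate_rate_grid(load_variant("R153A")))
        cmp = compare_variants(wt, mut)
        assert cmp.percent_reduction("k_ox") == pytest.approx(60.0, rel=1e-6)

    def test_mismatched_substrates_raise(self, pingpong_grid):
        _, grid = pingpong_grid
        heds = RateGrid(grid.data.copy(), substrate_label="HEDS")
        with pytest.raises(ValueError, match="different substrates"):
            compare_variants(fit_dalziel(grid), fit_dalziel(heds))
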