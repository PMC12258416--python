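import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chelcomp.equilibrium import CompetitionSystem, solve_competition
from chelcomp.errors import FitError, NonInformativePointWarning, ValidationError
from chelcomp.inference import (
    KdEstimate,
    compare_kds,
    fit_kd,
    kd_from_point,
    significance_stars,
    stoichiometry_slope,
)
from chelcomp.intensity import ApoSeries, apo_concentration, select_peaks
from chelcomp.synthetic import SyntheticConfig, simulate_titration

UM = 1e-6
NM = 1e-9


def series_from_fractions(fractions, zn_points, p_total=200.0, error=0.0):
    df = pd.DataFrame(
        {
            "point_index": range(len(zn_points)),
            "zn_added": zn_points,
            "time_h": np.arange(len(zn_points), dtype=float),
            "apo": [p_total * f for f in fractions],
            "error": error,
            "n_peaks": 6,
        }
    )
    return ApoSeries(df, control_conc=p_total)


def forward_fractions(kd_nM, zn_points, p_total=200.0, c_total=200.0, kd_c=4.4, mode="zn_only"):
    out = []
    for zn in zn_points:
        ct = c_total if mode == "zn_only" else zn
        state = solve_competition(
            CompetitionSystem(p_total * UM, ct * UM, zn * UM, kd_nM * NM, kd_c * NM)
        )
        out.append(state.p_free / (p_total * UM))
    return out


class TestKdFromPoint:
    def test_inverts_forward_solve(self):
        state = solve_competition(
            CompetitionSystem(200 * UM, 200 * UM, 100 * UM, 6 * NM, 4.4 * NM)
        )
        kd = kd_from_point(state.p_free / UM, 200.0, 100.0, 200.0, kd_c=4.4)
        assert kd == pytest.approx(6.0, rel=1e-6)

    def test_inverts_with_measured_czn(self):
        state = solve_competition(
            CompetitionSystem(200 * UM, 200 * UM, 100 * UM, 6 * NM, 4.4 * NM)
        )
        kd = kd_from_point(
            state.p_free / UM, 200.0, 100.0, 200.0, kd_c=4.4, czn_measured=state.czn / UM
        )
        assert kd == pytest.approx(6.0, rel=1e-6)

    def test_apo_equal_to_total_is_non_informative(self):
        with pytest.raises(ValidationError, match="no detectable binding"):
            kd_from_point(200.0, 200.0, 100.0, 200.0)

    def test_perturbed_fixture(self):
        # p_free +5% on the 100 uM Zn fixture; expected value frozen from the
        # test-local bisection inversion of the chelator balance
        kd = kd_from_point(163.5856412310668, 200.0, 100.0, 200.0, kd_c=4.4)
        assert kd == pytest.approx(9.213054137862972, rel=1e-9)

    def test_no_chelator_reduces_to_free_zn_subtraction(self):
        # c_total = 0: free Zn is just zn_total - pzn
        kd = kd_from_point(30.0, 40.0, 20.0, 0.0, kd_c=4.4)
        pzn = 10.0
        zn_free = 20.0 - pzn
        assert kd == pytest.approx(30.0 * zn_free / pzn * 1e3, rel=1e-9)  # uM -> nM

    def test_excess_protein_binding_rejected(self):
        with pytest.raises(ValidationError, match="exceeds total Zn"):
            kd_from_point(100.0, 200.0, 50.0, 200.0)


class TestFitKd:
    def test_noiseless_recovery_both_methods(self, zn_grid):
        fractions = forward_fractions(6.0, zn_grid)
        series = series_from_fractions(fractions, zn_grid)
        for method in ("per_point", "global"):
            est = fit_kd(series, 200.0, 200.0, method=method)
            assert est.kd == pytest.approx(6.0, rel=1e-4), method
            assert est.n_points == 7
            assert est.method == method

    def test_per_point_and_global_agree_noiseless(self, zn_grid):
        fractions = forward_fractions(50.0, zn_grid)
        series = series_from_fractions(fractions, zn_grid)
        a = fit_kd(series, 200.0, 200.0, method="per_point")
        b = fit_kd(series, 200.0, 200.0, method="global")
        assert a.kd == pytest.approx(b.kd, rel=1e-4)

    def test_premixed_mode(self, zn_grid):
        fractions = forward_fractions(11.0, zn_grid, c_total=0.0, mode="premixed_chelator_zn")
        series = series_from_fractions(fractions, zn_grid)
        est = fit_kd(series, 200.0, 0.0, mode="premixed_chelator_zn")
        assert est.kd == pytest.approx(11.0, rel=1e-4)

    def test_measured_czn_preferred(self, zn_grid):
        fractions = []
        czn = {}
        for i, zn in enumerate(zn_grid):
            state = solve_competition(
                CompetitionSystem(200 * UM, 200 * UM, zn * UM, 6 * NM, 4.4 * NM)
            )
            fractions.append(state.p_free / (200 * UM))
            czn[i] = state.czn / UM
        series = series_from_fractions(fractions, zn_grid)
        est = fit_kd(series, 200.0, 200.0, czn=czn)
        assert est.kd == pytest.approx(6.0, rel=1e-6)

    def test_all_points_at_zero_zn_fails(self):
        series = series_from_fractions([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(FitError, match="no titration point"):
            fit_kd(series, 200.0, 200.0)

    def test_uninformative_points_raise_fit_error(self, zn_grid):
        # apo == p_total everywhere: every point excluded
        series = series_from_fractions([1.0] * len(zn_grid), zn_grid)
        with pytest.warns(NonInformativePointWarning):
            with pytest.raises(FitError, match="no informative"):
                fit_kd(series, 200.0, 200.0)

    def test_synthetic_recovery_default_seed(self):
        cfg = SyntheticConfig(kd_p_true=6.0, seed=20250303, drift_per_h=0.0)
        table, chel, truth = simulate_titration(cfg)
        series = apo_concentration(table, select_peaks(table))
        czn = dict(enumerate(truth.czn))
        est = fit_kd(series, 200.0, 200.0, czn=czn)
        assert est.kd == pytest.approx(6.0, rel=0.2)


class TestCompareKds:
    def test_identical_estimates(self):
        a = KdEstimate(kd=6.0, sd=1.0, n_points=7, method="per_point")
        res = compare_kds(a, a)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.df == 7 + 7 - 3
        assert res.stars == "ns"

    def test_hand_computed_pooled_t_df5(self):
        # per-point Kd vectors, n = 4 each; oracle: direct pooled-t on the
        # log values with the restricted df = 8 - 3 = 5 in both the pooled
        # variance and the t distribution
        va = np.log([5.2, 6.1, 5.8, 6.5])
        vb = np.log([8.9, 9.4, 10.2, 8.7])
        m1, m2 = va.mean(), vb.mean()
        s1, s2 = va.std(ddof=1), vb.std(ddof=1)
        df = 5
        sp = (3 * s1**2 + 3 * s2**2) / df
        t_ref = (m1 - m2) / math.sqrt(sp * 0.5)
        p_ref = 2 * stats.t.sf(abs(t_ref), df)

        a = KdEstimate(kd=math.exp(m1), sd=math.exp(m1) * s1, n_points=4, method="per_point")
        b = KdEstimate(kd=math.exp(m2), sd=math.exp(m2) * s2, n_points=4, method="per_point")
        res = compare_kds(a, b, restriction=3)
        assert res.df == 5
        assert res.t == pytest.approx(t_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_symmetry(self):
        a = KdEstimate(kd=6.0, sd=1.0, n_points=7, method="per_point")
        b = KdEstimate(kd=48.0, sd=4.0, n_points=6, method="per_point")
        ab = compare_kds(a, b)
        ba = compare_kds(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p == pytest.approx(ba.p)

    def test_df_guard(self):
        a = KdEstimate(kd=6.0, sd=1.0, n_points=1, method="per_point")
        with pytest.raises(ValidationError):
            compare_kds(a, a, restriction=3)

    def test_stars_mapping(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.00004) == "****"


class TestStoichiometrySlope:
    def test_tight_binding_slope_one(self, zn_grid):
        # tight binder, no chelator: bound fraction tracks equivalents 1:1
        fractions = forward_fractions(0.001, zn_grid, c_total=0.0)
        series = series_from_fractions(fractions, zn_grid)
        assert stoichiometry_slope(series, 200.0) == pytest.approx(1.0, abs=1e-3)

    def test_weak_binding_slope_below_half(self, zn_grid):
        # Kd equal to the protein concentration (frozen oracle slope 0.385)
        fractions = forward_fractions(200_000.0, zn_grid, c_total=0.0)
        series = series_from_fractions(fractions, zn_grid)
        slope = stoichiometry_slope(series, 200.0)
        assert slope == pytest.approx(0.3845661640523084, rel=1e-6)
        assert slope < 0.5

    def test_premixed_series_slope_defined(self, zn_grid):
        fractions = forward_fractions(6.0, zn_grid, c_total=0.0, mode="premixed_chelator_zn")
        series = series_from_fractions(fractions, zn_grid)
        slope = stoichiometry_slope(series, 200.0)
        assert math.isfinite(slope)
        assert 0.0 < slope < 1.0

    def test_requires_substoichiometric_points(self):
        series = series_from_fractions([1.0, 0.5], [0.0, 400.0])
        with pytest.raises(ValidationError):
            stoichiometry_slope(series, 200.0)


class TestParameterRecoverySmall:
    """Scaled-down recovery checks; the full 200-replicate protocol runs in
    the acceptance suite."""

    @pytest.mark.parametrize("kd_true", [6.0, 252.0])
    def test_median_recovery_within_20pct(self, kd_true):
        from chelcomp.pipeline import recover_kd_replicates

        values = recover_kd_replicates(kd_true, n_replicates=40, master_seed=99)
        med = float(np.nanmedian(values))
        assert abs(med - kd_true) / kd_true < 0.2
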