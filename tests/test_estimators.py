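"""Estimator correctness: frozen values, independent oracles, and invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tsmr import (
    AnalysisError,
    ConfigurationError,
    HarmonizedDataset,
    HarmonizedInstrument,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)
from tsmr.estimators import weighted_median_point

from conftest import random_dataset


def _inst(rsid, g, sg, G, sG):
    return HarmonizedInstrument(rsid=rsid, beta_exp=g, se_exp=sg, beta_out=G, se_out=sG)


def _ds(rows):
    return HarmonizedDataset(instruments=[_inst(f"rs{i}", *r) for i, r in enumerate(rows)])


def grid_search_ivw(g, sG, G, lo=-10.0, hi=10.0, rounds=6, points=2001):
    """Brute-force minimizer of the weighted RSS over a refined grid."""
    w = sG**-2.0
    best = None
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        rss = (w[:, None] * (G[:, None] - grid[None, :] * g[:, None]) ** 2).sum(axis=0)
        i = int(np.argmin(rss))
        best = grid[i]
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, points - 1)]
    return float(best)


def cdf_inversion_median(ratios, ratio_ses):
    """Invert the piecewise-linear weighted empirical CDF at 0.5 by bisection."""
    from scipy.optimize import brentq

    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(ratio_ses, float)[order] ** -2.0
    w /= w.sum()
    p = np.cumsum(w) - 0.5 * w

    def cdf(x):
        return np.interp(x, r, p, left=0.0, right=1.0)

    if cdf(r[0]) >= 0.5:
        return float(r[0])
    if cdf(r[-1]) <= 0.5:
        return float(r[-1])
    return float(brentq(lambda x: cdf(x) - 0.5, r[0], r[-1], xtol=1e-12))


class TestWaldRatio:
    def test_published_instrument_ratio(self, lst_dr_dataset):
        inst = next(i for i in lst_dr_dataset.instruments if i.rsid == "rs12617870")
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.038 / -0.026)
        assert est.beta == pytest.approx(1.4615384615, abs=1e-9)
        assert est.se == pytest.approx(0.015 / 0.026)

    def test_zero_outcome_effect(self):
        est = wald_ratio(_inst("rs1", 1.0, 0.1, 0.0, 0.2))
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.2)

    def test_ratio_symmetry_under_joint_negation(self):
        a = wald_ratio(_inst("rs1", 0.3, 0.1, 0.12, 0.2))
        b = wald_ratio(_inst("rs1", -0.3, 0.1, -0.12, 0.2))
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(AnalysisError):
            wald_ratio(_inst("rs1", 0.0, 0.1, 0.1, 0.2))


class TestIvw:
    def test_duplicated_pair_equals_wald_ratio(self):
        inst = _inst("rs1", 0.3, 0.05, 0.12, 0.2)
        dup = HarmonizedDataset(instruments=[inst, _inst("rs2", 0.3, 0.05, 0.12, 0.2)])
        assert ivw(dup).beta == pytest.approx(wald_ratio(inst).beta)

    def test_single_instrument_fixed_mode_equals_wald(self):
        inst = _inst("rs1", 0.3, 0.05, 0.12, 0.2)
        est = ivw(HarmonizedDataset(instruments=[inst]), mode="fixed")
        ref = wald_ratio(inst)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_single_instrument_random_effects_rejected(self):
        with pytest.raises(AnalysisError):
            ivw(HarmonizedDataset(instruments=[_inst("rs1", 0.3, 0.05, 0.12, 0.2)]))

    @given(seed=st.integers(0, 10_000))
    def test_matches_grid_search_oracle(self, seed):
        ds = random_dataset(seed, L=10)
        g, _, G, sG = ds.arrays()
        assert ivw(ds).beta == pytest.approx(grid_search_ivw(g, sG, G), abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    def test_random_effects_se_never_below_fixed(self, seed):
        ds = random_dataset(seed)
        assert ivw(ds).se >= ivw(ds, mode="fixed").se - 1e-15

    def test_matches_statsmodels_wls(self, lst_dr_dataset):
        """Independent cross-check: zero-intercept WLS via statsmodels."""
        import statsmodels.api as sm

        g, _, G, sG = lst_dr_dataset.arrays()
        fit = sm.WLS(G, g, weights=sG**-2.0).fit()
        est = ivw(lst_dr_dataset, mode="fixed")
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)


class TestEgger:
    def test_noiseless_linear_data_recovered_exactly(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.1, 1.0, 8)
        ds = _ds([(g[j], 0.05, 0.3 * g[j], 0.2) for j in range(8)])
        fit, est = egger(ds)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_canonicalizes(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(0.1, 1.0, 9)
        G = 0.4 * g + rng.normal(0, 0.1, 9)
        base = _ds([(g[j], 0.05, G[j], 0.2) for j in range(9)])
        signs = np.where(np.arange(9) % 2 == 0, -1.0, 1.0)
        flipped = _ds([(signs[j] * g[j], 0.05, signs[j] * G[j], 0.2) for j in range(9)])
        fa, ea = egger(base)
        fb, eb = egger(flipped)
        assert ea.beta == pytest.approx(eb.beta)
        assert fa.intercept == pytest.approx(fb.intercept)
        assert fa.intercept_se == pytest.approx(fb.intercept_se)

    def test_collinear_exposures_rejected(self):
        ds = _ds([(0.2, 0.05, 0.1, 0.2)] * 4)
        with pytest.raises(AnalysisError):
            egger(ds)

    def test_insufficient_instruments(self):
        with pytest.raises(AnalysisError):
            egger(_ds([(0.2, 0.05, 0.1, 0.2), (0.3, 0.05, 0.1, 0.2)]))

    def test_matches_statsmodels_wls(self, lst_dr_dataset):
        """Slope, intercept and (dispersion > 1) scaled SEs against statsmodels."""
        import statsmodels.api as sm

        g, _, G, sG = lst_dr_dataset.arrays()
        sign = np.where(g < 0, -1.0, 1.0)
        g, G = g * sign, G * sign
        X = sm.add_constant(g)
        ref = sm.WLS(G, X, weights=sG**-2.0).fit()
        fit, est = egger(lst_dr_dataset)
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert est.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.phi > 1  # dispersion present on this dataset, so SEs match too
        assert fit.intercept_se == pytest.approx(ref.bse[0], rel=1e-10)
        assert est.se == pytest.approx(ref.bse[1], rel=1e-10)
        assert est.p == pytest.approx(ref.pvalues[1], rel=1e-10)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        ds = _ds([(1.0, 0.05, 0.1, 0.2), (1.0, 0.05, 0.2, 0.2), (1.0, 0.05, 0.9, 0.2)])
        est = weighted_median(ds, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    @given(seed=st.integers(0, 10_000))
    def test_matches_cdf_inversion_oracle(self, seed):
        ds = random_dataset(seed, L=5)
        g, _, G, sG = ds.arrays()
        ratios, ses = G / g, sG / np.abs(g)
        assert weighted_median_point(ratios, ses) == pytest.approx(
            cdf_inversion_median(ratios, ses), abs=1e-9
        )

    @given(seed=st.integers(0, 10_000))
    def test_estimate_within_ratio_range(self, seed):
        ds = random_dataset(seed, L=7)
        g, _, G, sG = ds.arrays()
        ratios = G / g
        est = weighted_median(ds, n_boot=100, seed=0)
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_bootstrap_reproducible_under_seed(self, lst_dr_dataset):
        a = weighted_median(lst_dr_dataset, n_boot=300, seed=42)
        b = weighted_median(lst_dr_dataset, n_boot=300, seed=42)
        c = weighted_median(lst_dr_dataset, n_boot=300, seed=43)
        assert a.se == b.se
        assert a.se != c.se  # different seed, different bootstrap
        assert a.beta == c.beta  # point estimate is deterministic

    def test_seed_and_boot_count_required(self, lst_dr_dataset):
        with pytest.raises(ConfigurationError):
            weighted_median(lst_dr_dataset, n_boot=300, seed=None)
        with pytest.raises(ConfigurationError):
            weighted_median(lst_dr_dataset, n_boot=50, seed=1)


class TestSharedInvariances:
    @given(seed=st.integers(0, 5_000), c=st.floats(0.1, 5.0))
    def test_scale_equivariance(self, seed, c):
        """Scaling all outcome effects and SEs by c scales beta and se by c."""
        ds = random_dataset(seed)
        scaled = HarmonizedDataset(
            instruments=[
                HarmonizedInstrument(
                    rsid=i.rsid, beta_exp=i.beta_exp, se_exp=i.se_exp,
                    beta_out=c * i.beta_out, se_out=c * i.se_out,
                )
                for i in ds.instruments
            ]
        )
        for a, b in [
            (ivw(ds), ivw(scaled)),
            (weighted_median(ds, 100, seed=0), weighted_median(scaled, 100, seed=0)),
            (egger(ds)[1], egger(scaled)[1]),
        ]:
            assert b.beta == pytest.approx(c * a.beta, rel=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=1e-9)

    @given(seed=st.integers(0, 5_000))
    def test_orientation_invariance_ivw_and_median(self, seed):
        """Negating (gamma, Gamma) for any subset leaves estimates unchanged."""
        ds = random_dataset(seed)
        rng = np.random.default_rng(seed + 1)
        signs = rng.choice([-1.0, 1.0], len(ds))
        flipped = HarmonizedDataset(
            instruments=[
                HarmonizedInstrument(
                    rsid=i.rsid, beta_exp=s * i.beta_exp, se_exp=i.se_exp,
                    beta_out=s * i.beta_out, se_out=i.se_out,
                )
                for i, s in zip(ds.instruments, signs)
            ]
        )
        assert ivw(flipped).beta == pytest.approx(ivw(ds).beta, rel=1e-9)
        assert weighted_median(flipped, 100, seed=0).beta == pytest.approx(
            weighted_median(ds, 100, seed=0).beta, rel=1e-9
        )
        assert egger(flipped)[1].beta == pytest.approx(egger(ds)[1].beta, rel=1e-9)
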