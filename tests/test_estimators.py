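"""Estimator correctness against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from mrpipe import (
    HarmonizedInstrument,
    InstrumentSet,
    egger,
    ivw,
    ivw_standard_error,
    mode_estimate,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from mrpipe.estimators import InsufficientInstrumentsError, compute_ratios

from conftest import random_instruments


def make_instrument(sid, beta_exp, se_exp, beta_out, se_out):
    return HarmonizedInstrument(
        snp_id=sid, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
    )


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, loop-based)


def oracle_ivw(instruments):
    num = den = 0.0
    for i in instruments:
        w = i.beta_exp**2 / i.se_out**2
        num += w * (i.beta_out / i.beta_exp)
        den += w
    return num / den, den**-0.5


def oracle_wls(instruments):
    """Weighted normal equations for intercept+slope, exposure oriented positive."""
    s11 = s1x = sxx = s1y = sxy = 0.0
    for i in instruments:
        sgn = 1.0 if i.beta_exp > 0 else -1.0
        x, y, w = sgn * i.beta_exp, sgn * i.beta_out, 1.0 / i.se_out**2
        s11 += w
        s1x += w * x
        sxx += w * x * x
        s1y += w * y
        sxy += w * x * y
    det = s11 * sxx - s1x**2
    intercept = (sxx * s1y - s1x * sxy) / det
    slope = (s11 * sxy - s1x * s1y) / det
    return intercept, slope


def oracle_weighted_median(instruments):
    pairs = sorted(
        ((i.beta_out / i.beta_exp, i.beta_exp**2 / i.se_out**2) for i in instruments),
    )
    total = sum(w for _, w in pairs)
    cum = 0.0
    points = []
    for r, w in pairs:
        points.append((r, (cum + w / 2) / total))
        cum += w
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        if p0 <= 0.5 <= p1:
            return r0 + (r1 - r0) * (0.5 - p0) / (p1 - p0)
    return points[0][0] if 0.5 < points[0][1] else points[-1][0]


def oracle_mode(instruments, weighted, phi=1.0):
    """Grid-search argmax of the weighted normal-kernel density."""
    r = np.array([i.beta_out / i.beta_exp for i in sorted(instruments, key=lambda x: x.snp_id)])
    w = (
        np.array([i.beta_exp**2 / i.se_out**2 for i in sorted(instruments, key=lambda x: x.snp_id)])
        if weighted
        else np.ones_like(r)
    )
    s = np.std(r, ddof=1)
    m = sps.median_abs_deviation(r, scale="normal")
    h = phi * 0.9 * min(s, m) * len(r) ** -0.2
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = np.zeros_like(grid)
    for ri, wi in zip(r, w):
        dens += wi * sps.norm.pdf(grid, ri, h)
    return grid[np.argmax(dens)]


# ---------------------------------------------------------------------------


class TestWaldRatio:
    def test_fixture_single_snp(self, reverse_set):
        inst = next(i for i in reverse_set.kept if i.snp_id == "rs9677504")
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.044 / 0.1169, rel=1e-12)
        assert est.beta == pytest.approx(-0.376, abs=0.001)

    def test_simple_values(self):
        est = wald_ratio(make_instrument("rs1", 1.0, 0.1, 0.5, 0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(make_instrument("rs1", 0.2, 0.1, 0.0, 0.1)).beta == 0.0

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_instrument("rs1", 0.0, 0.1, 0.5, 0.1))


class TestIvw:
    def test_reverse_fixture_headline(self, reverse_set):
        est = ivw(reverse_set)
        assert est.or_ == pytest.approx(0.857, abs=0.005)
        assert est.or_low == pytest.approx(0.755, abs=0.005)
        assert est.or_high == pytest.approx(0.974, abs=0.005)
        assert est.pval == pytest.approx(0.018, abs=0.005)

    def test_identical_pair_returns_common_ratio(self):
        a = make_instrument("rs1", 0.1, 0.01, 0.05, 0.01)
        b = make_instrument("rs2", 0.1, 0.01, 0.05, 0.01)
        assert ivw([a, b]).beta == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [5, 8, 20])
    def test_matches_bruteforce_oracle(self, k):
        rng = np.random.default_rng(k)
        iset = random_instruments(rng, k)
        est = ivw(iset)
        beta, se = oracle_ivw(iset.kept)
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_mre_inflates_se_only_under_heterogeneity(self):
        rng = np.random.default_rng(3)
        iset = random_instruments(rng, 10)
        fixed = ivw(iset, effects_model="fixed")
        mre = ivw(iset, effects_model="multiplicative_random")
        assert mre.beta == pytest.approx(fixed.beta)
        assert mre.se >= fixed.se

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        iset = random_instruments(rng, 6)
        scaled = [
            make_instrument(i.snp_id, i.beta_exp, i.se_exp, i.beta_out, i.se_out * 3)
            for i in iset.kept
        ]
        assert ivw(scaled).beta == pytest.approx(ivw(iset).beta)
        assert ivw(scaled).se == pytest.approx(3 * ivw(iset).se)

    def test_reordering_equivariance(self):
        rng = np.random.default_rng(11)
        iset = random_instruments(rng, 7)
        shuffled = list(iset.kept)
        rng.shuffle(shuffled)
        assert ivw(shuffled).beta == pytest.approx(ivw(iset).beta, abs=1e-14)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([make_instrument("rs1", 0.1, 0.01, 0.05, 0.01)])


class TestIvwStandardError:
    def test_forward_fixture_se_without_outcome_betas(self, forward_set):
        # computable although no outcome beta is present
        assert ivw_standard_error(forward_set) == pytest.approx(0.052, abs=0.001)

    def test_quadruplicated_instrument_halves_se(self):
        one = make_instrument("rs1", 0.1, 0.01, 0.05, 0.02)
        four = [make_instrument(f"rs{i}", 0.1, 0.01, 0.05, 0.02) for i in range(4)]
        single_ratio_se = one.se_out / abs(one.beta_exp)
        assert ivw_standard_error(four) == pytest.approx(single_ratio_se / 2)

    def test_consistent_with_full_ivw(self, reverse_set):
        assert ivw_standard_error(reverse_set) == pytest.approx(
            ivw(reverse_set).se, abs=1e-14
        )


class TestEgger:
    def test_reverse_fixture_slope_and_intercept(self, reverse_set):
        est = egger(reverse_set)
        assert est.or_ == pytest.approx(0.509, abs=0.01)
        assert est.intercept == pytest.approx(0.048, abs=0.003)
        assert est.intercept_pval == pytest.approx(0.192, abs=0.01)

    def test_exact_line_recovers_theta(self):
        theta = 0.7
        insts = [
            make_instrument(f"rs{i}", b, 0.01, theta * b, 0.01)
            for i, b in enumerate([0.05, 0.1, 0.2, -0.15])
        ]
        est = egger(insts)
        assert est.beta == pytest.approx(theta, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [5, 12, 20])
    def test_matches_normal_equations_oracle(self, k):
        rng = np.random.default_rng(k + 100)
        iset = random_instruments(rng, k)
        est = egger(iset)
        intercept, slope = oracle_wls(iset.kept)
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        """Regression through the origin with 1/se_out^2 weights equals IVW."""
        rng = np.random.default_rng(21)
        iset = random_instruments(rng, 9)
        sxx = sxy = 0.0
        for i in iset.kept:
            w = 1.0 / i.se_out**2
            sxx += w * i.beta_exp**2
            sxy += w * i.beta_exp * i.beta_out
        assert sxy / sxx == pytest.approx(ivw(iset).beta, abs=1e-12)

    def test_insufficient_instruments(self):
        insts = [make_instrument(f"rs{i}", 0.1, 0.01, 0.05, 0.01) for i in range(2)]
        with pytest.raises(InsufficientInstrumentsError):
            egger(insts)


class TestWeightedMedian:
    def test_reverse_fixture(self, reverse_set):
        est = weighted_median(reverse_set, n_boot=500, seed=7)
        assert est.or_ == pytest.approx(0.842, abs=0.01)

    def test_equal_weight_median(self):
        insts = [
            make_instrument(f"rs{i}", 1.0, 0.1, r, 1.0)
            for i, r in enumerate([1.0, 2.0, 9.0])
        ]
        est = weighted_median(insts, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [5, 9, 15])
    def test_matches_interpolation_oracle(self, k):
        rng = np.random.default_rng(k + 200)
        iset = random_instruments(rng, k)
        est = weighted_median(iset, n_boot=100, seed=1)
        assert est.beta == pytest.approx(oracle_weighted_median(iset.kept), abs=1e-10)

    def test_within_ratio_range(self):
        rng = np.random.default_rng(31)
        iset = random_instruments(rng, 12)
        est = weighted_median(iset, n_boot=100, seed=1)
        rs = compute_ratios(iset)
        assert rs.ratio.min() <= est.beta <= rs.ratio.max()

    def test_bootstrap_reproducible(self, reverse_set):
        a = weighted_median(reverse_set, n_boot=300, seed=42)
        b = weighted_median(reverse_set, n_boot=300, seed=42)
        assert a.se == b.se


class TestModeEstimators:
    def test_reverse_fixture_soft_values(self, reverse_set):
        simple = mode_estimate(reverse_set, weighted=False, n_boot=300, seed=3)
        weighted = mode_estimate(reverse_set, weighted=True, n_boot=300, seed=3)
        assert simple.or_ == pytest.approx(0.851, abs=0.05)
        assert weighted.or_ == pytest.approx(0.853, abs=0.05)

    def test_identical_ratios_return_common_value(self):
        insts = [
            make_instrument(f"rs{i}", b, 0.01, 0.4 * b, 0.01)
            for i, b in enumerate([0.1, 0.2, 0.3])
        ]
        est = mode_estimate(insts, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.4, abs=1e-10)

    def test_majority_cluster_wins(self):
        # ratios {0, 0, 0, 5} with uniform weights: mode at 0
        insts = [
            make_instrument("rs1", 0.1, 0.01, 0.0, 0.01),
            make_instrument("rs2", 0.2, 0.01, 0.0, 0.01),
            make_instrument("rs3", 0.3, 0.01, 0.0, 0.01),
            make_instrument("rs4", 0.1, 0.01, 0.5, 0.01),
        ]
        est = mode_estimate(insts, weighted=False, n_boot=200, seed=0)
        assert abs(est.beta) < 0.5

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("k", [6, 11])
    def test_matches_grid_argmax_oracle(self, weighted, k):
        rng = np.random.default_rng(k + 300)
        iset = random_instruments(rng, k)
        est = mode_estimate(iset, weighted=weighted, n_boot=100, seed=2)
        assert est.beta == pytest.approx(
            oracle_mode(iset.kept, weighted), abs=1e-10
        )


class TestOddsScale:
    def test_fixture_scale_conversion(self):
        or_, lo, hi = to_odds_scale(-0.1533, 0.0652)
        assert or_ == pytest.approx(0.858, abs=0.002)
        assert lo == pytest.approx(0.755, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_null_beta_symmetric(self):
        or_, lo, hi = to_odds_scale(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_degenerate_interval(self):
        or_, lo, hi = to_odds_scale(1.0, 0.0)
        assert or_ == lo == hi == pytest.approx(np.e)
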