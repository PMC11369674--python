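"""Univariable MR estimators against independently coded oracles.

The oracles deliberately use a different route than the implementation:
explicit summation formulas and statsmodels WLS for the regressions, a
step-by-step cumulative-weight walk for the medians.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import egger, ivw, simple_median, wald_ratio, weighted_median
from mrmediate.errors import DegenerateInstrumentError, InsufficientInstrumentsError

from conftest import make_pair, random_pair


# ---------------------------------------------------------------- oracles


def ivw_closed_form(bx, by, sy):
    """Fixed-effect IVW via the explicit ratio of sums."""
    w = 1.0 / np.asarray(sy) ** 2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sqrt(1.0 / np.sum(w * bx**2))
    return beta, se


def egger_wls_oracle(bx, by, sy):
    """MR-Egger via statsmodels WLS (free intercept, weights 1/sy^2)."""
    s = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    bxo, byo = np.asarray(bx) * s, np.asarray(by) * s
    res = sm.WLS(byo, sm.add_constant(bxo), weights=1.0 / np.asarray(sy) ** 2).fit()
    scale_fixed = res.bse / np.sqrt(res.scale)  # unit-scale (fixed) SEs
    se = scale_fixed * max(1.0, np.sqrt(res.scale))
    return res.params[0], se[0], res.params[1], se[1]


def median_walk_oracle(values, weights):
    """Weighted 50th percentile by walking the cumulative weights."""
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return v[0]
    for i in range(1, len(v)):
        if cum[i] >= 0.5:
            frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
            return v[i - 1] + frac * (v[i] - v[i - 1])
    return v[-1]


# ---------------------------------------------------------------- Wald


class TestWald:
    def test_direct_ratio(self):
        est = wald_ratio(0.5, 0.25, 0.1)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.5, 0.0, 0.1).beta == 0.0

    def test_sign_symmetry(self):
        assert wald_ratio(-0.5, -0.25, 0.1).beta == wald_ratio(0.5, 0.25, 0.1).beta

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.1)


# ---------------------------------------------------------------- IVW


class TestIVW:
    def test_shared_ratio_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.05])
        pair = make_pair(bx, 0.3 * bx, [0.01, 0.02, 0.01])
        est = ivw(pair, model="fixed")
        assert est.beta == pytest.approx(0.3, abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_oracle(self, seed):
        pair = random_pair(seed)
        est = ivw(pair, model="fixed")
        beta, se = ivw_closed_form(pair.beta_exposure, pair.beta_outcome, pair.se_outcome)
        assert est.beta == pytest.approx(beta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_wls(self, seed):
        pair = random_pair(seed)
        res = sm.WLS(
            pair.beta_outcome, pair.beta_exposure[:, None],
            weights=1.0 / pair.se_outcome**2,
        ).fit()
        est = ivw(pair, model="fixed")
        assert est.beta == pytest.approx(res.params[0], abs=1e-12)
        assert est.se == pytest.approx(res.bse[0] / np.sqrt(res.scale), abs=1e-12)

    def test_duplicating_variants_leaves_fixed_beta_unchanged(self):
        pair = random_pair(3)
        doubled = make_pair(
            np.tile(pair.beta_exposure, 2),
            np.tile(pair.beta_outcome, 2),
            np.tile(pair.se_outcome, 2),
            np.tile(pair.se_exposure, 2),
        )
        assert ivw(doubled, model="fixed").beta == pytest.approx(
            ivw(pair, model="fixed").beta, abs=1e-12
        )

    def test_random_model_inflates_se_under_heterogeneity(self):
        pair = make_pair([0.1, 0.1, 0.1, 0.1], [0.05, -0.03, 0.08, 0.0], 0.005)
        fixed = ivw(pair, model="fixed")
        random = ivw(pair, model="random_multiplicative")
        assert random.beta == pytest.approx(fixed.beta)
        assert random.se > fixed.se

    def test_single_variant_delegates_to_wald(self):
        est = ivw(make_pair([0.5], [0.25], [0.1]))
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5)

    def test_all_zero_exposure_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            ivw(make_pair([0.0, 0.0], [0.1, 0.1], [0.01, 0.01]))

    def test_or_and_ci_consistent(self):
        est = ivw(random_pair(1))
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_ < est.ci_high


# ---------------------------------------------------------------- Egger


class TestEgger:
    def test_affine_identity_recovered_exactly(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        pair = make_pair(bx, 0.1 + 0.3 * bx, 0.01)
        res = egger(pair)
        assert res.intercept.beta == pytest.approx(0.1, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_zero_pleiotropy_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.15])
        res = egger(make_pair(bx, 0.3 * bx, 0.01))
        assert res.intercept.beta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        pair = random_pair(seed, n=6)
        res = egger(pair)
        i, i_se, s, s_se = egger_wls_oracle(
            pair.beta_exposure, pair.beta_outcome, pair.se_outcome
        )
        assert res.intercept.beta == pytest.approx(i, abs=1e-12)
        assert res.slope.beta == pytest.approx(s, abs=1e-12)
        assert res.intercept.se == pytest.approx(i_se, abs=1e-12)
        assert res.slope.se == pytest.approx(s_se, abs=1e-12)

    def test_directional_pleiotropy_recovered_noise_free(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        delta = 0.02
        pair = make_pair(bx, delta + 0.25 * bx, 0.01)
        res = egger(pair)
        assert res.intercept.beta == pytest.approx(delta, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.25, abs=1e-12)

    def test_too_few_variants_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pair([0.1, 0.2], [0.03, 0.06], 0.01))


# ---------------------------------------------------------------- medians


class TestMedians:
    def test_plain_median_equal_weights(self):
        pair = make_pair([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], 1.0)
        est = weighted_median(pair, n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_simple_median_odd(self):
        pair = make_pair([1.0, 1.0, 1.0], [3.0, 1.0, 2.0], 1.0)
        assert simple_median(pair, n_boot=100, seed=0).beta == pytest.approx(2.0)

    def test_consistency_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        pair = make_pair(bx, 0.4 * bx, [0.01, 0.02, 0.03], sx=1e-8)
        est = weighted_median(pair, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_bootstrap_se_vanishes_with_input_ses(self):
        bx = np.array([0.1, 0.2, 0.3])
        pair = make_pair(bx, 0.4 * bx, 1e-9, sx=1e-9)
        est = weighted_median(pair, n_boot=200, seed=0)
        assert est.se < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_median_matches_walk_oracle(self, seed):
        pair = random_pair(seed, n=5)
        est = weighted_median(pair, n_boot=100, seed=0)
        ratios = pair.beta_outcome / pair.beta_exposure
        weights = pair.beta_exposure**2 / pair.se_outcome**2
        assert est.beta == pytest.approx(median_walk_oracle(ratios, weights), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_simple_median_matches_walk_oracle(self, seed):
        pair = random_pair(seed, n=5)
        est = simple_median(pair, n_boot=100, seed=0)
        ratios = pair.beta_outcome / pair.beta_exposure
        assert est.beta == pytest.approx(
            median_walk_oracle(ratios, np.ones_like(ratios)), abs=1e-12
        )

    def test_even_count_midpoint_convention(self):
        assert median_walk_oracle(np.array([1.0, 3.0]), np.ones(2)) == pytest.approx(2.0)
        pair = make_pair([1.0] * 4, [1.0, 3.0, 0.0, 4.0], 1.0)
        assert simple_median(pair, n_boot=100, seed=0).beta == pytest.approx(2.0)

    def test_simple_equals_weighted_under_equal_weights(self):
        # equal outcome SEs and equal |bx| make the two weightings coincide
        pair = make_pair([0.1, 0.1, 0.1, 0.1, 0.1], [0.02, 0.05, 0.01, 0.07, 0.03], 0.01)
        wm = weighted_median(pair, n_boot=100, seed=0)
        sme = simple_median(pair, n_boot=100, seed=0)
        assert wm.beta == pytest.approx(sme.beta, abs=1e-12)

    def test_bootstrap_reproducible_with_seed(self):
        pair = random_pair(7, n=6)
        a = weighted_median(pair, n_boot=300, seed=11)
        b = weighted_median(pair, n_boot=300, seed=11)
        c = weighted_median(pair, n_boot=300, seed=12)
        assert a.se == b.se
        assert a.se != c.se


# ------------------------------------------------- shared invariances


@pytest.mark.parametrize("seed", range(3))
def test_per_variant_allele_recoding_invariance(seed):
    """Recoding any subset of variants (negating bx and by together, the
    effect of choosing the other allele) leaves every estimator unchanged."""
    pair = random_pair(seed, n=7)
    rng = np.random.default_rng(seed + 100)
    s = rng.choice([-1.0, 1.0], 7)
    recoded = make_pair(
        pair.beta_exposure * s, pair.beta_outcome * s, pair.se_outcome, pair.se_exposure
    )
    assert ivw(recoded, "fixed").beta == pytest.approx(ivw(pair, "fixed").beta, abs=1e-12)
    assert egger(recoded).slope.beta == pytest.approx(egger(pair).slope.beta, abs=1e-12)
    assert egger(recoded).intercept.beta == pytest.approx(
        egger(pair).intercept.beta, abs=1e-12
    )
    assert weighted_median(recoded, 100, 0).beta == pytest.approx(
        weighted_median(pair, 100, 0).beta, abs=1e-12
    )
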