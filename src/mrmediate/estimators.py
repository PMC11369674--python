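"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrmediate.sumstats.HarmonizedPair` of
per-variant exposure effects ``bx`` (SE ``sx``) and outcome effects ``by``
(SE ``sy``). The per-variant causal estimate is the Wald ratio by/bx; IVW
pools the ratios by inverse-variance weighting, equivalently a weighted
regression of by on bx through the origin with weights 1/sy². MR-Egger frees
the intercept, which absorbs (and tests for) directional horizontal
pleiotropy; the weighted and simple medians are robust to up to half the
weight coming from invalid instruments.

P-values use the standard-normal reference throughout, the usual convention
for summary-data MR. Binary outcomes are on the log-odds scale, so every
estimate also carries an odds ratio with a 95% CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return np.finfo(float).tiny if beta != 0 else 1.0
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


@dataclass
class MREstimate:
    """One estimator's causal effect, with odds-ratio reporting.

    ``beta`` is the effect on the outcome scale per unit exposure (log-odds
    for binary outcomes); ``or_`` = exp(beta) with a 95% Wald CI.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + _Z95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class EggerResult:
    """MR-Egger slope (pleiotropy-adjusted effect) and intercept (bias test)."""

    slope: MREstimate
    intercept: MREstimate


def _arrays(pair: HarmonizedPair) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return pair.beta_exposure, pair.se_exposure, pair.beta_outcome, pair.se_outcome


def wald_ratio(bx: float, by: float, sy: float) -> MREstimate:
    """Single-instrument causal estimate by/bx with first-order SE sy/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald", beta, se, _two_sided_p(beta, se), 1)


def ivw(pair: HarmonizedPair, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of by on bx through the origin.

    ``model``: ``"fixed"`` uses the nominal SE; ``"random_multiplicative"``
    inflates it by sqrt(max(1, Q/(n-1))); ``"auto"`` (default) picks the
    multiplicative random-effects model for >= 3 variants and fixed otherwise.
    A single variant delegates to the Wald ratio.
    """
    bx, _, by, sy = _arrays(pair)
    n = pair.n_snp
    if n == 0:
        raise InsufficientInstrumentsError("IVW requires at least one variant")
    if n == 1:
        return wald_ratio(float(bx[0]), float(by[0]), float(sy[0]))
    if not np.any(bx != 0):
        raise DegenerateInstrumentError("all exposure effects are zero")
    if model == "auto":
        model = "random_multiplicative" if n >= 3 else "fixed"
    if model not in ("fixed", "random_multiplicative"):
        raise ValueError(f"unknown IVW model {model!r}")

    w = 1.0 / sy**2
    sw = np.sqrt(w)
    # Regression formulation: fit sqrt(w)*by on sqrt(w)*bx, no intercept.
    beta, *_ = linalg.lstsq(
        (sw * bx)[:, None], sw * by, lapack_driver="gelsd"
    )
    beta = float(beta[0])
    se = float(1.0 / math.sqrt(np.sum(w * bx**2)))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    method = "ivw_fixed"
    if model == "random_multiplicative":
        se *= math.sqrt(max(1.0, q / (n - 1)))
        method = "ivw_random"
    return MREstimate(method, beta, se, _two_sided_p(beta, se), n)


def egger(pair: HarmonizedPair) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Variants are re-signed so every bx >= 0 before fitting (the orientation
    the intercept test is defined under). SEs carry a multiplicative
    random-effects scale max(1, sqrt(RSS_w/(n-2))).
    """
    bx, _, by, sy = _arrays(pair)
    n = pair.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    w = 1.0 / sy**2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(n), bxo])
    coef, *_ = linalg.lstsq(sw[:, None] * X, sw * byo, lapack_driver="gelsd")
    resid = byo - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (n - 2)))
    cov = linalg.inv(X.T @ (w[:, None] * X))
    se_int = math.sqrt(cov[0, 0]) * scale
    se_slope = math.sqrt(cov[1, 1]) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    return EggerResult(
        slope=MREstimate("egger_slope", slope, se_slope, _two_sided_p(slope, se_slope), n),
        intercept=MREstimate(
            "egger_intercept", intercept, se_int, _two_sided_p(intercept, se_int), n
        ),
    )


def _interpolated_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation over the cumulative
    normalized weights (each value sits at its cumulative weight minus half
    its own)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights[order].sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def _median_estimator(
    pair: HarmonizedPair, weighted: bool, n_boot: int, seed: int
) -> MREstimate:
    bx, sx, by, sy = _arrays(pair)
    nonzero = bx != 0
    if not np.all(nonzero):
        logger.warning(
            "%d variants with bx = 0 excluded from the median estimator",
            int(np.sum(~nonzero)),
        )
        bx, sx, by, sy = bx[nonzero], sx[nonzero], by[nonzero], sy[nonzero]
    n = bx.size
    if n == 0:
        raise DegenerateInstrumentError("no usable variants (all bx = 0)")
    if n < 3:
        raise InsufficientInstrumentsError("median estimators require >= 3 variants")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")

    def weights_for(bx_: np.ndarray) -> np.ndarray:
        # inverse first-order ratio variance sy^2/bx^2
        return bx_**2 / sy**2 if weighted else np.ones_like(bx_)

    ratios = by / bx
    beta = _interpolated_weighted_median(ratios, weights_for(bx))

    rng = np.random.default_rng(seed)
    bx_draws = rng.normal(bx, sx, size=(n_boot, n))
    by_draws = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxd = bx_draws[i]
        bxd = np.where(bxd == 0, np.finfo(float).tiny, bxd)
        boots[i] = _interpolated_weighted_median(by_draws[i] / bxd, weights_for(bxd))
    se = float(np.std(boots, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    return MREstimate(method, beta, se, _two_sided_p(beta, se), n)


def weighted_median(pair: HarmonizedPair, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate: weighted 50th percentile of the Wald ratios,
    weights 1/var(ratio) by the delta method; SE by seeded parametric
    bootstrap (``n_boot`` resamples of bx, by from their normal errors)."""
    return _median_estimator(pair, weighted=True, n_boot=n_boot, seed=seed)


def simple_median(pair: HarmonizedPair, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Simple-median estimate: unweighted median of the Wald ratios, bootstrap SE."""
    return _median_estimator(pair, weighted=False, n_boot=n_boot, seed=seed)
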