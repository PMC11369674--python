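"""Two-step MR mediation: product-of-coefficients decomposition.

Given three MR estimates for a coherent exposure -> mediator -> outcome
triplet — the total effect c (exposure on outcome), a (exposure on mediator)
and b (mediator on outcome) — the indirect effect is the product a*b, the
direct effect is c - a*b, and the proportion mediated is (a*b)/c. When the
indirect and total effects have opposite signs the mediator *masks*
(suppresses) part of the direct effect rather than transmitting it; the
proportion is then reported by magnitude with a masking flag.

The proportion's uncertainty uses the delta method assuming the three
estimates are independent: var(a*b) ~ a² var(b) + b² var(a) and
var(ab/c) ~ var(ab)/c² + (ab)² var(c)/c⁴. A seeded Monte-Carlo alternative
(normal resampling of a, b, c) is available via ``ci_method="montecarlo"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate

_Z95 = 1.959963984540054


def _as_estimate(x) -> tuple[float, float]:
    """Accept an MREstimate or a bare point value (SE then unknown -> NaN)."""
    if isinstance(x, MREstimate):
        return float(x.beta), float(x.se)
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return float(x[0]), float(x[1])
    return float(x), math.nan


@dataclass
class MediationResult:
    """The (c, a, b) decomposition for one exposure/mediator/outcome triplet."""

    exposure: str
    mediator: str
    outcome: str
    c: float
    c_se: float
    a: float
    a_se: float
    b: float
    b_se: float
    indirect: float
    indirect_se: float
    direct: float
    proportion: float  # signed indirect/c; NaN when c == 0
    proportion_se: float
    proportion_ci_low: float
    proportion_ci_high: float
    classification: str  # "mediation" | "masking" | "none"


def _significant(value: float, se: float, alpha: float) -> bool:
    """Nominal two-sided significance; point values without SEs are taken at
    face value (significant when nonzero) so printed tables stay classifiable."""
    if math.isnan(se):
        return value != 0
    if se == 0:
        return value != 0
    p = 2.0 * stats.norm.sf(abs(value) / se)
    return p < alpha


def _classify(
    c: float, c_se: float, indirect: float, indirect_se: float, alpha: float
) -> str:
    if c == 0 or indirect == 0:
        return "none"
    if not (_significant(indirect, indirect_se, alpha) and _significant(c, c_se, alpha)):
        return "none"
    return "mediation" if math.copysign(1, indirect) == math.copysign(1, c) else "masking"


def two_step_decompose(
    c_est,
    a_est,
    b_est,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
    alpha: float = 0.05,
    ci_method: str = "delta",
    n_draws: int = 10000,
    seed: int = 0,
) -> MediationResult:
    """Decompose a total effect into indirect (a*b) and direct (c - a*b) parts.

    ``c_est``, ``a_est``, ``b_est`` are :class:`MREstimate` objects, ``(beta,
    se)`` pairs, or bare floats (SE then unknown). With ``c = 0`` the
    proportion is undefined (NaN) and the classification is ``"none"``.
    """
    c, c_se = _as_estimate(c_est)
    a, a_se = _as_estimate(a_est)
    b, b_se = _as_estimate(b_est)

    indirect = a * b
    direct = c - indirect
    ind_var = a * a * b_se * b_se + b * b * a_se * a_se
    indirect_se = math.sqrt(ind_var) if not math.isnan(ind_var) else math.nan

    if c == 0:
        proportion = prop_se = lo = hi = math.nan
    else:
        proportion = indirect / c
        if ci_method == "delta":
            prop_var = ind_var / c**2 + indirect**2 * c_se**2 / c**4
            prop_se = math.sqrt(prop_var) if not math.isnan(prop_var) else math.nan
            lo, hi = proportion - _Z95 * prop_se, proportion + _Z95 * prop_se
        elif ci_method == "montecarlo":
            rng = np.random.default_rng(seed)
            cd = rng.normal(c, c_se, n_draws)
            ad = rng.normal(a, a_se, n_draws)
            bd = rng.normal(b, b_se, n_draws)
            draws = ad * bd / cd
            prop_se = float(np.std(draws, ddof=1))
            lo, hi = (float(q) for q in np.quantile(draws, [0.025, 0.975]))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")

    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        c=c,
        c_se=c_se,
        a=a,
        a_se=a_se,
        b=b,
        b_se=b_se,
        indirect=indirect,
        indirect_se=indirect_se,
        direct=direct,
        proportion=proportion,
        proportion_se=prop_se,
        proportion_ci_low=lo,
        proportion_ci_high=hi,
        classification=_classify(c, c_se, indirect, indirect_se, alpha),
    )


def classify(result: MediationResult, alpha: float = 0.05) -> str:
    """Re-classify a decomposition at a chosen significance level.

    ``"masking"`` when the indirect effect is nominally significant and
    opposes the total effect's sign (the total also significant);
    ``"mediation"`` when aligned and significant; ``"none"`` otherwise.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return _classify(result.c, result.c_se, result.indirect, result.indirect_se, alpha)


def mediated_proportion_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """One row per triplet with the full decomposition; proportions as
    percentages. ``proportion_pct`` is signed (100*indirect/c);
    ``abs_proportion_pct`` and the CI magnitudes mirror the convention of
    printing magnitudes with a masking flag."""
    rows = []
    for r in results:
        ci = sorted([abs(r.proportion_ci_low), abs(r.proportion_ci_high)])
        rows.append(
            {
                "exposure": r.exposure,
                "mediator": r.mediator,
                "outcome": r.outcome,
                "c": r.c,
                "a": r.a,
                "b": r.b,
                "indirect": r.indirect,
                "direct": r.direct,
                "proportion_pct": 100.0 * r.proportion,
                "abs_proportion_pct": 100.0 * abs(r.proportion),
                "ci_low_pct": 100.0 * ci[0],
                "ci_high_pct": 100.0 * ci[1],
                "classification": r.classification,
            }
        )
    cols = [
        "exposure", "mediator", "outcome", "c", "a", "b", "indirect", "direct",
        "proportion_pct", "abs_proportion_pct", "ci_low_pct", "ci_high_pct",
        "classification",
    ]
    return pd.DataFrame(rows, columns=cols)
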