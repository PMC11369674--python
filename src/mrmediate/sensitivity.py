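"""Heterogeneity and pleiotropy diagnostics for a harmonized pair.

Cochran's Q measures dispersion of the per-variant Wald ratios around the
fixed-effect IVW estimate (Q > expectation signals heterogeneity, i.e. some
instruments estimate a different effect); the MR-Egger intercept tests for
directional pleiotropy; leave-one-out re-estimates IVW with each instrument
removed to expose single-variant dominance. The screening convention is that
Q p > 0.05 and Egger-intercept p > 0.05 leave the core assumptions untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import egger, ivw
from .sumstats import HarmonizedPair


@dataclass
class SensitivityReport:
    q: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_pvalue: float
    loo: pd.DataFrame | None


def cochran_q(pair: HarmonizedPair) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios, centred on the fixed-effect IVW.

    Q = sum_j w_j (r_j - beta_ivw)^2 with r_j = by_j/bx_j and ratio weights
    w_j = bx_j^2/sy_j^2; p from chi-square with n - 1 degrees of freedom.
    """
    bx, by, sy = pair.beta_exposure, pair.beta_outcome, pair.se_outcome
    nonzero = bx != 0
    bx, by, sy = bx[nonzero], by[nonzero], sy[nonzero]
    n = bx.size
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 variants")
    w = bx**2 / sy**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    df = n - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def leave_one_out(pair: HarmonizedPair, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated with each variant excluded in turn.

    One row per left-out variant, flagged when the reduced estimate changes
    sign relative to the full estimate or crosses nominal significance at
    ``alpha`` in either direction.
    """
    n = pair.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 variants")
    full = ivw(pair)
    rows = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        est = ivw(pair.subset(keep))
        sign_change = np.sign(est.beta) != np.sign(full.beta) and est.beta != full.beta
        sig_change = (est.pvalue < alpha) != (full.pvalue < alpha)
        rows.append(
            {
                "left_out_variant_id": pair.variant_ids[i],
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "sign_change": bool(sign_change),
                "significance_change": bool(sig_change),
                "flagged": bool(sign_change or sig_change),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_report(pair: HarmonizedPair, alpha: float = 0.05) -> SensitivityReport:
    """Bundle Q, the Egger-intercept test, and (when feasible) leave-one-out."""
    q, df, qp = cochran_q(pair)
    if pair.n_snp >= 3:
        eg = egger(pair)
        intercept, intercept_p = eg.intercept.beta, eg.intercept.pvalue
        loo = leave_one_out(pair, alpha)
    else:
        intercept, intercept_p, loo = float("nan"), float("nan"), None
    return SensitivityReport(
        q=q,
        q_df=df,
        q_pvalue=qp,
        egger_intercept=intercept,
        egger_intercept_pvalue=intercept_p,
        loo=loo,
    )
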