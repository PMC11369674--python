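"""Multivariable MR: joint direct effects of several exposures on one outcome.

With instruments pooled across exposures, the outcome effects are regressed
on the matrix of exposure effects (no intercept), weights 1/se_outcome².
Each coefficient is the direct effect of that exposure holding the others
fixed. Measurement error in the exposure effects is ignored, as in standard
summary-data MVMR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .estimators import MREstimate, _two_sided_p
from .instruments import LDMatrix, clump, select_significant
from .sumstats import SummaryStatSet, _align_alleles

logger = logging.getLogger(__name__)


@dataclass
class MVMRInput:
    """Aligned effect matrices over the union of per-exposure instruments."""

    variant_ids: list[str]
    beta_exposures: np.ndarray  # (variants, exposures)
    se_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_names: list[str]

    def __post_init__(self) -> None:
        self.beta_exposures = np.asarray(self.beta_exposures, dtype=float)
        self.se_exposures = np.asarray(self.se_exposures, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        n, p = self.beta_exposures.shape
        if (
            self.se_exposures.shape != (n, p)
            or self.beta_outcome.shape != (n,)
            or self.se_outcome.shape != (n,)
            or len(self.variant_ids) != n
            or len(self.exposure_names) != p
        ):
            raise ValueError("MVMR input dimensions disagree")


def build_mvmr_input(
    exposures: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_max: float = 0.001,
    window_kb: float = 5000.0,
    palindrome_eaf_limit: float = 0.42,
) -> MVMRInput:
    """Select instruments per exposure, union and deduplicate them, and align
    all traits to a common effect-allele frame.

    The allele frame for each variant is set by the first exposure whose
    selected instruments contain it. Variants missing from any trait, or with
    irreconcilable/ambiguous alleles in any trait, are dropped (logged).
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")

    # union of selected instruments, first-seen order, deduplicated
    union: list[str] = []
    ref_rows: dict[str, pd.Series] = {}
    for exp in exposures:
        sel = select_significant(exp, p_threshold)
        if ld is not None and len(sel):
            sel = clump(sel, ld, r2_max, window_kb)
        for _, row in sel.table.iterrows():
            if row["SNP"] not in ref_rows:
                union.append(row["SNP"])
                ref_rows[row["SNP"]] = row
    if not union:
        raise DegenerateInstrumentError("no instruments selected for any exposure")

    traits = list(exposures) + [outcome]
    indexed = [t.table.set_index("SNP", drop=False) for t in traits]

    kept_ids: list[str] = []
    bX: list[list[float]] = []
    sX: list[list[float]] = []
    by: list[float] = []
    sy: list[float] = []
    dropped: list[tuple[str, str]] = []

    for vid in union:
        ref = ref_rows[vid]
        ref_eaf = float(ref["EAF"]) if pd.notna(ref["EAF"]) else math.nan
        betas: list[float] = []
        ses: list[float] = []
        reason = None
        for trait, tab in zip(traits, indexed):
            if vid not in tab.index:
                reason = f"missing_in_{trait.trait_name}"
                break
            row = tab.loc[vid]
            eaf = float(row["EAF"]) if pd.notna(row["EAF"]) else math.nan
            flip, why = _align_alleles(
                ref["EA"], ref["OA"], row["EA"], row["OA"],
                ref_eaf, eaf, palindrome_eaf_limit,
            )
            if flip is None:
                reason = f"{why}_in_{trait.trait_name}"
                break
            betas.append(-float(row["BETA"]) if flip else float(row["BETA"]))
            ses.append(float(row["SE"]))
        if reason is not None:
            dropped.append((vid, reason))
            continue
        kept_ids.append(vid)
        bX.append(betas[:-1])
        sX.append(ses[:-1])
        by.append(betas[-1])
        sy.append(ses[-1])

    if dropped:
        logger.info("MVMR input: dropped %d of %d union variants", len(dropped), len(union))
    if not kept_ids:
        raise DegenerateInstrumentError("no variant present and alignable in every trait")
    return MVMRInput(
        variant_ids=kept_ids,
        beta_exposures=np.array(bX),
        se_exposures=np.array(sX),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        exposure_names=[e.trait_name for e in exposures],
    )


def mvmr_ivw(inp: MVMRInput) -> list[MREstimate]:
    """IVW multivariable MR: WLS of outcome effects on the exposure-effect
    matrix without intercept, weights 1/se_outcome²; one estimate per
    exposure, SEs from the weighted normal equations, p from the normal
    reference."""
    X = inp.beta_exposures
    y = inp.beta_outcome
    n, p = X.shape
    if n <= p:
        raise InsufficientInstrumentsError(
            f"MVMR needs more variants ({n}) than exposures ({p})"
        )
    # An exposure with no instrumented signal (all-zero column) contributes a
    # zero coefficient rather than making the design singular.
    zero = np.all(X == 0, axis=0)
    if zero.all():
        raise DegenerateInstrumentError("every exposure column is zero")
    active = ~zero
    Xa = X[:, active]
    w = 1.0 / inp.se_outcome**2
    sw = np.sqrt(w)
    Xw = sw[:, None] * Xa
    if np.linalg.matrix_rank(Xw) < Xa.shape[1]:
        raise CollinearityError(inp.exposure_names)
    coef_a, *_ = linalg.lstsq(Xw, sw * y, lapack_driver="gelsd")
    cov = linalg.inv(Xa.T @ (w[:, None] * Xa))
    ses_a = np.sqrt(np.diag(cov))
    coef = np.zeros(p)
    ses = np.full(p, np.inf)
    coef[active] = coef_a
    ses[active] = ses_a
    return [
        MREstimate("mvmr_ivw", float(b), float(s), _two_sided_p(float(b), float(s)), n)
        for b, s in zip(coef, ses)
    ]


def mvmr_table(inp: MVMRInput, estimates: Sequence[MREstimate]) -> pd.DataFrame:
    """Tidy one-row-per-exposure table of MVMR results."""
    rows = []
    for name, est in zip(inp.exposure_names, estimates):
        d = est.to_dict()
        d["exposure"] = name
        rows.append(d)
    cols = ["exposure", "method", "n_snp", "beta", "se", "pvalue", "or", "ci_low", "ci_high"]
    return pd.DataFrame(rows)[cols]
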