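"""Instrument selection and strength: significance filter, LD clumping, r², F.

A valid MR instrument must be robustly associated with the exposure
(conventionally P < 5e-8), and instruments must be mutually independent so
that the inverse-variance weights are correct — hence greedy LD clumping at a
stringent r² within a genomic window (defaults r² = 0.001 within 5 000 kb).
Instrument strength is summarized by the variance in the exposure a variant
explains and the corresponding F statistic; F > 10 is the usual rule of thumb
for negligible weak-instrument bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValueUnavailableError
from .sumstats import SummaryStatRecord, SummaryStatSet

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation matrix over a panel of variants."""

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match variant count")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_tsv(cls, path: str | Path, fmt: str = "square") -> "LDMatrix":
        """Load from TSV; ``square`` (id-labelled matrix with a POS column
        optional) or ``long`` (columns id1, id2, r2 — positions all zero)."""
        path = Path(path)
        if fmt == "square":
            df = pd.read_csv(path, sep="\t", index_col=0)
            pos = (
                df.pop("POS").to_numpy(dtype=np.int64)
                if "POS" in df.columns
                else np.zeros(len(df), dtype=np.int64)
            )
            return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), pos)
        if fmt == "long":
            df = pd.read_csv(path, sep="\t")
            ids = sorted(set(df["id1"].astype(str)) | set(df["id2"].astype(str)))
            index = {v: i for i, v in enumerate(ids)}
            mat = np.eye(len(ids))
            for row in df.itertuples(index=False):
                i, j = index[str(row.id1)], index[str(row.id2)]
                mat[i, j] = mat[j, i] = float(row.r2)
            return cls(ids, mat, np.zeros(len(ids), dtype=np.int64))
        raise ValueError(f"unknown LD matrix format {fmt!r}")

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)
        df.insert(0, "POS", self.positions)
        path = Path(path)
        df.to_csv(path, sep="\t", lineterminator="\n")
        return path


@dataclass
class InstrumentSet:
    """Per-variant strength summaries for a selected instrument panel.

    ``r2_explained`` is each variant's share of exposure variance; ``f_stat``
    the per-variant F (single-instrument convention, K = 1). ``joint_f``
    applies the same F formula to the summed r² with K = panel size.
    """

    variant_ids: list[str]
    r2_explained: np.ndarray
    f_stat: np.ndarray
    k: int
    n_exposure: int

    def __post_init__(self) -> None:
        self.r2_explained = np.asarray(self.r2_explained, dtype=float)
        self.f_stat = np.asarray(self.f_stat, dtype=float)
        if self.k != len(self.variant_ids):
            raise ValueError("k must equal the number of variants")

    @property
    def joint_f(self) -> float:
        if self.k == 0:
            return math.nan
        total_r2 = float(np.nansum(self.r2_explained))
        return f_statistic(total_r2, self.n_exposure, self.k)


def select_significant(sset: SummaryStatSet, p_threshold: float = 5e-8) -> SummaryStatSet:
    """Variants with p strictly below the genome-wide threshold, order preserved."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    keep = sset.table["P"] < p_threshold
    return SummaryStatSet(sset.trait_name, sset.trait_type, sset.table[keep])


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def clump(
    candidates: SummaryStatSet,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 5000.0,
) -> SummaryStatSet:
    """Greedy LD clumping: keep the most significant variant, discard its
    same-chromosome neighbours within ``window_kb`` having r² > ``r2_max``,
    repeat. Ties on p are broken by chromosome, position, then variant ID.
    Returns the kept variants sorted by chromosome and position.
    """
    tab = candidates.table
    missing = [v for v in tab["SNP"] if v not in ld]
    if missing:
        raise ConfigurationError(
            f"variant {missing[0]!r} absent from the LD matrix "
            f"({len(missing)} candidates missing in total)"
        )
    rows = sorted(
        tab.itertuples(index=False),
        key=lambda r: (r.P, _chrom_key(r.CHR), r.POS, r.SNP),
    )
    window_bp = window_kb * 1000.0
    kept = []
    remaining = list(rows)
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        remaining = [
            r
            for r in remaining
            if not (
                r.CHR == lead.CHR
                and abs(r.POS - lead.POS) <= window_bp
                and ld.r2_between(r.SNP, lead.SNP) > r2_max
            )
        ]
    kept.sort(key=lambda r: (_chrom_key(r.CHR), r.POS, r.SNP))
    return candidates.subset([r.SNP for r in kept])


def variance_explained(
    record: SummaryStatRecord, mode: str = "squared"
) -> float:
    """Share of exposure variance explained by one variant.

    With MAF = min(EAF, 1-EAF) and SD = SE * sqrt(N): mode ``"squared"``
    returns 2*MAF*(1-MAF)*(beta/SD)**2 (a proper variance share);
    ``"paper_verbatim"`` returns 2*MAF*(1-MAF)*(beta/SD), reproducing the
    unsquared printed form some reports use. Requires EAF and N.
    """
    return _variance_explained(record.eaf, record.beta, record.se, record.n, mode)


def _variance_explained(eaf: float, beta: float, se: float, n: float, mode: str) -> float:
    if mode not in ("squared", "paper_verbatim"):
        raise ValueError(f"unknown mode {mode!r}")
    if eaf is None or math.isnan(eaf):
        raise ValueUnavailableError("EAF required for variance explained")
    if n is None or n <= 0:
        raise ValueUnavailableError("sample size required for variance explained")
    maf = min(eaf, 1.0 - eaf)
    sd = se * math.sqrt(n)
    ratio = beta / sd
    base = 2.0 * maf * (1.0 - maf)
    return base * ratio * ratio if mode == "squared" else base * ratio


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F: ((n - k - 1)/k) * (r2 / (1 - r2))."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("require n > k + 1 >= 2")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def instrument_strength(
    sset: SummaryStatSet, mode: str = "squared"
) -> InstrumentSet:
    """Per-variant r² and single-instrument F for a selected panel.

    Variants lacking EAF (or a usable N) get NaN strength with a logged
    warning; they still count toward ``k``.
    """
    r2 = np.full(len(sset), np.nan)
    f = np.full(len(sset), np.nan)
    n_exp = int(sset.table["N"].max()) if len(sset) else 0
    n_missing = 0
    for i, rec in enumerate(sset.records()):
        try:
            r2[i] = _variance_explained(rec.eaf, rec.beta, rec.se, rec.n, mode)
            f[i] = f_statistic(min(r2[i], 1 - 1e-15), rec.n, 1) if r2[i] >= 0 else np.nan
        except ValueUnavailableError:
            n_missing += 1
    if n_missing:
        logger.warning(
            "%s: %d instruments lack EAF/N; strength unavailable for them",
            sset.trait_name, n_missing,
        )
    return InstrumentSet(
        variant_ids=sset.variant_ids,
        r2_explained=r2,
        f_stat=f,
        k=len(sset),
        n_exposure=n_exp,
    )


def filter_weak(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Retain instruments with per-variant F strictly greater than ``f_min``."""
    if f_min < 0:
        raise ValueError("f_min must be >= 0")
    with np.errstate(invalid="ignore"):
        keep = instruments.f_stat > f_min
    idx = np.flatnonzero(keep)
    return InstrumentSet(
        variant_ids=[instruments.variant_ids[i] for i in idx],
        r2_explained=instruments.r2_explained[idx],
        f_stat=instruments.f_stat[idx],
        k=len(idx),
        n_exposure=instruments.n_exposure,
    )
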