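"""GWAS summary-statistics I/O, validation, and allele harmonization.

Every trait enters the workflow as a :class:`SummaryStatSet`: one row per
variant with the canonical columns ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N``
(effect allele ``EA``, other allele ``OA``, effect-allele frequency ``EAF``;
``BETA`` is the per-allele effect, on the log-odds scale for binary traits).
Two-sample MR combines per-variant effects estimated in different cohorts, so
before any estimator runs the outcome effects must be expressed relative to the
exposure's effect allele — that is :func:`harmonize`.

Strand-ambiguous (palindromic) variants, whose alleles are complementary
(A/T or C/G), cannot be aligned from allele labels alone; they are retained
only when the allele frequencies in both cohorts agree on which allele is the
minor one and are far enough from 0.5 to make that call reliable.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPairError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: Columns that must be present; EAF may be absent (filled with NaN).
REQUIRED_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "EAF"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Reverse-strand complement of an allele string (A<->T, C<->G)."""
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def is_palindromic(ea: str, oa: str) -> bool:
    """True when the two alleles are strand complements of each other (A/T, C/G)."""
    return complement(ea) == oa


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from a source file layout to the canonical layout.

    ``columns`` maps canonical name -> source column name. ``effect_scale``
    is ``"beta"`` for effects reported directly, or ``"odds_ratio"`` when the
    effect column holds odds ratios (converted to log-odds on read).
    """

    columns: Mapping[str, str]
    effect_scale: str = "beta"


DIALECTS: dict[str, Dialect] = {
    "generic": Dialect({c: c for c in CANONICAL_COLUMNS}),
    "odds_ratio": Dialect(
        {**{c: c for c in CANONICAL_COLUMNS}, "BETA": "OR"}, effect_scale="odds_ratio"
    ),
}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when unavailable
    beta: float
    se: float
    pvalue: float
    n: int


@dataclass
class SummaryStatSet:
    """A validated per-variant association table for a single trait.

    ``trait_type`` is ``"continuous"`` or ``"binary"`` (binary effects are
    log-odds). Variant IDs are unique within a set.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"missing canonical columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["SNP"].tolist()

    def records(self) -> Iterator[SummaryStatRecord]:
        for row in self.table.itertuples(index=False):
            yield SummaryStatRecord(
                variant_id=row.SNP,
                chromosome=row.CHR,
                position=int(row.POS),
                effect_allele=row.EA,
                other_allele=row.OA,
                eaf=float(row.EAF) if pd.notna(row.EAF) else math.nan,
                beta=float(row.BETA),
                se=float(row.SE),
                pvalue=float(row.P),
                n=int(row.N),
            )

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatSet":
        """Row subset by variant ID, preserving the requested order."""
        idx = self.table.set_index("SNP", drop=False)
        sub = idx.loc[list(variant_ids)].reset_index(drop=True)
        return replace(self, table=sub)

    def checksum(self) -> str:
        """SHA-256 of the canonical TSV serialization (for run manifests)."""
        return hashlib.sha256(to_tsv_bytes(self)).hexdigest()


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating per-record invariants; return kept rows and counts."""
    drops: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)

    def mark(mask: pd.Series, reason: str) -> None:
        bad = mask & keep
        n = int(bad.sum())
        if n:
            drops[reason] = n
            keep[bad] = False

    valid_allele = df["EA"].str.fullmatch(r"[ACGT]+") & df["OA"].str.fullmatch(r"[ACGT]+")
    mark(~valid_allele.fillna(False), "invalid_allele")
    mark(df["EA"] == df["OA"], "identical_alleles")
    mark(~(df["SE"] > 0) | ~np.isfinite(df["SE"]), "nonpositive_se")
    mark(~np.isfinite(df["BETA"]), "nonfinite_beta")
    mark(~((df["P"] > 0) & (df["P"] <= 1)), "invalid_pvalue")
    mark(df["EAF"].notna() & ~((df["EAF"] > 0) & (df["EAF"] < 1)), "invalid_eaf")
    mark(~(df["N"] > 0), "invalid_n")
    mark(~(df["POS"] > 0), "invalid_position")
    mark(df["SNP"].duplicated(), "duplicate_id")

    return df[keep].reset_index(drop=True), drops


def read_sumstats(
    path: str | Path,
    dialect: str | Dialect = "generic",
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStatSet:
    """Read a TSV of GWAS summary statistics into a validated set.

    Rows violating record invariants (SE <= 0, p outside (0, 1], identical or
    non-ACGT alleles, EAF outside (0, 1), duplicate IDs, ...) are dropped and
    the counts logged. ``dialect`` selects a named column mapping from
    :data:`DIALECTS` or is a :class:`Dialect` instance; odds-ratio dialects
    convert the effect column to log-odds.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise SchemaError(f"unknown dialect {dialect!r}") from None
    try:
        raw = pd.read_csv(
            path, sep="\t", na_values=["NA"],
            dtype={dialect.columns.get("CHR", "CHR"): str},
        )
    except OSError as exc:
        raise OSError(f"cannot read summary statistics from {path}: {exc}") from exc

    df = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        src = dialect.columns.get(canon, canon)
        if src not in raw.columns:
            if canon == "EAF":
                df[canon] = np.nan
                continue
            raise SchemaError(f"column {src!r} (for {canon}) absent from {path.name}")
        df[canon] = raw[src]

    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    for col in ("EAF", "BETA", "SE", "P"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["POS"] = pd.to_numeric(df["POS"], errors="coerce").fillna(-1).astype(np.int64)
    df["N"] = pd.to_numeric(df["N"], errors="coerce").fillna(-1).astype(np.int64)

    if dialect.effect_scale == "odds_ratio":
        with np.errstate(invalid="ignore", divide="ignore"):
            df["BETA"] = np.log(df["BETA"])

    clean, drops = _validate(df)
    if drops:
        logger.warning(
            "%s: dropped %d invalid rows (%s)",
            path.name,
            sum(drops.values()),
            ", ".join(f"{k}={v}" for k, v in sorted(drops.items())),
        )
    return SummaryStatSet(
        trait_name=trait_name or path.stem, trait_type=trait_type, table=clean
    )


def to_tsv_bytes(sset: SummaryStatSet) -> bytes:
    """Canonical TSV serialization (UTF-8, NA for missing, LF line ends)."""
    return sset.table[CANONICAL_COLUMNS].to_csv(
        sep="\t", index=False, na_rep="NA", lineterminator="\n"
    ).encode()


def write_sumstats(sset: SummaryStatSet, path: str | Path) -> Path:
    """Write the canonical TSV layout; round-trips through :func:`read_sumstats`."""
    path = Path(path)
    path.write_bytes(to_tsv_bytes(sset))
    return path


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effects on the shared variants.

    After harmonization every outcome effect refers to the exposure's effect
    allele; ``flipped`` records where the outcome coding was reversed and
    ``dropped`` lists excluded variants as ``(variant_id, reason)``.
    """

    exposure_name: str
    outcome_name: str
    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf_exposure: np.ndarray = field(default=None)  # type: ignore[assignment]
    flipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        n = len(self.variant_ids)
        if self.eaf_exposure is None:
            self.eaf_exposure = np.full(n, np.nan)
        self.eaf_exposure = np.asarray(self.eaf_exposure, dtype=float)
        if self.flipped is None:
            self.flipped = np.zeros(n, dtype=bool)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        lengths = {
            n,
            self.beta_exposure.size,
            self.se_exposure.size,
            self.beta_outcome.size,
            self.se_outcome.size,
            self.eaf_exposure.size,
            self.flipped.size,
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors have inconsistent lengths")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def subset(self, indices: Sequence[int]) -> "HarmonizedPair":
        idx = np.asarray(indices, dtype=int)
        return HarmonizedPair(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf_exposure=self.eaf_exposure[idx],
            flipped=self.flipped[idx],
            dropped=list(self.dropped),
        )


def _align_alleles(
    ref_ea: str,
    ref_oa: str,
    ea: str,
    oa: str,
    eaf_ref: float,
    eaf: float,
    palindrome_eaf_limit: float,
) -> tuple[bool, str] | tuple[None, str]:
    """Decide how a record's alleles map onto a reference coding.

    Returns ``(flip, "")`` when reconcilable (flip=True means the record's
    effect refers to the reference *other* allele, so its beta sign and EAF
    must be reversed), or ``(None, reason)`` when the variant must be dropped.
    """
    if is_palindromic(ref_ea, ref_oa):
        # For palindromic variants label pairs on opposite strands coincide,
        # so only the frequencies can anchor the alignment.
        if (ea, oa) == (ref_ea, ref_oa):
            flip = False
        elif (ea, oa) == (ref_oa, ref_ea):
            flip = True
        else:
            return None, "allele_mismatch"
        if math.isnan(eaf_ref) or math.isnan(eaf):
            return None, "palindromic_ambiguous"
        aligned_eaf = 1.0 - eaf if flip else eaf
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        same_side_low = eaf_ref < lo and aligned_eaf < lo
        same_side_high = eaf_ref > hi and aligned_eaf > hi
        if same_side_low or same_side_high:
            return flip, ""
        return None, "palindromic_ambiguous"

    if (ea, oa) == (ref_ea, ref_oa):
        return False, ""
    if (ea, oa) == (ref_oa, ref_ea):
        return True, ""
    cea, coa = complement(ea), complement(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return False, ""
    if (cea, coa) == (ref_oa, ref_ea):
        return True, ""
    return None, "allele_mismatch"


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect-allele coding.

    Variants are matched by ID. When the outcome's alleles are swapped
    (directly or on the opposite strand) relative to the exposure, the outcome
    beta sign is flipped and its EAF replaced by 1 - EAF. Palindromic variants
    are retained only when both cohorts' aligned EAFs fall on the same side of
    0.5 and outside ``[limit, 1 - limit]``; otherwise they are dropped with
    reason ``"palindromic_ambiguous"``. Irreconcilable allele pairs are dropped
    with reason ``"allele_mismatch"``.
    """
    merged = exposure.table.merge(
        outcome.table, on="SNP", how="inner", suffixes=("_exp", "_out")
    )
    if merged.empty:
        raise EmptyPairError(
            f"{exposure.trait_name} and {outcome.trait_name} share no variants"
        )

    ids: list[str] = []
    bx: list[float] = []
    sx: list[float] = []
    by: list[float] = []
    sy: list[float] = []
    eaf: list[float] = []
    flips: list[bool] = []
    dropped: list[tuple[str, str]] = []

    for row in merged.itertuples(index=False):
        eaf_exp = float(row.EAF_exp) if pd.notna(row.EAF_exp) else math.nan
        eaf_out = float(row.EAF_out) if pd.notna(row.EAF_out) else math.nan
        flip, reason = _align_alleles(
            row.EA_exp, row.OA_exp, row.EA_out, row.OA_out,
            eaf_exp, eaf_out, palindrome_eaf_limit,
        )
        if flip is None:
            dropped.append((row.SNP, reason))
            continue
        ids.append(row.SNP)
        bx.append(float(row.BETA_exp))
        sx.append(float(row.SE_exp))
        by.append(-float(row.BETA_out) if flip else float(row.BETA_out))
        sy.append(float(row.SE_out))
        eaf.append(eaf_exp)
        flips.append(flip)

    if dropped:
        logger.info(
            "harmonize(%s, %s): dropped %d of %d shared variants",
            exposure.trait_name, outcome.trait_name, len(dropped), len(merged),
        )
    return HarmonizedPair(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        variant_ids=ids,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        eaf_exposure=np.array(eaf),
        flipped=np.array(flips, dtype=bool),
        dropped=dropped,
    )
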