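"""Synthetic three-trait GWAS summary statistics under a known structural model.

The generator emulates the summary-level inputs of a two-step mediation MR
study — an exposure, a mediator, and a binary outcome (log-odds scale) — so
every stage of the workflow can be exercised against known truth without any
external GWAS. The structural model is

    exposure  X:  per-variant effects gamma_j (its instruments)
    mediator  M:  M = a*X + its own genetics (gamma_mediator on a second
                  chromosome) + noise
    outcome   Y:  Y = direct*X + b*M + per-variant pleiotropy + noise

so the marginal (GWAS) effects are gamma_j on X, a*gamma_j on M,
(direct + a*b)*gamma_j (+ pleiotropy) on Y at the exposure's instruments, and
gamma_mediator_j on M, b*gamma_mediator_j on Y at the mediator's. The implied
total effect is c = direct + a*b and the true proportion mediated a*b/c.

Estimation noise is added per variant with the standard GWAS scaling
SE = 1/sqrt(2*MAF*(1-MAF)*N), independently across the three traits (three
non-overlapping cohorts). The LD matrix is block-diagonal with a constant
within-block r², so clumping behaviour is easy to verify exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import CANONICAL_COLUMNS, SummaryStatSet

_BLOCK_SPACING_BP = 10_000_000  # keeps distinct blocks outside any clumping window
_WITHIN_BLOCK_BP = 1_000


@dataclass
class StructuralModel:
    """True parameters of the exposure -> mediator -> outcome system.

    Defaults describe a realistic desk-scale study: 60 exposure and 40
    mediator instruments with per-allele effects of magnitude 0.03-0.10
    (genome-wide significant at the default cohort sizes), cohorts of
    100k/35k/500k, moderate mediation (a = 0.3, b = 0.2, direct = 0.05 on the
    log-odds scale), no pleiotropy and no LD unless requested.
    """

    n_variants: int = 60           # exposure instruments
    n_mediator_variants: int = 40  # mediator-specific instruments
    n_exposure: int = 100_000
    n_mediator: int = 35_000
    n_outcome: int = 500_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma: np.ndarray | None = None           # drawn if None
    gamma_mediator: np.ndarray | None = None  # drawn if None
    effect_low: float = 0.03   # |effect| range when gamma is drawn
    effect_high: float = 0.10
    a_true: float = 0.3
    b_true: float = 0.2
    direct_true: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_variants < 1 or self.n_mediator_variants < 0:
            raise ValueError("variant counts must be positive")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) < 10:
            raise ValueError("sample sizes implausibly small")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.ld_block_size < 1 or not 0 <= self.ld_r2 <= 1:
            raise ValueError("invalid LD block configuration")

    @property
    def c_true(self) -> float:
        """Implied total exposure -> outcome effect, direct + a*b."""
        return self.direct_true + self.a_true * self.b_true

    @property
    def proportion_true(self) -> float:
        """True proportion mediated a*b/c (NaN when c = 0)."""
        c = self.c_true
        return (self.a_true * self.b_true) / c if c != 0 else math.nan


@dataclass
class SimulatedStudy:
    """Generated summary statistics plus the realized model that produced them."""

    exposure: SummaryStatSet
    mediator: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    model: StructuralModel  # with gamma / gamma_mediator realized

    @property
    def truth(self) -> dict[str, float]:
        m = self.model
        return {
            "a_true": m.a_true,
            "b_true": m.b_true,
            "direct_true": m.direct_true,
            "c_true": m.c_true,
            "proportion_true": m.proportion_true,
        }


def _draw_effects(rng: np.random.Generator, k: int, lo: float, hi: float) -> np.ndarray:
    return rng.uniform(lo, hi, k) * rng.choice([-1.0, 1.0], k)


def _marginal_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _positions(k: int, block_size: int) -> np.ndarray:
    idx = np.arange(k)
    return 1_000_000 + (idx // block_size) * _BLOCK_SPACING_BP + (idx % block_size) * _WITHIN_BLOCK_BP


def _block_ld(k: int, block_size: int, r2: float) -> np.ndarray:
    mat = np.eye(k)
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        mat[start:stop, start:stop] = r2
    np.fill_diagonal(mat, 1.0)
    return mat


def _trait_table(
    ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    eaf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    maf = np.minimum(eaf, 1.0 - eaf)
    se = _marginal_se(maf, n)
    beta = true_beta + se * rng.standard_normal(len(ids))
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "SNP": ids,
            "CHR": chrom,
            "POS": pos,
            "EA": "A",
            "OA": "G",
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )[CANONICAL_COLUMNS]


def simulate_sumstats(model: StructuralModel) -> SimulatedStudy:
    """Generate exposure/mediator/outcome summary statistics and an LD matrix.

    Deterministic for a given model (the seed is a model field). Exposure
    instruments sit on chromosome 1, mediator-specific instruments on
    chromosome 2; blocks within a chromosome are spaced far beyond any
    realistic clumping window.
    """
    rng = np.random.default_rng(model.seed)
    kx, km = model.n_variants, model.n_mediator_variants
    k = kx + km

    maf = rng.uniform(model.maf_range[0], model.maf_range[1], k)
    eaf = np.where(rng.random(k) < 0.5, maf, 1.0 - maf)

    gamma = (
        np.asarray(model.gamma, dtype=float)
        if model.gamma is not None
        else _draw_effects(rng, kx, model.effect_low, model.effect_high)
    )
    if gamma.shape != (kx,):
        raise ValueError("gamma length must equal n_variants")
    gmed = (
        np.asarray(model.gamma_mediator, dtype=float)
        if model.gamma_mediator is not None
        else _draw_effects(rng, km, model.effect_low, model.effect_high)
    )
    if gmed.shape != (km,):
        raise ValueError("gamma_mediator length must equal n_mediator_variants")

    pleio = np.zeros(k)
    if model.pleiotropy_sd > 0 or model.pleiotropy_mean != 0:
        pleio = model.pleiotropy_mean + model.pleiotropy_sd * rng.standard_normal(k)

    true_x = np.concatenate([gamma, np.zeros(km)])
    true_m = np.concatenate([model.a_true * gamma, gmed])
    true_y = (
        np.concatenate([model.c_true * gamma, model.b_true * gmed]) + pleio
    )

    ids = [f"rs{i + 1}" for i in range(k)]
    chrom = np.concatenate([np.repeat("1", kx), np.repeat("2", km)])
    pos = np.concatenate(
        [_positions(kx, model.ld_block_size), _positions(km, model.ld_block_size)]
    ).astype(np.int64)

    exposure = SummaryStatSet(
        "exposure", "continuous",
        _trait_table(ids, chrom, pos, eaf, true_x, model.n_exposure, rng),
    )
    mediator = SummaryStatSet(
        "mediator", "continuous",
        _trait_table(ids, chrom, pos, eaf, true_m, model.n_mediator, rng),
    )
    outcome = SummaryStatSet(
        "outcome", "binary",
        _trait_table(ids, chrom, pos, eaf, true_y, model.n_outcome, rng),
    )

    ld_blocks = np.eye(k)
    ld_blocks[:kx, :kx] = _block_ld(kx, model.ld_block_size, model.ld_r2)
    ld_blocks[kx:, kx:] = _block_ld(km, model.ld_block_size, model.ld_r2)
    ld = LDMatrix(ids, ld_blocks, pos)

    realized = replace(model, gamma=gamma, gamma_mediator=gmed)
    return SimulatedStudy(exposure, mediator, outcome, ld, realized)


def make_masking_scenario(base: StructuralModel) -> StructuralModel:
    """A variant of ``base`` whose indirect effect opposes its total effect.

    The mediated path a*b is re-signed against the direct effect and the
    direct effect scaled (if needed) so |direct| > |a*b|; the total effect
    c = direct + a*b then takes the direct effect's sign while the indirect
    effect opposes it — the mediator masks part of the direct effect.
    """
    a = base.a_true if base.a_true != 0 else 0.3
    b = abs(base.b_true) if base.b_true != 0 else 0.2
    direct = abs(base.direct_true) if base.direct_true != 0 else 0.05
    b = -b if a > 0 else b  # force a*b < 0 while direct > 0
    ab = a * b
    if direct <= abs(ab):
        direct = 1.5 * abs(ab)
    return replace(base, a_true=a, b_true=b, direct_true=direct)


def simulate_screen_battery(
    effects: list[float],
    base: StructuralModel | None = None,
    seed: int = 0,
) -> tuple[list[SummaryStatSet], SummaryStatSet, LDMatrix]:
    """Independent exposure traits against one shared outcome GWAS.

    Trait ``i`` gets its own instrument block (variant IDs prefixed
    ``t{i}_``) and a total effect ``effects[i]`` on the outcome; the outcome
    tables are concatenated into a single summary-statistic set and the LD
    matrices combined block-diagonally. Used for forward/reverse screening
    tests and examples.
    """
    base = base or StructuralModel()
    ss = np.random.SeedSequence(seed)
    exposures: list[SummaryStatSet] = []
    outcome_tables: list[pd.DataFrame] = []
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    ld_pos: list[np.ndarray] = []
    for i, (eff, child) in enumerate(zip(effects, ss.spawn(len(effects)))):
        sub = replace(
            base,
            a_true=0.0,
            b_true=0.0,
            direct_true=eff,
            n_mediator_variants=0,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        sim = simulate_sumstats(sub)
        rename = {old: f"t{i}_{old}" for old in sim.ld.variant_ids}
        for sset, sink in ((sim.exposure, None), (sim.outcome, outcome_tables)):
            tab = sset.table.copy()
            tab["SNP"] = tab["SNP"].map(rename)
            if sink is None:
                exposures.append(SummaryStatSet(f"trait_{i}", sset.trait_type, tab))
            else:
                sink.append(tab)
        ld_ids.extend(rename[v] for v in sim.ld.variant_ids)
        ld_blocks.append(sim.ld.r2)
        ld_pos.append(sim.ld.positions)

    outcome = SummaryStatSet(
        "outcome", "binary", pd.concat(outcome_tables, ignore_index=True)
    )
    full = np.eye(len(ld_ids))
    at = 0
    for blk in ld_blocks:
        full[at : at + len(blk), at : at + len(blk)] = blk
        at += len(blk)
    ld = LDMatrix(ld_ids, full, np.concatenate(ld_pos))
    return exposures, outcome, ld


def simulate_null_targets(
    base: StructuralModel,
    n_targets: int,
    n_target_sample: int = 50_000,
    seed: int = 0,
) -> tuple[SummaryStatSet, list[SummaryStatSet]]:
    """One instrumented trait plus targets it has no effect on.

    The instrumented trait (e.g. a disease used as the exposure in a reverse
    screen) is simulated from ``base``; each target trait's effects at those
    variants are pure estimation noise. Screens of target traits against this
    exposure should flag ~alpha of them by chance alone.
    """
    sim = simulate_sumstats(replace(base, n_mediator_variants=0))
    exposure = sim.exposure
    tab = exposure.table
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    eaf = tab["EAF"].to_numpy()
    targets = []
    for j in range(n_targets):
        targets.append(
            SummaryStatSet(
                f"target_{j}",
                "continuous",
                _trait_table(
                    tab["SNP"].tolist(),
                    tab["CHR"].to_numpy(),
                    tab["POS"].to_numpy(),
                    eaf,
                    np.zeros(len(tab)),
                    n_target_sample,
                    rng,
                ),
            )
        )
    return exposure, targets
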