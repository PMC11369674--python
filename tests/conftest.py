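"""Shared fixtures: hand-built harmonized pairs and random-but-seeded fixtures.

The oracle implementations used to cross-check the estimators live in the
individual test modules; everything here only builds inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedPair, SummaryStatSet
from mrmediate.sumstats import CANONICAL_COLUMNS


def make_pair(bx, by, sy, sx=None, ids=None) -> HarmonizedPair:
    """Harmonized pair straight from effect vectors (tests' main entry)."""
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    by = np.broadcast_to(np.asarray(by, dtype=float), bx.shape).copy()
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape).copy()
    sx = np.broadcast_to(
        np.asarray(0.01 if sx is None else sx, dtype=float), bx.shape
    ).copy()
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    return HarmonizedPair(
        exposure_name="X",
        outcome_name="Y",
        variant_ids=list(ids),
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
    )


def random_pair(seed: int, n: int = 8) -> HarmonizedPair:
    """A realistic random fixture: strong instruments, noisy outcome effects."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.03, 0.12, n) * rng.choice([-1.0, 1.0], n)
    sx = rng.uniform(0.002, 0.006, n)
    sy = rng.uniform(0.002, 0.008, n)
    slope = rng.normal(0.1, 0.05)
    by = slope * bx + sy * rng.standard_normal(n)
    return make_pair(bx, by, sy, sx)


def make_sumstat_table(
    ids,
    beta,
    se,
    p=None,
    eaf=0.3,
    ea="A",
    oa="G",
    chrom="1",
    pos=None,
    n=100_000,
) -> pd.DataFrame:
    """Canonical summary-statistics table from vectors/scalars."""
    from scipy import stats

    k = len(ids)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), k)
    se = np.broadcast_to(np.asarray(se, dtype=float), k)
    if p is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.clip(2 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "SNP": ids,
            "CHR": np.broadcast_to(np.asarray(chrom, dtype=object), k),
            "POS": pos if pos is not None else np.arange(1, k + 1) * 100_000,
            "EA": np.broadcast_to(np.asarray(ea, dtype=object), k),
            "OA": np.broadcast_to(np.asarray(oa, dtype=object), k),
            "EAF": np.broadcast_to(np.asarray(eaf, dtype=float), k),
            "BETA": beta,
            "SE": se,
            "P": np.broadcast_to(np.asarray(p, dtype=float), k),
            "N": n,
        }
    )
    return df[CANONICAL_COLUMNS]


def make_set(name, table, trait_type="continuous") -> SummaryStatSet:
    return SummaryStatSet(name, trait_type, table)


@pytest.fixture
def simple_pair() -> HarmonizedPair:
    return make_pair(
        bx=[0.10, 0.08, -0.05, 0.12],
        by=[0.030, 0.026, -0.014, 0.035],
        sy=[0.004, 0.005, 0.003, 0.006],
        sx=[0.003, 0.003, 0.002, 0.004],
    )
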