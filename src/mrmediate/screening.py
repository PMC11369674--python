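"""End-to-end screening and mediation workflow.

Orchestrates the study design: a forward screen of many exposures against the
outcome, a forward screen of candidate mediators against the outcome, a
reverse screen (outcome as exposure) for reverse causation, pairwise
exposure -> mediator MR among the survivors, two-step mediation decomposition
for every triplet whose three links all pass the significance screen, and a
final multivariable MR over the surviving traits. Every stage consumes
validated :class:`~mrmediate.sumstats.SummaryStatSet` objects, so the whole
workflow runs identically on real GWAS files or on the synthetic generator.

Outputs are tidy TSV tables plus a YAML manifest recording every parameter,
seed, and input checksum; a fixed config and seed reproduce the output files
byte for byte.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .errors import EmptyPairError, MRMediateError
from .estimators import MREstimate, egger, ivw, simple_median, weighted_median
from .instruments import LDMatrix, clump, filter_weak, instrument_strength, select_significant
from .mediation import MediationResult, mediated_proportion_table, two_step_decompose
from .mvmr import build_mvmr_input, mvmr_ivw, mvmr_table
from .sensitivity import cochran_q, leave_one_out
from .sumstats import HarmonizedPair, SummaryStatSet, harmonize

logger = logging.getLogger(__name__)

_RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snp", "beta", "se", "pvalue",
    "or", "ci_low", "ci_high", "q", "q_df", "q_pvalue",
    "egger_intercept", "egger_intercept_pvalue", "selected", "skipped_reason",
]


@dataclass
class ScreenConfig:
    """Thresholds, significance level and seeds for the whole workflow."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 5000.0
    f_min: float = 10.0
    alpha: float = 0.05
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 1000
    seed: int = 0
    bh_correction: bool = False      # Benjamini-Hochberg on screen p-values (off: raw p)
    disjoint_instruments: bool = False  # drop exposure instruments from the mediator's set

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible runs")


def _derive_seed(base: int, *names: str) -> int:
    h = zlib.crc32("|".join(names).encode())
    return int((base * 1_000_003 + h) % (2**31))


@dataclass
class PairAnalysis:
    """Everything one exposure/outcome analysis produced (or why it was skipped)."""

    exposure_name: str
    outcome_name: str
    pair: HarmonizedPair | None = None
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    q: float = float("nan")
    q_df: int = 0
    q_pvalue: float = float("nan")
    loo: pd.DataFrame | None = None
    skipped_reason: str | None = None

    @property
    def primary(self) -> MREstimate | None:
        return self.estimates.get("ivw") or self.estimates.get("wald")


def analyze_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    cfg: ScreenConfig,
    ld: LDMatrix | None = None,
    exclude_ids: set[str] | None = None,
) -> PairAnalysis:
    """Instrument selection, harmonization, all estimators and diagnostics for
    one exposure/outcome pair. Exposures without usable instruments come back
    with ``skipped_reason`` set instead of raising."""
    result = PairAnalysis(exposure.trait_name, outcome.trait_name)

    sel = select_significant(exposure, cfg.p_threshold)
    if exclude_ids:
        keep = ~sel.table["SNP"].isin(exclude_ids)
        sel = SummaryStatSet(sel.trait_name, sel.trait_type, sel.table[keep])
    if len(sel) == 0:
        result.skipped_reason = "no_significant_instruments"
        return result
    if ld is not None:
        sel = clump(sel, ld, cfg.clump_r2, cfg.clump_kb)
    if cfg.f_min > 0:
        strong = filter_weak(instrument_strength(sel), cfg.f_min)
        if strong.k == 0:
            result.skipped_reason = "no_strong_instruments"
            return result
        sel = sel.subset(strong.variant_ids)

    try:
        pair = harmonize(sel, outcome, cfg.palindrome_eaf_limit)
    except EmptyPairError:
        result.skipped_reason = "no_shared_variants"
        return result
    if pair.n_snp == 0:
        result.skipped_reason = "no_harmonized_variants"
        return result
    result.pair = pair

    result.estimates["ivw"] = ivw(pair)
    if pair.n_snp >= 2:
        result.q, result.q_df, result.q_pvalue = cochran_q(pair)
    if pair.n_snp >= 3:
        eg = egger(pair)
        result.estimates["egger_slope"] = eg.slope
        result.estimates["egger_intercept"] = eg.intercept
        med_seed = _derive_seed(cfg.seed, exposure.trait_name, outcome.trait_name)
        result.estimates["weighted_median"] = weighted_median(pair, cfg.n_boot, med_seed)
        result.estimates["simple_median"] = simple_median(pair, cfg.n_boot, med_seed + 1)
        result.loo = leave_one_out(pair, cfg.alpha)
    return result


def _screen_table(analyses: Sequence[PairAnalysis], cfg: ScreenConfig) -> pd.DataFrame:
    primary_p = np.array(
        [a.primary.pvalue if a.primary is not None else np.nan for a in analyses]
    )
    if cfg.bh_correction:
        ok = ~np.isnan(primary_p)
        adj = np.full_like(primary_p, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(primary_p[ok], method="bh")
        selected = adj < cfg.alpha
    else:
        selected = primary_p < cfg.alpha

    rows = []
    for a, sel in zip(analyses, selected):
        base = {
            "exposure": a.exposure_name,
            "outcome": a.outcome_name,
            "q": a.q,
            "q_df": a.q_df,
            "q_pvalue": a.q_pvalue,
            "egger_intercept": a.estimates["egger_intercept"].beta
            if "egger_intercept" in a.estimates
            else np.nan,
            "egger_intercept_pvalue": a.estimates["egger_intercept"].pvalue
            if "egger_intercept" in a.estimates
            else np.nan,
            "selected": bool(sel) if a.skipped_reason is None else False,
            "skipped_reason": a.skipped_reason or "",
        }
        if a.skipped_reason is not None:
            rows.append({**base, "method": "", "n_snp": 0, "beta": np.nan,
                         "se": np.nan, "pvalue": np.nan, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        for est in a.estimates.values():
            rows.append({**base, **est.to_dict()})
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def _run_screen(
    exposures: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    cfg: ScreenConfig,
    ld: LDMatrix | None = None,
) -> tuple[pd.DataFrame, list[PairAnalysis]]:
    analyses = [analyze_pair(exp, outcome, cfg, ld) for exp in exposures]
    return _screen_table(analyses, cfg), analyses


def forward_screen(
    exposures: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    cfg: ScreenConfig,
    ld: LDMatrix | None = None,
) -> pd.DataFrame:
    """Screen many exposures against one outcome.

    Per exposure: instrument selection, harmonization, all estimators and
    diagnostics; the ``selected`` column marks exposures whose primary (IVW)
    p-value passes ``cfg.alpha`` (Benjamini-Hochberg-adjusted when
    ``cfg.bh_correction``). Exposures without instruments appear as skipped
    rows, not errors.
    """
    table, _ = _run_screen(exposures, outcome, cfg, ld)
    return table


def reverse_screen(
    outcome_as_exposure: SummaryStatSet,
    targets: Sequence[SummaryStatSet],
    cfg: ScreenConfig,
    ld: LDMatrix | None = None,
) -> pd.DataFrame:
    """Reverse-causation screen: the outcome trait plays the exposure role
    against each target trait. Same table layout as :func:`forward_screen`."""
    analyses = [analyze_pair(outcome_as_exposure, t, cfg, ld) for t in targets]
    return _screen_table(analyses, cfg)


@dataclass
class WorkflowResult:
    """All tables from one mediation-workflow run plus its manifest."""

    screen_exposures: pd.DataFrame
    screen_mediators: pd.DataFrame
    pair_screen: pd.DataFrame
    mediation: pd.DataFrame
    mediation_results: list[MediationResult]
    mvmr: pd.DataFrame
    loo: pd.DataFrame
    manifest: dict

    _TABLES = {
        "screen_results.tsv": "screen_exposures",
        "screen_mediators.tsv": "screen_mediators",
        "pair_screen.tsv": "pair_screen",
        "mediation.tsv": "mediation",
        "mvmr.tsv": "mvmr",
        "loo.tsv": "loo",
    }

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write every table as TSV plus ``run_manifest.yaml``; deterministic
        formatting so identical runs produce byte-identical files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for fname, attr in self._TABLES.items():
            path = out / fname
            getattr(self, attr).to_csv(
                path, sep="\t", index=False, na_rep="NA",
                float_format="%.12g", lineterminator="\n",
            )
            paths.append(path)
        manifest_path = out / "run_manifest.yaml"
        manifest_path.write_text(
            yaml.safe_dump(self.manifest, sort_keys=True, default_flow_style=False)
        )
        paths.append(manifest_path)
        return paths


def run_mediation_workflow(
    exposures: Sequence[SummaryStatSet],
    mediators: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    cfg: ScreenConfig,
    ld: LDMatrix | None = None,
    out_dir: str | Path | None = None,
) -> WorkflowResult:
    """The full two-step mediation study on summary statistics.

    Stages: forward screen of exposures and of mediators against the outcome;
    pairwise exposure -> mediator MR among survivors; two-step decomposition
    for triplets whose three links all pass ``cfg.alpha``; multivariable MR
    over all surviving traits. Returns every table plus a manifest; with
    ``out_dir`` the tables are also written to disk.
    """
    exp_table, exp_analyses = _run_screen(exposures, outcome, cfg, ld)
    med_table, med_analyses = _run_screen(mediators, outcome, cfg, ld)

    exp_selected = {
        a.exposure_name: a
        for a in exp_analyses
        if a.primary is not None and a.primary.pvalue < cfg.alpha
    }
    med_selected = {
        a.exposure_name: a
        for a in med_analyses
        if a.primary is not None and a.primary.pvalue < cfg.alpha
    }
    exp_by_name = {s.trait_name: s for s in exposures}
    med_by_name = {s.trait_name: s for s in mediators}

    pair_rows = []
    mediation_results: list[MediationResult] = []
    for exp_name, exp_a in exp_selected.items():
        for med_name, med_a in med_selected.items():
            link = analyze_pair(exp_by_name[exp_name], med_by_name[med_name], cfg, ld)
            a_est = link.primary
            pair_rows.append(
                {
                    "exposure": exp_name,
                    "mediator": med_name,
                    "n_snp": a_est.n_snp if a_est else 0,
                    "beta": a_est.beta if a_est else np.nan,
                    "se": a_est.se if a_est else np.nan,
                    "pvalue": a_est.pvalue if a_est else np.nan,
                    "selected": bool(a_est and a_est.pvalue < cfg.alpha),
                    "skipped_reason": link.skipped_reason or "",
                }
            )
            if a_est is None or a_est.pvalue >= cfg.alpha:
                continue
            b_analysis = med_a
            if cfg.disjoint_instruments and exp_a.pair is not None:
                b_analysis = analyze_pair(
                    med_by_name[med_name], outcome, cfg, ld,
                    exclude_ids=set(exp_a.pair.variant_ids),
                )
            if b_analysis.primary is None:
                continue
            mediation_results.append(
                two_step_decompose(
                    exp_a.primary,
                    a_est,
                    b_analysis.primary,
                    exposure=exp_name,
                    mediator=med_name,
                    outcome=outcome.trait_name,
                    alpha=cfg.alpha,
                )
            )
    pair_screen = pd.DataFrame(
        pair_rows,
        columns=["exposure", "mediator", "n_snp", "beta", "se", "pvalue",
                 "selected", "skipped_reason"],
    )
    mediation_tab = mediated_proportion_table(mediation_results)

    surviving = [exp_by_name[n] for n in exp_selected] + [med_by_name[n] for n in med_selected]
    if len(surviving) >= 2:
        try:
            mv_inp = build_mvmr_input(
                surviving, outcome, ld, cfg.p_threshold, cfg.clump_r2,
                cfg.clump_kb, cfg.palindrome_eaf_limit,
            )
            mv_tab = mvmr_table(mv_inp, mvmr_ivw(mv_inp))
        except MRMediateError as exc:
            logger.warning("MVMR stage skipped: %s", exc)
            mv_tab = pd.DataFrame(
                columns=["exposure", "method", "n_snp", "beta", "se", "pvalue",
                         "or", "ci_low", "ci_high"]
            )
    else:
        mv_tab = pd.DataFrame(
            columns=["exposure", "method", "n_snp", "beta", "se", "pvalue",
                     "or", "ci_low", "ci_high"]
        )

    loo_rows = []
    for a in exp_analyses + med_analyses:
        if a.loo is not None:
            loo = a.loo.copy()
            loo.insert(0, "exposure", a.exposure_name)
            loo.insert(1, "outcome", a.outcome_name)
            loo_rows.append(loo)
    loo_tab = (
        pd.concat(loo_rows, ignore_index=True)
        if loo_rows
        else pd.DataFrame(
            columns=["exposure", "outcome", "left_out_variant_id", "n_snp",
                     "beta", "se", "pvalue", "sign_change",
                     "significance_change", "flagged"]
        )
    )

    manifest = {
        "package_version": __version__,
        "parameters": asdict(cfg),
        "inputs": {
            "outcome": {outcome.trait_name: outcome.checksum()},
            "exposures": {s.trait_name: s.checksum() for s in exposures},
            "mediators": {s.trait_name: s.checksum() for s in mediators},
        },
        "counts": {
            "exposures_screened": len(exposures),
            "mediators_screened": len(mediators),
            "exposures_selected": len(exp_selected),
            "mediators_selected": len(med_selected),
            "triplets_decomposed": len(mediation_results),
        },
    }

    result = WorkflowResult(
        screen_exposures=exp_table,
        screen_mediators=med_table,
        pair_screen=pair_screen,
        mediation=mediation_tab,
        mediation_results=mediation_results,
        mvmr=mv_tab,
        loo=loo_tab,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
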