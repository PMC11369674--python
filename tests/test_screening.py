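"""The orchestrated screening + mediation workflow on synthetic batteries."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest
import yaml

from mrmediate import (
    ScreenConfig,
    StructuralModel,
    forward_screen,
    make_masking_scenario,
    reverse_screen,
    run_mediation_workflow,
    simulate_null_targets,
    simulate_screen_battery,
    simulate_sumstats,
)

SMALL = StructuralModel(n_variants=15)


@pytest.fixture(scope="module")
def battery():
    # 12 exposure traits, the first 4 with real effects on the outcome
    effects = [0.1, 0.08, -0.09, 0.12] + [0.0] * 8
    exposures, outcome, ld = simulate_screen_battery(effects, SMALL, seed=31)
    return effects, exposures, outcome, ld


class TestForwardScreen:
    def test_true_positives_all_flagged(self, battery):
        effects, exposures, outcome, ld = battery
        cfg = ScreenConfig(seed=1, n_boot=100)
        table = forward_screen(exposures, outcome, cfg, ld)
        ivw_rows = table[table["method"].str.startswith("ivw")]
        flagged = set(ivw_rows[ivw_rows["selected"]]["exposure"])
        truly_causal = {f"trait_{i}" for i, e in enumerate(effects) if e != 0}
        assert truly_causal <= flagged

    def test_alpha_one_flags_everything_with_instruments(self, battery):
        _, exposures, outcome, ld = battery
        cfg = ScreenConfig(seed=1, n_boot=100, alpha=1.0)
        table = forward_screen(exposures, outcome, cfg, ld)
        with_instruments = table[table["skipped_reason"] == ""]
        assert with_instruments["selected"].all()

    def test_exposure_without_instruments_skipped(self, battery):
        _, exposures, outcome, ld = battery
        weak = exposures[0].table.copy()
        weak["P"] = 0.5  # nothing genome-wide significant
        weak_set = dataclasses.replace(exposures[0], trait_name="weak", table=weak)
        cfg = ScreenConfig(seed=1, n_boot=100)
        table = forward_screen([weak_set], outcome, cfg, ld)
        assert len(table) == 1
        assert table.loc[0, "skipped_reason"] == "no_significant_instruments"
        assert not table.loc[0, "selected"]

    def test_estimator_and_diagnostic_columns_populated(self, battery):
        _, exposures, outcome, ld = battery
        cfg = ScreenConfig(seed=1, n_boot=100)
        table = forward_screen(exposures[:1], outcome, cfg, ld)
        assert set(table["method"]) == {
            "ivw_random", "egger_slope", "egger_intercept",
            "weighted_median", "simple_median",
        }
        assert table["q_pvalue"].notna().all()
        assert table["egger_intercept_pvalue"].notna().all()

    def test_bh_correction_never_flags_more(self, battery):
        _, exposures, outcome, ld = battery
        raw = forward_screen(exposures, outcome, ScreenConfig(seed=1, n_boot=100), ld)
        bh = forward_screen(
            exposures, outcome, ScreenConfig(seed=1, n_boot=100, bh_correction=True), ld
        )
        assert bh["selected"].sum() <= raw["selected"].sum()


class TestReverseScreen:
    def test_null_targets_flagged_near_alpha(self):
        exposure, targets = simulate_null_targets(SMALL, n_targets=100, seed=13)
        cfg = ScreenConfig(seed=2, n_boot=100)
        table = reverse_screen(exposure, targets, cfg)
        ivw_rows = table[table["method"].str.startswith("ivw")]
        rate = ivw_rows["selected"].mean()
        assert 0.0 <= rate <= 0.12  # ~alpha, binomial noise on 100 traits

    def test_injected_reverse_effect_flagged(self):
        sim = simulate_sumstats(dataclasses.replace(SMALL, n_variants=20, seed=19))
        # the mediator is causally downstream of the exposure trait here,
        # so it serves as a genuine positive control for a reverse screen
        cfg = ScreenConfig(seed=2, n_boot=100)
        table = reverse_screen(sim.exposure, [sim.mediator], cfg)
        assert table[table["method"].str.startswith("ivw")]["selected"].all()

    def test_empty_target_list(self):
        exposure, _ = simulate_null_targets(SMALL, n_targets=0, seed=13)
        table = reverse_screen(exposure, [], ScreenConfig(seed=2))
        assert len(table) == 0


class TestMediationWorkflow:
    @pytest.fixture(scope="class")
    @staticmethod
    def mediated_run(tmp_path_factory):
        sim = simulate_sumstats(StructuralModel(seed=23))
        cfg = ScreenConfig(seed=3, n_boot=100)
        out = tmp_path_factory.mktemp("wf")
        result = run_mediation_workflow(
            [sim.exposure], [sim.mediator], sim.outcome, cfg, sim.ld, out_dir=out
        )
        return sim, result, out

    def test_true_mediated_path_recovered(self, mediated_run):
        sim, result, _ = mediated_run
        assert len(result.mediation) == 1
        row = result.mediation.iloc[0]
        assert row["classification"] == "mediation"
        truth_pct = 100 * sim.truth["proportion_true"]
        half_width = (row["ci_high_pct"] - row["ci_low_pct"]) / 2
        # within ~4 SEs of the truth (coverage itself is checked over many
        # replicates elsewhere)
        assert abs(row["proportion_pct"] - truth_pct) < 2 * half_width

    def test_manifest_records_inputs_and_parameters(self, mediated_run):
        sim, result, out = mediated_run
        manifest = yaml.safe_load((Path(out) / "run_manifest.yaml").read_text())
        assert manifest["parameters"]["p_threshold"] == 5e-8
        assert manifest["parameters"]["seed"] == 3
        checksum = manifest["inputs"]["exposures"]["exposure"]
        assert checksum == sim.exposure.checksum()
        assert manifest["counts"]["triplets_decomposed"] == 1

    def test_all_output_tables_written(self, mediated_run):
        _, _, out = mediated_run
        names = {p.name for p in Path(out).iterdir()}
        assert {
            "screen_results.tsv", "screen_mediators.tsv", "pair_screen.tsv",
            "mediation.tsv", "mvmr.tsv", "loo.tsv", "run_manifest.yaml",
        } <= names

    def test_mvmr_table_has_one_row_per_surviving_trait(self, mediated_run):
        _, result, _ = mediated_run
        assert set(result.mvmr["exposure"]) == {"exposure", "mediator"}

    def test_masking_scenario_classified_masking(self):
        mod = dataclasses.replace(make_masking_scenario(StructuralModel()), seed=29)
        sim = simulate_sumstats(mod)
        cfg = ScreenConfig(seed=4, n_boot=100)
        result = run_mediation_workflow(
            [sim.exposure], [sim.mediator], sim.outcome, cfg, sim.ld
        )
        assert list(result.mediation["classification"]) == ["masking"]

    def test_no_surviving_triplet_gives_empty_mediation_table(self):
        # no mediated or direct path: the mediator never associates with the outcome
        mod = StructuralModel(a_true=0.0, b_true=0.0, direct_true=0.1, seed=37)
        sim = simulate_sumstats(mod)
        cfg = ScreenConfig(seed=5, n_boot=100)
        result = run_mediation_workflow(
            [sim.exposure], [sim.mediator], sim.outcome, cfg, sim.ld
        )
        assert len(result.mediation) == 0
        assert result.manifest["counts"]["triplets_decomposed"] == 0

    def test_end_to_end_byte_reproducibility(self, tmp_path):
        sim = simulate_sumstats(StructuralModel(n_variants=25, seed=41))
        cfg = ScreenConfig(seed=6, n_boot=100)
        digests = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_mediation_workflow(
                [sim.exposure], [sim.mediator], sim.outcome, cfg, sim.ld, out_dir=out
            )
            digests.append(
                [hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(out.iterdir())]
            )
        assert digests[0] == digests[1]

    def test_disjoint_instruments_option_runs(self):
        sim = simulate_sumstats(StructuralModel(n_variants=25, seed=43))
        cfg = ScreenConfig(seed=7, n_boot=100, disjoint_instruments=True)
        result = run_mediation_workflow(
            [sim.exposure], [sim.mediator], sim.outcome, cfg, sim.ld
        )
        assert len(result.mediation) <= 1
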