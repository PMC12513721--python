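"""Sweep driver, outcome tables, serialisation and the CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import coevosim as cs
from coevosim import io as cio
from coevosim.cli import main as cli_main

TINY = dict(K=300, T_end=12.0)


class TestSweep:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            cs.SweepSpec(alpha0_grid=[], beta0_grid=[0.1])
        with pytest.raises(ValueError):
            cs.SweepSpec(alpha0_grid=[0.01], beta0_grid=[0.1], n_replicates=0)

    def test_log_grid_spacing(self):
        g = cs.SweepSpec.log_grid(1e-3, 1e-1, 3)
        assert np.allclose(g, [1e-3, 1e-2, 1e-1])

    def test_single_replicate_proportions_are_binary(self):
        spec = cs.SweepSpec(alpha0_grid=[0.01], beta0_grid=[0.01],
                            n_replicates=1, base_seed=7, overrides=TINY)
        res = cs.run_ensemble(spec, with_neutral_reference=False)
        row = res.table.iloc[0]
        for col in ("p_extinct", "p_slow", "p_no_suppression"):
            assert row[col] in (0.0, 1.0)

    def test_outcome_table_contract(self):
        spec = cs.SweepSpec(alpha0_grid=[0.005, 0.05], beta0_grid=[0.01, 0.3],
                            n_replicates=6, base_seed=11, overrides=TINY,
                            neutral_replicates=4)
        res = cs.run_ensemble(spec)
        tab = res.table
        assert len(tab) == 4
        assert np.allclose(
            tab.p_extinct + tab.p_slow + tab.p_no_suppression, 1.0)
        assert np.allclose(tab.p_suppressed, tab.p_extinct + tab.p_slow)
        assert ((0 <= tab.p_suppressed_lo) & (tab.p_suppressed_lo <=
                tab.p_suppressed) & (tab.p_suppressed <=
                tab.p_suppressed_hi) & (tab.p_suppressed_hi <= 1)).all()
        assert (tab.K == TINY["K"]).all()
        assert (tab.n_failed == 0).all()
        # W1 columns are finite wherever at least one tumour grew to K.
        grown = tab.p_no_suppression > 0
        assert np.isfinite(tab.W1_antigenic[grown]).all()

    def test_replicate_seeding_is_order_independent(self):
        params = cs.ModelParams(lambda_=1.0, alpha0=0.01, beta0=0.05, **TINY)
        batch, _ = cs.run_replicates(params, 6, base_seed=50)
        shuffled = []
        for r in (4, 0, 5, 2, 1, 3):
            single, _ = cs.run_replicates(params, 1, base_seed=50,
                                          first_replicate=r)
            shuffled.append(single[0])
        key = lambda e: e["seed"]
        for a, b in zip(sorted(batch, key=key), sorted(shuffled, key=key)):
            assert a["outcome"] == b["outcome"]

    def test_rerun_reproduces_table_exactly(self):
        spec = cs.SweepSpec(alpha0_grid=[0.02], beta0_grid=[0.1],
                            n_replicates=4, base_seed=3, overrides=TINY)
        t1 = cs.run_ensemble(spec, with_neutral_reference=False).table
        t2 = cs.run_ensemble(spec, with_neutral_reference=False).table
        pd.testing.assert_frame_equal(t1, t2)


class TestIO:
    def test_trajectory_roundtrip(self, tmp_path):
        res = cs.run(cs.ModelParams(lambda_=1.0, **TINY), seed=2)
        path = tmp_path / "t.tsv"
        cio.write_trajectory(res.trajectory, path)
        back = cio.read_trajectory(path)
        assert np.allclose(back.times, res.trajectory.times)
        assert np.array_equal(back.C, res.trajectory.C)

    def test_histogram_roundtrip(self, tmp_path):
        h = cs.Histogram([0, 3, 5], [2.5, 1.0, 4.0])
        path = tmp_path / "h.tsv"
        cio.write_histogram(h, path, "k", "B_k", header_comment="MBD test")
        back = cio.read_histogram(path)
        assert np.array_equal(back.index, h.index)
        assert np.array_equal(back.counts, h.counts)

    def test_cells_roundtrip_preserves_classes(self, tmp_path):
        res = cs.run(cs.ModelParams(lambda_=3.0, p_a=0.4, **TINY), seed=4)
        path = tmp_path / "cells.tsv"
        cio.write_cells(res.state, path)
        back = cio.read_cells(path)
        orig = res.state.cells.values()
        assert cs.compute_mbd(back, "antigenic").mean == \
            cs.compute_mbd(orig, "antigenic").mean
        assert cs.total_occurrences(back, "neutral") == \
            cs.total_occurrences(orig, "neutral")


class TestCLI:
    def test_simulate_twice_is_byte_identical(self, tmp_path):
        runner = CliRunner()
        args = ["simulate", "--seed", "5", "--lambda", "1", "--k", "200",
                "--t-end", "8"]
        for prefix in ("a", "b"):
            out = runner.invoke(cli_main, args + ["--out-prefix",
                                                  str(tmp_path / prefix)])
            assert out.exit_code == 0, out.output
        for suffix in (".trajectory.tsv", ".meta.json"):
            a = (tmp_path / f"a{suffix}").read_bytes()
            b_raw = (tmp_path / f"b{suffix}").read_bytes()
            assert a == b_raw

    def test_unknown_config_key_is_hard_error(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("b: 1.0\nnot_a_parameter: 2\n")
        out = CliRunner().invoke(cli_main, ["simulate", "--config", str(cfg)])
        assert out.exit_code != 0
        assert "unknown parameter" in out.output

    def test_stats_on_neutral_run_yields_empty_antigenic_sfs(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "simulate", "--seed", "9", "--lambda", "1", "--p-a", "0",
            "--k", "200", "--t-end", "8", "--save-cells",
            "--out-prefix", str(tmp_path / "neutral")])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, [
            "stats", str(tmp_path / "neutral.cells.tsv"),
            "--mutation-class", "antigenic",
            "--out-prefix", str(tmp_path / "s")])
        assert out.exit_code == 0, out.output
        sfs = cio.read_histogram(tmp_path / "s.sfs.tsv")
        assert sfs.total == 0

    def test_cycles_command_reports_counts(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "simulate", "--seed", "12", "--lambda", "1", "--k", "500",
            "--out-prefix", str(tmp_path / "r")])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, [
            "cycles", str(tmp_path / "r.trajectory.tsv"),
            "--out", str(tmp_path / "cyc.json")])
        assert out.exit_code == 0, out.output
        payload = json.loads((tmp_path / "cyc.json").read_text())
        assert payload["cycles"]["n_cycles_total"] == \
            payload["cycles"]["n_ccw"] + payload["cycles"]["n_cw"]

    def test_sweep_command_writes_grid_table(self, tmp_path):
        out = CliRunner().invoke(cli_main, [
            "sweep", "--alpha0-grid", "0.005,0.05", "--beta0-grid", "0.1",
            "--replicates", "3", "--seed", "1", "--k", "200", "--t-end", "8",
            "--lambda", "1", "--no-neutral-ref",
            "--out", str(tmp_path / "sweep.tsv")])
        assert out.exit_code == 0, out.output
        tab = pd.read_csv(tmp_path / "sweep.tsv", sep="\t")
        assert len(tab) == 2
        assert {"alpha0", "beta0", "p_suppressed", "mean_end_time"} <= \
            set(tab.columns)
        assert (tmp_path / "sweep.manifest.json").exists()

    def test_lv_control_command(self, tmp_path):
        out = CliRunner().invoke(cli_main, [
            "lv-control", "--t", "4", "--seed", "2",
            "--out", str(tmp_path / "lv.tsv")])
        assert out.exit_code == 0, out.output
        tab = pd.read_csv(tmp_path / "lv.tsv", sep="\t")
        assert {"time", "prey", "predator"} == set(tab.columns)
        assert len(tab) > 100
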