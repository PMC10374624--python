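"""End-to-end pipeline behavior, file round-trips, and the CLI surface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from wormquant import io as wio
from wormquant import synth
from wormquant.cli import main
from wormquant.errors import ValidationError
from wormquant.pipelines import (EvokedRunConfig, SpontaneousRunConfig,
                                 run_evoked_pipeline,
                                 run_spontaneous_pipeline)


def _coupled_csv(path, shared_fraction=1.0, n_neurons=3, seed=1):
    traces, truth = synth.generate_coupled(
        synth.SpontaneousConfig(seed=seed),
        synth.CouplingConfig(n_neurons=n_neurons,
                             shared_fraction=shared_fraction))
    wio.write_traces_csv(path, traces)
    return truth


def _evoked_csv(path, drop_amp, drop_dur, n=3, noise=0.0):
    traces = []
    for i in range(n):
        raw, _ = synth.generate_evoked(synth.EvokedConfig(
            drop_amp=drop_amp, drop_dur_s=drop_dur, recovery_shape="step",
            duration_s=150, noise_sd=noise, seed=100 + i))
        raw.roi_label = f"roi_{i}"
        traces.append(raw)
    wio.write_traces_csv(path, traces)


class TestSpontaneousPipeline:
    def test_fully_coupled_set_high_r0(self, tmp_path):
        _coupled_csv(tmp_path / "traces.csv")
        cfg = SpontaneousRunConfig(traces_csv=str(tmp_path / "traces.csv"),
                                   out_dir=str(tmp_path / "out"))
        run_spontaneous_pipeline(cfg)
        xc = wio.read_table(tmp_path / "out" / "xcorr.csv")
        assert len(xc) == 3
        assert (xc["r0"] > 0.7).all()

    def test_rerun_byte_identical(self, tmp_path):
        _coupled_csv(tmp_path / "traces.csv", shared_fraction=0.5)
        cfg = SpontaneousRunConfig(traces_csv=str(tmp_path / "traces.csv"),
                                   out_dir=str(tmp_path / "out"))
        first = run_spontaneous_pipeline(cfg).outputs
        second = run_spontaneous_pipeline(cfg).outputs
        assert first == second

    def test_empty_roi_list_fails_before_stages(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("time_s\n0.0\n1.0\n")
        cfg = SpontaneousRunConfig(traces_csv=str(p),
                                   out_dir=str(tmp_path / "out"))
        with pytest.raises(ValidationError, match="ROI"):
            run_spontaneous_pipeline(cfg)
        assert not (tmp_path / "out").exists()

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValidationError, match="unknown keys"):
            SpontaneousRunConfig.from_mapping({"tracess_csv": "x"})


class TestEvokedPipeline:
    def test_training_effect_percentages(self, tmp_path):
        _evoked_csv(tmp_path / "naive.csv", -0.6, 60)
        _evoked_csv(tmp_path / "trained.csv", -0.3, 30)
        cfg = EvokedRunConfig(naive_csv=str(tmp_path / "naive.csv"),
                              trained_csv=str(tmp_path / "trained.csv"),
                              out_dir=str(tmp_path / "out"))
        run_evoked_pipeline(cfg)
        eff = wio.read_table(tmp_path / "out" / "training_effect.tsv",
                             sep="\t").iloc[0]
        assert eff["amp_change_pct"] == pytest.approx(-50.0, abs=0.5)
        assert eff["dur_change_pct"] == pytest.approx(-50.0, abs=1.0)

    def test_identical_groups_zero_change(self, tmp_path):
        _evoked_csv(tmp_path / "naive.csv", -0.5, 40)
        _evoked_csv(tmp_path / "trained.csv", -0.5, 40)
        cfg = EvokedRunConfig(naive_csv=str(tmp_path / "naive.csv"),
                              trained_csv=str(tmp_path / "trained.csv"),
                              out_dir=str(tmp_path / "out"))
        run_evoked_pipeline(cfg)
        eff = wio.read_table(tmp_path / "out" / "training_effect.tsv",
                             sep="\t").iloc[0]
        assert eff["amp_change_pct"] == pytest.approx(0.0, abs=1e-9)
        assert eff["dur_change_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_heatmap_order_sorts_by_descending_duration(self, tmp_path):
        traces = []
        for i, dur in enumerate((20, 60, 40)):
            raw, _ = synth.generate_evoked(synth.EvokedConfig(
                drop_amp=-0.5, drop_dur_s=dur, recovery_shape="step",
                duration_s=150, seed=i))
            raw.roi_label = f"roi_{i}"
            traces.append(raw)
        wio.write_traces_csv(tmp_path / "naive.csv", traces)
        wio.write_traces_csv(tmp_path / "trained.csv", traces)
        cfg = EvokedRunConfig(naive_csv=str(tmp_path / "naive.csv"),
                              trained_csv=str(tmp_path / "trained.csv"),
                              out_dir=str(tmp_path / "out"))
        run_evoked_pipeline(cfg)
        df = wio.read_table(tmp_path / "out" / "evoked_metrics.tsv", sep="\t")
        naive = df[df["condition"] == "naive"].sort_values("heatmap_order")
        assert list(naive["roi"]) == ["roi_1", "roi_2", "roi_0"]
        durs = list(naive["duration_s"])
        assert durs == sorted(durs, reverse=True)


class TestTraceCsvRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path):
        traces, _ = synth.generate_coupled(
            synth.SpontaneousConfig(seed=3),
            synth.CouplingConfig(n_neurons=2))
        p = tmp_path / "t.csv"
        wio.write_traces_csv(p, traces)
        back = wio.read_traces_csv(p)
        assert [t.roi_label for t in back] == ["roi_0", "roi_1"]
        for orig, rt in zip(traces, back):
            np.testing.assert_allclose(rt.f_total, orig.f_total, rtol=1e-12)

    def test_missing_values_rejected(self, tmp_path):
        p = tmp_path / "na.csv"
        p.write_text("time_s,roi_0\n0.0,1.0\n1.0,\n2.0,1.0\n")
        with pytest.raises(ValidationError, match="missing"):
            wio.read_table(p)


class TestCli:
    def test_simulate_correct_detect_chain(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, ["--quiet", "simulate", "spontaneous",
                                 "--out", str(tmp_path / "sim"),
                                 "--seed", "5"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["--quiet", "correct",
                                 str(tmp_path / "sim" / "traces.csv"),
                                 "--out", str(tmp_path / "corr.csv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["--quiet", "detect",
                                 str(tmp_path / "corr.csv"),
                                 "--out", str(tmp_path / "events.tsv")])
        assert r.exit_code == 0, r.output
        events = wio.read_table(tmp_path / "events.tsv", sep="\t")
        truth = pd.read_csv(tmp_path / "sim" / "truth.tsv", sep="\t",
                            comment="#")
        detectable = truth[truth["onset_s"] < 180 - 3]
        assert abs(len(events) - len(detectable)) <= 1

    def test_run_spontaneous_from_yaml(self, tmp_path):
        _coupled_csv(tmp_path / "traces.csv", n_neurons=2)
        cfgfile = tmp_path / "run.yaml"
        wio.write_yaml(cfgfile, {"traces_csv": str(tmp_path / "traces.csv"),
                                 "out_dir": str(tmp_path / "out")})
        r = CliRunner().invoke(main, ["--quiet", "run-spontaneous",
                                      "--config", str(cfgfile)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "stats.tsv").exists()

    def test_validation_error_exit_code_two(self, tmp_path):
        cfgfile = tmp_path / "bad.yaml"
        wio.write_yaml(cfgfile, {"not_a_key": 1})
        r = CliRunner().invoke(main, ["--quiet", "run-spontaneous",
                                      "--config", str(cfgfile)])
        assert r.exit_code == 2

    def test_behavior_ic50_subcommand(self, tmp_path):
        doses = np.array([0.0, 0.5, 1, 2, 5, 10, 20, 50])
        resp = synth.hill_response(doses, 150, 20, 5, 1.5)
        wio.write_table(tmp_path / "dr.csv",
                        pd.DataFrame({"dose_mM": doses, "response": resp}),
                        stage="test")
        r = CliRunner().invoke(main, ["--quiet", "behavior", "ic50",
                                      str(tmp_path / "dr.csv"),
                                      "--out", str(tmp_path / "fit.tsv")])
        assert r.exit_code == 0, r.output
        fit = wio.read_table(tmp_path / "fit.tsv", sep="\t").iloc[0]
        assert fit["ic50"] == pytest.approx(5.0, rel=1e-3)
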