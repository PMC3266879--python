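"""Closed-loop runner: schedule, determinism, configs, protocols, CLI."""

import json

import numpy as np
import pytest
import yaml

from eibstdp.plasticity import STDPRule
from eibstdp.runner import (
    ExperimentConfig,
    PopulationConfig,
    inhibitory_population_config,
    learning_rate_schedule,
    reproduce_figure,
    run_experiment,
    single_synapse_config,
)
from eibstdp.spikegen import CorrelationSpec


class TestLearningRateSchedule:
    def test_accelerated_starts_at_sixteen_fold(self):
        assert learning_rate_schedule(0.0, "accelerated") == pytest.approx(16e-3)

    def test_accelerated_ends_near_base(self):
        assert learning_rate_schedule(1.0, "accelerated") == pytest.approx(
            1e-3, rel=0.05
        )

    def test_trailing_seventy_percent_flat(self):
        vals = np.array([learning_rate_schedule(r, "accelerated") for r in
                         np.linspace(0.3, 1.0, 20)])
        # the trailing 70% of the run sits close to the base rate
        assert np.all(np.abs(vals / 1e-3 - 1) < 0.11)
        assert np.all(np.diff(vals) < 0)

    def test_constant_mode(self):
        assert learning_rate_schedule(0.7, "constant", base=2e-3) == 2e-3

    def test_domain_error(self):
        with pytest.raises(ValueError):
            learning_rate_schedule(1.5, "accelerated")
        with pytest.raises(ValueError):
            learning_rate_schedule(0.5, "bogus")


@pytest.fixture(scope="module")
def tiny_config():
    return single_synapse_config(w_probe=0.4, plastic=True, duration=20e3,
                                 seed=42)


class TestRunExperiment:
    def test_plasticity_disabled_keeps_weights_constant(self):
        cfg = single_synapse_config(w_probe=0.37, plastic=False,
                                    duration=15e3, seed=2, record=True)
        rec = run_experiment(cfg)
        assert np.all(rec.trajectory("probe") == 0.37)

    def test_bit_exact_reproducibility(self, tiny_config):
        a = run_experiment(tiny_config)
        b = run_experiment(tiny_config)
        assert a.content_hash() == b.content_hash()
        assert np.array_equal(a.weights, b.weights)

    def test_seed_changes_output(self, tiny_config):
        import dataclasses

        a = run_experiment(tiny_config)
        c = run_experiment(dataclasses.replace(tiny_config, seed=43))
        assert a.content_hash() != c.content_hash()

    def test_population_bookkeeping(self, tiny_config):
        rec = run_experiment(tiny_config)
        assert (rec.syn_population == "probe").sum() == 1
        assert rec.post_rate > 0
        assert rec.times[-1] == tiny_config.duration

    def test_plastic_population_requires_rule(self):
        with pytest.raises(ValueError, match="rule"):
            PopulationConfig("x", "I", CorrelationSpec([2], 10.0), plastic=True)

    def test_manifest_and_hdf5(self, tiny_config, tmp_path):
        rec = run_experiment(tiny_config)
        man = rec.manifest()
        assert man["seed"] == 42 and man["hash"]
        rec.to_hdf5(tmp_path / "rec.h5")
        import h5py

        with h5py.File(tmp_path / "rec.h5") as f:
            assert json.loads(f.attrs["manifest"])["hash"] == man["hash"]

    def test_linear_neuron_run(self):
        rule = STDPRule(1e-3, 0.8, 0.0, 20.0, "I")
        cfg = ExperimentConfig(
            populations=(
                PopulationConfig("inh", "I", CorrelationSpec([5], 10.0),
                                 plastic=True, rule=rule, initial_weights=0.02),
            ),
            duration=20e3, seed=3, neuron_model="linear", drive=100.0,
            delay=1.0, dt=1.0,
        )
        rec = run_experiment(cfg)
        assert rec.post_rate == pytest.approx(100.0, rel=0.2)


class TestYamlConfig:
    def test_roundtrip_and_run(self, tmp_path):
        from eibstdp.config import load_experiment_config

        doc = {
            "neuron_model": "lif",
            "duration_ms": 10e3,
            "seed": 7,
            "schedule": "accelerated",
            "scaling": {"n_exc": 100, "n_inh": 10},
            "populations": [
                {"name": "bgE", "sign": "E", "initial_weights": 0.5,
                 "inputs": {"groups": [100], "rate": 10.0}},
                {"name": "inh", "sign": "I", "plastic": True,
                 "initial_weights": "spread",
                 "inputs": {"groups": [5, 5], "rate": 10.0,
                            "within_corr": 0.2, "between_corr": 0.05},
                 "plasticity": {"lambda": 1e-3, "alpha": 0.8, "mu": 0.0,
                                "tau_ms": 20.0}},
            ],
        }
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(doc))
        cfg = load_experiment_config(path)
        assert cfg.seed == 7
        assert cfg.populations[1].spec.within_corr == (0.2, 0.2)
        rec = run_experiment(cfg)
        assert rec.weights.shape[1] == 10

        cfg2 = load_experiment_config(path, seed=9)
        assert cfg2.seed == 9

    def test_meanfield_model_from_yaml(self, tmp_path):
        from eibstdp.config import load_meanfield_model
        from eibstdp.meanfield import homogeneous_fixed_point

        doc = {
            "rate": 10.0, "drive": 100.0, "delay_ms": 1.0,
            "inh": {"n": 20,
                    "corr": {"groups": [20], "within_corr": 0.1},
                    "plasticity": {"lambda": 1e-3, "alpha": 0.8, "mu": 0.0}},
        }
        path = tmp_path / "model.yaml"
        path.write_text(yaml.safe_dump(doc))
        model = load_meanfield_model(path)
        fp = homogeneous_fixed_point(model)
        assert 0 < fp.weights["inh"] < 1


class TestReproduceFigure:
    def test_unknown_protocol_lists_available(self):
        with pytest.raises(ValueError, match="fig5"):
            reproduce_figure("fig99")

    def test_fig7_smoke_writes_artifacts(self, tmp_path):
        out = tmp_path / "fig7"
        res = reproduce_figure("fig7", scale=0.03, seed=1, out_dir=out)
        assert (out / "balance_points.csv").exists()
        man = json.loads((out / "manifest.json").read_text())
        assert man["protocol"] == "fig7" and man["scale"] == 0.03
        assert res["points"].shape[1] == 2

    def test_fig5_smoke(self, tmp_path):
        out = tmp_path / "fig5"
        res = reproduce_figure("fig5", scale=0.05, seed=1, out_dir=out)
        assert (out / "inhibitory_trajectories.csv").exists()
        assert 0 <= res["cv"]


class TestCLI:
    def test_run_command(self, tmp_path):
        from click.testing import CliRunner

        from eibstdp.cli import main

        doc = {
            "duration_ms": 5e3, "seed": 1,
            "scaling": {"n_exc": 50, "n_inh": 5},
            "populations": [
                {"name": "bgE", "sign": "E", "initial_weights": 0.5,
                 "inputs": {"groups": [50], "rate": 10.0}},
                {"name": "inh", "sign": "I", "plastic": True,
                 "initial_weights": 0.4,
                 "inputs": {"groups": [5], "rate": 10.0},
                 "plasticity": {"lambda": 1e-3, "alpha": 0.8}},
            ],
        }
        cfg = tmp_path / "run.yaml"
        cfg.write_text(yaml.safe_dump(doc))
        out = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg), "--seed", "5", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert (out / "run.h5").exists()
        assert json.loads((out / "manifest.json").read_text())["seed"] == 5

    def test_meanfield_sweep_command(self, tmp_path):
        import pandas as pd
        from click.testing import CliRunner

        from eibstdp.cli import main

        doc = {
            "rate": 10.0, "drive": 100.0, "delay_ms": 1.0,
            "inh": {"n": 20,
                    "corr": {"groups": [20], "within_corr": 0.1},
                    "plasticity": {"lambda": 1e-3, "alpha": 0.8, "mu": 0.0}},
        }
        cfg = tmp_path / "model.yaml"
        cfg.write_text(yaml.safe_dump(doc))
        out = tmp_path / "fp.csv"
        result = CliRunner().invoke(
            main,
            ["meanfield", "--config", str(cfg),
             "--sweep", "alpha=0.5:0.9:5", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert len(df) == 5
        assert np.all(np.diff(df["w_inh"]) < 0)   # higher alpha, lower weight
        assert df["stable"].all()

    def test_reproduce_unknown_errors(self):
        from click.testing import CliRunner

        from eibstdp.cli import main

        result = CliRunner().invoke(main, ["reproduce", "nope"])
        assert result.exit_code != 0
        assert "fig2" in result.output
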