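import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from c14growth import (
    ExperimentDesign,
    MCMCConfig,
    PriorSpec,
    Window,
    case_study_pipeline,
    run_experiment,
    simulate_dates,
    table1_designs,
    write_dates,
)
from c14growth.cli import main as cli_main
from c14growth.errors import ConfigError, InsufficientDataError
from c14growth.workbench import bp_to_bce, manifest


@pytest.fixture
def smoke_design():
    return ExperimentDesign(
        name="smoke",
        variant="exponential",
        true_params={"r": 0.003},
        window=Window(5400, 4600),
        n_dates=100,
        priors={"r": PriorSpec.exponential(500)},
        mcmc=MCMCConfig(n_chains=1, n_iterations=2500, n_burnin=500, thin=2),
        n_replicates=3,
    )


class TestDesigns:
    def test_yaml_roundtrip(self, smoke_design, tmp_path):
        path = tmp_path / "design.yaml"
        smoke_design.to_yaml(path)
        back = ExperimentDesign.from_yaml(path)
        assert back == smoke_design

    def test_table1_presets_cover_all_experiments(self):
        designs = table1_designs()
        assert {"exp1_r0.003", "exp2_plateau", "exp3a_n50", "exp3b_n500"} <= set(designs)
        # experiment 4: nine rate combinations at the case-study sample size
        exp4 = [d for k, d in designs.items() if k.startswith("exp4")]
        assert len(exp4) == 9
        assert all(d.n_dates == 288 and d.window == Window(3400, 1850) for d in exp4)
        # changepoint prior bounded by the experiment's own window
        c_prior = exp4[0].priors["c"]
        assert c_prior.params == (1851.0, 3399.0)

    def test_infeasible_changepoint_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentDesign(
                name="bad", variant="double_exponential",
                true_params={"r1": 0.001, "r2": 0.002, "c": 7000},
                window=Window(6000, 4000), n_dates=10,
                priors={"r1": PriorSpec.normal(0, 0.1), "r2": PriorSpec.normal(0, 0.1),
                        "c": PriorSpec.uniform(4001, 5999)},
                mcmc=MCMCConfig(n_iterations=10, n_burnin=0),
            )


class TestRunExperiment:
    def test_smoke_recovery(self, smoke_design, identity_curve):
        report = run_experiment(smoke_design, identity_curve, seed=1)
        assert len(report.table) == 3  # one free parameter x three replicates
        assert set(report.table["parameter"]) == {"r"}
        assert report.coverage_count("r") >= 2
        cov = report.coverage()
        assert cov.loc["r", "total"] == 3

    def test_covered_flag_consistent_with_bounds(self, smoke_design, identity_curve):
        report = run_experiment(smoke_design, identity_curve, seed=2)
        t = report.table
        manual = (t["truth"] >= t["hpd_lower"]) & (t["truth"] <= t["hpd_upper"])
        assert (manual == t["covered"]).all()

    def test_scale_shrinks_replicates(self, smoke_design, identity_curve):
        report = run_experiment(smoke_design, identity_curve, scale=1 / 3, seed=3)
        assert len(report.table) == 1

    def test_seeded_runs_reproducible(self, smoke_design, identity_curve):
        a = run_experiment(smoke_design, identity_curve, scale=1 / 3, seed=4)
        b = run_experiment(smoke_design, identity_curve, scale=1 / 3, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)


@pytest.fixture(scope="module")
def case_curve():
    from c14growth import synth_curve

    return synth_curve("identity", (1500, 4000), tau0=20.0)


@pytest.fixture(scope="module")
def case_result(case_curve):
    curve = case_curve
    w = Window(3400, 1850)
    rng = np.random.default_rng(77)
    samples = simulate_dates(
        "double_exponential", {"r1": -0.001, "r2": 0.003, "c": 2700}, w, 60,
        curve, 20.0, seed=rng,
    )
    df = pd.DataFrame(
        {"labcode": [s.labcode for s in samples], "c14age": [s.x for s in samples],
         "error": [s.sigma_lab for s in samples]}
    )
    # rows the hygiene filters must drop
    extra = pd.DataFrame(
        {"labcode": ["big-error", "", "no-age"],
         "c14age": [2500.0, 2500.0, np.nan],
         "error": [150.0, 20.0, 20.0]}
    )
    mcmc = MCMCConfig(n_chains=2, n_iterations=2000, n_burnin=500, thin=2)
    return case_study_pipeline(
        pd.concat([df, extra], ignore_index=True), curve, window=w,
        mcmc=mcmc, models=("m1", "m2"), n_ppc=40, waic_draws=100, seed=5,
    )


class TestCaseStudyPipeline:
    def test_hygiene_filters_drop_bad_rows(self, case_result):
        names = {s.labcode for s in case_result.samples}
        assert "big-error" not in names and "no-age" not in names and "" not in names

    def test_summary_table_shape(self, case_result):
        assert {"model", "parameter", "Rhat", "ESS", "Median", "HPD90lower", "HPD90upper"} <= set(case_result.summary.columns)
        assert set(case_result.summary["model"]) == {"m1", "m2"}
        m2 = case_result.summary[case_result.summary["model"] == "m2"]
        assert set(m2["parameter"]) == {"r1", "r2", "c"}

    def test_waic_table(self, case_result):
        assert len(case_result.waic_table) == 2
        assert case_result.waic_table["dWAIC"].iloc[0] == 0.0
        assert case_result.waic_table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_envelopes_attached(self, case_result):
        assert set(case_result.envelopes) == {"m1", "m2"}
        env = case_result.envelopes["m2"]
        assert env.observed is not None
        assert len(env.grid) == case_result.window.T + 1

    def test_growth_rate_estimate_plausible(self, case_result):
        m2 = case_result.summary[case_result.summary["model"] == "m2"].set_index("parameter")
        assert 0.0 < m2.loc["r2", "Median"] < 0.02

    def test_empty_after_filters_raises(self, case_curve):
        df = pd.DataFrame({"labcode": ["a"], "c14age": [150.0], "error": [20.0]})
        with pytest.raises(InsufficientDataError):
            case_study_pipeline(df, case_curve, window=(3400, 1850),
                                mcmc=MCMCConfig(n_iterations=100, n_burnin=10))


class TestHelpers:
    def test_bp_to_bce_convention(self):
        assert bp_to_bce(2664) == 715  # 2664 cal BP = 715 BCE

    def test_manifest_contents(self, identity_curve):
        m = manifest(7, config={"x": 1}, curve=identity_curve)
        assert m["seed"] == 7
        assert len(m["curve_sha256"]) == 64
        assert m == manifest(7, config={"x": 1}, curve=identity_curve)


class TestCLI:
    def test_simulate_then_calibrate_and_experiment(self, smoke_design, tmp_path):
        runner = CliRunner()
        design_path = tmp_path / "design.yaml"
        smoke_design.to_yaml(design_path)
        dates_path = tmp_path / "dates.csv"
        res = runner.invoke(cli_main, [
            "simulate", str(design_path), "--out", str(dates_path),
            "--curve", "identity:4000-6500", "--seed", "1",
        ])
        assert res.exit_code == 0, res.output
        assert len(pd.read_csv(dates_path)) == 100
        assert (tmp_path / "dates.csv.manifest.json").exists()

        spd_path = tmp_path / "spd.csv"
        res = runner.invoke(cli_main, [
            "calibrate", str(dates_path), "--out", str(spd_path),
            "--curve", "identity:4000-6500", "--window", "5400-4600",
        ])
        assert res.exit_code == 0, res.output
        spd_df = pd.read_csv(spd_path)
        assert spd_df["density"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_fit_and_compare_commands(self, smoke_design, tmp_path, identity_curve):
        runner = CliRunner()
        design_path = tmp_path / "design.yaml"
        smoke_design.to_yaml(design_path)
        samples = simulate_dates("exponential", {"r": 0.003}, smoke_design.window, 60, identity_curve, 20.0, seed=2)
        dates_path = tmp_path / "dates.csv"
        write_dates(samples, dates_path)
        post_path = tmp_path / "posterior.csv"
        res = runner.invoke(cli_main, [
            "fit", str(dates_path), "--out", str(post_path),
            "--curve", "identity:4000-6500", "--model", str(design_path), "--seed", "3",
        ])
        assert res.exit_code == 0, res.output
        post_df = pd.read_csv(post_path)
        assert {"chain", "r"} == set(post_df.columns)
        assert (tmp_path / "posterior.summary.csv").exists()

        # WAIC comparison of two toy log-likelihood matrices
        rng = np.random.default_rng(0)
        for name in ("mA", "mB"):
            pd.DataFrame(-rng.gamma(1, 1, size=(10, 4))).to_csv(tmp_path / f"{name}.csv", index=False)
        res = runner.invoke(cli_main, [
            "compare", str(tmp_path / "mA.csv"), str(tmp_path / "mB.csv"),
            "--out", str(tmp_path / "waic.csv"),
        ])
        assert res.exit_code == 0, res.output
        waic_df = pd.read_csv(tmp_path / "waic.csv")
        assert waic_df["weight"].sum() == pytest.approx(1.0, abs=1e-6)
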