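"""Orchestration: configs, coupled runs, fixtures, oracle suite, CLI."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from mwablate import SimulationConfig, driver
from mwablate.cli import main as cli_main


@pytest.fixture(scope="module")
def tiny_config(coarse_config):
    """Very short run for plumbing tests."""
    return coarse_config.replace(ablation_time=25.0, dt=2.5, input_power=15.0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path, tiny_config):
        p = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(p)
        again = SimulationConfig.from_yaml(p)
        assert again.to_dict() == tiny_config.to_dict()
        # provenance comments are part of the written schema
        assert "external literature" in p.read_text()

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(backend="comsol")
        with pytest.raises(ValueError):
            SimulationConfig(vaporization="magic")
        with pytest.raises(ValueError):
            SimulationConfig(ablation_time=-5.0)
        with pytest.raises(ValueError):
            SimulationConfig(input_power=-1.0)


class TestRunSimulation:
    def test_zero_power_run_is_inert(self, coarse_config, coarse_mesh):
        cfg = coarse_config.replace(input_power=0.0, ablation_time=10.0, dt=2.5)
        rep = driver.run_simulation(cfg, mesh=coarse_mesh)
        assert np.max(np.abs(rep.T - 37.0)) < 1e-9
        assert rep.final.tumor_coverage == 0.0
        assert rep.em_solves == 0

    def test_default_run_heats_and_reports(self, tiny_config, coarse_mesh, tmp_path):
        rep = driver.run_simulation(tiny_config, mesh=coarse_mesh, out_dir=tmp_path)
        assert rep.final.peak_temperature > 60.0
        assert rep.final.lethal_isotherm_volume > 0.0  # 60 degC contour nonempty
        assert rep.em_solves >= 1
        assert (tmp_path / "coverage.csv").exists()
        vtk = (tmp_path / "final_state.vtk").read_text()
        assert "temperature_C" in vtk and "UNSTRUCTURED_GRID" in vtk
        times = [m.time for m in rep.metrics]
        assert times == sorted(times) and len(set(times)) == len(times)

    def test_determinism(self, tiny_config, coarse_mesh):
        r1 = driver.run_simulation(tiny_config, mesh=coarse_mesh)
        r2 = driver.run_simulation(tiny_config, mesh=coarse_mesh)
        assert np.array_equal(r1.T, r2.T)
        assert np.array_equal(r1.Omega, r2.Omega)
        assert [m.tumor_coverage for m in r1.metrics] == [
            m.tumor_coverage for m in r2.metrics
        ]

    def test_empty_power_sweep_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            driver.power_sweep(tiny_config, [])

    def test_invalid_bisection_bracket(self, tiny_config, coarse_mesh):
        # 25 s at low powers cannot cover the tumor: bracket check must fire
        with pytest.raises(ValueError, match="bracket"):
            driver.optimal_power_search(
                tiny_config, 0.5, 1.0, coverage_target=1.0, tol_W=0.5, mesh=coarse_mesh
            )

    def test_zero_target_returns_lower_bracket(self, tiny_config, coarse_mesh):
        p, _ = driver.optimal_power_search(
            tiny_config, 4.0, 8.0, coverage_target=0.0, mesh=coarse_mesh
        )
        assert p == 4.0


class TestFixtures:
    def test_fixture_inventory(self, tmp_path):
        files = driver.make_fixtures(tmp_path, seed=11)
        names = sorted(f.name for f in files)
        assert sum(n.endswith("_ellipsoid.stl") for n in names) == 3
        assert sum(n.endswith("_lumpy.stl") for n in names) == 3
        assert sum(n.endswith(".yaml") for n in names) == 3

    def test_fixture_surfaces_are_valid_tumors(self, tmp_path):
        from mwablate import load_tumor_surface

        driver.make_fixtures(tmp_path, seed=11)
        t = load_tumor_surface(tmp_path / "hcc_a_ellipsoid.stl")
        semi = np.array(driver.FIXTURE_TUMOR_EXTENTS["hcc_a"]) / 2
        analytic = 4 / 3 * np.pi * semi.prod()
        assert t.volume == pytest.approx(analytic, rel=0.02)
        lumpy = load_tumor_surface(tmp_path / "hcc_a_lumpy.stl")
        assert lumpy.surface.is_watertight
        assert 0.7 * analytic < lumpy.volume < 1.4 * analytic

    def test_fixture_determinism(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        driver.make_fixtures(a, seed=3)
        driver.make_fixtures(b, seed=3)
        for f in sorted(a.iterdir()):
            assert f.read_bytes() == (b / f.name).read_bytes()

    def test_config_fixture_is_loadable(self, tmp_path):
        driver.make_fixtures(tmp_path, seed=0)
        cfg = SimulationConfig.from_yaml(tmp_path / "hcc_b.yaml")
        assert cfg.tumor.semi_axes[2] == pytest.approx(21.0e-3 / 2)

    def test_bad_path_raises(self, tmp_path):
        f = tmp_path / "not_a_dir"
        f.write_text("x")
        with pytest.raises((OSError, NotADirectoryError, FileExistsError)):
            driver.make_fixtures(f / "sub", seed=0)


class TestOracleSuite:
    def test_all_oracles_pass(self):
        """Release gate: every closed-form check holds at its tolerance."""
        report = driver.validate()
        failures = {k: v for k, v in report.items() if not v["passed"]}
        assert not failures, f"oracle failures: {failures}"

    def test_report_is_serializable(self):
        import json

        report = driver.validate()
        json.dumps(report)  # machine-readable summary

    def test_degraded_integrator_is_detected(self):
        """A deliberately coarsened Arrhenius step must miss the closed form."""
        from mwablate import damage as D

        p = D.DEFAULT_ARRHENIUS
        # one 600 s rectangle step on a rising trajectory vs the exact integral
        T = np.linspace(37.0, 100.0, 601)
        exact = np.trapezoid(p.rate(T), dx=1.0)
        coarse = 600.0 * p.rate(T[0])
        assert abs(coarse - exact) / exact > 0.5


class TestCLI:
    def test_validate_command(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["validate", "--json"])
        assert res.exit_code == 0
        assert '"passed": true' in res.output

    def test_fixtures_command(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["fixtures", str(tmp_path), "--seed", "2"])
        assert res.exit_code == 0
        assert (tmp_path / "hcc_c_lumpy.stl").exists()

    def test_run_command(self, tmp_path, tiny_config):
        cfgp = tmp_path / "c.yaml"
        tiny_config.to_yaml(cfgp)
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["run", str(cfgp), "--out", str(tmp_path / "out")]
        )
        assert res.exit_code == 0, res.output
        assert "coverage=" in res.output
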