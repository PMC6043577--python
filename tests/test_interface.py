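"""File formats, configuration validation, pipeline driver, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from nmrdyn.cli import main as cli_main
from nmrdyn.config import RunConfig, load_config
from nmrdyn.io import (
    read_dispersion_curves,
    read_peak_table,
    read_shift_table,
    write_dispersion_curves,
    write_peak_table,
    write_shift_table,
)
from nmrdyn.pipeline import run_pipeline
from nmrdyn.synthetic import (
    generate_dispersion_intensities,
    generate_temp_shift_series,
    generate_two_state_system,
)


class TestPeakTableIO:
    def test_roundtrip_identity(self, tmp_path, noiseless_truth):
        table = generate_dispersion_intensities(noiseless_truth, (66.7, 1000.0))
        path = tmp_path / "peaks.csv"
        write_peak_table(table, path)
        back = read_peak_table(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True),
            table[back.columns].reset_index(drop=True),
        )

    def test_negative_intensity_cites_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = ["residue_id,field_mhz,temp_k,condition,nu_cpmg_hz,intensity"]
        rows += [f"1,500,298,reference,0,100.0"]
        for i, nu in enumerate((66.7, 133.3, 200.0, 266.7, 333.3)):
            inten = -5.0 if i == 4 else 60.0
            rows.append(f"1,500,298,cpmg,{nu},{inten}")
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="line 7"):
            read_peak_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("residue_id,intensity\n1,5\n")
        with pytest.raises(ValueError, match="field_mhz"):
            read_peak_table(path)

    def test_twelve_frequency_design_parses(self, tmp_path):
        truth = generate_two_state_system(n_residues=2, noise_fraction=0.0,
                                          seed=1)
        table = generate_dispersion_intensities(truth)
        path = tmp_path / "t.csv"
        write_peak_table(table, path)
        back = read_peak_table(path)
        per_curve = back[back["nu_cpmg_hz"] > 0].groupby(
            ["residue_id", "field_mhz", "temp_k"]
        ).size()
        assert (per_curve == 12).all()


class TestShiftAndCurveIO:
    def test_shift_table_roundtrip(self, tmp_path):
        series = [generate_temp_shift_series(-4.0, (298.0, 303.0, 308.0),
                                             residue_id=r) for r in (1, 2)]
        path = tmp_path / "shifts.csv"
        write_shift_table(series, path)
        back = read_shift_table(path)
        assert [s.residue_id for s in back] == [1, 2]
        np.testing.assert_allclose(back[0].h_ppm, series[0].h_ppm)

    def test_dispersion_curve_roundtrip(self, tmp_path, noiseless_dataset):
        path = tmp_path / "curves.csv"
        write_dispersion_curves(noiseless_dataset.curves, path)
        back = read_dispersion_curves(path)
        assert len(back) == len(noiseless_dataset.curves)
        np.testing.assert_allclose(
            back[0].r2eff, noiseless_dataset.curves[0].r2eff
        )


class TestConfig:
    def test_defaults_echo_reference_constants(self):
        cfg = RunConfig()
        assert cfg.t_relax_s == 0.030
        assert cfg.error_floor == 0.03
        assert cfg.delta_r2eff_threshold == 5.0
        assert cfg.hetnoe_cut == 0.65
        assert cfg.tci_cut_ppb_per_k == -5.0
        assert cfg.kappa == 1.6e-7
        assert (cfg.probe_small, cfg.probe_large) == (1.3, 3.0)
        assert cfg.csp_alpha == 0.14

    def test_yaml_sections_and_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "dispersion:\n  t_relax_s: 0.04\nsimulation:\n  seed: 9\n"
        )
        cfg = load_config(path, {"seed": 11})
        assert cfg.t_relax_s == 0.04
        assert cfg.seed == 11  # CLI override wins

    def test_unknown_key_rejected_with_schema(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("dispersion:\n  t_relaxx: 0.04\n")
        with pytest.raises(ValueError, match="valid keys"):
            load_config(path)

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("dispersionn:\n  t_relax_s: 0.04\n")
        with pytest.raises(ValueError, match="valid sections"):
            load_config(path)


@pytest.fixture(scope="module")
def pipeline_report(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(output_dir=str(out), seed=1, n_residues=22,
                    n_fit_starts=1)
    return run_pipeline(cfg), out


class TestPipeline:

    def test_all_stages_complete(self, pipeline_report):
        rep, _ = pipeline_report
        assert rep["errors"] == []
        for stage in ("dispersion", "thermo", "relaxation", "tempcoeff",
                      "titration", "cavity"):
            assert rep["stages"][stage]["status"] == "ok"

    def test_recovered_kinetics_match_truth(self, pipeline_report):
        rep, _ = pipeline_report
        entry = rep["stages"]["dispersion"]
        for t, kex_true in entry["truth_kex"].items():
            assert entry["fitted_kex"][t] == pytest.approx(kex_true, rel=0.15)

    def test_report_echoes_every_config_value(self, pipeline_report):
        rep, _ = pipeline_report
        assert rep["config"]["error_floor"] == 0.03
        assert rep["config"]["kappa"] == 1.6e-7
        assert set(rep["config"]) >= {
            "t_relax_s", "delta_r2eff_threshold", "hetnoe_cut",
            "tci_cut_ppb_per_k", "probe_small", "probe_large", "csp_alpha",
            "seed",
        }

    def test_outputs_written(self, pipeline_report):
        _, out = pipeline_report
        for name in ("report.json", "report.md", "peak_table.csv",
                     "dispersion_curves.csv", "fit_params.csv", "thermo.csv",
                     "cavity.json"):
            assert (out / name).exists()

    def test_determinism_byte_identical_outputs(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            cfg = RunConfig(output_dir=str(out), seed=5, n_residues=4,
                            n_fit_starts=1, run_cavity=False)
            run_pipeline(cfg)
            outs.append(out)
        for name in ("peak_table.csv", "dispersion_curves.csv",
                     "fit_params.csv", "thermo.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()
        # reports identical apart from the differing output paths
        reps = [json.loads((o / "report.json").read_text()) for o in outs]
        for rep in reps:
            rep["config"].pop("output_dir")
        assert reps[0] == reps[1]

    def test_stage_failure_does_not_block_independent_stages(self, tmp_path):
        cfg = RunConfig(output_dir=str(tmp_path / "f"), seed=1,
                        peak_table=str(tmp_path / "missing.csv"),
                        run_cavity=True, run_titration=True)
        rep = run_pipeline(cfg)
        assert rep["stages"]["dispersion"]["status"] == "failed"
        assert rep["stages"]["thermo"]["status"] == "skipped"
        assert rep["stages"]["titration"]["status"] == "ok"
        assert rep["stages"]["cavity"]["status"] == "ok"


class TestCli:
    def test_simulate_writes_peak_table(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "simulate", "--seed", "3", "--out", str(tmp_path / "sim"),
        ])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sim" / "peak_table.csv").exists()

    def test_cavity_subcommand_reports_volume(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "cavity", "--out", str(tmp_path / "cav"),
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads(
            (tmp_path / "cav" / "cavity.json").read_text()
        )
        assert payload["cavity_volume_A3"] > 1900.0
        assert payload["small_probe_A"] == 1.3
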