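"""File-format, configuration and CLI tests."""

from __future__ import annotations

import json

import numpy as np
import pytest

from corneafit.airpuff import DeformationRecord
from corneafit.cli import cli
from corneafit.errors import CapabilityError, ConfigurationError, ParseError
from corneafit.interface import (
    RunConfig,
    dump_json,
    load_config,
    read_deformation_record,
    write_deformation_record,
)
from corneafit.metrics import compute_metrics


@pytest.fixture()
def toy_record() -> DeformationRecord:
    t = np.linspace(0.0, 30.0, 11)
    x = np.linspace(-4.0, 4.0, 33)
    a = np.sin(np.pi * t / 30.0) ** 2
    ref = 9.15 - x**2 / 18.0
    heights = ref[None, :] - a[:, None] * 1.1 * np.exp(-(x**2) / 4.0)
    return DeformationRecord(
        times=t, x=x, apex_trace=a * 1.1, heights=heights, ref_height=ref
    )


class TestRecordIO:
    def test_full_roundtrip_is_exact(self, tmp_path, toy_record):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(toy_record, sp, tp)
        back = read_deformation_record(sp, tp)
        assert np.abs(back.heights - toy_record.heights).max() <= 1e-12
        assert np.abs(back.apex_trace - toy_record.apex_trace).max() <= 1e-12
        assert np.array_equal(back.x, toy_record.x)

    def test_reduced_roundtrip_and_capability_contract(self, tmp_path, toy_record):
        reduced = DeformationRecord(
            times=toy_record.times, x=toy_record.x,
            apex_trace=toy_record.apex_trace,
            hc_displacement=toy_record.displacement_at_hc(),
        )
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(reduced, sp, tp)
        back = read_deformation_record(sp, tp)
        assert back.is_reduced
        m_red = compute_metrics(back)
        m_full = compute_metrics(toy_record)
        assert m_red.da == pytest.approx(m_full.da, abs=1e-12)
        assert m_red.pda == pytest.approx(m_full.pda, abs=1e-12)
        with pytest.raises(CapabilityError):
            back.displacement_profiles()

    def test_nonmonotone_time_rejected_with_line_number(self, tmp_path, toy_record):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(toy_record, sp, tp)
        lines = tp.read_text().splitlines()
        lines[4], lines[5] = lines[5], lines[4]  # swap two time samples
        tp.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError) as exc:
            read_deformation_record(sp, tp)
        assert exc.value.line is not None

    def test_ragged_row_rejected(self, tmp_path, toy_record):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(toy_record, sp, tp)
        text = sp.read_text().splitlines()
        text[5] = text[5] + ",0.1"
        sp.write_text("\n".join(text) + "\n")
        with pytest.raises(ParseError):
            read_deformation_record(sp, tp)

    def test_wrong_header_rejected(self, tmp_path, toy_record):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(toy_record, sp, tp)
        sp.write_text("x_mm,height_mm\n0,1\n")
        with pytest.raises(ParseError):
            read_deformation_record(sp, tp)


class TestConfig:
    def test_defaults_build_valid_domain_objects(self):
        cfg = RunConfig()
        geom = cfg.geometry.build()
        assert geom.anterior_radius == pytest.approx(9.15)
        load = cfg.load.build()
        assert load.peak_pressure == pytest.approx(0.0045)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("geometry:\n  thicknesss_mm: 0.45\n")
        with pytest.raises(ConfigurationError):
            load_config(p)

    def test_yaml_overrides_applied(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(
            "geometry:\n  thickness_mm: 0.35\niop_mmhg: 20\nseed: 3\n"
            "material:\n  c10_mpa: 0.04\n  c01_mpa: 0.02\n"
        )
        cfg = load_config(p)
        assert cfg.geometry.build().anterior_radius == pytest.approx(8.95)
        assert cfg.iop_mmhg == 20
        assert cfg.material.build().c10 == 0.04

    def test_dump_json_rounds_and_sorts(self, tmp_path):
        p = tmp_path / "o.json"
        dump_json({"b": 1 / 3, "a": np.float64(2.0)}, p)
        data = json.loads(p.read_text())
        assert list(data) == ["a", "b"]
        assert data["b"] == pytest.approx(1 / 3, rel=1e-11)


class TestCli:
    def test_metrics_command_emits_table2_parameters(self, tmp_path, toy_record):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_deformation_record(toy_record, sp, tp)
        out = tmp_path / "m.json"
        code = cli(["metrics", "--spatial", str(sp), "--temporal", str(tp),
                    "--out", str(out)])
        assert code == 0
        data = json.loads(out.read_text())
        assert set(data) == {"DA_mm", "PDA_mm", "CPR", "THC_ms"}

    def test_invalid_geometry_config_exits_2(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "geometry:\n  thickness_mm: 0.55\n  anterior_radius_mm: 9.5\n"
            "material:\n  c10_mpa: 0.03\n  c01_mpa: 0.015\n"
        )
        assert cli(["simulate", "--config", str(p), "--out", str(tmp_path / "o")]) == 2

    def test_missing_material_section_exits_2(self, tmp_path):
        assert cli(["tensile", "--out", str(tmp_path / "o")]) == 2

    def test_tensile_command_writes_curve_and_modulus(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("material:\n  c10_mpa: 0.3\n  c01_mpa: 0.1\n")
        out = tmp_path / "o"
        assert cli(["tensile", "--config", str(p), "--out", str(out)]) == 0
        data = json.loads((out / "tensile.json").read_text())
        assert data["equivalent_youngs_modulus_mpa"] == pytest.approx(2.139, abs=2e-3)

    def test_simulate_then_fit_roundtrip_converges(self, tmp_path):
        """Noiseless self-fit through the CLI: simulate a record, fit it back,
        exit 0 with converged=true."""
        p = tmp_path / "c.yaml"
        p.write_text(
            "material:\n  c10_mpa: 0.033333\n  c01_mpa: 0.016667\n"
            "geometry:\n  thickness_mm: 0.45\n"
            "solver:\n  n_through_thickness: 2\n  n_meridian: 24\n"
            "load:\n  n_frames: 9\n"
            "inverse:\n  n_initial_samples: 8\n  max_fe_evaluations: 16\n"
            "  ga_population: 20\n  ga_generations: 20\n"
        )
        simdir = tmp_path / "sim"
        assert cli(["simulate", "--config", str(p), "--out", str(simdir)]) == 0
        fit_out = tmp_path / "fit.json"
        code = cli([
            "fit", "--config", str(p), "--seed", "2",
            "--spatial", str(simdir / "spatial.csv"),
            "--temporal", str(simdir / "temporal.csv"),
            "--out", str(fit_out),
        ])
        assert code == 0
        data = json.loads(fit_out.read_text())
        assert data["converged"] is True
        assert data["merit"] <= 0.05
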