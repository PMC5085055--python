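"""File formats and run configuration -- the pipeline's outer shell.

CSV dialects
------------
*Spatial profiles* (full record)::

    # corneafit spatial profiles v1
    # n_frames=<F> duration_ms=<T>
    # reference
    x_mm,height_mm
    <x>,<h>
    ...
    # frame 0 t=<ms>
    x_mm,height_mm
    ...

*Temporal profile*::

    # corneafit temporal profile v1
    t_ms,apex_disp_mm
    ...

*Reduced highest-concavity profile* (what the instrument exports)::

    # corneafit hc profile v1
    x_mm,disp_mm
    ...

*Stress-strain curve*::

    strain,stress_MPa

CSV output uses 17 significant digits (an exact double-precision round
trip); JSON results round to 12 significant digits.  Either way repeated
runs with the same seed are byte-identical.

The run configuration is one schema-validated document (YAML or JSON);
unknown keys are rejected.  Lengths are mm and pressures MPa internally; the
IOP is accepted in mmHg and converted explicitly (1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from corneafit.airpuff import AirPuffLoad, DeformationRecord
from corneafit.errors import ConfigurationError, ParseError
from corneafit.geometry import CorneaGeometry
from corneafit.materials import LinearElasticParams, MooneyRivlinParams
from corneafit.tensile import StressStrainCurve, TensileSpec

__all__ = [
    "write_deformation_record",
    "read_deformation_record",
    "write_stress_strain_csv",
    "read_stress_strain_csv",
    "dump_json",
    "RunConfig",
    "load_config",
    "xlsx_sheets_to_csv",
]

_FMT = "%.16e"  # 17 significant digits: double-precision exact round trip


def _fmt(v: float) -> str:
    return _FMT % v


# ---------------------------------------------------------------------------
# deformation records


def write_deformation_record(
    record: DeformationRecord, spatial_path: str | Path, temporal_path: str | Path
) -> None:
    """Write a record as the spatial/temporal CSV dialect (full or reduced)."""
    spatial_path, temporal_path = Path(spatial_path), Path(temporal_path)
    with open(temporal_path, "w") as f:
        f.write("# corneafit temporal profile v1\n")
        f.write("t_ms,apex_disp_mm\n")
        for t, d in zip(record.times, record.apex_trace):
            f.write(f"{_fmt(t)},{_fmt(d)}\n")
    with open(spatial_path, "w") as f:
        if record.is_reduced:
            f.write("# corneafit hc profile v1\n")
            f.write("x_mm,disp_mm\n")
            for x, d in zip(record.x, record.displacement_at_hc()):
                f.write(f"{_fmt(x)},{_fmt(d)}\n")
            return
        f.write("# corneafit spatial profiles v1\n")
        f.write(
            f"# n_frames={record.n_frames} duration_ms={_fmt(record.times[-1])}\n"
        )
        f.write("# reference\nx_mm,height_mm\n")
        for x, h in zip(record.x, record.ref_height):
            f.write(f"{_fmt(x)},{_fmt(h)}\n")
        for k in range(record.n_frames):
            f.write(f"# frame {k} t={_fmt(record.times[k])}\n")
            f.write("x_mm,height_mm\n")
            for x, h in zip(record.x, record.heights[k]):
                f.write(f"{_fmt(x)},{_fmt(h)}\n")


def _read_two_col(lines: list[tuple[int, str]], header: str) -> np.ndarray:
    if not lines or lines[0][1].strip() != header:
        num = lines[0][0] if lines else 0
        raise ParseError(f"expected column header '{header}'", num)
    rows = []
    for num, line in lines[1:]:
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected 2 comma-separated values, got {len(parts)}", num)
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric value in '{line.strip()}'", num) from None
    if not rows:
        raise ParseError("empty data block", lines[0][0])
    return np.asarray(rows)


def _read_temporal(path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = [(i + 1, l) for i, l in enumerate(path.read_text().splitlines()) if l.strip()]
    if not lines or "temporal profile v1" not in lines[0][1]:
        raise ParseError("not a corneafit temporal profile file", 1)
    data = _read_two_col(lines[1:], "t_ms,apex_disp_mm")
    t = data[:, 0]
    if np.any(np.diff(t) <= 0.0):
        bad = int(np.flatnonzero(np.diff(t) <= 0.0)[0])
        raise ParseError("non-monotone time column", lines[2 + bad + 1][0])
    return t, data[:, 1]


def read_deformation_record(
    spatial_path: str | Path, temporal_path: str | Path
) -> DeformationRecord:
    """Parse a record from its CSV files.

    Accepts the full dialect (reference block + one block per frame) and the
    reduced form (highest-concavity profile + temporal trace).  Malformed
    headers or ragged rows raise :class:`ParseError` with the line number.
    """
    spatial_path, temporal_path = Path(spatial_path), Path(temporal_path)
    times, trace = _read_temporal(temporal_path)
    lines = [
        (i + 1, l)
        for i, l in enumerate(spatial_path.read_text().splitlines())
        if l.strip()
    ]
    if not lines:
        raise ParseError("empty spatial file", 1)
    head = lines[0][1]
    if "hc profile v1" in head:
        data = _read_two_col(lines[1:], "x_mm,disp_mm")
        return DeformationRecord(
            times=times, x=data[:, 0], apex_trace=trace,
            hc_displacement=data[:, 1],
        )
    if "spatial profiles v1" not in head:
        raise ParseError("not a corneafit spatial file", 1)
    # split into '# reference' / '# frame' blocks
    blocks: list[tuple[str, list[tuple[int, str]]]] = []
    for num, line in lines[1:]:
        s = line.strip()
        if s.startswith("# reference") or s.startswith("# frame"):
            blocks.append((s, []))
        elif s.startswith("#"):
            continue  # metadata comment
        else:
            if not blocks:
                raise ParseError("data before first block header", num)
            blocks[-1][1].append((num, line))
    if not blocks or not blocks[0][0].startswith("# reference"):
        raise ParseError("missing '# reference' block", lines[0][0])
    ref = _read_two_col(blocks[0][1], "x_mm,height_mm")
    x = ref[:, 0]
    heights = []
    for tag, blines in blocks[1:]:
        data = _read_two_col(blines, "x_mm,height_mm")
        if data.shape[0] != len(x):
            raise ParseError(
                f"frame block '{tag}' has {data.shape[0]} rows, expected {len(x)}",
                blines[0][0],
            )
        heights.append(data[:, 1])
    if len(heights) != len(times):
        raise ParseError(
            f"{len(heights)} frame blocks but {len(times)} temporal samples", 1
        )
    return DeformationRecord(
        times=times, x=x, apex_trace=trace,
        heights=np.asarray(heights), ref_height=ref[:, 1],
    )


# ---------------------------------------------------------------------------
# stress-strain curves


def write_stress_strain_csv(curve: StressStrainCurve, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("strain,stress_MPa\n")
        for e, s in zip(curve.strain, curve.stress):
            f.write(f"{_fmt(e)},{_fmt(s)}\n")


def read_stress_strain_csv(path: str | Path) -> StressStrainCurve:
    lines = [
        (i + 1, l) for i, l in enumerate(Path(path).read_text().splitlines())
        if l.strip() and not l.startswith("#")
    ]
    data = _read_two_col(lines, "strain,stress_MPa")
    return StressStrainCurve(strain=data[:, 0], stress=data[:, 1])


# ---------------------------------------------------------------------------
# deterministic JSON output


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.12e}")
    if isinstance(obj, (int, np.integer, str, bool)) or obj is None:
        return obj
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_round_floats(v) for v in np.asarray(obj).tolist()] \
            if isinstance(obj, np.ndarray) else [_round_floats(v) for v in obj]
    return obj


def dump_json(obj: Any, path: str | Path) -> None:
    """Write JSON with floats at 12 significant digits (bit-reproducible)."""
    with open(path, "w") as f:
        json.dump(_round_floats(obj), f, indent=2, sort_keys=True)
        f.write("\n")


# ---------------------------------------------------------------------------
# run configuration (schema-validated; unknown keys rejected)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Model):
    posterior_radius_mm: float = 8.60
    thickness_mm: float = 0.55
    anterior_radius_mm: float | None = None
    aperture_radius_mm: float = 5.5
    holder_youngs_modulus_mpa: float = 1500.0
    holder_poisson_ratio: float = 0.3
    holder_width_mm: float = 2.0
    holder_depth_mm: float = 2.0

    def build(self) -> CorneaGeometry:
        return CorneaGeometry(
            posterior_radius=self.posterior_radius_mm,
            thickness=self.thickness_mm,
            anterior_radius=self.anterior_radius_mm,
            aperture_radius=self.aperture_radius_mm,
            holder=LinearElasticParams(
                self.holder_youngs_modulus_mpa, self.holder_poisson_ratio
            ),
            holder_width=self.holder_width_mm,
            holder_depth=self.holder_depth_mm,
        )


class LoadConfig(_Model):
    peak_pressure_mpa: float = 0.0045
    spatial_sigma_mm: float = 1.5
    duration_ms: float = 30.0
    n_frames: int = 140
    pressure_table_csv: str | None = None

    def build(self) -> AirPuffLoad:
        table = None
        if self.pressure_table_csv is not None:
            data = np.loadtxt(self.pressure_table_csv, delimiter=",", comments="#",
                              skiprows=1)
            table = (data[:, 0], data[:, 1])
        return AirPuffLoad(
            peak_pressure=self.peak_pressure_mpa,
            spatial_sigma=self.spatial_sigma_mm,
            duration=self.duration_ms,
            n_frames=self.n_frames,
            spatial_table=table,
        )


class MaterialConfig(_Model):
    c10_mpa: float
    c01_mpa: float
    bulk_penalty_mpa: float | None = None

    def build(self) -> MooneyRivlinParams:
        return MooneyRivlinParams(self.c10_mpa, self.c01_mpa, self.bulk_penalty_mpa)


class SolverConfig(_Model):
    n_through_thickness: int = 4
    n_meridian: int = 100
    tol: float = 1.0e-6


class InverseSection(_Model):
    c10_bounds_mpa: tuple[float, float] = (0.005, 2.0)
    c01_bounds_mpa: tuple[float, float] = (0.005, 2.0)
    n_initial_samples: int = 20
    max_fe_evaluations: int = 80
    ga_population: int = 40
    ga_generations: int = 50
    merit_tolerance: float = 0.005
    weight_cpr: float = 1.0 / 3.0

    def build(self, seed: int):
        from corneafit.inverse import InverseConfig

        return InverseConfig(
            c10_bounds=self.c10_bounds_mpa,
            c01_bounds=self.c01_bounds_mpa,
            n_initial_samples=self.n_initial_samples,
            max_fe_evaluations=self.max_fe_evaluations,
            ga_population=self.ga_population,
            ga_generations=self.ga_generations,
            merit_tolerance=self.merit_tolerance,
            weight_cpr=self.weight_cpr,
            rng_seed=seed,
        )


class TensileSection(_Model):
    free_length_mm: float = 12.0
    width_mm: float = 3.0
    thickness_mm: float = 0.55
    max_strain: float = 0.4
    n_points: int = 101

    def build(self) -> TensileSpec:
        return TensileSpec(
            free_length=self.free_length_mm,
            width=self.width_mm,
            thickness=self.thickness_mm,
            max_strain=self.max_strain,
            n_points=self.n_points,
        )


class NoiseSection(_Model):
    displacement_noise_mm: float = 0.010
    stress_noise_rel: float = 0.02


class RunConfig(_Model):
    """One document configuring a pipeline run."""

    geometry: GeometryConfig = GeometryConfig()
    load: LoadConfig = LoadConfig()
    solver: SolverConfig = SolverConfig()
    inverse: InverseSection = InverseSection()
    tensile: TensileSection = TensileSection()
    noise: NoiseSection = NoiseSection()
    material: MaterialConfig | None = None
    iop_mmhg: float = 15.0
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (defaults when None)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
        return RunConfig.model_validate(data)
    except (yaml.YAMLError, ValidationError) as exc:
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# optional thin importer for supplementary XLSX workbooks


def xlsx_sheets_to_csv(xlsx_path: str | Path, outdir: str | Path) -> list[Path]:
    """Dump each worksheet of an XLSX workbook to ``<outdir>/<sheet>.csv``.

    Thin convenience for converting supplementary spreadsheet data (measured
    profiles, stress-strain tables) into the plain CSV forms this package
    reads.  Requires ``openpyxl`` (optional extra ``corneafit[xlsx]``).
    """
    try:
        import openpyxl
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "xlsx import requires openpyxl (pip install corneafit[xlsx])"
        ) from exc
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wb = openpyxl.load_workbook(xlsx_path, read_only=True, data_only=True)
    written = []
    for ws in wb.worksheets:
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in ws.title)
        path = outdir / f"{safe}.csv"
        with open(path, "w") as f:
            for row in ws.iter_rows(values_only=True):
                f.write(",".join("" if v is None else str(v) for v in row) + "\n")
        written.append(path)
    return written
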