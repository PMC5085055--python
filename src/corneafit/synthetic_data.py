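"""Seeded generator of instrument-like measurements with known ground truth.

The package's test bed: forward-simulates an air-puff test (or a tensile
test) at known Mooney-Rivlin parameters, adds measurement noise, and writes
the same file formats the analysis pipeline reads -- so the whole
reconstruction chain can be exercised end-to-end against a known answer
without any instrument data.

Noise model
-----------
* Air-puff records: i.i.d. Gaussian noise (default sigma 0.010 mm) added to
  every sampled surface height and to the apex trace, approximating the
  sub-pixel segmentation error of a 640x480 Scheimpflug frame spanning
  ~10 mm.  The t=0 trace sample stays exactly zero (the instrument reports
  displacement relative to the first frame).
* Tensile curves: multiplicative Gaussian noise (default 2% relative) on the
  stress channel, the dominant error of small-force load cells.

Phantom presets ``G``/``S``/``Q`` reproduce the manufacturer Young's moduli
of the three hydrogel contact-lens materials (0.16, 0.30, 0.38 MPa) via
``6 (C10 + C01) = E`` with a fixed split ``C01 = C10 / 2``; thickness
variants 1/2/3 are 350/450/550 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from corneafit.airpuff import AirPuffLoad, AirPuffSimulator, DeformationRecord
from corneafit.errors import ConfigurationError
from corneafit.geometry import CorneaGeometry
from corneafit.materials import MooneyRivlinParams
from corneafit.tensile import StressStrainCurve, TensileSpec, simulate_tensile

__all__ = [
    "PHANTOM_MODULI",
    "PHANTOM_THICKNESSES",
    "SyntheticStudy",
    "phantom_params",
    "apply_displacement_noise",
    "generate_airpuff_measurement",
    "generate_tensile_measurement",
]

PHANTOM_MODULI = {"G": 0.16, "S": 0.30, "Q": 0.38}
"""Manufacturer Young's moduli (MPa) of the three phantom materials."""

PHANTOM_THICKNESSES = {1: 0.35, 2: 0.45, 3: 0.55}
"""Phantom thickness variants (mm)."""


def phantom_params(material: str) -> MooneyRivlinParams:
    """Mooney-Rivlin constants of a phantom preset (C01 = C10/2, E = 6(C10+C01))."""
    e = PHANTOM_MODULI[material]
    return MooneyRivlinParams(c10=e / 9.0, c01=e / 18.0)


@dataclass(frozen=True)
class SyntheticStudy:
    """One synthetic air-puff experiment with known ground truth."""

    material: MooneyRivlinParams
    geometry: CorneaGeometry
    iop_mmhg: float = 15.0
    load: AirPuffLoad = field(default_factory=AirPuffLoad)
    displacement_noise_mm: float = 0.010
    stress_noise_rel: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_noise_mm < 0.0 or self.stress_noise_rel < 0.0:
            raise ConfigurationError("noise sigmas must be >= 0")

    @classmethod
    def from_preset(
        cls, material: str, thickness_variant: int = 3, rng_seed: int = 0, **kw
    ) -> "SyntheticStudy":
        return cls(
            material=phantom_params(material),
            geometry=CorneaGeometry(thickness=PHANTOM_THICKNESSES[thickness_variant]),
            rng_seed=rng_seed,
            **kw,
        )


def apply_displacement_noise(
    record: DeformationRecord, sigma_mm: float, rng: np.random.Generator
) -> DeformationRecord:
    """Add i.i.d. Gaussian height/trace noise to a full record (t=0 stays 0)."""
    if record.heights is None:
        raise ConfigurationError("need a full record to apply noise")
    heights = record.heights + rng.normal(0.0, sigma_mm, record.heights.shape) \
        if sigma_mm > 0 else record.heights.copy()
    trace = record.apex_trace.copy()
    if sigma_mm > 0:
        trace[1:] = trace[1:] + rng.normal(0.0, sigma_mm, len(trace) - 1)
    return DeformationRecord(
        times=record.times.copy(), x=record.x.copy(), apex_trace=trace,
        heights=heights, ref_height=record.ref_height.copy(),
        meta=dict(record.meta),
    )


def generate_airpuff_measurement(
    study: SyntheticStudy,
    outdir: str | Path | None = None,
    simulator: AirPuffSimulator | None = None,
) -> tuple[DeformationRecord, DeformationRecord]:
    """Simulate one air-puff test and emit a noisy measurement.

    Returns ``(noisy record, ground-truth record)``.  When ``outdir`` is
    given, writes the spatial/temporal CSV dialects plus a ground-truth JSON
    (``truth.json``); bitwise reproducible for a given ``study.rng_seed``.
    """
    sim = simulator or AirPuffSimulator(study.geometry, study.iop_mmhg, study.load)
    truth = sim.record(study.material)
    rng = np.random.default_rng(study.rng_seed)
    noisy = apply_displacement_noise(truth, study.displacement_noise_mm, rng)
    if outdir is not None:
        from corneafit.interface import dump_json, write_deformation_record

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_deformation_record(
            noisy, outdir / "spatial.csv", outdir / "temporal.csv"
        )
        dump_json(
            {
                "c10_mpa": study.material.c10,
                "c01_mpa": study.material.c01,
                "equivalent_youngs_modulus_mpa": study.material.youngs_modulus,
                "thickness_mm": study.geometry.thickness,
                "posterior_radius_mm": study.geometry.posterior_radius,
                "iop_mmhg": study.iop_mmhg,
                "peak_pressure_mpa": study.load.peak_pressure,
                "spatial_sigma_mm": study.load.spatial_sigma,
                "displacement_noise_mm": study.displacement_noise_mm,
                "rng_seed": study.rng_seed,
            },
            outdir / "truth.json",
        )
    return noisy, truth


def generate_tensile_measurement(
    params: MooneyRivlinParams,
    spec: TensileSpec | None = None,
    noise_rel: float = 0.02,
    rng_seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Closed-form tensile curve with multiplicative stress noise.

    Returns ``(noisy curve, ground-truth curve)``; optionally writes
    ``tensile.csv`` (columns strain, stress_MPa) and ``tensile_truth.json``.
    """
    spec = spec or TensileSpec()
    truth = simulate_tensile(params, spec)
    rng = np.random.default_rng(rng_seed)
    stress = truth.stress * (1.0 + rng.normal(0.0, noise_rel, truth.stress.shape)) \
        if noise_rel > 0 else truth.stress.copy()
    stress[0] = 0.0
    noisy = StressStrainCurve(strain=truth.strain.copy(), stress=stress)
    if outdir is not None:
        from corneafit.interface import dump_json, write_stress_strain_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stress_strain_csv(noisy, outdir / "tensile.csv")
        dump_json(
            {
                "c10_mpa": params.c10,
                "c01_mpa": params.c01,
                "equivalent_youngs_modulus_mpa": params.youngs_modulus,
                "noise_rel": noise_rel,
                "rng_seed": rng_seed,
            },
            outdir / "tensile_truth.json",
        )
    return noisy, truth
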