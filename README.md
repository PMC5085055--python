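# corneafit

Inverse finite-element reconstruction of corneal hyperelastic material
parameters from air-puff deformation imaging.

## The problem

Non-contact tonometers deform the cornea with a rapid (~30 ms) air pulse
while a high-speed Scheimpflug camera records the deformation, but they
report *deformation parameters* (how far the apex moved), not *inherent
material parameters* (how stiff the tissue is).  Inherent parameters are
what clinicians need for keratoconus screening, refractive-surgery planning
and cross-linking monitoring, and what biomechanical simulations consume.

`corneafit` closes that gap for corneas and hydrogel corneal phantoms
mounted in an artificial pressurised chamber.  It couples:

* a **forward model** — an axisymmetric, total-Lagrangian, near-incompressible
  finite-element simulation of the air-puff test (follower pressure loads,
  selective reduced integration against volumetric locking, complex-step
  consistent tangents);
* **deformation metrics** — central deformation amplitude DA, peripheral
  amplitude PDA (at ±2 mm), their ratio CPR = DA/PDA, and time to highest
  concavity THC;
* an **inverse loop** — Kriging (Gaussian-process) surrogate plus a seeded
  genetic algorithm minimising the merit
  Φ = |DA_m − DA_sim| + |CPR_m − CPR_sim|/3
  over the Mooney-Rivlin constants (C10, C01) of
  W = C10(Ī₁−3) + C01(Ī₂−3);
* a **tensile cross-check** — simulated strip extensiometry and the
  equivalent Young's modulus (the 0–0.1 strain secant of the nominal
  stress-strain curve), the currency in which air-puff reconstructions are
  compared with standard material tests.  For an incompressible
  Mooney-Rivlin solid, E = 6(C10 + C01) at small strain and the uniaxial
  response is P(λ) = 2(λ − λ⁻²)(C10 + C01/λ) in closed form.

A seeded synthetic-data generator emulates the instrument (140 frames over
30 ms, additive 0.010 mm displacement noise) with known ground truth, so the
whole pipeline is testable end-to-end without instrument data.  See
`docs/methods.md` for models, assumptions and numerical choices — including
the identifiability limit: DA and CPR pin down the stiffness 6(C10+C01) to a
few percent but barely separate C10 from C01 individually.

## Worked example

Reconstruct material constants from a synthetic noisy measurement of the
mid-stiffness phantom (manufacturer modulus 0.30 MPa, 450 µm thick):

```python
from corneafit.inverse import InverseConfig, fit_material
from corneafit.metrics import compute_metrics
from corneafit.synthetic_data import SyntheticStudy, generate_airpuff_measurement

study = SyntheticStudy.from_preset("S", 2, rng_seed=7)   # truth E = 0.30 MPa
noisy, _ = generate_airpuff_measurement(study)
measured = compute_metrics(noisy)
print(f"DA={measured.da:.3f} mm  CPR={measured.cpr:.3f}  THC={measured.thc_ms:.1f} ms")

result = fit_material(measured, study.geometry, study.iop_mmhg, study.load,
                      InverseConfig(rng_seed=7))
print(f"C10={result.params.c10:.4f}  C01={result.params.c01:.4f} MPa")
print(f"equivalent E = {result.params.youngs_modulus:.3f} MPa "
      f"(truth 0.300), merit {result.merit:.4f}")
```

prints

```
DA=0.978 mm  CPR=1.808  THC=14.5 ms
C10=0.0398  C01=0.0101 MPa
equivalent E = 0.299 MPa (truth 0.300), merit 0.0104
```

The apex moved ~1 mm at highest concavity; the fit matches the measured
DA/CPR to merit 0.01 and recovers the equivalent Young's modulus within
0.5% — the split between C10 and C01 is not separately identifiable, only
their sum (see the methods note).  The same pipeline is available from the
shell: `corneafit synth`, `corneafit fit`, `corneafit recover`, plus
`corneafit simulate`, `corneafit metrics` and `corneafit tensile`
(exit codes: 0 success, 2 configuration error, 3 solver non-convergence).

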