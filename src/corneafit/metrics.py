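"""Deformation parameters, the inverse-fit merit function, and comparison
statistics.

The four standard air-puff deformation parameters are

* **DA** -- central deformation amplitude: apex displacement at highest
  concavity (HC), mm;
* **PDA** -- peripheral deformation amplitude: mean displacement at +-2 mm
  lateral from the apex at HC, mm;
* **CPR** -- central-peripheral ratio DA/PDA (dimensionless; ~1 for
  rigid-like motion, larger for localised indentation);
* **THC** -- time from pulse start to HC, ms.

The inverse fit minimises the merit

    Phi = |DA_m - DA_sim| + w * |CPR_m - CPR_sim|,   w = 1/3 by default,

mixing the mm-valued amplitude residual with a down-weighted dimensionless
shape residual.  Any positive weight shares the same zero-merit optimum when
an exact fit exists; the weight only matters under model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from corneafit.airpuff import DeformationRecord
from corneafit.errors import ConfigurationError

__all__ = [
    "DeformationMetrics",
    "DegenerateProfileError",
    "compute_metrics",
    "merit",
    "profile_rms",
    "correspondence",
]


class DegenerateProfileError(ValueError):
    """The HC profile has zero peripheral displacement but nonzero DA."""


@dataclass(frozen=True)
class DeformationMetrics:
    da: float
    pda: float
    cpr: float
    thc_ms: float

    def as_dict(self) -> dict[str, float]:
        return {"DA_mm": self.da, "PDA_mm": self.pda, "CPR": self.cpr,
                "THC_ms": self.thc_ms}


def compute_metrics(record: DeformationRecord) -> DeformationMetrics:
    """DA / PDA / CPR / THC of a deformation record.

    HC is the frame of maximal apex displacement; PDA is obtained by linear
    interpolation of the HC displacement profile at exactly +-2.0 mm.  For an
    all-zero record CPR is defined as 1 (rigid-identity limit).
    """
    if record.n_frames < 3:
        raise ConfigurationError("record needs >= 3 frames")
    if record.x.max() < 2.0 or record.x.min() > -2.0:
        raise ConfigurationError("lateral grid must span at least +-2 mm")
    hc = record.hc_index()
    da = float(record.apex_trace[hc])
    disp = record.displacement_at_hc()
    pda = float(
        0.5 * (np.interp(2.0, record.x, disp) + np.interp(-2.0, record.x, disp))
    )
    if da > 1e-9 and abs(pda) < 1e-9:
        raise DegenerateProfileError("DA > 0 but PDA == 0")
    cpr = da / pda if abs(pda) >= 1e-9 else 1.0
    return DeformationMetrics(da=da, pda=pda, cpr=cpr, thc_ms=float(record.times[hc]))


def merit(
    measured: DeformationMetrics,
    simulated: DeformationMetrics,
    weight_cpr: float = 1.0 / 3.0,
) -> float:
    """Inverse-fit merit Phi = |dDA| + weight_cpr * |dCPR| (>= 0, symmetric)."""
    vals = [measured.da, simulated.da, measured.cpr, simulated.cpr]
    if not np.all(np.isfinite(vals)):
        raise ValueError("metrics must be finite")
    return float(
        abs(measured.da - simulated.da)
        + weight_cpr * abs(measured.cpr - simulated.cpr)
    )


def _as_xy(profile) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(profile, "strain"):
        return np.asarray(profile.strain, float), np.asarray(profile.stress, float)
    x, y = profile
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def profile_rms(a, b, window: tuple[float, float] | None = None, n: int = 256) -> float:
    """RMS difference of two sampled profiles on their shared support.

    Both profiles (pairs of abscissa/ordinate arrays) are resampled by linear
    interpolation onto a uniform grid over the overlap of their supports,
    optionally intersected with ``window`` (e.g. the central +-4 mm for
    spatial profiles).
    """
    xa, ya = _as_xy(a)
    xb, yb = _as_xy(b)
    lo, hi = max(xa.min(), xb.min()), min(xa.max(), xb.max())
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if not hi > lo:
        raise ConfigurationError("profiles have no overlapping support")
    grid = np.linspace(lo, hi, n)
    d = np.interp(grid, xa, ya) - np.interp(grid, xb, yb)
    return float(np.sqrt(np.mean(d**2)))


def correspondence(
    reference,
    test,
    strain_range: tuple[float, float] = (0.0, 0.4),
    n_points: int = 101,
) -> float:
    """Mean point-to-point correspondence (%) of two stress-strain curves.

    ``100 * (1 - mean |sigma_test - sigma_ref| / max(|sigma_ref|, floor))``
    over a uniform strain grid; the floor (1% of the range-max reference
    stress) guards the relative error near the origin.
    """
    xr, yr = _as_xy(reference)
    xt, yt = _as_xy(test)
    lo, hi = strain_range
    if xr.min() > lo + 1e-12 or xr.max() < hi - 1e-12 or xt.min() > lo + 1e-12 \
            or xt.max() < hi - 1e-12:
        raise ConfigurationError("curves do not cover the requested strain range")
    grid = np.linspace(lo, hi, n_points)
    sr = np.interp(grid, xr, yr)
    st = np.interp(grid, xt, yt)
    floor = 0.01 * np.abs(sr).max()
    rel = np.abs(st - sr) / np.maximum(np.abs(sr), floor)
    return float(100.0 * (1.0 - np.mean(rel)))
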