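"""Deformation-metric, merit and comparison-statistic tests."""

from __future__ import annotations

import numpy as np
import pytest

from corneafit.airpuff import DeformationRecord
from corneafit.errors import ConfigurationError
from corneafit.metrics import (
    DeformationMetrics,
    DegenerateProfileError,
    compute_metrics,
    correspondence,
    merit,
    profile_rms,
)


def gaussian_record(
    da: float = 1.2, width: float = 1.3, n_frames: int = 141, duration: float = 30.0
) -> DeformationRecord:
    """Analytic stand-in record: Gaussian dent, sin^2 time course."""
    t = np.linspace(0.0, duration, n_frames)
    x = np.linspace(-4.0, 4.0, 161)
    a = np.sin(np.pi * t / duration) ** 2
    ref = np.full_like(x, 10.0)
    heights = ref[None, :] - a[:, None] * da * np.exp(-(x**2) / (2 * width**2))
    return DeformationRecord(
        times=t, x=x, apex_trace=a * da, heights=heights, ref_height=ref
    )


class TestComputeMetrics:
    def test_gaussian_dent_metrics(self):
        rec = gaussian_record(da=1.2, width=1.3)
        m = compute_metrics(rec)
        assert m.da == pytest.approx(1.2, rel=1e-9)
        assert m.pda == pytest.approx(1.2 * np.exp(-(2.0**2) / (2 * 1.3**2)), rel=1e-6)
        assert m.cpr == pytest.approx(np.exp(2.0 / 1.3**2), rel=1e-6)

    def test_thc_is_time_of_peak(self):
        # trace peaking at frame 70 of 140 spanning 30 ms -> THC ~ 15 ms
        rec = gaussian_record(n_frames=141)
        m = compute_metrics(rec)
        assert m.thc_ms == pytest.approx(15.0, abs=0.2)

    def test_hand_worked_ratio(self):
        """DA=1.2 and displacement 0.8 at +-2 mm give CPR 1.5 by definition."""
        t = np.linspace(0, 30, 5)
        x = np.linspace(-3, 3, 61)
        disp = np.interp(np.abs(x), [0, 2, 3], [1.2, 0.8, 0.5])
        rec = DeformationRecord(
            times=t, x=x, apex_trace=np.array([0, 0.6, 1.2, 0.6, 0]),
            hc_displacement=disp,
        )
        m = compute_metrics(rec)
        assert (m.da, m.pda, m.cpr) == pytest.approx((1.2, 0.8, 1.5))

    def test_rigid_translation_has_unit_cpr(self):
        t = np.linspace(0, 30, 5)
        x = np.linspace(-3, 3, 31)
        rec = DeformationRecord(
            times=t, x=x, apex_trace=np.array([0, 0.2, 0.4, 0.2, 0]),
            hc_displacement=np.full_like(x, 0.4),
        )
        assert compute_metrics(rec).cpr == pytest.approx(1.0)

    def test_mirroring_leaves_metrics_unchanged(self):
        rec = gaussian_record()
        rec.heights += 0.05 * np.sin(rec.x)[None, :]  # break symmetry
        mirrored = DeformationRecord(
            times=rec.times, x=rec.x, apex_trace=rec.apex_trace,
            heights=rec.heights[:, ::-1], ref_height=rec.ref_height[::-1],
        )
        m1, m2 = compute_metrics(rec), compute_metrics(mirrored)
        assert m1.da == pytest.approx(m2.da)
        assert m1.pda == pytest.approx(m2.pda)

    def test_degenerate_profile_raises(self):
        t = np.linspace(0, 30, 5)
        x = np.linspace(-3, 3, 31)
        rec = DeformationRecord(
            times=t, x=x, apex_trace=np.array([0, 0.5, 1.0, 0.5, 0]),
            hc_displacement=np.where(np.abs(x) < 1, 1.0, 0.0),
        )
        with pytest.raises(DegenerateProfileError):
            compute_metrics(rec)

    def test_narrow_grid_rejected(self):
        t = np.linspace(0, 30, 5)
        x = np.linspace(-1, 1, 11)
        rec = DeformationRecord(
            times=t, x=x, apex_trace=np.linspace(0, 1, 5),
            hc_displacement=np.ones_like(x),
        )
        with pytest.raises(ConfigurationError):
            compute_metrics(rec)


class TestMerit:
    M1 = DeformationMetrics(da=1.0, pda=0.5, cpr=2.0, thc_ms=15.0)

    def test_identical_metrics_give_zero(self):
        assert merit(self.M1, self.M1) == 0.0

    def test_hand_value_with_default_weight(self):
        m2 = DeformationMetrics(da=0.9, pda=0.53, cpr=1.7, thc_ms=15.0)
        # |1.0 - 0.9| + |2.0 - 1.7| / 3 = 0.2
        assert merit(self.M1, m2, weight_cpr=1 / 3) == pytest.approx(0.2)

    def test_symmetric_in_arguments(self):
        m2 = DeformationMetrics(da=0.8, pda=0.5, cpr=1.5, thc_ms=10.0)
        assert merit(self.M1, m2) == merit(m2, self.M1)

    def test_zero_iff_da_and_cpr_agree(self):
        m2 = DeformationMetrics(da=1.0, pda=0.9, cpr=2.0, thc_ms=3.0)
        assert merit(self.M1, m2) == 0.0  # PDA and THC do not enter
        m3 = DeformationMetrics(da=1.0, pda=0.5, cpr=2.1, thc_ms=15.0)
        assert merit(self.M1, m3) > 0.0

    def test_nonfinite_metrics_rejected(self):
        bad = DeformationMetrics(da=np.nan, pda=1.0, cpr=1.0, thc_ms=1.0)
        with pytest.raises(ValueError):
            merit(self.M1, bad)


class TestProfileRms:
    X = np.linspace(-4, 4, 81)

    def test_identical_profiles_give_zero(self):
        y = np.sin(self.X)
        assert profile_rms((self.X, y), (self.X, y)) == 0.0

    def test_constant_offset_returns_offset(self):
        y = np.sin(self.X)
        assert profile_rms((self.X, y), (self.X, y + 0.05)) == pytest.approx(0.05)

    def test_linear_ramp_closed_form(self):
        """Slope difference k over [-4, 4]: RMS = k sqrt(mean x^2) = k sqrt(16/3)."""
        a = (self.X, 0.10 * self.X)
        b = (self.X, 0.12 * self.X)
        assert profile_rms(a, b) == pytest.approx(
            0.02 * np.sqrt(16.0 / 3.0), rel=1e-2
        )

    def test_triangle_inequality(self, rng):
        ya, yb, yc = rng.standard_normal((3, len(self.X)))
        ab = profile_rms((self.X, ya), (self.X, yb))
        bc = profile_rms((self.X, yb), (self.X, yc))
        ac = profile_rms((self.X, ya), (self.X, yc))
        assert ac <= ab + bc + 1e-12

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ConfigurationError):
            profile_rms((self.X, self.X), (self.X + 100, self.X))


class TestCorrespondence:
    def test_identical_curves_give_100(self):
        e = np.linspace(0, 0.4, 41)
        s = 0.5 * e + e**2
        assert correspondence((e, s), (e, s)) == pytest.approx(100.0)

    def test_uniform_10pct_error_gives_90(self):
        # evaluated away from the origin so the relative-error floor is inert
        e = np.linspace(0, 0.4, 41)
        s = 0.5 * e + e**2
        assert correspondence(
            (e, s), (e, 1.10 * s), strain_range=(0.1, 0.4)
        ) == pytest.approx(90.0, abs=0.01)

    def test_constant_offset_hand_value(self):
        """sigma = eps vs eps + 0.01 on the 4-point grid {0.1..0.4}:
        mean of 0.01/eps = 0.0521 -> ~94.8%."""
        e = np.linspace(0, 0.5, 101)
        c = correspondence(
            (e, e), (e, e + 0.01), strain_range=(0.1, 0.4), n_points=4
        )
        assert c == pytest.approx(94.79, abs=0.05)

    def test_insufficient_coverage_rejected(self):
        e = np.linspace(0, 0.2, 21)
        with pytest.raises(ConfigurationError):
            correspondence((e, e), (e, e), strain_range=(0.0, 0.4))
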