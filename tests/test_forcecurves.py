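"""Force-curve analysis: contact detection, conversion, Hertz and Oliver-Pharr."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fibromech import (
    ElastoMap,
    ForceCurve,
    SynthProtocol,
    aggregate_modulus,
    detect_contact_point,
    elastograph_stats,
    fit_hertz_sphere,
    fit_oliver_pharr,
    synth_indentation_curve,
    to_force_indentation,
)
from fibromech.exceptions import (
    InsufficientDataError,
    NoContactError,
    ParameterError,
    ValidationError,
)


def constructed_curve(contact_index=200, n=400, step=10.0, noise=0.0, offset=0.0, seed=0):
    """Baseline + Hertz-like approach with the contact at a known sample."""
    rng = np.random.default_rng(seed)
    z = np.arange(n) * step
    d = np.zeros(n)
    post = np.arange(contact_index, n)
    d[post] = 1e-2 * (z[post] - z[contact_index]) ** 1.5
    d += offset + rng.normal(0.0, noise, n)
    return ForceCurve(z, d, 0.48, np.array(["approach"] * n))


class TestContactDetection:
    @pytest.mark.parametrize("noise,offset", [(0.0, 0.0), (0.3, 0.0), (0.3, 25.0)])
    def test_detected_within_three_samples(self, noise, offset):
        curve = constructed_curve(noise=noise, offset=offset, seed=3)
        cp = detect_contact_point(curve)
        assert abs(cp.index - 200) <= 3

    def test_offset_invariance(self):
        base = detect_contact_point(constructed_curve(noise=0.2, seed=5))
        shifted = detect_contact_point(constructed_curve(noise=0.2, offset=40.0, seed=5))
        assert base.index == shifted.index

    def test_all_zero_deflection_no_contact(self):
        n = 100
        curve = ForceCurve(
            np.arange(n, dtype=float), np.zeros(n), 0.48, np.array(["approach"] * n)
        )
        with pytest.raises(NoContactError):
            detect_contact_point(curve)


class TestForceIndentation:
    def test_force_from_spring_constant(self):
        # d = 10 nm at k = 0.48 N/m carries F = 4.8 nN
        n = 60
        z = np.linspace(0, 600, n)
        d = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        curve = ForceCurve(z, d, 0.48, np.array(["approach"] * n))
        cp = detect_contact_point(curve)
        _, force = to_force_indentation(curve, cp)
        assert force.max() == pytest.approx(4.8, rel=1e-6)

    def test_zero_deflection_indentation_equals_travel(self):
        curve = synth_indentation_curve(
            0.0,
            __import__("fibromech").IndenterSpec(shape="sphere", radius_um=7.5),
            SynthProtocol(seed=0),
        )
        truth = curve.meta["truth"]
        from fibromech.forcecurves import ContactPoint

        cp = ContactPoint(0, truth["z_c_nm"], 0.0, 0.0)
        delta, force = to_force_indentation(curve, cp)
        approach_z = curve.z_nm[curve.segment("approach")]
        expected = approach_z[approach_z >= truth["z_c_nm"]] - truth["z_c_nm"]
        assert np.allclose(force, 0.0)
        assert np.allclose(np.sort(delta)[-expected.size :], np.sort(expected))

    def test_rigid_sample_limit_zero_indentation(self):
        # d = z - z_c beyond contact: all travel deflects the cantilever
        n = 80
        z = np.linspace(0, 800, n)
        z_c = z[40]
        d = np.clip(z - z_c, 0, None)
        curve = ForceCurve(z, d, 0.48, np.array(["approach"] * n))
        from fibromech.forcecurves import ContactPoint

        delta, _ = to_force_indentation(curve, ContactPoint(40, z_c, 0.0, 0.0))
        assert np.allclose(delta, 0.0, atol=1e-9)


class TestHertzFit:
    def test_noiseless_round_trip(self, sphere_indenter, quiet_protocol):
        curve = synth_indentation_curve(10.0, sphere_indenter, quiet_protocol)
        delta, force = to_force_indentation(curve)
        res = fit_hertz_sphere(delta, force, sphere_indenter)
        assert res.modulus_kpa == pytest.approx(10.0, abs=0.1)

    def test_linearity_in_force(self, sphere_indenter, quiet_protocol):
        curve = synth_indentation_curve(8.0, sphere_indenter, quiet_protocol)
        delta, force = to_force_indentation(curve)
        e1 = fit_hertz_sphere(delta, force, sphere_indenter, refine_contact=False)
        e2 = fit_hertz_sphere(delta, 2 * force, sphere_indenter, refine_contact=False)
        assert e2.modulus_kpa == pytest.approx(2 * e1.modulus_kpa, rel=1e-9)

    def test_radius_scaling(self, sphere_indenter, quiet_protocol):
        # E scales as R^(-1/2) with the assumed radius (closed form)
        from fibromech import IndenterSpec

        curve = synth_indentation_curve(8.0, sphere_indenter, quiet_protocol)
        delta, force = to_force_indentation(curve)
        e1 = fit_hertz_sphere(delta, force, sphere_indenter, refine_contact=False)
        bigger = IndenterSpec(shape="sphere", radius_um=4 * 7.5, poisson=0.5)
        e2 = fit_hertz_sphere(delta, force, bigger, refine_contact=False)
        assert e2.modulus_kpa == pytest.approx(e1.modulus_kpa / 2, rel=1e-9)

    def test_insufficient_points(self, sphere_indenter):
        with pytest.raises(InsufficientDataError):
            fit_hertz_sphere(
                np.array([1.0, 2, 3, 4, 5]), np.array([1.0, 2, 3, 4, 5]), sphere_indenter
            )


class TestOliverPharr:
    def test_unloading_stiffness_closed_form(self, cone_indenter, quiet_protocol):
        curve = synth_indentation_curve(
            1000.0, cone_indenter, quiet_protocol, max_depth_nm=800.0
        )
        res = fit_oliver_pharr(curve, cone_indenter)
        t = curve.meta["truth"]
        s_closed = (
            t["unload_alpha"]
            * t["unload_m"]
            * (t["max_depth_nm"] - t["unload_h_f_nm"]) ** (t["unload_m"] - 1)
        )
        assert res.unload_stiffness_nn_per_nm == pytest.approx(s_closed, rel=0.01)

    def test_modulus_round_trip_within_5pct(self, cone_indenter, quiet_protocol):
        m_true = 1000.0 / (1 - 0.5**2)  # plane-strain modulus of a 1 MPa sample
        curve = synth_indentation_curve(
            1000.0, cone_indenter, quiet_protocol, max_depth_nm=800.0
        )
        res = fit_oliver_pharr(curve, cone_indenter)
        assert res.modulus_kpa == pytest.approx(m_true, rel=0.05)
        assert 1.0 <= res.m_exponent <= 3.0
        assert not res.flags

    def test_short_unloading_rejected(self, cone_indenter):
        n_app, n_ret = 30, 8
        z = np.concatenate([np.linspace(0, 300, n_app), np.linspace(300, 250, n_ret)])
        d = np.concatenate([np.zeros(n_app), np.linspace(20, 0, n_ret)])
        curve = ForceCurve(
            z, d, 0.48, np.array(["approach"] * n_app + ["retract"] * n_ret)
        )
        with pytest.raises(InsufficientDataError):
            fit_oliver_pharr(curve, cone_indenter)


class TestAggregation:
    def test_identical_values(self):
        summary = aggregate_modulus([5.0] * 30, level="fibril")
        assert summary.mean_kpa == 5.0
        assert summary.sem_kpa == 0.0
        assert not summary.below_protocol

    def test_simple_mean(self):
        summary = aggregate_modulus([1.0, 2.0, 3.0], level="fibril")
        assert summary.mean_kpa == pytest.approx(2.0)

    def test_below_protocol_flag(self):
        assert aggregate_modulus([1.0] * 20, level="fibril").below_protocol
        assert aggregate_modulus([1.0] * 79, level="donor").below_protocol
        assert not aggregate_modulus([1.0] * 80, level="donor").below_protocol

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_modulus([], level="fibril")


def make_map(values):
    values = np.asarray(values, dtype=float)
    x = np.arange(values.size, dtype=float)
    return ElastoMap(x, np.zeros_like(x), values)


class TestElastograph:
    def test_hand_computed_cv(self):
        # {1, 2, 3} kPa: sample SD 1, mean 2, CV 50%
        stats = elastograph_stats(make_map([1.0, 2.0, 3.0]))
        assert stats["cv_percent"] == pytest.approx(50.0, rel=1e-12)

    def test_constant_map_zero_cv(self):
        assert elastograph_stats(make_map([2.0] * 9))["cv_percent"] == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_cv_scale_invariance(self, scale):
        base = elastograph_stats(make_map([1.0, 2.0, 3.0, 5.0]))["cv_percent"]
        scaled = elastograph_stats(make_map(np.array([1.0, 2.0, 3.0, 5.0]) * scale))[
            "cv_percent"
        ]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_mean_undefined(self):
        with pytest.raises(ParameterError):
            elastograph_stats(make_map([0.0, 0.0, 0.0]))
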