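"""Generator contracts: physical forward models, determinism, ground truth."""

import math

import numpy as np
import pytest

from fibromech import (
    CohortSpec,
    SynthProtocol,
    synth_cohort,
    synth_compression_test,
    synth_dose_response,
    synth_fibril_topography,
    synth_indentation_curve,
)
from fibromech.compression import phase_durations, segment_cycles
from fibromech.exceptions import ParameterError
from fibromech.stats import pairwise_tests
from fibromech.synth import VariableSpec


def hertz_force_oracle(e_kpa, nu, r_um, delta_nm):
    """Closed-form Hertz sphere force in nN (independent of the package)."""
    e_red = e_kpa * 1e-6 / (1 - nu**2)  # nN/nm^2
    return (4.0 / 3.0) * e_red * math.sqrt(r_um * 1e3) * delta_nm**1.5


class TestIndentationCurve:
    def test_hertz_force_at_max_depth(self, sphere_indenter, quiet_protocol):
        # E = 10 kPa, nu = 0.5, R = 7.5 um, depth 1 um: closed form gives 48.7 nN
        curve = synth_indentation_curve(
            10.0, sphere_indenter, quiet_protocol, max_depth_nm=1000.0
        )
        expected = hertz_force_oracle(10.0, 0.5, 7.5, 1000.0)
        assert expected == pytest.approx(48.69, abs=0.01)
        assert curve.force_nn.max() == pytest.approx(expected, rel=1e-6)

    def test_zero_modulus_gives_zero_force(self, sphere_indenter, quiet_protocol):
        curve = synth_indentation_curve(0.0, sphere_indenter, quiet_protocol)
        assert np.allclose(curve.force_nn, 0.0)

    def test_seed_determinism(self, sphere_indenter):
        a = synth_indentation_curve(10.0, sphere_indenter, SynthProtocol(seed=7, noise_sd=1.0))
        b = synth_indentation_curve(10.0, sphere_indenter, SynthProtocol(seed=7, noise_sd=1.0))
        assert np.array_equal(a.z_nm, b.z_nm)
        assert np.array_equal(a.deflection_nm, b.deflection_nm)

    @pytest.mark.parametrize("bad", [dict(modulus_kpa=-1.0), dict(max_depth_nm=0.0)])
    def test_parameter_validation(self, sphere_indenter, quiet_protocol, bad):
        kwargs = dict(modulus_kpa=10.0, max_depth_nm=500.0)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            synth_indentation_curve(
                kwargs["modulus_kpa"], sphere_indenter, quiet_protocol,
                max_depth_nm=kwargs["max_depth_nm"],
            )

    def test_truth_sidecar_present(self, cone_indenter, quiet_protocol):
        curve = synth_indentation_curve(500.0, cone_indenter, quiet_protocol)
        truth = curve.meta["truth"]
        assert truth["modulus_kpa"] == 500.0
        assert truth["unload_m"] == 2.0  # cone elastic exponent
        assert curve.meta["seed"] == quiet_protocol.seed


class TestFibrilTopography:
    def test_autocorrelation_peak_at_67nm(self, quiet_protocol):
        topo = synth_fibril_topography(protocol=quiet_protocol, pixel_nm=1.0)
        row = topo.heights_nm[topo.meta["ridge_row"]]
        x = row - row.mean()
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        # first local max beyond the zero-lag lobe sits at the 67 nm period
        lag = 30 + int(np.argmax(ac[30:100]))
        assert lag == pytest.approx(67, abs=1)

    def test_resampling_halves_lag_index_not_period(self):
        fine = synth_fibril_topography(protocol=SynthProtocol(seed=3), pixel_nm=1.0)
        coarse = synth_fibril_topography(protocol=SynthProtocol(seed=3), pixel_nm=2.0)

        def peak_lag(topo):
            row = topo.heights_nm[topo.meta["ridge_row"]]
            x = row - row.mean()
            ac = np.correlate(x, x, "full")[x.size - 1 :]
            lo = int(20 / topo.pixel_nm)
            hi = int(100 / topo.pixel_nm)
            return lo + int(np.argmax(ac[lo:hi]))

    # physical period unchanged; index halves with doubled pixel
        lag_fine, lag_coarse = peak_lag(fine), peak_lag(coarse)
        assert lag_coarse == pytest.approx(lag_fine / 2, abs=1)
        assert lag_coarse * 2.0 == pytest.approx(lag_fine * 1.0, abs=2)

    def test_nyquist_rejection(self):
        with pytest.raises(ParameterError):
            synth_fibril_topography(period_nm=3.0, pixel_nm=2.0)

    def test_determinism(self):
        a = synth_fibril_topography(protocol=SynthProtocol(seed=9, noise_sd=0.5))
        b = synth_fibril_topography(protocol=SynthProtocol(seed=9, noise_sd=0.5))
        assert np.array_equal(a.heights_nm, b.heights_nm)


class TestCompressionTrace:
    def test_peak_strain_and_phases(self, quiet_protocol):
        test = synth_compression_test(5.0, 500.0, 450.0, quiet_protocol)
        assert test.displacement_um.max() / test.d0_um == pytest.approx(0.25, abs=1e-9)
        cycles = segment_cycles(test)
        assert len(cycles) == 5
        dt = test.time_s[1] - test.time_s[0]
        for cyc in cycles:
            durations = phase_durations(test, cyc)
            assert durations["compress"] == pytest.approx(15.0, abs=2 * dt)
            assert durations["hold"] == pytest.approx(2.0, abs=2 * dt)
            assert durations["recover"] == pytest.approx(15.0, abs=2 * dt)

    def test_determinism(self):
        a = synth_compression_test(5.0, 500.0, 450.0, SynthProtocol(seed=4), force_noise_rel=0.05)
        b = synth_compression_test(5.0, 500.0, 450.0, SynthProtocol(seed=4), force_noise_rel=0.05)
        assert np.array_equal(a.force_un, b.force_un)


class TestCohort:
    def test_spearman_matches_target_without_group_effects(self):
        # within-group correlation target: use a null-contrast cohort so the
        # pooled coefficient estimates the generative correlation directly
        variables = {
            "stiffness_kpa": VariableSpec(2.0, 2.0, 0.35),
            "mature_per_collagen": VariableSpec(0.25, 0.25, 0.30),
        }
        rs = []
        from scipy.stats import spearmanr

        for seed in range(100):
            spec = CohortSpec(n_control=16, n_case=16, variables=variables)
            tab = synth_cohort(spec, SynthProtocol(seed=seed))
            rs.append(
                spearmanr(
                    tab.data["stiffness_kpa"], tab.data["mature_per_collagen"]
                ).statistic
            )
        assert np.mean(rs) == pytest.approx(0.72, abs=0.15)

    def test_marginal_moments_at_large_n(self):
        spec = CohortSpec(n_control=5000, n_case=5000)
        tab = synth_cohort(spec, SynthProtocol(seed=1))
        for name, v in spec.variables.items():
            for group, mean in (("control", v.control_mean), ("case", v.case_mean)):
                x = tab.data.loc[tab.data["group"] == group, name].to_numpy()
                if v.log_scale:
                    z = (np.log(x).mean() - math.log(mean)) / (v.sd / math.sqrt(x.size))
                else:
                    z = (x.mean() - mean) / (v.sd / math.sqrt(x.size))
                assert abs(z) < 4.5, f"{name}/{group} marginal off: z={z:.2f}"

    def test_welch_type_one_error_under_null(self):
        # all group effects zero: Welch-t on log stiffness rejects ~5%
        variables = {"stiffness_kpa": VariableSpec(2.0, 2.0, 0.35)}
        rejections = 0
        reps = 2000
        for seed in range(reps):
            spec = CohortSpec(n_control=10, n_case=10, variables=variables)
            tab = synth_cohort(spec, SynthProtocol(seed=seed))
            a = tab.data.loc[tab.data["group"] == "control", "stiffness_kpa"].to_numpy()
            b = tab.data.loc[tab.data["group"] == "case", "stiffness_kpa"].to_numpy()
            res = pairwise_tests(a, b, method="welch_t", log_transform=True)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_missing_rate_within_binomial_bounds(self):
        spec = CohortSpec(n_control=200, n_case=200, missing_rate=0.2)
        tab = synth_cohort(spec, SynthProtocol(seed=2))
        cells = tab.data.drop(columns=["donor_id", "group"])
        frac = float(cells.isna().to_numpy().mean())
        n_cells = cells.size
        half_width = 2.576 * math.sqrt(0.2 * 0.8 / n_cells)  # binomial 99%
        assert abs(frac - 0.2) <= half_width

    def test_infeasible_correlation_rejected(self):
        spec = CohortSpec(
            target_corr=0.99,
            extra_corr={
                ("stiffness_kpa", "immature_per_collagen"): 0.99,
                ("immature_per_collagen", "mature_per_collagen"): -0.9,
            },
        )
        with pytest.raises(ParameterError):
            synth_cohort(spec, SynthProtocol(seed=0))

    def test_determinism(self):
        a = synth_cohort(CohortSpec(missing_rate=0.1), SynthProtocol(seed=5))
        b = synth_cohort(CohortSpec(missing_rate=0.1), SynthProtocol(seed=5))
        assert a.data.equals(b.data)


class TestDoseResponse:
    def test_midpoint_and_asymptote(self, quiet_protocol):
        table = synth_dose_response(0.005, doses_um=[1e-4, 1e-3, 0.005, 0.1, 1.0],
                                    protocol=quiet_protocol)
        act = table.data.set_index("dose_um")["activity_pct"]
        assert act.loc[0.005] == pytest.approx(50.0, abs=1e-9)
        assert act.loc[1e-4] > 95.0  # dose -> 0 approaches top

    def test_invalid_ic50(self, quiet_protocol):
        with pytest.raises(ParameterError):
            synth_dose_response(0.0, protocol=quiet_protocol)

    def test_determinism(self):
        a = synth_dose_response(0.016, protocol=SynthProtocol(seed=8, noise_sd=2.0))
        b = synth_dose_response(0.016, protocol=SynthProtocol(seed=8, noise_sd=2.0))
        assert a.data.equals(b.data)
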