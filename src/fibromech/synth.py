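"""Seeded synthetic-data generators for every input class the pipeline consumes.

Each generator draws from the same physical forward model its analysis
counterpart inverts (Hertz/Sneddon contact for indentation, two-plate Hertz
for spheroid compression, a banded ridge for fibril topography, a 4PL curve
for enzyme inhibition, a log-scale multivariate normal for donor cohorts), so
noiseless output is exactly invertible up to fit tolerance.  Ground-truth
parameters are attached to each object's ``meta["truth"]`` sidecar so tests
never re-derive truth from outputs, and the seed is echoed in the metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .compression import CompressionTest, PhaseProtocol, two_plate_hertz_force
from .exceptions import ParameterError, ValidationError
from .fibrilmorph import D_PERIOD_NM, Topography
from .forcecurves import (
    APPROACH,
    RETRACT,
    ForceCurve,
    IndenterSpec,
    hertz_sphere_force,
    sneddon_cone_force,
)


@dataclass
class SynthProtocol:
    """Shared generator knobs: seed, additive noise level, sampling.

    ``noise_sd`` is in the units of the generated signal (deflection nm,
    height nm, force uN); ``n_points``/``sampling_step`` override each
    generator's default sampling when set.
    """

    seed: int = 0
    noise_sd: float = 0.0
    n_points: int | None = None
    sampling_step: float | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --------------------------------------------------------------------------
# indentation curves
# --------------------------------------------------------------------------

def synth_indentation_curve(
    modulus_kpa: float,
    indenter: IndenterSpec,
    protocol: SynthProtocol,
    max_depth_nm: float = 1000.0,
    pre_contact_nm: float | None = None,
    k_n_per_m: float | None = None,
    unload_m: float | None = None,
    unload_h_f_nm: float = 0.0,
) -> ForceCurve:
    """Simulate one approach/retract cycle over a sample of known modulus.

    The approach follows the indenter's contact law (Hertz sphere or Sneddon
    cone) through the cantilever force balance k (z - z_c - delta) = F(delta),
    solved per piezo position; unloading is the power law
    P = alpha (h - h_f)^m with alpha continuous at maximum load and m
    defaulting to the elastic exponent (3/2 sphere, 2 cone).  Additive
    Gaussian noise of ``protocol.noise_sd`` nm goes on the deflection.
    """
    if modulus_kpa < 0:
        raise ParameterError("modulus must be non-negative")
    if max_depth_nm <= 0:
        raise ParameterError("max depth must be positive")
    if k_n_per_m is None:
        # paper-typical cantilevers: 0.03 N/m bead microindentation, 0.48 N/m nano
        k_n_per_m = 0.03 if indenter.shape == "sphere" else 0.48

    forward = hertz_sphere_force if indenter.shape == "sphere" else sneddon_cone_force
    power = 1.5 if indenter.shape == "sphere" else 2.0
    if unload_m is None:
        unload_m = power

    n = protocol.n_points or 600
    n_app = n // 2
    n_ret = n - n_app
    rng = protocol.rng()

    f_max = float(forward(max_depth_nm, modulus_kpa, indenter))
    d_max = f_max / k_n_per_m
    if pre_contact_nm is None:
        # contact at mid-range: the pre-contact baseline spans half the approach
        pre_contact_nm = max_depth_nm + d_max
    z_c = pre_contact_nm
    z_max = z_c + max_depth_nm + d_max
    z_app = np.linspace(0.0, z_max, n_app)

    def solve_delta(z):
        if z <= z_c:
            return 0.0

        def bal(delta):
            return k_n_per_m * (z - z_c - delta) - float(forward(delta, modulus_kpa, indenter))

        return brentq(bal, 0.0, z - z_c, xtol=1e-9)

    if modulus_kpa == 0:
        delta_app = np.clip(z_app - z_c, 0, None)
        d_app = np.zeros_like(z_app)
    else:
        delta_app = np.array([solve_delta(z) for z in z_app])
        d_app = forward(delta_app, modulus_kpa, indenter) / k_n_per_m

    # unloading: depth h from max depth back to h_f, power law in (h - h_f)
    h_top = max_depth_nm
    h_f = unload_h_f_nm
    if h_f >= h_top:
        raise ParameterError("unloading residual depth must be below max depth")
    alpha = f_max / (h_top - h_f) ** unload_m if f_max > 0 else 0.0
    h_ret = np.linspace(h_top, h_f, n_ret)
    p_ret = alpha * np.clip(h_ret - h_f, 0, None) ** unload_m
    d_ret = p_ret / k_n_per_m
    z_ret = z_c + h_ret + d_ret

    z = np.concatenate([z_app, z_ret])
    d = np.concatenate([d_app, d_ret])
    if protocol.noise_sd > 0:
        d = d + rng.normal(0.0, protocol.noise_sd, size=d.size)
    segments = np.array([APPROACH] * n_app + [RETRACT] * n_ret)
    truth = {
        "modulus_kpa": modulus_kpa,
        "z_c_nm": z_c,
        "max_depth_nm": max_depth_nm,
        "f_max_nn": f_max,
        "unload_alpha": alpha,
        "unload_m": unload_m,
        "unload_h_f_nm": h_f,
        "indenter_shape": indenter.shape,
    }
    return ForceCurve(
        z, d, k_n_per_m, segments,
        meta={"seed": protocol.seed, "truth": truth},
    )


# --------------------------------------------------------------------------
# fibril topography
# --------------------------------------------------------------------------

def synth_fibril_topography(
    period_nm: float = D_PERIOD_NM,
    peak_height_nm: float = 4.0,
    length_nm: float = 2010.0,
    protocol: SynthProtocol = SynthProtocol(),
    pixel_nm: float = 1.0,
    ridge_height_nm: float = 100.0,
    ridge_width_nm: float = 120.0,
    waveform: str = "sine",
) -> Topography:
    """Synthetic collagen-fibril height image with axial D-banding.

    A straight ridge (Gaussian cross-section of peak ``ridge_height_nm``) on a
    flat background carries an axial modulation of amplitude
    ``peak_height_nm`` at the given period: a raised sinusoid by default, or a
    smoothed square gap/overlap profile (``waveform="gap"``).  Additive
    Gaussian height noise of ``protocol.noise_sd`` nm is applied to the whole
    grid.  The ridge's centre row index is stored in ``meta["ridge_row"]``.
    """
    if protocol.sampling_step is not None:
        pixel_nm = protocol.sampling_step
    if period_nm <= 2 * pixel_nm:
        raise ParameterError(
            f"period {period_nm} nm must exceed twice the pixel size (Nyquist)"
        )
    if waveform not in ("sine", "gap"):
        raise ParameterError(f"unknown waveform {waveform!r}")
    ncol = max(int(round(length_nm / pixel_nm)), 8)
    width_px = ridge_width_nm / pixel_nm
    nrow = max(int(round(3 * width_px)), 8)
    x_nm = np.arange(ncol) * pixel_nm
    rows = np.arange(nrow)
    centre = (nrow - 1) / 2.0
    sigma_px = width_px / 2.355  # FWHM -> sigma
    cross = np.exp(-0.5 * ((rows - centre) / sigma_px) ** 2)

    phase = 2 * math.pi * x_nm / period_nm
    if waveform == "sine":
        axial = 0.5 * (1 + np.cos(phase))
    else:
        # smoothed square wave: steep tanh of the sinusoid, rescaled to [0, 1]
        axial = 0.5 * (1 + np.tanh(4 * np.cos(phase)) / math.tanh(4))
    heights = cross[:, None] * (ridge_height_nm + peak_height_nm * axial[None, :])
    if protocol.noise_sd > 0:
        heights = heights + protocol.rng().normal(0.0, protocol.noise_sd, heights.shape)
    truth = {
        "period_nm": period_nm,
        "peak_height_nm": peak_height_nm,
        "ridge_height_nm": ridge_height_nm,
        "waveform": waveform,
    }
    return Topography(
        heights,
        pixel_nm,
        meta={"seed": protocol.seed, "ridge_row": int(round(centre)), "truth": truth},
    )


# --------------------------------------------------------------------------
# parallel-plate compression
# --------------------------------------------------------------------------

def synth_compression_test(
    e_true_kpa: float,
    r_h_um: float,
    r_v_um: float,
    protocol: SynthProtocol = SynthProtocol(),
    d0_um: float | None = None,
    poisson: float = 0.5,
    phase_protocol: PhaseProtocol | None = None,
    toe_strain: float = 0.08,
    force_noise_rel: float = 0.0,
) -> CompressionTest:
    """Simulate a five-cycle parallel-plate compression test.

    Displacement follows the protocol exactly (15 s ramp to 25% engineering
    strain, 2 s hold, 15 s recovery, 2 s rest, five cycles); force comes from
    the same two-plate Hertz model the analysis inverts, with an effective
    radius sqrt(R_eff) = 2 / (1/sqrt(R_h) + 1/sqrt(R_v)) so the two-axis
    averaged inversion recovers ``e_true_kpa`` exactly, and a soft "toe"
    (smoothstep attenuation below ``toe_strain``) that leaves the 10-20%
    strain analysis window untouched.  ``force_noise_rel`` applies
    multiplicative Gaussian force noise; ``protocol.noise_sd`` adds uN noise.
    """
    if e_true_kpa < 0:
        raise ParameterError("modulus must be non-negative")
    if r_h_um <= 0 or r_v_um <= 0:
        raise ParameterError("radii must be positive")
    if phase_protocol is None:
        phase_protocol = PhaseProtocol()
    if d0_um is None:
        d0_um = 2.0 * r_h_um
    dt = protocol.sampling_step or 0.1
    rng = protocol.rng()

    delta_max = phase_protocol.peak_strain * d0_um
    pp = phase_protocol
    t_phase = np.cumsum([0.0, pp.compress_s, pp.hold_s, pp.recover_s, pp.rest_s])
    period = pp.period_s
    t = np.arange(0.0, pp.n_cycles * period, dt)
    tc = t % period
    disp = np.zeros_like(t)
    ramp = (tc >= t_phase[0]) & (tc < t_phase[1])
    disp[ramp] = delta_max * (tc[ramp] - t_phase[0]) / pp.compress_s
    hold = (tc >= t_phase[1]) & (tc < t_phase[2])
    disp[hold] = delta_max
    rec = (tc >= t_phase[2]) & (tc < t_phase[3])
    disp[rec] = delta_max * (1 - (tc[rec] - t_phase[2]) / pp.recover_s)

    sqrt_r_eff = 2.0 / (1.0 / math.sqrt(r_h_um) + 1.0 / math.sqrt(r_v_um))
    r_eff = sqrt_r_eff**2
    force = two_plate_hertz_force(disp, e_true_kpa, r_eff, poisson)
    strain = disp / d0_um
    u = np.clip(strain / toe_strain, 0.0, 1.0)
    force = force * (u * u * (3 - 2 * u))  # smoothstep toe, identity past toe_strain
    if force_noise_rel > 0:
        force = force * (1 + rng.normal(0.0, force_noise_rel, force.size))
    if protocol.noise_sd > 0:
        force = force + rng.normal(0.0, protocol.noise_sd, force.size)

    truth = {
        "e_true_kpa": e_true_kpa,
        "r_eff_um": r_eff,
        "toe_strain": toe_strain,
        "poisson": poisson,
    }
    return CompressionTest(
        t, force, disp, r_h_um, r_v_um, d0_um,
        protocol=phase_protocol,
        meta={"seed": protocol.seed, "truth": truth},
    )


# --------------------------------------------------------------------------
# donor cohorts
# --------------------------------------------------------------------------

@dataclass
class VariableSpec:
    """Marginal specification of one cohort variable.

    For log-scale variables the group means are geometric means and ``sd`` is
    the standard deviation of the natural log; for linear variables both are
    on the raw scale.
    """

    control_mean: float
    case_mean: float
    sd: float
    log_scale: bool = True


def default_cohort_variables() -> dict:
    """Default cohort structure: a fibrotic (case) vs control contrast.

    Stiffness, cross-link densities, fibril diameter and swelling ratio are
    log-normal; collagen concentration is normal, unchanged between groups
    (the study's central negative finding).  Case donors are stiffer, carry
    more immature and mature cross-links, and have smaller, right-skewed
    fibril diameters and a lower swelling ratio.
    """
    return {
        "stiffness_kpa": VariableSpec(2.0, 5.0, 0.35),
        "collagen_ug_per_mg": VariableSpec(75.0, 75.0, 15.0, log_scale=False),
        "immature_per_collagen": VariableSpec(0.6, 1.2, 0.30),
        "mature_per_collagen": VariableSpec(0.25, 0.55, 0.30),
        "fibril_diameter_nm": VariableSpec(97.0, 80.0, 0.18),
        "swelling_ratio": VariableSpec(2.5, 1.9, 0.15),
    }


@dataclass
class CohortSpec:
    """Two-group donor cohort specification.

    ``target_corr`` is the within-group correlation between (log) stiffness
    and (log) mature cross-link density the study's key scatterplot reports;
    ``extra_corr`` adds further pairs on the transformed scale.  Missing
    cells are inserted completely at random at ``missing_rate`` per cell
    (group and donor identifiers are never blanked).
    """

    n_control: int = 15
    n_case: int = 17
    variables: dict = field(default_factory=default_cohort_variables)
    target_corr: float = 0.72
    extra_corr: dict = field(
        default_factory=lambda: {
            ("stiffness_kpa", "immature_per_collagen"): 0.35,
            ("immature_per_collagen", "mature_per_collagen"): 0.5,
        }
    )
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_control < 0 or self.n_case < 0:
            raise ParameterError("donor counts must be non-negative")
        if abs(self.target_corr) > 1:
            raise ParameterError("|target_corr| must be <= 1")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError("missing_rate must be in [0, 1)")


@dataclass
class CohortTable:
    """Per-donor records plus the generator's ground-truth sidecar."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_donors(self) -> int:
        return len(self.data)


def _cohort_correlation_matrix(spec: CohortSpec, names: list[str]) -> np.ndarray:
    corr = np.eye(len(names))
    pairs = dict(spec.extra_corr)
    pairs[("stiffness_kpa", "mature_per_collagen")] = spec.target_corr
    for (a, b), rho in pairs.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("requested correlation matrix is not positive definite") from exc
    return corr


def synth_cohort(spec: CohortSpec, protocol: SynthProtocol) -> CohortTable:
    """Generate a two-group donor cohort with known correlation structure.

    Each donor row is drawn from a multivariate normal on the transformed
    scale (natural log for log-scale variables) with the requested
    cross-variable correlations imposed via Cholesky factorisation, then
    mapped back to the raw scale.  MCAR missingness is applied per data cell.
    """
    rng = protocol.rng()
    names = list(spec.variables.keys())
    corr = _cohort_correlation_matrix(spec, names)
    chol = np.linalg.cholesky(corr)

    frames = []
    for group, count, prefix in (
        ("control", spec.n_control, "C"),
        ("case", spec.n_case, "F"),
    ):
        if count == 0:
            continue
        z = rng.standard_normal((count, len(names))) @ chol.T
        cols = {}
        for j, name in enumerate(names):
            v = spec.variables[name]
            mean = v.case_mean if group == "case" else v.control_mean
            if v.log_scale:
                cols[name] = np.exp(math.log(mean) + v.sd * z[:, j])
            else:
                cols[name] = mean + v.sd * z[:, j]
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        df.insert(0, "donor_id", [f"{prefix}{i + 1:03d}" for i in range(count)])
        frames.append(df)
    if not frames:
        data = pd.DataFrame(columns=["donor_id", "group", *names])
    else:
        data = pd.concat(frames, ignore_index=True)

    if spec.missing_rate > 0 and len(data):
        blank = rng.random((len(data), len(names))) < spec.missing_rate
        values = data[names].to_numpy(dtype=float)
        values[blank] = np.nan
        data[names] = values

    truth = {
        "spec": spec,
        "correlation_matrix": corr,
        "variable_order": names,
    }
    return CohortTable(data, meta={"seed": protocol.seed, "truth": truth})


# --------------------------------------------------------------------------
# dose-response tables
# --------------------------------------------------------------------------

@dataclass
class DoseResponseTable:
    data: pd.DataFrame  # columns: dose_um, activity_pct
    meta: dict = field(default_factory=dict)


def synth_dose_response(
    ic50_um: float,
    hill: float = 1.0,
    doses_um=None,
    protocol: SynthProtocol = SynthProtocol(),
    top: float = 100.0,
    bottom: float = 0.0,
    noise_rel: float = 0.0,
) -> DoseResponseTable:
    """Enzyme-inhibition activity table from a 4PL curve with known IC50.

    activity(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill) plus
    additive Gaussian noise of ``protocol.noise_sd`` (% activity units) and/or
    multiplicative noise with coefficient of variation ``noise_rel`` (the
    usual error model for enzymatic activity assays).
    """
    if ic50_um <= 0:
        raise ParameterError("ic50 must be positive")
    if doses_um is None:
        doses_um = np.geomspace(ic50_um / 300.0, ic50_um * 300.0, 10)
    doses = np.asarray(doses_um, dtype=float)
    if np.any(doses <= 0):
        raise ParameterError("doses must be positive")
    activity = bottom + (top - bottom) / (1.0 + (doses / ic50_um) ** hill)
    rng = protocol.rng()
    if noise_rel > 0:
        activity = activity * (1 + rng.normal(0.0, noise_rel, doses.size))
    if protocol.noise_sd > 0:
        activity = activity + rng.normal(0.0, protocol.noise_sd, doses.size)
    truth = {"ic50_um": ic50_um, "hill": hill, "top": top, "bottom": bottom}
    return DoseResponseTable(
        pd.DataFrame({"dose_um": doses, "activity_pct": activity}),
        meta={"seed": protocol.seed, "truth": truth},
    )
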