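"""AFM force-curve analysis: contact detection, force-indentation conversion,
Hertz (microindentation) and Oliver-Pharr (nanoindentation) modulus estimation,
and stiffness-map (elastograph) statistics.

Internal units are fixed: piezo displacement, deflection and indentation in nm,
force in nN, moduli in kPa, spring constant in N/m (1 N/m x 1 nm = 1 nN).
Conversions happen at the I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    FitError,
    InsufficientDataError,
    NoContactError,
    ParameterError,
    ValidationError,
)

APPROACH = "approach"
DWELL = "dwell"
RETRACT = "retract"

#: protocol minima for aggregation flags: curves per fibril / per donor
PROTOCOL_MIN = {"fibril": 30, "donor": 80}


@dataclass
class ForceCurve:
    """One indentation cycle as recorded by the instrument.

    Parameters
    ----------
    z_nm : piezo displacement (nm), increasing toward the sample on approach.
    deflection_nm : cantilever deflection (nm); force is ``k * deflection``.
    k_n_per_m : cantilever spring constant (N/m), the ratio of force to the
        deflection it causes.
    segments : per-sample labels from {approach, dwell, retract}.
    medium : "hydrated" or "dry".
    """

    z_nm: np.ndarray
    deflection_nm: np.ndarray
    k_n_per_m: float
    segments: np.ndarray
    medium: str = "hydrated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        self.segments = np.asarray(self.segments)
        if self.z_nm.shape != self.deflection_nm.shape or self.z_nm.ndim != 1:
            raise ValidationError("z and deflection must be 1-D arrays of equal length")
        if self.z_nm.size < 2:
            raise ValidationError("a force curve needs at least 2 samples")
        if self.segments.shape != self.z_nm.shape:
            raise ValidationError("segment labels must match the sample arrays")
        if not (self.k_n_per_m > 0):
            raise ValidationError("spring constant must be positive")

    @classmethod
    def from_force(cls, z_nm, force_nn, k_n_per_m, segments, **kw):
        """Build a curve from force samples (nN) instead of deflection."""
        force_nn = np.asarray(force_nn, dtype=float)
        return cls(z_nm, force_nn / k_n_per_m, k_n_per_m, segments, **kw)

    @property
    def force_nn(self) -> np.ndarray:
        return self.k_n_per_m * self.deflection_nm

    def segment(self, label: str) -> np.ndarray:
        """Boolean mask for one segment label."""
        return self.segments == label


@dataclass
class IndenterSpec:
    """Indenter geometry and sample Poisson ratio.

    shape is "sphere" (microindentation bead, radius in um) or "cone"
    (sharp tip: half-angle from the indentation axis in degrees plus a blunting
    tip radius in nm).  ``poisson`` is the sample's Poisson ratio; 0.5 encodes
    the incompressible assumption used for hydrated soft tissue.
    """

    shape: str = "sphere"
    radius_um: float = 7.5
    half_angle_deg: float = 20.0
    tip_radius_nm: float = 8.5
    poisson: float = 0.5

    def __post_init__(self):
        if self.shape not in ("sphere", "cone"):
            raise ValidationError(f"unknown indenter shape {self.shape!r}")
        if self.shape == "sphere" and not (self.radius_um > 0):
            raise ValidationError("sphere radius must be positive")
        if self.shape == "cone" and not (0 < self.half_angle_deg < 90):
            raise ValidationError("cone half-angle must be in (0, 90) degrees")
        if not (0 <= self.poisson <= 0.5):
            raise ValidationError("Poisson ratio must be in [0, 0.5]")

    @property
    def radius_nm(self) -> float:
        return self.radius_um * 1e3


@dataclass
class ContactPoint:
    index: int
    z_c_nm: float
    d_c_nm: float
    threshold_nm: float


@dataclass
class ModulusResult:
    """Outcome of a modulus fit.

    ``modulus_kpa`` is the Hertz sample modulus E for the sphere model and the
    plane-strain indentation modulus M = E/(1-nu^2) for Oliver-Pharr (the tip
    is treated as rigid; no tip-compliance correction is applied).
    """

    modulus_kpa: float
    model: str
    contact_index: int | None = None
    fit_window: tuple[int, int] | None = None
    residual_norm: float = 0.0
    n_points: int = 0
    flags: list[str] = field(default_factory=list)
    # Oliver-Pharr extras (nm / nN units)
    unload_stiffness_nn_per_nm: float | None = None
    h_max_nm: float | None = None
    h_f_nm: float | None = None
    h_c_nm: float | None = None
    alpha: float | None = None
    m_exponent: float | None = None
    contact_area_nm2: float | None = None


@dataclass
class ModulusSummary:
    mean_kpa: float
    sem_kpa: float
    n: int
    level: str
    below_protocol: bool


@dataclass
class ElastoMap:
    """Spatial map of indentation moduli over a tissue section."""

    x_um: np.ndarray
    y_um: np.ndarray
    modulus_kpa: np.ndarray
    donor: str = ""
    site: str = ""

    def __post_init__(self):
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.modulus_kpa = np.asarray(self.modulus_kpa, dtype=float)
        if not (self.x_um.shape == self.y_um.shape == self.modulus_kpa.shape):
            raise ValidationError("positions and moduli must have matching shapes")
        if np.any(self.modulus_kpa < 0):
            raise ValidationError("moduli must be non-negative")
        pts = np.column_stack([self.x_um.ravel(), self.y_um.ravel()])
        if len(pts) != len(np.unique(pts, axis=0)):
            raise ValidationError("map positions must be unique")


# --------------------------------------------------------------------------
# contact detection and conversion
# --------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_contact_point(curve: ForceCurve, threshold_factor: float = 5.0) -> ContactPoint:
    """Locate the tip-sample contact point on the approach segment.

    A line is fitted to the first half of the approach (robustified by one
    reweighting pass that drops gross outliers), the deflection excess over
    that baseline is compared against ``threshold_factor`` x the scaled MAD of
    the baseline residuals, and the first sustained exceedance is walked back
    to the baseline crossing.  Raises NoContactError if nothing exceeds the
    threshold.
    """
    mask = curve.segment(APPROACH)
    if not mask.any():
        raise ValidationError("curve has no approach segment")
    z = curve.z_nm[mask]
    d = curve.deflection_nm[mask]
    n = z.size
    nb = max(2, n // 2)
    coeff = np.polyfit(z[:nb], d[:nb], 1)
    resid = d[:nb] - np.polyval(coeff, z[:nb])
    s = _mad(resid)
    if s > 0:
        keep = np.abs(resid) <= 3 * s
        if keep.sum() >= 2:
            coeff = np.polyfit(z[:nb][keep], d[:nb][keep], 1)
            resid = d[:nb][keep] - np.polyval(coeff, z[:nb][keep])
            s = _mad(resid)
    scale = max(np.max(np.abs(d)), 1.0)
    threshold = threshold_factor * s + 1e-9 * scale
    excess = d - np.polyval(coeff, z)

    above = excess > threshold
    # require the exceedance to be sustained (next sample also above, or last)
    idx = None
    for i in np.flatnonzero(above):
        if i == n - 1 or above[i + 1]:
            idx = int(i)
            break
    if idx is None:
        raise NoContactError("no deflection exceeds the contact threshold")
    # walk back toward the baseline crossing
    back = threshold / threshold_factor  # ~1 MAD
    while idx > 0 and excess[idx - 1] > back:
        idx -= 1
    approach_indices = np.flatnonzero(mask)
    gi = int(approach_indices[idx])
    return ContactPoint(
        index=gi,
        z_c_nm=float(z[idx]),
        d_c_nm=float(np.polyval(coeff, z[idx])),
        threshold_nm=float(threshold),
    )


def to_force_indentation(
    curve: ForceCurve,
    contact: ContactPoint | None = None,
    segment: str = APPROACH,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a curve segment to indentation depth (nm) and force (nN).

    F = k * (d - d_c) and delta = (z - z_c) - (d - d_c): the piezo travel in
    excess of the cantilever deflection is what indents the sample.  Only the
    post-contact part with delta >= 0 is returned.
    """
    if contact is None:
        contact = detect_contact_point(curve)
    mask = curve.segment(segment)
    if not mask.any():
        raise ValidationError(f"curve has no {segment!r} segment")
    z = curve.z_nm[mask]
    d = curve.deflection_nm[mask] - contact.d_c_nm
    delta = (z - contact.z_c_nm) - d
    force = curve.k_n_per_m * d
    keep = (z >= contact.z_c_nm) & (delta >= 0)
    return delta[keep], force[keep]


# --------------------------------------------------------------------------
# Hertz sphere fit (microindentation)
# --------------------------------------------------------------------------

#: kPa expressed in nN/nm^2
_KPA = 1e-6


def hertz_sphere_force(delta_nm, modulus_kpa, indenter: IndenterSpec):
    """Forward Hertz model F = (4/3) (E/(1-nu^2)) sqrt(R) delta^{3/2} (nN)."""
    delta = np.asarray(delta_nm, dtype=float)
    e_red = modulus_kpa * _KPA / (1 - indenter.poisson**2)
    return (4.0 / 3.0) * e_red * math.sqrt(indenter.radius_nm) * np.clip(delta, 0, None) ** 1.5


def sneddon_cone_force(delta_nm, modulus_kpa, indenter: IndenterSpec):
    """Forward Sneddon cone F = (2/pi) (E/(1-nu^2)) tan(theta) delta^2 (nN)."""
    delta = np.asarray(delta_nm, dtype=float)
    e_red = modulus_kpa * _KPA / (1 - indenter.poisson**2)
    tan = math.tan(math.radians(indenter.half_angle_deg))
    return (2.0 / math.pi) * e_red * tan * np.clip(delta, 0, None) ** 2


def fit_hertz_sphere(
    delta_nm,
    force_nn,
    indenter: IndenterSpec,
    min_points: int = 10,
    refine_contact: bool = True,
) -> ModulusResult:
    """Least-squares Hertz sphere fit returning the sample modulus E (kPa).

    The model F = (4/3)(E/(1-nu^2)) sqrt(R) delta^{3/2} is linear in E, so
    the base fit is an exact projection onto delta^{3/2}.  Because upstream
    contact detection is quantised to the sampling grid, a small contact
    offset delta0 (bounded to 10% of the depth range) is refined jointly by
    default; set ``refine_contact=False`` for the pure projection.
    """
    from scipy.optimize import curve_fit

    if indenter.shape != "sphere":
        raise ParameterError("fit_hertz_sphere needs a spherical indenter")
    delta = np.asarray(delta_nm, dtype=float)
    force = np.asarray(force_nn, dtype=float)
    pos = delta > 0
    if pos.sum() < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} positive-indentation points, got {int(pos.sum())}"
        )
    x = delta[pos]
    y = force[pos]
    amp = float(np.dot(y, x**1.5) / np.dot(x**1.5, x**1.5))
    if amp < 0:
        raise FitError("fitted force amplitude is negative")

    if refine_contact:
        span = 0.1 * float(x.max())

        def model(d, a, d0):
            return a * np.clip(d - d0, 0, None) ** 1.5

        try:
            popt, _ = curve_fit(
                model, x, y, p0=[amp, 0.0], bounds=([0, -span], [np.inf, span]),
                maxfev=10000,
            )
            amp = float(popt[0])
            resid = float(np.linalg.norm(y - model(x, *popt)))
        except (RuntimeError, ValueError):
            resid = float(np.linalg.norm(y - amp * x**1.5))
    else:
        resid = float(np.linalg.norm(y - amp * x**1.5))

    e_red = amp * 3.0 / (4.0 * math.sqrt(indenter.radius_nm))
    modulus = e_red * (1 - indenter.poisson**2) / _KPA
    return ModulusResult(
        modulus_kpa=modulus,
        model="hertz_sphere",
        residual_norm=resid,
        n_points=int(pos.sum()),
    )


# --------------------------------------------------------------------------
# Oliver-Pharr (nanoindentation)
# --------------------------------------------------------------------------

def blunted_cone_area(h_c_nm: float, indenter: IndenterSpec) -> float:
    """Projected contact area (nm^2) of a cone blunted by a spherical cap.

    For contact depths within the cap the area is that of a sphere chord;
    beyond the tangency depth h_t = R_t (1 - sin(theta)) the profile is the
    cone offset so the two pieces join continuously.
    """
    theta = math.radians(indenter.half_angle_deg)
    r_t = indenter.tip_radius_nm
    h_c = max(float(h_c_nm), 0.0)
    h_t = r_t * (1 - math.sin(theta))
    if h_c <= h_t:
        return math.pi * max(2 * r_t * h_c - h_c**2, 0.0)
    a = math.tan(theta) * (h_c + r_t * (1 - math.sin(theta)) / math.sin(theta))
    return math.pi * a**2


def fit_oliver_pharr(
    curve: ForceCurve,
    indenter: IndenterSpec,
    epsilon: float = 0.75,
    beta: float = 1.0,
    window: tuple[float, float] = (0.75, 0.95),
    min_points: int = 10,
) -> ModulusResult:
    """Oliver-Pharr analysis of the unloading (retract) segment.

    A power law P = alpha (h - h_f)^m is fitted to the part of unloading with
    P in ``window`` x P_max; the unloading stiffness S = dP/dh at h_max, the
    contact depth h_c = h_max - epsilon P_max / S, and the indentation modulus
    M = sqrt(pi) S / (2 beta sqrt(A(h_c))) with the blunted-cone area function.
    M is the plane-strain modulus (rigid tip assumed).
    """
    from scipy.optimize import curve_fit

    mask = curve.segment(RETRACT)
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"unloading needs >= {min_points} points, got {int(mask.sum())}"
        )
    contact = detect_contact_point(curve)
    z = curve.z_nm[mask]
    d = curve.deflection_nm[mask] - contact.d_c_nm
    h = (z - contact.z_c_nm) - d
    p = curve.k_n_per_m * d
    keep = (p > 0) & (h > 0)
    if keep.sum() < min_points:
        raise InsufficientDataError("too few positive unloading points")
    h, p = h[keep], p[keep]
    order = np.argsort(h)
    h, p = h[order], p[order]
    # monotonicity beyond noise: unloading force must broadly increase with depth
    if np.corrcoef(h, p)[0, 1] < 0.5:
        raise FitError("unloading segment is not monotone within tolerance")

    p_max = float(p.max())
    h_max = float(h[np.argmax(p)])
    sel = (p >= window[0] * p_max) & (p <= window[1] * p_max)
    if sel.sum() < 5:
        sel = p >= window[0] * p_max
    if sel.sum() < 5:
        raise InsufficientDataError("too few points in the unloading fit window")
    hw, pw = h[sel], p[sel]

    h_lo = float(hw.min())

    def model(hh, log_alpha, h_f, m):
        return np.exp(log_alpha) * np.clip(hh - h_f, 1e-12, None) ** m

    m0 = 1.5
    h_f0 = h_lo - 0.1 * (h_max - h_lo) - 1e-6
    a0 = p_max / max(h_max - h_f0, 1e-12) ** m0
    try:
        popt, _ = curve_fit(
            model,
            hw,
            pw,
            p0=[math.log(a0), h_f0, m0],
            bounds=([-50, -10 * h_max, 0.5], [50, h_lo, 5.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(f"unloading power-law fit failed: {exc}") from exc
    alpha = float(np.exp(popt[0]))
    h_f = float(popt[1])
    m = float(popt[2])

    s = alpha * m * (h_max - h_f) ** (m - 1)  # nN/nm
    h_c = h_max - epsilon * p_max / s
    area = blunted_cone_area(h_c, indenter)
    if area <= 0:
        raise FitError("non-positive contact area")
    modulus = math.sqrt(math.pi) * s / (2 * beta * math.sqrt(area)) / _KPA

    flags = []
    if not (1.0 <= m <= 3.0):
        flags.append("exponent_out_of_range")
    resid = float(np.linalg.norm(pw - model(hw, *popt)))
    return ModulusResult(
        modulus_kpa=modulus,
        model="oliver_pharr",
        contact_index=contact.index,
        residual_norm=resid,
        n_points=int(sel.sum()),
        flags=flags,
        unload_stiffness_nn_per_nm=float(s),
        h_max_nm=h_max,
        h_f_nm=h_f,
        h_c_nm=float(h_c),
        alpha=alpha,
        m_exponent=m,
        contact_area_nm2=float(area),
    )


# --------------------------------------------------------------------------
# aggregation and elastograph statistics
# --------------------------------------------------------------------------

def aggregate_modulus(results, level: str = "fibril") -> ModulusSummary:
    """Mean / SEM / n over a set of modulus results, with a protocol flag.

    ``level`` selects the minimum-n convention: 30 curves per fibril, 80 per
    donor; summaries below the minimum are carried but flagged.
    """
    if level not in PROTOCOL_MIN:
        raise ParameterError(f"unknown aggregation level {level!r}")
    values = np.array(
        [r.modulus_kpa if isinstance(r, ModulusResult) else float(r) for r in results],
        dtype=float,
    )
    if values.size == 0:
        raise ValidationError("cannot aggregate an empty result list")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return ModulusSummary(
        mean_kpa=mean,
        sem_kpa=sem,
        n=int(values.size),
        level=level,
        below_protocol=values.size < PROTOCOL_MIN[level],
    )


def elastograph_stats(emap: ElastoMap) -> dict:
    """Mean modulus and coefficient of variation of a stiffness map.

    CV = 100 * sample SD / mean (the n-1 convention), the figure-of-merit the
    study reports for spatial stiffness heterogeneity.
    """
    values = emap.modulus_kpa.ravel()
    if values.size < 2:
        raise InsufficientDataError("elastograph statistics need >= 2 points")
    mean = float(values.mean())
    if mean <= 0:
        raise ParameterError("CV undefined for non-positive mean modulus")
    cv = 100.0 * float(values.std(ddof=1)) / mean
    return {"mean_kpa": mean, "cv_percent": cv, "n": int(values.size)}


def render_elastograph(emap: ElastoMap, path=None):
    """Render the map with matplotlib; returns the figure.

    Regular grids are shown as an image, irregular point sets as a scatter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    xs = np.unique(emap.x_um)
    ys = np.unique(emap.y_um)
    if xs.size * ys.size == emap.modulus_kpa.size:
        grid = np.full((ys.size, xs.size), np.nan)
        xi = np.searchsorted(xs, emap.x_um.ravel())
        yi = np.searchsorted(ys, emap.y_um.ravel())
        grid[yi, xi] = emap.modulus_kpa.ravel()
        im = ax.imshow(
            grid,
            origin="lower",
            extent=(xs.min(), xs.max(), ys.min(), ys.max()),
            cmap="viridis",
        )
    else:
        im = ax.scatter(emap.x_um, emap.y_um, c=emap.modulus_kpa, cmap="viridis")
    fig.colorbar(im, ax=ax, label="indentation modulus (kPa)")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
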