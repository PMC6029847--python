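"""Parallel-plate compression analysis of quasi-spherical 3D cultures.

A sample is compressed between rigid plates through five preconditioning
cycles (15 s compression to 25% engineering strain, 2 s hold, 15 s recovery,
2 s rest); the compression phase of the fifth, stabilised cycle is converted
to engineering stress/strain, the toe region is excluded by restricting to
the 10-20% strain window, and the Young's modulus is inverted point-wise from
the two-plate Hertz relation for an elastic sphere (each plate contact takes
half the platen travel), averaging the values obtained with the horizontal
and vertical sample radii.

Units: time s, force uN, displacement and radii um, stress Pa, modulus kPa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CycleCountError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

PHASES = ("compress", "hold", "recover", "rest")


@dataclass
class PhaseProtocol:
    """Cycle timing protocol (durations in seconds)."""

    compress_s: float = 15.0
    hold_s: float = 2.0
    recover_s: float = 15.0
    rest_s: float = 2.0
    n_cycles: int = 5
    peak_strain: float = 0.25

    @property
    def period_s(self) -> float:
        return self.compress_s + self.hold_s + self.recover_s + self.rest_s


@dataclass
class CompressionTest:
    """Raw trace of one parallel-plate test plus sample geometry."""

    time_s: np.ndarray
    force_un: np.ndarray
    displacement_um: np.ndarray
    r_h_um: float
    r_v_um: float
    d0_um: float
    protocol: PhaseProtocol = field(default_factory=PhaseProtocol)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_un = np.asarray(self.force_un, dtype=float)
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if not (self.time_s.shape == self.force_un.shape == self.displacement_um.shape):
            raise ValidationError("trace arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time must be strictly increasing")
        for name, v in (("r_h_um", self.r_h_um), ("r_v_um", self.r_v_um), ("d0_um", self.d0_um)):
            if not (v > 0):
                raise ValidationError(f"{name} must be positive")


@dataclass
class Cycle:
    index: int           # 1-based cycle number
    sample_slice: slice  # indices into the parent trace
    phases: np.ndarray   # per-sample phase labels within the slice


@dataclass
class StressStrain:
    stress_pa: np.ndarray
    strain: np.ndarray
    cycle_index: int
    phases: np.ndarray

    def __post_init__(self):
        if np.any(self.strain < -1e-9) or np.any(self.strain > 0.5 + 1e-9):
            raise ValidationError("engineering strain outside [0, 0.5]")
        if not np.all(np.isfinite(self.stress_pa)):
            raise ValidationError("stress must be finite")


@dataclass
class YoungsModulusResult:
    e_horizontal_kpa: float
    e_vertical_kpa: float
    e_kpa: float
    poisson: float
    strain_window: tuple[float, float]
    n_points: int
    flags: list[str] = field(default_factory=list)


def segment_cycles(test: CompressionTest) -> list[Cycle]:
    """Split a trace into compression cycles and label phases.

    Cycles are located from displacement extrema (peak plateaus); phases are
    assigned from the sign of the displacement increment and the displacement
    level, so the segmentation is invariant to shifting the time axis.
    Raises CycleCountError when fewer cycles than the protocol's are found.
    """
    disp = test.displacement_um
    dmax = float(disp.max())
    if dmax <= 0:
        raise ValidationError("displacement never leaves zero")
    d = np.diff(disp)
    tol = 1e-6 * dmax
    labels = np.empty(disp.size, dtype="<U8")
    rising = np.concatenate([d > tol, [False]])
    falling = np.concatenate([d < -tol, [False]])
    # carry the last increment's sign onto the final sample
    rising[-1] = d[-1] > tol
    falling[-1] = d[-1] < -tol
    high = disp > 0.5 * dmax
    labels[rising] = "compress"
    labels[falling] = "recover"
    plateau = ~(rising | falling)
    labels[plateau & high] = "hold"
    labels[plateau & ~high] = "rest"

    onsets = [
        i
        for i in range(disp.size)
        if labels[i] == "compress" and (i == 0 or labels[i - 1] != "compress")
    ]
    found = len(onsets)
    if found < test.protocol.n_cycles:
        raise CycleCountError(found, test.protocol.n_cycles)
    cycles = []
    bounds = onsets + [disp.size]
    for k in range(found):
        sl = slice(bounds[k], bounds[k + 1])
        cycles.append(Cycle(index=k + 1, sample_slice=sl, phases=labels[sl]))
    return cycles


def phase_durations(test: CompressionTest, cycle: Cycle) -> dict:
    """Duration (s) of each phase within a cycle."""
    t = test.time_s[cycle.sample_slice]
    dt = np.diff(t, append=t[-1] + (t[-1] - t[-2]))
    return {ph: float(dt[cycle.phases == ph].sum()) for ph in PHASES}


def stabilisation_drift(test: CompressionTest, cycles=None) -> float:
    """Relative peak-force drift between the 4th and 5th cycle (diagnostic).

    The protocol treats cycles 1-4 as preconditioning; a small drift confirms
    the force response has stabilised before the analysed fifth cycle.
    """
    if cycles is None:
        cycles = segment_cycles(test)
    peaks = [float(test.force_un[c.sample_slice].max()) for c in cycles]
    if peaks[-2] == 0:
        return math.inf
    return abs(peaks[-1] - peaks[-2]) / abs(peaks[-2])


def engineering_stress_strain(test: CompressionTest, cycle: Cycle) -> StressStrain:
    """Engineering stress (Pa) and strain for one cycle.

    sigma = F / (pi d0^2 / 4) referenced to the undeformed horizontal
    cross-section, eps = delta / d0.  1 uN/um^2 = 1 MPa, hence the 1e6 factor.
    """
    if not (test.d0_um > 0):
        raise ParameterError("d0 must be positive")
    f = test.force_un[cycle.sample_slice]
    delta = test.displacement_um[cycle.sample_slice]
    area = math.pi * test.d0_um**2 / 4.0
    return StressStrain(
        stress_pa=f / area * 1e6,
        strain=delta / test.d0_um,
        cycle_index=cycle.index,
        phases=cycle.phases,
    )


def select_linear_region(ss: StressStrain, bounds: tuple[float, float] = (0.10, 0.20)) -> np.ndarray:
    """Indices of the linear-regime samples (strain within ``bounds``).

    The initial toe region, where stress rises slowly, is excluded by
    construction.  Raises when the curve never reaches the upper bound.
    """
    strain = ss.strain
    if float(strain.max()) < bounds[1] - 1e-9:
        raise InsufficientDataError(
            f"max strain {strain.max():.3f} below linear-region bound {bounds[1]}"
        )
    idx = np.flatnonzero((strain >= bounds[0]) & (strain <= bounds[1]))
    if idx.size == 0:
        raise InsufficientDataError("no samples inside the linear strain window")
    return idx


#: kPa expressed in uN/um^2
_KPA_UN_UM2 = 1e-3


def two_plate_hertz_force(delta_um, e_kpa, radius_um, poisson=0.5):
    """Forward two-plate Hertz force (uN): F = (4/3)(E/(1-nu^2)) sqrt(R) (delta/2)^{3/2}.

    The total platen travel is split equally between the two plate contacts.
    """
    delta = np.asarray(delta_um, dtype=float)
    e_red = e_kpa * _KPA_UN_UM2 / (1 - poisson**2)
    return (4.0 / 3.0) * e_red * np.sqrt(radius_um) * np.clip(delta / 2.0, 0, None) ** 1.5


def young_modulus_sphere(
    test: CompressionTest,
    cycle: Cycle | None = None,
    poisson: float = 0.5,
    bounds: tuple[float, float] = (0.10, 0.20),
    method: str = "pointwise",
) -> YoungsModulusResult:
    """Young's modulus of a quasi-spherical sample from the fifth-cycle loading.

    Within the linear strain window each sample point is inverted through the
    two-plate Hertz relation for both the horizontal and vertical radii; E per
    axis is the window mean ("pointwise", the default) or comes from a single
    3/2-power-law fit over the window ("powerlaw").  The reported E averages
    the two axis values.  nu defaults to 0.5 (incompressible hydrated tissue).
    """
    if method not in ("pointwise", "powerlaw"):
        raise ParameterError(f"unknown method {method!r}")
    if cycle is None:
        cycles = segment_cycles(test)
        cycle = cycles[test.protocol.n_cycles - 1]
    ss = engineering_stress_strain(test, cycle)
    comp = cycle.phases == "compress"
    ss_comp = StressStrain(
        ss.stress_pa[comp], ss.strain[comp], cycle.index, ss.phases[comp]
    )
    idx = select_linear_region(ss_comp, bounds)
    f = test.force_un[cycle.sample_slice][comp][idx]
    delta = test.displacement_um[cycle.sample_slice][comp][idx]

    flags: list[str] = []
    e_axis = {}
    for name, radius in (("h", test.r_h_um), ("v", test.r_v_um)):
        half = delta / 2.0
        if method == "pointwise":
            e_red = f * 3.0 / (4.0 * np.sqrt(radius) * half**1.5)
            e_vals = e_red * (1 - poisson**2) / _KPA_UN_UM2
            e = float(e_vals.mean())
        else:
            x = half**1.5
            amp = float(np.dot(f, x) / np.dot(x, x))
            e = amp * 3.0 / (4.0 * math.sqrt(radius)) * (1 - poisson**2) / _KPA_UN_UM2
        if e < 0:
            flags.append(f"negative_modulus_{name}")
        e_axis[name] = e
        a_over_r = math.sqrt(float(half.max()) / radius)
        if a_over_r > 0.5:
            warnings.warn(
                f"contact radius reaches {a_over_r:.2f} R on axis {name}; "
                "Hertz small-contact assumption is strained",
                stacklevel=2,
            )
    return YoungsModulusResult(
        e_horizontal_kpa=e_axis["h"],
        e_vertical_kpa=e_axis["v"],
        e_kpa=0.5 * (e_axis["h"] + e_axis["v"]),
        poisson=poisson,
        strain_window=bounds,
        n_points=int(idx.size),
        flags=flags,
    )
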