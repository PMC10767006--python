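"""Biaxial extension-inflation analysis of arteries under the thin-wall assumption.

The experiment: a cannulated artery segment is held at a fixed axial stretch
``λz`` while luminal pressure is stepped (typically 0–120 mmHg in 10 mmHg
increments), recording outer diameter and axial force at every step.  This
module turns those raw sweeps, together with the traced unloaded ring
geometry, into kinematics (stretches, deformed wall thickness) and mean
biaxial Cauchy stresses

    σθ = P·ri / h
    σz = (f + P·π·ri²) / (π·h·(2·ri + h))

with the deformed inner diameter obtained from wall incompressibility

    di = sqrt(do² − (Do² − Di²)/λz).

It also estimates the in vivo axial stretch (the stretch at which axial
force stays constant during pressurization), interpolates the mechanical
state at mean arterial pressure (MAP), and computes the circumferential
tangent modulus dσθ/dλθ there.

Units follow the bench conventions: pressures in mmHg (converted internally
with 1 mmHg = 0.1333224 kPa), lengths in mm, forces in mN, stresses in kPa,
moduli in MPa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import (
    ExtrapolationRefusedError,
    IllConditionedFitError,
    InfeasibleDeformationError,
    InsufficientDataError,
    InvalidGeometryError,
)

logger = logging.getLogger(__name__)

#: 1 mmHg in kPa (CODATA conventional value).
MMHG_TO_KPA = 0.1333224

#: Default axial-force plateau threshold, mN (50 μN).
FORCE_PLATEAU_THRESHOLD_MN = 0.05

#: Tolerance on the incompressibility residual (do² − di²)·λz − (Do² − Di²), mm².
INCOMPRESSIBILITY_TOL_MM2 = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnloadedGeometry:
    """Reference (unloaded) ring geometry traced from a cut ring.

    Attributes
    ----------
    outer_diameter, inner_diameter : float
        Unloaded outer/inner diameters ``Do``, ``Di`` in mm.
    """

    outer_diameter: float
    inner_diameter: float

    def __post_init__(self) -> None:
        if not (self.outer_diameter > self.inner_diameter > 0):
            raise InvalidGeometryError(
                f"require Do > Di > 0, got Do={self.outer_diameter}, "
                f"Di={self.inner_diameter}"
            )

    @property
    def wall_thickness(self) -> float:
        """Unloaded wall thickness H = (Do − Di)/2, mm."""
        return 0.5 * (self.outer_diameter - self.inner_diameter)

    @property
    def mid_wall_radius(self) -> float:
        """Unloaded mid-wall radius (Do + Di)/4, mm."""
        return 0.25 * (self.outer_diameter + self.inner_diameter)


@dataclass(frozen=True)
class InflationRecord:
    """One pressurization sweep at a fixed axial stretch.

    ``samples`` is an ordered sequence of (pressure mmHg, outer diameter mm,
    axial force mN) tuples with strictly increasing pressures.
    """

    axial_stretch: float
    samples: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(tuple(s) for s in self.samples))
        if self.axial_stretch < 1.0:
            raise ValueError(f"axial stretch must be >= 1, got {self.axial_stretch}")
        p = self.pressures
        if len(p) and np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")
        if len(self.samples) and np.any(self.outer_diameters <= 0):
            raise ValueError("outer diameters must be positive")

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def outer_diameters(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)

    @property
    def axial_forces(self) -> np.ndarray:
        return np.array([s[2] for s in self.samples], dtype=float)


@dataclass(frozen=True)
class BiaxialDataset:
    """All sweeps for one specimen plus its reference geometry and MAP."""

    geometry: UnloadedGeometry
    records: tuple[InflationRecord, ...]
    map_pressure: float
    group_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 1:
            raise ValueError("dataset needs at least one inflation record")
        stretches = [r.axial_stretch for r in self.records]
        if len(set(stretches)) != len(stretches):
            raise ValueError("records must be at distinct axial stretches")


@dataclass(frozen=True)
class DeformedState:
    """Full kinematic and stress state at one pressure step.

    Diameters and thickness in mm, stresses in kPa.
    """

    pressure: float
    outer_diameter: float
    inner_diameter: float
    wall_thickness: float
    circ_stretch: float
    axial_stretch: float
    circ_stress: float
    axial_stress: float


@dataclass(frozen=True)
class StressStrainCurve:
    """DeformedStates of one sweep, ordered by pressure, sharing one λz."""

    axial_stretch: float
    states: tuple[DeformedState, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s.pressure for s in self.states], dtype=float)

    @property
    def circ_stretches(self) -> np.ndarray:
        return np.array([s.circ_stretch for s in self.states], dtype=float)

    @property
    def circ_stresses(self) -> np.ndarray:
        return np.array([s.circ_stress for s in self.states], dtype=float)


@dataclass(frozen=True)
class InVivoStretchEstimate:
    """Estimated in vivo axial stretch λz* and its plateau diagnostics."""

    value: float
    force_variation: float
    within_threshold: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def geometry_from_ring_circumferences(
    outer_circ: float, inner_circ: float
) -> UnloadedGeometry:
    """Build the reference geometry from manually traced ring circumferences.

    Parameters are the traced outer/inner circumferences in mm; diameters are
    circumference / π.
    """
    if not (outer_circ > inner_circ > 0):
        raise InvalidGeometryError(
            f"require outer_circ > inner_circ > 0, got {outer_circ}, {inner_circ}"
        )
    return UnloadedGeometry(outer_circ / math.pi, inner_circ / math.pi)


def inner_diameter(do: float, geometry: UnloadedGeometry, lambda_z: float) -> float:
    """Deformed inner diameter from wall incompressibility.

    ``di = sqrt(do² − (Do² − Di²)/λz)``: the unloaded wall cross-section area
    is conserved after axial stretching by λz.
    """
    if lambda_z <= 0:
        raise ValueError(f"axial stretch must be positive, got {lambda_z}")
    arg = do**2 - (geometry.outer_diameter**2 - geometry.inner_diameter**2) / lambda_z
    if arg <= 0:
        raise InfeasibleDeformationError(
            f"outer diameter {do} mm cannot accommodate the wall volume at "
            f"λz={lambda_z} (squared inner diameter {arg:.3e} <= 0)"
        )
    return math.sqrt(arg)


def cauchy_stresses(
    pressure_mmhg: float, ri: float, h: float, f: float
) -> tuple[float, float]:
    """Mean biaxial Cauchy stresses of a pressurized thin-walled cylinder.

    Parameters
    ----------
    pressure_mmhg : float
        Transmural pressure, mmHg.
    ri : float
        Deformed inner radius, mm.
    h : float
        Deformed wall thickness, mm.
    f : float
        Measured axial force, mN.

    Returns
    -------
    (σθ, σz) in kPa.  With lengths in mm, forces in mN and pressure in kPa
    the expressions are dimensionally consistent (1 kPa·mm² = 1 mN).
    """
    if ri <= 0 or h <= 0:
        raise ValueError(f"need ri > 0 and h > 0, got ri={ri}, h={h}")
    p_kpa = pressure_mmhg * MMHG_TO_KPA
    sigma_theta = p_kpa * ri / h
    sigma_z = (f + p_kpa * math.pi * ri**2) / (math.pi * h * (2 * ri + h))
    return sigma_theta, sigma_z


def circumferential_stretch(
    do: float,
    di: float,
    geometry: UnloadedGeometry,
    convention: Literal["mid-wall", "inner-wall"] = "mid-wall",
) -> float:
    """Circumferential stretch ratio λθ.

    Default is the mid-wall circumference ratio (do + di)/(Do + Di), matching
    the "mean" character of the thin-wall stresses; ``inner-wall`` uses the
    inner circumference ratio di/Di instead.
    """
    if not (do > di > 0):
        raise ValueError(f"require do > di > 0, got do={do}, di={di}")
    if convention == "mid-wall":
        return (do + di) / (geometry.outer_diameter + geometry.inner_diameter)
    if convention == "inner-wall":
        return di / geometry.inner_diameter
    raise ValueError(f"unknown λθ convention {convention!r}")


def process_record(
    record: InflationRecord,
    geometry: UnloadedGeometry,
    stretch_convention: Literal["mid-wall", "inner-wall"] = "mid-wall",
) -> StressStrainCurve:
    """Process one sweep into a stress–strain curve of DeformedStates."""
    if len(record.samples) == 0:
        raise InsufficientDataError("inflation record has no samples")
    lz = record.axial_stretch
    states = []
    for idx, (p, do, f) in enumerate(record.samples):
        try:
            di = inner_diameter(do, geometry, lz)
        except InfeasibleDeformationError as err:
            raise InfeasibleDeformationError(
                f"sample {idx} (P={p} mmHg): {err}"
            ) from err
        h = 0.5 * (do - di)
        st, sz = cauchy_stresses(p, 0.5 * di, h, f)
        lt = circumferential_stretch(do, di, geometry, stretch_convention)
        states.append(
            DeformedState(
                pressure=p,
                outer_diameter=do,
                inner_diameter=di,
                wall_thickness=h,
                circ_stretch=lt,
                axial_stretch=lz,
                circ_stress=st,
                axial_stress=sz,
            )
        )
    return StressStrainCurve(axial_stretch=lz, states=tuple(states))


def _force_variation(
    record: InflationRecord, metric: Literal["range", "std"]
) -> float:
    f = record.axial_forces
    if metric == "range":
        return float(f.max() - f.min())
    if metric == "std":
        return float(f.std(ddof=0))
    raise ValueError(f"unknown plateau metric {metric!r}")


def estimate_in_vivo_stretch(
    dataset: BiaxialDataset,
    force_threshold: float = FORCE_PLATEAU_THRESHOLD_MN,
    metric: Literal["range", "std"] = "range",
    interpolate: bool = False,
) -> InVivoStretchEstimate:
    """Estimate the in vivo axial stretch from the axial-force plateau.

    The in vivo stretch is the axial stretch at which axial force stays
    constant during pressurization.  For each sweep the force variation
    (max − min by default) is computed; the tested stretch minimizing it is
    returned.  ``within_threshold`` reports whether that variation is at or
    below ``force_threshold`` (default 0.05 mN, i.e. 50 μN).

    With ``interpolate=True`` and ≥ 3 sweeps, a parabola through the three
    lowest (λz, variation) points refines the estimate between tested values.
    """
    if len(dataset.records) < 2:
        raise InsufficientDataError(
            "in vivo stretch estimation needs >= 2 sweeps at distinct stretches"
        )
    for r in dataset.records:
        if len(r.samples) < 2:
            raise InsufficientDataError(
                f"sweep at λz={r.axial_stretch} has < 2 samples; "
                "plateau analysis is undefined"
            )
    recs = sorted(dataset.records, key=lambda r: r.axial_stretch)
    lz = np.array([r.axial_stretch for r in recs])
    var = np.array([_force_variation(r, metric) for r in recs])
    k = int(np.argmin(var))
    value = float(lz[k])
    variation = float(var[k])

    if interpolate and len(recs) >= 3:
        order = np.argsort(var)[:3]
        x, y = lz[order], var[order]
        coeffs = np.polyfit(x, y, 2)
        if coeffs[0] > 0:  # parabola opens upward -> interior minimum
            vtx = -coeffs[1] / (2 * coeffs[0])
            if x.min() <= vtx <= x.max():
                value = float(vtx)
                variation = float(np.polyval(coeffs, vtx))

    within = variation <= force_threshold
    if not within:
        logger.warning(
            "axial-force plateau not reached: best variation %.4f mN at "
            "λz=%.3f exceeds threshold %.4f mN",
            variation, value, force_threshold,
        )
    return InVivoStretchEstimate(
        value=value, force_variation=variation, within_threshold=within
    )


def state_at_pressure(curve: StressStrainCurve, p_target: float) -> DeformedState:
    """Mechanical state at a target pressure by linear interpolation.

    All state fields are interpolated linearly in pressure between the two
    bracketing samples; an exact sample is returned unchanged.  Used to
    evaluate "at MAP" quantities between 10 mmHg protocol steps.
    """
    p = curve.pressures
    if len(p) == 0:
        raise InsufficientDataError("empty curve")
    if not (p.min() <= p_target <= p.max()):
        raise ExtrapolationRefusedError(
            f"P={p_target} mmHg outside sampled range [{p.min()}, {p.max()}]"
        )
    exact = np.flatnonzero(np.isclose(p, p_target, rtol=0, atol=1e-12))
    if len(exact):
        return curve.states[int(exact[0])]
    j = int(np.searchsorted(p, p_target))
    lo, hi = curve.states[j - 1], curve.states[j]
    t = (p_target - lo.pressure) / (hi.pressure - lo.pressure)

    def lerp(a: float, b: float) -> float:
        return a + t * (b - a)

    return DeformedState(
        pressure=p_target,
        outer_diameter=lerp(lo.outer_diameter, hi.outer_diameter),
        inner_diameter=lerp(lo.inner_diameter, hi.inner_diameter),
        wall_thickness=lerp(lo.wall_thickness, hi.wall_thickness),
        circ_stretch=lerp(lo.circ_stretch, hi.circ_stretch),
        axial_stretch=curve.axial_stretch,
        circ_stress=lerp(lo.circ_stress, hi.circ_stress),
        axial_stress=lerp(lo.axial_stress, hi.axial_stress),
    )


def tangent_modulus(
    curve: StressStrainCurve,
    p_target: float,
    n_points: int = 5,
    method: Literal["quadratic", "finite-difference"] = "quadratic",
) -> float:
    """Circumferential tangent modulus dσθ/dλθ at a target pressure, in MPa.

    Default: a quadratic least-squares fit over the ``n_points`` (λθ, σθ)
    samples nearest ``p_target`` in pressure (all samples if fewer), with the
    derivative evaluated at λθ(p_target).  Robust to the 10 mmHg step
    discretization of the protocol.  ``finite-difference`` instead uses a
    central difference between the two bracketing samples.
    """
    if len(curve.states) < 3:
        raise InsufficientDataError("tangent modulus needs >= 3 samples")
    p = curve.pressures
    if not (p.min() <= p_target <= p.max()):
        raise ExtrapolationRefusedError(
            f"P={p_target} mmHg outside sampled range [{p.min()}, {p.max()}]"
        )
    lt = curve.circ_stretches
    st = curve.circ_stresses
    lt0 = float(np.interp(p_target, p, lt))

    if method == "finite-difference":
        j = int(np.clip(np.searchsorted(p, p_target), 1, len(p) - 1))
        dlt = lt[j] - lt[j - 1]
        if abs(dlt) < 1e-14:
            raise IllConditionedFitError("identical stretches across the step")
        return float((st[j] - st[j - 1]) / dlt) / 1000.0

    if method != "quadratic":
        raise ValueError(f"unknown tangent modulus method {method!r}")

    k = min(n_points, len(p))
    nearest = np.argsort(np.abs(p - p_target))[:k]
    x, y = lt[nearest], st[nearest]
    if np.ptp(x) < 1e-12:
        raise IllConditionedFitError(
            "circumferential stretches in the fit window are indistinguishable"
        )
    # centre the abscissa for conditioning
    xc = x - lt0
    deg = 2 if k >= 3 else 1
    coeffs = np.polyfit(xc, y, deg)
    deriv = np.polyder(coeffs)
    return float(np.polyval(deriv, 0.0)) / 1000.0  # kPa -> MPa


def incompressibility_residual(
    state: DeformedState, geometry: UnloadedGeometry
) -> float:
    """(do² − di²)·λz − (Do² − Di²), mm²; zero for a volume-conserving state."""
    return (
        (state.outer_diameter**2 - state.inner_diameter**2) * state.axial_stretch
        - (geometry.outer_diameter**2 - geometry.inner_diameter**2)
    )
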