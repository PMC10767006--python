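"""Synthetic biaxial extension-inflation data from a membrane constitutive model.

The generator plays the role of the pressure myograph: it produces
(pressure, outer diameter, axial force) sweeps with a *known* underlying
constitutive response, so every quantity the analysis side estimates
(stresses, in vivo axial stretch, tangent modulus) has an analytic ground
truth.

Model
-----
Incompressible plane-stress membrane with a neo-Hookean ground matrix and
four exponential fiber families (axial, circumferential, symmetric
diagonal pair) — the de facto standard description of rodent arteries.
With λr = 1/(λθ·λz) eliminated by incompressibility, the reduced strain
energy per reference volume is

    W(λθ, λz) = (c/2)·(λθ² + λz² + 1/(λθ²λz²) − 3)
              + Σk c1k/(4·c2k)·(exp(c2k·(λk² − 1)²) − 1)

with fiber stretch λk² = λθ²·sin²φk + λz²·cos²φk (φk measured from the
axial direction), and the Cauchy stresses are σθ = λθ·∂W/∂λθ,
σz = λz·∂W/∂λz.

Kinematics use mid-wall radius r = λθ·R_mid with membrane thickness update
h = H/(λθ·λz); the emitted outer diameter is do = 2·(ri + h), ri = r − h/2.
Because the annular wall area implied by this membrane kinematics equals
the area the incompressibility relation assigns, the analysis side recovers
the simulator's mid-wall stretch and stresses exactly (before noise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterRangeError, StiffnessTooLowError
from .mechanics import (
    MMHG_TO_KPA,
    BiaxialDataset,
    InflationRecord,
    UnloadedGeometry,
)

logger = logging.getLogger(__name__)

#: Group mean arterial pressures (mmHg) used as preset labels:
#: 3-month control, 8-month hypertensive, 8-month denervated rats.
GROUP_MAP_MMHG = {"CTL": 124.8, "HT": 136.2, "RDN": 126.8}

#: λθ search bracket for the pressure-equilibrium solve.  The lower bound is
#: below 1 because at P = 0 an axially stretched tube contracts
#: circumferentially (σθ = 0 requires λθ < 1 when λz > 1).
_LAMBDA_THETA_BRACKET = (0.25, 4.0)

_EXP_OVERFLOW = 700.0  # exp argument beyond which float64 overflows


@dataclass(frozen=True)
class FiberFamily:
    """One exponential fiber family: stiffness c1 (kPa), dimensionless
    exponent c2, angle φ from the axial direction (degrees)."""

    c1: float
    c2: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 <= 0:
            raise ValueError("require c1 >= 0 and c2 > 0")
        if not (0.0 <= self.angle_deg <= 90.0):
            raise ValueError("fiber angle must lie in [0, 90] degrees from axial")


@dataclass(frozen=True)
class ConstitutiveParams:
    """Constitutive parameters plus the reference geometry of one specimen."""

    ground_matrix_stiffness: float  # c, kPa
    fiber_families: tuple[FiberFamily, ...]
    geometry: UnloadedGeometry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ground_matrix_stiffness < 0:
            raise ValueError("ground matrix stiffness must be >= 0")
        object.__setattr__(self, "fiber_families", tuple(self.fiber_families))


@dataclass(frozen=True)
class SimulationProtocol:
    """Inflation protocol: pressure grid (mmHg), tested axial stretches
    (None = λz*·{0.95, 1.00, 1.05}), Gaussian measurement noise, seed.

    Defaults mirror the bench protocol (0–120 mmHg in 10 mmHg steps at the
    in vivo stretch ±5%) with noise of 5 μm SD on diameter and 0.05 mN SD
    on force.
    """

    pressure_grid: tuple[float, ...] = tuple(float(p) for p in range(0, 121, 10))
    axial_stretches: tuple[float, ...] | None = None
    diameter_noise_sd_um: float = 5.0
    force_noise_sd_mn: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure_grid, dtype=float)
        if len(p) and np.any(np.diff(p) <= 0):
            raise ValueError("pressure grid must be strictly increasing")
        if self.diameter_noise_sd_um < 0 or self.force_noise_sd_mn < 0:
            raise ValueError("noise SDs must be >= 0")
        object.__setattr__(self, "pressure_grid", tuple(float(x) for x in p))
        if self.axial_stretches is not None:
            object.__setattr__(
                self, "axial_stretches",
                tuple(float(x) for x in self.axial_stretches),
            )


# ---------------------------------------------------------------------------
# Constitutive response
# ---------------------------------------------------------------------------

def membrane_response(params: ConstitutiveParams, lam_t, lam_z, *, _clip: bool = False):
    """Cauchy stresses (σθ, σz) in kPa at stretches (λθ, λz).

    Accepts scalars or broadcastable arrays; the stress-free reference
    (λθ = λz = 1) returns exactly (0, 0).  ``_clip`` caps the fiber exponent
    instead of raising; the bisection solver uses it to evaluate bracket
    endpoints far outside the physical range (signs stay correct).
    """
    lt = np.asarray(lam_t, dtype=float)
    lz = np.asarray(lam_z, dtype=float)
    if np.any(lt <= 0) or np.any(lz <= 0):
        raise ValueError("stretches must be positive")
    c = params.ground_matrix_stiffness
    inv = 1.0 / (lt**2 * lz**2)
    s_t = c * (lt**2 - inv)
    s_z = c * (lz**2 - inv)
    for fam in params.fiber_families:
        phi = math.radians(fam.angle_deg)
        s2, c2ang = math.sin(phi) ** 2, math.cos(phi) ** 2
        x = lt**2 * s2 + lz**2 * c2ang - 1.0
        arg = fam.c2 * x**2
        if np.any(arg > _EXP_OVERFLOW):
            if not _clip:
                raise ParameterRangeError(
                    "fiber exponential overflows; reduce c2 or the stretch range "
                    f"(max exponent {np.max(arg):.3g})"
                )
            arg = np.minimum(arg, _EXP_OVERFLOW)
        common = fam.c1 * x * np.exp(arg)
        s_t = s_t + common * lt**2 * s2
        s_z = s_z + common * lz**2 * c2ang
    if s_t.ndim == 0:
        return float(s_t), float(s_z)
    return s_t, s_z


def circ_stress_derivative(params: ConstitutiveParams, lam_t, lam_z):
    """Analytic ∂σθ/∂λθ at fixed λz, kPa (ground truth for tangent modulus)."""
    lt = np.asarray(lam_t, dtype=float)
    lz = np.asarray(lam_z, dtype=float)
    c = params.ground_matrix_stiffness
    d = c * (2 * lt + 2 / (lt**3 * lz**2))
    for fam in params.fiber_families:
        phi = math.radians(fam.angle_deg)
        s2, c2ang = math.sin(phi) ** 2, math.cos(phi) ** 2
        x = lt**2 * s2 + lz**2 * c2ang - 1.0
        e = np.exp(fam.c2 * x**2)
        # d/dλθ [c1·x·e^{c2 x²}·λθ²·s²] with dx/dλθ = 2·λθ·s²
        d = d + fam.c1 * s2 * e * (
            2 * lt**3 * s2 * (1 + 2 * fam.c2 * x**2) + 2 * lt * x
        )
    if d.ndim == 0:
        return float(d)
    return d


# ---------------------------------------------------------------------------
# Equilibrium solve
# ---------------------------------------------------------------------------

def _equilibrium_mismatch(params, lam_t, lam_z, p_kpa):
    """σθ·h/ri − P with membrane kinematics, kPa (vectorized in λθ/λz)."""
    geo = params.geometry
    r = lam_t * geo.mid_wall_radius
    h = geo.wall_thickness / (lam_t * lam_z)
    ri = r - 0.5 * h
    s_t, _ = membrane_response(params, lam_t, lam_z, _clip=True)
    return s_t * h / ri - p_kpa


def solve_circ_stretch(params: ConstitutiveParams, lam_z, pressure_mmhg: float,
                       rel_tol: float = 1e-12, on_failure: str = "raise"):
    """Solve σθ(λθ, λz)·h/ri = P for λθ by bisection (vectorized over λz).

    Returns λθ with the same shape as ``lam_z``.  When the bracket holds no
    sign change the entry is infeasible (e.g. no P = 0 equilibrium with a
    positive lumen at extreme axial stretch): raise
    :class:`StiffnessTooLowError` (default) or return NaN there
    (``on_failure="nan"``, used by grid searches).
    """
    lz = np.atleast_1d(np.asarray(lam_z, dtype=float))
    p_kpa = pressure_mmhg * MMHG_TO_KPA
    geo = params.geometry
    # keep ri = λθ·R_mid − H/(2·λθ·λz) positive: λθ² > H/(2·R_mid·λz)
    ri_floor = np.sqrt(geo.wall_thickness / (2.0 * geo.mid_wall_radius * lz))
    lo = np.maximum(_LAMBDA_THETA_BRACKET[0], 1.02 * ri_floor)
    hi = np.full_like(lz, _LAMBDA_THETA_BRACKET[1])
    f_lo = _equilibrium_mismatch(params, lo, lz, p_kpa)
    f_hi = _equilibrium_mismatch(params, hi, lz, p_kpa)
    bad = f_lo * f_hi > 0
    if np.any(bad):
        if on_failure != "nan":
            raise StiffnessTooLowError(
                f"no equilibrium λθ in {_LAMBDA_THETA_BRACKET} at P={pressure_mmhg} "
                "mmHg; the wall is too compliant (or too stiff) for this pressure"
            )
    with np.errstate(invalid="ignore", over="ignore"):
        while np.max((hi - lo) / np.maximum(lo, 1e-12)) > rel_tol:
            mid = 0.5 * (lo + hi)
            f_mid = _equilibrium_mismatch(params, mid, lz, p_kpa)
            take_lo = f_lo * f_mid <= 0
            hi = np.where(take_lo, mid, hi)
            f_hi = np.where(take_lo, f_mid, f_hi)
            lo = np.where(take_lo, lo, mid)
            f_lo = np.where(take_lo, f_lo, f_mid)
    out = 0.5 * (lo + hi)
    out = np.where(bad, np.nan, out)
    if np.isscalar(lam_z) or np.asarray(lam_z).ndim == 0:
        return float(out[0])
    return out


def _sweep_observables(params: ConstitutiveParams, lam_z, pressures_mmhg,
                       on_failure: str = "raise"):
    """Zero-noise (do mm, f mN) arrays over a pressure sweep.

    ``lam_z`` may be an array; returns arrays of shape (n_pressures,) + lam_z.shape.
    """
    lz = np.atleast_1d(np.asarray(lam_z, dtype=float))
    geo = params.geometry
    do_all, f_all = [], []
    for p in pressures_mmhg:
        lt = np.atleast_1d(
            solve_circ_stretch(params, lz, p, on_failure=on_failure)
        )
        r = lt * geo.mid_wall_radius
        h = geo.wall_thickness / (lt * lz)
        ri = r - 0.5 * h
        _, s_z = membrane_response(params, lt, lz)
        p_kpa = p * MMHG_TO_KPA
        do_all.append(2 * (ri + h))
        f_all.append(s_z * math.pi * h * (2 * ri + h) - p_kpa * math.pi * ri**2)
    return np.array(do_all), np.array(f_all)


# ---------------------------------------------------------------------------
# Record / dataset generation
# ---------------------------------------------------------------------------

def simulate_inflation(
    params: ConstitutiveParams,
    lam_z: float,
    protocol: SimulationProtocol,
    rng: np.random.Generator | None = None,
) -> InflationRecord:
    """Simulate one pressurization sweep at fixed axial stretch.

    Gaussian noise (protocol SDs) is added to the emitted diameters and
    forces; pass ``rng`` to share a noise stream across sweeps, otherwise a
    fresh generator is derived from protocol and parameter seeds.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(params.seed, protocol.seed))
        )
    do, f = _sweep_observables(params, lam_z, protocol.pressure_grid)
    do = do[:, 0] + rng.normal(0, protocol.diameter_noise_sd_um * 1e-3, size=len(do))
    f = f[:, 0] + rng.normal(0, protocol.force_noise_sd_mn, size=len(f))
    samples = tuple(
        (float(p), float(d), float(ff))
        for p, d, ff in zip(protocol.pressure_grid, do, f)
    )
    return InflationRecord(axial_stretch=float(lam_z), samples=samples)


def find_force_invariant_stretch(
    params: ConstitutiveParams,
    pressures_mmhg: Sequence[float] | None = None,
    grid_step: float = 0.001,
    bracket: tuple[float, float] = (1.3, 2.5),
) -> float:
    """Ground-truth in vivo axial stretch λz* of the constitutive model.

    Fine-grid (Δλz = ``grid_step``) minimizer of the axial-force range over
    the 0–120 mmHg sweep.  If the minimizer falls on a bracket edge the
    bracket is widened (with a warning) until it is interior.
    """
    if pressures_mmhg is None:
        pressures_mmhg = [float(p) for p in range(0, 121, 10)]
    lo, hi = bracket
    for _ in range(6):
        grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
        _, f = _sweep_observables(params, grid, pressures_mmhg, on_failure="nan")
        force_range = f.max(axis=0) - f.min(axis=0)  # NaN where infeasible
        if np.all(np.isnan(force_range)):
            raise StiffnessTooLowError(
                "no axial stretch in the bracket admits a full pressure sweep"
            )
        k = int(np.nanargmin(force_range))
        feasible = ~np.isnan(force_range)
        # interior either in the grid or against the feasibility boundary
        if (0 < k < len(grid) - 1) and feasible[k - 1] and feasible[k + 1]:
            return float(grid[k])
        if 0 < k < len(grid) - 1:
            return float(grid[k])
        logger.warning(
            "force-invariant stretch at bracket edge [%g, %g]; widening", lo, hi
        )
        lo, hi = max(1.01, lo - 0.3), hi + 0.3
    raise StiffnessTooLowError(
        "no interior force-invariant stretch found; check constitutive parameters"
    )


def simulate_dataset(
    params: ConstitutiveParams,
    protocol: SimulationProtocol | None = None,
    map_pressure: float = 100.0,
    group_label: str = "",
) -> BiaxialDataset:
    """Simulate a full specimen dataset.

    By default three sweeps are generated at λz*·{0.95, 1.00, 1.05} around
    the model's force-invariant stretch, mirroring the in vivo ±5% protocol.
    """
    if protocol is None:
        protocol = SimulationProtocol()
    if protocol.axial_stretches is None:
        lz_star = find_force_invariant_stretch(
            params, pressures_mmhg=protocol.pressure_grid
        )
        stretches = tuple(lz_star * s for s in (0.95, 1.00, 1.05))
    else:
        stretches = protocol.axial_stretches
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(params.seed, protocol.seed))
    )
    records = tuple(
        simulate_inflation(params, lz, protocol, rng=rng) for lz in stretches
    )
    return BiaxialDataset(
        geometry=params.geometry,
        records=records,
        map_pressure=map_pressure,
        group_label=group_label,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> ConstitutiveParams:
    """Constitutive presets for a young-rat ("CTL-like") and a
    hypertensive-rat ("HT-like") common carotid artery.

    Each preset was calibrated once, offline, so that the model realizes the
    defining property of the in vivo axial stretch — the axial force stays
    within the 50 μN experimental plateau criterion over the whole 0–120 mmHg
    sweep at the design stretch (λz* = 1.75 for CTL-like, 2.00 for HT-like) —
    while the state at 100 mmHg lands at physiological rat-carotid values
    (CTL-like: σθ ≈ 85 kPa, σz ≈ 122 kPa; HT-like: σθ ≈ 137 kPa,
    σz ≈ 174 kPa).  The full-precision stiffnesses below are part of that
    design; rounding them breaks the force invariance.  The presets are
    illustrative of their groups, not fits to any particular animal.
    """
    if name == "CTL-like":
        return ConstitutiveParams(
            ground_matrix_stiffness=0.0,
            fiber_families=(
                FiberFamily(c1=2.9284571391817296, c2=0.35, angle_deg=0.0),
                FiberFamily(c1=0.6532664590879173, c2=0.6, angle_deg=65.0),
                FiberFamily(c1=2.472501112455896, c2=0.6, angle_deg=90.0),
                FiberFamily(c1=0.0032005227072960203, c2=1.0, angle_deg=35.0),
                FiberFamily(c1=0.06903128730252289, c2=1.6, angle_deg=45.0),
            ),
            geometry=UnloadedGeometry(0.90, 0.4576775911136775),
            seed=seed,
        )
    if name == "HT-like":
        return ConstitutiveParams(
            ground_matrix_stiffness=1.0409490720792074,
            fiber_families=(
                FiberFamily(c1=11.633615560919292, c2=0.6, angle_deg=90.0),
                FiberFamily(c1=6.23240456699993e-05, c2=1.0, angle_deg=25.0),
                FiberFamily(c1=1.0306979303738906, c2=1.0, angle_deg=55.0),
                FiberFamily(c1=0.611214839699356, c2=1.0, angle_deg=65.0),
                FiberFamily(c1=0.22286528497124936, c2=1.0, angle_deg=90.0),
                FiberFamily(c1=4.7245586092237824e-06, c2=1.6, angle_deg=0.0),
                FiberFamily(c1=0.0011870174094272795, c2=1.6, angle_deg=45.0),
                FiberFamily(c1=0.04511475089308925, c2=1.6, angle_deg=55.0),
            ),
            geometry=UnloadedGeometry(1.00, 0.6727203710364492),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose 'CTL-like' or 'HT-like'")


def perturbed_preset(
    name: str,
    seed: int,
    stiffness_sd: float = 0.10,
    size_sd: float = 0.05,
) -> ConstitutiveParams:
    """A preset with inter-animal variability; deterministic in ``seed``.

    Variability is a common log-normal multiplier on every stiffness (the
    wall is uniformly stiffer or softer) plus a log-normal scale on the
    reference geometry (a larger or smaller animal).  Both transformations
    preserve the preset's designed axial-force invariance: a uniform
    geometry scale leaves the pressure–stretch relation unchanged and scales
    forces, while a uniform stiffness multiplier re-maps the sweep to an
    equivalent pressure range the design already covers.
    """
    base = preset(name, seed=seed)
    rng = np.random.default_rng(seed)
    s = float(np.exp(rng.normal(0, stiffness_sd)))
    g = float(np.exp(rng.normal(0, size_sd)))
    return ConstitutiveParams(
        ground_matrix_stiffness=base.ground_matrix_stiffness * s,
        fiber_families=tuple(
            FiberFamily(c1=f.c1 * s, c2=f.c2, angle_deg=f.angle_deg)
            for f in base.fiber_families
        ),
        geometry=UnloadedGeometry(
            base.geometry.outer_diameter * g, base.geometry.inner_diameter * g
        ),
        seed=seed,
    )
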