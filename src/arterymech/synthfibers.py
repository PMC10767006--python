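"""Synthetic multiphoton-like fiber images with known ground truth.

Renders 2-D fields of wavy fibers (sinusoidally perturbed straight lines
rasterized with a Gaussian transverse profile) and depth-graded z-stacks,
emulating second-harmonic-generation collagen / two-photon elastin
acquisitions: 425×425 μm field of view on a 512×512 grid, 1 μm z-spacing.
Because each fiber's centerline, orientation and waviness are prescribed,
the orientation distribution and the straightness parameter of every image
are known analytically — the generator is the ground truth for the
orientation and straightness analyses.

Angle convention: 0° is the image x-axis (vessel axis), angles increase
counter-clockwise toward +y, and orientation is axial (θ and θ+180° are
identical), so angles live on [−90°, 90°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter

#: Field of view of the emulated acquisitions, μm.
FIELD_OF_VIEW_UM = 425.0
#: Default raster size, px (pixel size = 425/512 ≈ 0.830 μm).
DEFAULT_IMAGE_SIZE = 512


@dataclass(frozen=True)
class VonMisesOrientation:
    """Axial von Mises orientation distribution: mean direction (deg, on
    [−90, 90)) and concentration κ (κ → 0 uniform, κ → ∞ parallel)."""

    mean_deg: float
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class FixedOrientation:
    """All fibers at exactly one angle (deg)."""

    angle_deg: float


@dataclass(frozen=True)
class FiberFieldSpec:
    """Specification of one synthetic fiber image.

    Waviness is a single-harmonic sinusoid: a perpendicular perturbation of
    amplitude ``waviness_amplitude_um`` and wavelength ``waviness_wavelength_um``
    along the fiber axis, which admits a closed quadrature for the
    straightness parameter (:func:`analytic_ps`).
    """

    image_size_px: int = DEFAULT_IMAGE_SIZE
    pixel_size_um: float = FIELD_OF_VIEW_UM / DEFAULT_IMAGE_SIZE
    n_fibers: int = 30
    orientation: VonMisesOrientation | FixedOrientation = VonMisesOrientation(0.0, 8.0)
    waviness_amplitude_um: float = 4.0
    waviness_wavelength_um: float = 40.0
    n_periods: int = 3
    fiber_width_px: float = 2.0
    intensity: float = 1.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 8 or self.pixel_size_um <= 0:
            raise ValueError("invalid raster geometry")
        if self.n_fibers < 0 or self.fiber_width_px <= 0:
            raise ValueError("invalid fiber parameters")
        if self.waviness_amplitude_um < 0 or self.waviness_wavelength_um <= 0:
            raise ValueError("invalid waviness parameters")
        if self.n_periods < 1:
            raise ValueError("fibers span at least one waviness period")


@dataclass(frozen=True)
class FiberRecord:
    """Ground truth for one rendered fiber."""

    orientation_deg: float
    centerline_um: np.ndarray  # (n, 2) points, μm, image coordinates (x, y)
    analytic_ps: float


@dataclass(frozen=True)
class FiberTruth:
    """Ground truth for a rendered image."""

    fibers: tuple[FiberRecord, ...]

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.array([f.orientation_deg for f in self.fibers])

    @property
    def ps_values(self) -> np.ndarray:
        return np.array([f.analytic_ps for f in self.fibers])


def analytic_ps(amplitude_um: float, wavelength_um: float) -> float:
    """Straightness parameter of a single-harmonic sinusoidal fiber.

    Chord over arc length across one period: arc length by adaptive
    quadrature of sqrt(1 + (A·k·cos(k·u))²), k = 2π/wavelength.  Scale
    invariant: Ps(c·A, c·L) = Ps(A, L).
    """
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude_um == 0:
        return 1.0
    k = 2 * math.pi / wavelength_um
    arc, _ = quad(
        lambda u: math.sqrt(1 + (amplitude_um * k * math.cos(k * u)) ** 2),
        0.0, wavelength_um, epsrel=1e-10, limit=200,
    )
    return wavelength_um / arc


def _wrap_half_deg(angle_deg: np.ndarray | float):
    """Wrap an orientation angle to [−90, 90)."""
    return (np.asarray(angle_deg) + 90.0) % 180.0 - 90.0


def sample_orientations(
    orientation: VonMisesOrientation | FixedOrientation,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` axial orientations (deg on [−90, 90)).

    Von Mises sampling uses the doubled-angle construction standard for
    axial data: 2θ ~ vonmises(2μ, κ).
    """
    if isinstance(orientation, FixedOrientation):
        return np.full(n, _wrap_half_deg(orientation.angle_deg), dtype=float)
    if orientation.kappa == 0:
        return rng.uniform(-90.0, 90.0, size=n)
    two_theta = rng.vonmises(
        2 * math.radians(orientation.mean_deg), orientation.kappa, size=n
    )
    return _wrap_half_deg(np.degrees(two_theta) / 2.0)


def _fiber_centerline(
    spec: FiberFieldSpec,
    theta_deg: float,
    center_um: np.ndarray,
    phase: float,
) -> np.ndarray:
    """Centerline points (μm) of one wavy fiber, ~4 samples per pixel."""
    length = spec.n_periods * spec.waviness_wavelength_um
    step = spec.pixel_size_um / 4.0
    u = np.arange(0.0, length + 0.5 * step, step) - 0.5 * length
    k = 2 * math.pi / spec.waviness_wavelength_um
    # perpendicular offset; endpoints at u = ±n_periods·L/2 share the same
    # phase, so the chord equals the fiber's axial extent exactly
    v = spec.waviness_amplitude_um * np.sin(k * u + phase)
    th = math.radians(theta_deg)
    ax = np.array([math.cos(th), math.sin(th)])
    perp = np.array([-math.sin(th), math.cos(th)])
    return center_um[None, :] + u[:, None] * ax[None, :] + v[:, None] * perp[None, :]


def polyline_ps(points: np.ndarray) -> float:
    """Chord/arc straightness of a polyline given as (n, 2) points."""
    seg = np.diff(points, axis=0)
    arc = float(np.sqrt((seg**2).sum(axis=1)).sum())
    chord = float(np.sqrt(((points[-1] - points[0]) ** 2).sum()))
    if arc == 0:
        raise ValueError("degenerate polyline")
    return chord / arc


def render_fiber_image(spec: FiberFieldSpec) -> tuple[np.ndarray, FiberTruth]:
    """Render one synthetic fiber image and its ground truth.

    Fibers are placed uniformly at random with bounded retries so that the
    whole centerline fits in the frame; a fiber that cannot be placed after
    200 tries raises.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.image_size_px
    extent = n_px * spec.pixel_size_um
    canvas = np.zeros((n_px, n_px), dtype=float)
    thetas = sample_orientations(spec.orientation, spec.n_fibers, rng)
    ps_true = analytic_ps(spec.waviness_amplitude_um, spec.waviness_wavelength_um)
    records = []
    for theta in thetas:
        placed = False
        for _ in range(200):
            # keep the whole fiber in frame: its half-extent from the centre
            # is bounded by half-length + amplitude
            margin = (
                0.5 * spec.n_periods * spec.waviness_wavelength_um
                + spec.waviness_amplitude_um
            )
            if 2 * margin >= extent:
                break  # fiber longer than frame: allow clipping
            center = rng.uniform(margin, extent - margin, size=2)
            phase = rng.uniform(0, 2 * math.pi)
            pts = _fiber_centerline(spec, theta, center, phase)
            inside = (pts >= 0).all() & (pts < extent - 1e-9).all()
            if inside:
                placed = True
                break
        if not placed:
            # clip: keep the in-frame part of a randomly placed fiber
            center = rng.uniform(0, extent, size=2)
            phase = rng.uniform(0, 2 * math.pi)
            pts = _fiber_centerline(spec, theta, center, phase)
            keep = (pts >= 0).all(axis=1) & (pts < extent - 1e-9).all(axis=1)
            if keep.sum() < 2:
                raise RuntimeError(
                    "could not place a fiber inside the frame; "
                    "reduce fiber length or enlarge the image"
                )
            pts = pts[keep]
        idx = np.floor(pts / spec.pixel_size_um).astype(int)
        canvas[idx[:, 1], idx[:, 0]] += 1.0  # row = y, col = x
        ps = ps_true if placed else polyline_ps(pts)
        records.append(
            FiberRecord(
                orientation_deg=float(theta), centerline_um=pts, analytic_ps=ps
            )
        )
    # Gaussian transverse profile via blur of the centerline impulses
    image = gaussian_filter(canvas, sigma=spec.fiber_width_px / 2.0)
    if image.max() > 0:
        image = image / image.max() * spec.intensity
    if spec.poisson_noise:
        photons = np.maximum(image, 0) * 50.0  # nominal photon budget
        image = rng.poisson(photons).astype(float) / 50.0
    if spec.gaussian_noise_sd > 0:
        image = image + rng.normal(0, spec.gaussian_noise_sd, size=image.shape)
    image = np.clip(image, 0, None)
    return image, FiberTruth(fibers=tuple(records))


@dataclass(frozen=True)
class DepthStackTruth:
    """Per-slice truth plus the index of the first slice drawn from the
    deep (medial) orientation distribution."""

    slices: tuple[FiberTruth, ...]
    switch_slice: int


def render_depth_stack(
    shallow: VonMisesOrientation | FixedOrientation,
    deep: VonMisesOrientation | FixedOrientation,
    interface_depth_um: float,
    n_slices: int,
    spec: FiberFieldSpec,
    z_spacing_um: float = 1.0,
) -> tuple[np.ndarray, DepthStackTruth]:
    """Render a z-stack with an abrupt orientation change at a set depth.

    Emulates the adventitia→media transition seen in elastin stacks: slices
    shallower than ``interface_depth_um`` draw orientations from ``shallow``,
    deeper slices from ``deep``.  Returns (voxels of shape
    (n_slices, rows, cols), truth).
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if n_slices > 1 and not (0 < interface_depth_um < n_slices * z_spacing_um):
        raise ValueError("interface depth must lie inside the stack")
    switch = min(
        n_slices, max(0, int(math.ceil(interface_depth_um / z_spacing_um)))
    )
    slices, truths = [], []
    for i in range(n_slices):
        ori = shallow if i < switch else deep
        sl_spec = FiberFieldSpec(
            **{
                **spec.__dict__,
                "orientation": ori,
                "seed": int(np.random.SeedSequence((spec.seed, i)).generate_state(1)[0] % (2**31)),
            }
        )
        img, truth = render_fiber_image(sl_spec)
        slices.append(img)
        truths.append(truth)
    return np.stack(slices), DepthStackTruth(
        slices=tuple(truths), switch_slice=switch if n_slices > 1 else 0
    )
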