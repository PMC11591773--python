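"""Seeded generators for foot-like topographies and calibration targets.

Every pipeline stage is testable without hardware: the footprint generator
composes a few Gaussian bumps (heel, metatarsal pad, toes, arch) on a base
plateau, the last generator derives a last lower surface from a footprint by
a constant offset plus a smooth low-frequency deformation with a known gap
field, and the calibration generator produces stripe pixel coordinates at
known height/width offsets through the forward camera model.  Foot realism
is deliberately minimal — the algorithms downstream are geometry-agnostic —
but amplitudes default to the ~25-30 mm height scale of a scanned last
lower surface so worked-example magnitudes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridError
from .grid import SurfaceGrid
from .laser import CalibrationData, CameraGeometry, height_to_pixel, width_to_pixel


@dataclass
class Bump:
    """One Gaussian feature: centre (mm), signed amplitude (mm), width (mm)."""

    center: tuple[float, float]
    amplitude: float
    width: float


@dataclass
class SurfaceSpec:
    """Recipe for a synthetic footprint topography.

    The default is a 31x21 lattice (6x4 patches) spanning a 250 x 90 mm
    plantar outline with heights in the 25-30 mm band: a 26.5 mm plateau,
    raised heel / metatarsal / toe pads and a lowered arch.
    """

    shape: tuple[int, int] = (31, 21)
    x_range: tuple[float, float] = (20.0, 270.0)
    y_range: tuple[float, float] = (10.0, 100.0)
    base_height: float = 26.5
    bumps: list[Bump] = field(
        default_factory=lambda: [
            Bump(center=(70.0, 55.0), amplitude=2.5, width=32.0),   # heel
            Bump(center=(195.0, 52.0), amplitude=2.2, width=36.0),  # metatarsal pad
            Bump(center=(248.0, 55.0), amplitude=1.2, width=22.0),  # toes
            Bump(center=(135.0, 42.0), amplitude=-1.3, width=40.0),  # arch
        ]
    )
    noise_sigma: float = 0.0
    seed: int | None = 0

    def validate(self) -> None:
        nx, ny = self.shape
        if nx % 5 != 1 or ny % 5 != 1 or nx < 6 or ny < 6:
            raise GridError(f"surface shape {self.shape} must be 5k+1 per axis")
        if not all(np.isfinite(b.amplitude) for b in self.bumps):
            raise GridError("bump amplitudes must be finite")


def make_footprint(spec: SurfaceSpec | None = None) -> SurfaceGrid:
    """Smooth sum-of-Gaussians footprint topography, deterministic from seed."""
    spec = spec or SurfaceSpec()
    spec.validate()
    nx, ny = spec.shape
    x = np.linspace(*spec.x_range, nx)
    y = np.linspace(*spec.y_range, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    z = np.full((nx, ny), spec.base_height, dtype=float)
    for b in spec.bumps:
        z += b.amplitude * np.exp(
            -((xx - b.center[0]) ** 2 + (yy - b.center[1]) ** 2) / (2.0 * b.width**2)
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        z += rng.normal(0.0, spec.noise_sigma, size=z.shape)
    return SurfaceGrid(z, x, y)


def make_last_from_footprint(
    footprint: SurfaceGrid,
    offset: float = 1.0,
    deformation_amplitude: float = 1.0,
    wavelength: float = 150.0,
    seed: int | None = 0,
) -> tuple[SurfaceGrid, np.ndarray]:
    """A last lower surface derived from a footprint, with its gap field.

    last = footprint + offset + deformation, where the deformation is a
    smooth low-frequency field (two random-phase cosine products at the
    given wavelength) scaled to the requested amplitude.  The returned gap
    field (last - footprint) is the ground truth for adjustment tests.
    """
    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(footprint.x_coords, footprint.y_coords, indexing="ij")
    deform = np.zeros_like(xx)
    if deformation_amplitude != 0.0:
        for _ in range(2):
            phx, phy = rng.uniform(0, 2 * np.pi, size=2)
            deform += np.cos(2 * np.pi * xx / wavelength + phx) * np.cos(
                2 * np.pi * yy / (0.8 * wavelength) + phy
            )
        peak = np.abs(deform).max()
        if peak > 0:
            deform *= deformation_amplitude / peak
    gap = offset + deform
    last = footprint.with_heights(footprint.heights + gap)
    return last, gap


def make_calibration_target(
    geom: CameraGeometry,
    n_steps: int = 10,
    step: float = 2.0,
    base_height: float = 10.0,
    n_rows: int = 12,
    width_span: float = 40.0,
    noise_px: float = 0.0,
    seed: int | None = 0,
    image_shape: tuple[int, int] = (480, 640),
) -> CalibrationData:
    """Stripe pixel coordinates of a stepped calibration target.

    A stack of ``n_steps`` known heights (``base_height + i * step`` mm
    above the glass) and, at each height, ``n_rows`` known width marks
    spanning ``width_span`` mm.  Pixels come from the forward camera model
    plus optional Gaussian pixel noise.  Every observation is differenced
    against the first mark at the first height — the cross-height width
    pairs are what identify the vertical principal point and the
    lens-to-sensor distance (equal-height pairs cancel them out).
    """
    from .exceptions import FieldOfViewError

    rng = np.random.default_rng(seed)
    H, W = image_shape
    heights = base_height + np.arange(n_steps) * step
    x_true = height_to_pixel(heights, geom)
    if x_true.min() < 0 or x_true.max() > W - 1:
        raise FieldOfViewError(
            f"calibration stripe columns {x_true.min():.0f}..{x_true.max():.0f} "
            f"leave the {W}-px sensor"
        )
    x_pix = x_true + (rng.normal(0, noise_px, n_steps) if noise_px > 0 else 0.0)
    x_ref = np.full(n_steps - 1, x_pix[0])
    dz = heights[1:] - heights[0]

    y_marks = np.linspace(10.0, 10.0 + width_span, n_rows)
    yy, zz = np.meshgrid(y_marks, heights, indexing="ij")
    yb = width_to_pixel(yy.ravel(), zz.ravel(), geom)
    if yb.min() < 0 or yb.max() > H - 1:
        raise FieldOfViewError("calibration stripe rows leave the sensor")
    if noise_px > 0:
        yb = yb + rng.normal(0, noise_px, yb.size)
    # reference: first mark at first height
    y0_pix, z0 = yb[0], zz.ravel()[0]
    dy = yy.ravel()[1:] - y_marks[0]
    return CalibrationData(
        dz=dz,
        x_pix=x_pix[1:],
        x_ref_pix=x_ref,
        dy=dy,
        y_pix=yb[1:],
        y_ref_pix=np.full(dy.size, y0_pix),
        z_at_y=zz.ravel()[1:],
        z_at_y_ref=np.full(dy.size, z0),
    )


def make_model_footprint(
    base: SurfaceGrid | None = None,
    weight_deviation: float = 0.03,
    seed: int | None = 0,
) -> tuple[SurfaceGrid, np.ndarray]:
    """A footprint that IS a Bezier patch model evaluation.

    Interior weights are drawn within ``1 +/- weight_deviation`` of one on a
    smooth base grid and the model is evaluated at the lattice; because the
    target lies exactly in the model class, adjustment should recover it to
    fractions of a percent.  Returns the surface and the generating weights.
    """
    from . import bezier
    from .adjust import enforce_g1_borders

    if base is None:
        base = make_footprint()
    rng = np.random.default_rng(seed)
    weights = np.ones(base.shape)
    interior = np.ones(base.shape, dtype=bool)
    interior[::5, :] = False
    interior[:, ::5] = False
    weights[interior] = 1.0 + rng.uniform(-weight_deviation, weight_deviation, interior.sum())
    control = enforce_g1_borders(weights * base.heights)
    weights = control / base.heights
    model = bezier.BezierPatchModel(base, weights)
    return bezier.eval_model(model), weights
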