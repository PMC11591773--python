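"""Laser-line triangulation: stripe localisation, reconstruction, calibration.

A vertical laser stripe is swept across the surface by a slider; a camera at
baseline D images it through a lens at distance A1 from the reference (glass)
plane and A2 from the sensor.  The stripe's lateral image displacement
encodes height:

    z = A1 * D / (eta * (x - xc)) - A2            (height from column x)
    y = eta * (yb - yc) * (A2 + z) / A1 + eta*yc  (width from row yb)

with principal point (xc, yc) in pixels and pixel size eta in mm/px.  The
stripe centre is located to sub-pixel precision from a Bezier curve fitted
through the pixel intensities of each row; radial distortion is corrected by
per-line / per-row shift tables referenced to a centre line.

The forward renderer is the exact inverse of the two equations above plus a
Gaussian stripe cross-section, which makes reconstruction correctness
testable in isolation from physical fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .exceptions import (
    CalibrationDesignError,
    FieldOfViewError,
    NoLineError,
    NoPeakError,
)
from .ga import GAConfig, GAResult, SearchSpace, run_ga
from .grid import SurfaceGrid


# ---------------------------------------------------------------------------
# camera geometry


@dataclass
class CameraGeometry:
    """Triangulation parameters.

    x_center, y_center : principal point (px); pixel_size : eta (mm/px);
    a1 : glass-to-lens distance (mm); a2 : lens-to-sensor distance (mm);
    d : laser-to-camera baseline (mm).
    """

    x_center: float
    y_center: float
    pixel_size: float
    a1: float
    a2: float
    d: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.a1 <= 0 or self.a2 <= 0 or self.d <= 0:
            raise ValueError("pixel_size, a1, a2 and d must all be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([self.x_center, self.y_center, self.pixel_size, self.a1, self.a2, self.d])

    @classmethod
    def from_vector(cls, v) -> "CameraGeometry":
        return cls(*(float(x) for x in v))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "x_center": self.x_center,
                    "y_center": self.y_center,
                    "pixel_size": self.pixel_size,
                    "a1": self.a1,
                    "a2": self.a2,
                    "d": self.d,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CameraGeometry":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_geometry() -> CameraGeometry:
    """A bench-scale default consistent with an 8 mm lens and 640x480 sensor."""
    return CameraGeometry(
        x_center=120.0, y_center=60.0, pixel_size=0.06, a1=20.0, a2=64.0, d=110.0
    )


def triangulate_height(x_bar, geom: CameraGeometry):
    """Height from stripe column: ``z = A1 D / (eta (x - xc)) - A2``.

    Strictly decreasing in x; the displacement ``eta (x - xc)`` must be
    positive (the stripe images on the baseline side of the principal
    point).
    """
    x_bar = np.asarray(x_bar, dtype=float)
    disp = geom.pixel_size * (x_bar - geom.x_center)
    if np.any(disp <= 0):
        raise FieldOfViewError("stripe at or left of the principal point: singular displacement")
    z = geom.a1 * geom.d / disp - geom.a2
    return float(z) if z.ndim == 0 else z


def height_to_pixel(z, geom: CameraGeometry):
    """Inverse of :func:`triangulate_height` (forward model)."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= -geom.a2):
        raise FieldOfViewError("height at or below -A2 has no image")
    x = geom.x_center + geom.a1 * geom.d / (geom.pixel_size * (z + geom.a2))
    return float(x) if x.ndim == 0 else x


def triangulate_width(y_bar, z, geom: CameraGeometry):
    """Width from stripe row: ``y = eta (yb - yc)(A2 + z)/A1 + eta yc``."""
    y_bar = np.asarray(y_bar, dtype=float)
    z = np.asarray(z, dtype=float)
    y = geom.pixel_size * (y_bar - geom.y_center) * (geom.a2 + z) / geom.a1 \
        + geom.pixel_size * geom.y_center
    return float(y) if y.ndim == 0 else y


def width_to_pixel(y, z, geom: CameraGeometry):
    """Inverse of :func:`triangulate_width` (forward model)."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    yb = geom.y_center + (y - geom.pixel_size * geom.y_center) * geom.a1 / (
        geom.pixel_size * (geom.a2 + z)
    )
    return float(yb) if yb.ndim == 0 else yb


# ---------------------------------------------------------------------------
# stripe localisation


def _bernstein_design(n: int, u: np.ndarray) -> np.ndarray:
    i = np.arange(n + 1)
    logc = np.log(comb(n, i))
    with np.errstate(divide="ignore"):
        B = np.exp(
            logc[None, :]
            + i[None, :] * np.log(np.where(u[:, None] > 0, u[:, None], 1.0))
            + (n - i)[None, :] * np.log(np.where(u[:, None] < 1, 1.0 - u[:, None], 1.0))
        )
    # patch the exact endpoints
    B[u == 0.0] = 0.0
    B[u == 0.0, 0] = 1.0
    B[u == 1.0] = 0.0
    B[u == 1.0, n] = 1.0
    return B


def _bezier_curve_value(control: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Evaluate Bezier curves row-wise: control (m, n+1), u (m,)."""
    n = control.shape[1] - 1
    B = _bernstein_design(n, u)
    return np.sum(B * control, axis=1)


def _bezier_curve_derivative(control: np.ndarray, u: np.ndarray) -> np.ndarray:
    n = control.shape[1] - 1
    dc = n * np.diff(control, axis=1)
    B = _bernstein_design(n - 1, u)
    return np.sum(B * dc, axis=1)


_WINDOW_EXPANSION = 2.5


def _peak_windows(rows: np.ndarray, min_window: int, threshold_frac: float):
    """Symmetric per-row windows around the intensity argmax.

    The stripe support is the span of pixels above background +
    ``threshold_frac`` of the range; the fitted window is that half-width
    expanded by a fixed factor (the Bernstein curve is a strong smoother
    whose peak is pulled toward the window centre, and the pull decays with
    window size — the expansion keeps the residual bias below ~0.02 px for
    Gaussian stripes), floored at ``min_window`` pixels and made symmetric
    about the argmax.
    """
    m, w = rows.shape
    centers = np.argmax(rows, axis=1)
    background = rows.min(axis=1)
    peak = rows.max(axis=1)
    thr = background + threshold_frac * (peak - background)
    above = rows > thr[:, None]
    # distance from the argmax to the farthest above-threshold pixel per row
    cols = np.arange(w)
    dist = np.where(above, np.abs(cols[None, :] - centers[:, None]), 0)
    half = np.maximum(
        np.ceil(_WINDOW_EXPANSION * dist.max(axis=1)).astype(int), (min_window - 1) // 2
    )
    half = np.minimum(half, np.minimum(centers, w - 1 - centers))
    return centers, half


def stripe_peak_subpixel(
    intensity_row,
    positions=None,
    min_window: int = 7,
    threshold_frac: float = 0.2,
    tol: float = 1e-6,
) -> float:
    """Sub-pixel stripe centre of one intensity row.

    A Bezier curve of order (window length - 1) is laid through the window's
    pixel positions and intensities (the samples are its control values, so
    the curve approximates, not interpolates, the interior samples); the
    centre is ``x(u*)`` at the stationary point ``I'(u*) = 0``, found by
    bisection on [0, 1].
    """
    row = np.asarray(intensity_row, dtype=float)
    if positions is None:
        positions = np.arange(row.size, dtype=float)
    positions = np.asarray(positions, dtype=float)
    out = stripe_peaks_rows(row[None, :], positions, min_window, threshold_frac, tol)
    return float(out[0])


def stripe_peaks_rows(
    rows: np.ndarray,
    positions: np.ndarray | None = None,
    min_window: int = 7,
    threshold_frac: float = 0.2,
    tol: float = 1e-6,
) -> np.ndarray:
    """Vectorised sub-pixel stripe centres, one per image row.

    All rows are processed with a common window length (the largest
    per-row symmetric window) so the bisection runs on a single array.
    """
    rows = np.asarray(rows, dtype=float)
    m, w = rows.shape
    if positions is None:
        positions = np.arange(w, dtype=float)
    if np.all(rows.max(axis=1) - rows.min(axis=1) == 0):
        raise NoPeakError("flat intensity rows: no stripe extremum")
    centers, half = _peak_windows(rows, min_window, threshold_frac)
    H = int(half.max())
    if H < 1:
        raise NoPeakError("stripe window degenerate (all intensity at one pixel)")
    # clamp so every window fits the sensor
    centers = np.clip(centers, H, w - 1 - H)
    idx = centers[:, None] + np.arange(-H, H + 1)[None, :]
    I_ctrl = np.take_along_axis(rows, idx, axis=1)
    x_ctrl = positions[idx]

    flat = I_ctrl.max(axis=1) - I_ctrl.min(axis=1) == 0
    if np.all(flat):
        raise NoPeakError("flat intensity windows: no stripe extremum")

    # the window is centred on the argmax, so the maximum sits near u = 0.5;
    # brackets start slightly inside [0, 1] because flat (e.g. quantised-to-
    # zero) tails make the derivative vanish identically at the endpoints
    lo = np.full(m, 0.05)
    hi = np.full(m, 0.95)
    d_lo = _bezier_curve_derivative(I_ctrl, lo)
    d_hi = _bezier_curve_derivative(I_ctrl, hi)
    bad = (d_lo <= 0) | (d_hi >= 0)  # no interior maximum bracketed
    n_iter = int(np.ceil(np.log2(1.0 / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        d_mid = _bezier_curve_derivative(I_ctrl, mid)
        take_hi = d_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    u_star = 0.5 * (lo + hi)
    # the fitted curve must be concave at the maximum
    ddc = _bezier_curve_derivative(np.diff(I_ctrl, axis=1) * (I_ctrl.shape[1] - 1), u_star)
    peaks = _bezier_curve_value(x_ctrl, u_star)
    peaks[bad | flat | (ddc >= 0)] = np.nan
    if np.all(np.isnan(peaks)):
        raise NoPeakError("no row produced a bracketed concave maximum")
    return peaks


def detect_line_edges(column_profile, smooth: int = 3) -> tuple[int, int]:
    """Stripe start/end rows from the vertical intensity profile.

    Rows of the maximum positive and maximum negative discrete first
    derivative of the (moving-average smoothed) profile.
    """
    p = np.asarray(column_profile, dtype=float)
    if p.size < 3 or p.max() - p.min() == 0:
        raise NoLineError("no stripe in the column profile")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        p = np.convolve(p, kernel, mode="same")
    d = np.diff(p)
    if d.max() <= 0 or d.min() >= 0:
        raise NoLineError("profile has no rising/falling edge pair")
    start = int(np.argmax(d)) + 1
    end = int(np.argmin(d))
    if end <= start:
        raise NoLineError("stripe edges out of order")
    return start, end


# ---------------------------------------------------------------------------
# distortion


@dataclass
class DistortionTable:
    """Radial-distortion shift tables referenced to a centre line.

    delta_x[i] corrects the stripe column of scan line i; delta_y[j]
    corrects image row j.  Undistorted coordinates are ``x + delta_x[i]``
    and ``row + delta_y[j]``; delta_x at the reference line is 0 by
    construction.
    """

    delta_x: np.ndarray
    delta_y: np.ndarray

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"delta_x": list(self.delta_x), "delta_y": list(self.delta_y)}, fh)

    @classmethod
    def from_json(cls, path) -> "DistortionTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["delta_x"], float), np.asarray(d["delta_y"], float))


def build_distortion_table(
    traces: np.ndarray,
    slider_steps: np.ndarray,
    row_indices: np.ndarray | None = None,
) -> DistortionTable:
    """Distortion tables from stripe traces at equally stepped slider moves.

    ``traces[i, j]`` is the measured stripe column of scan i at row j, with
    scan 0 the centre reference line (delta_x[0] = 0).  The ideal shift of
    scan i from the reference is ``i * S1`` with S1 the first-step shift;
    the x-distortion is the observed shift minus the ideal one, averaged
    over rows.  Rows are treated analogously for delta_y using the
    first-row spacing.
    """
    traces = np.asarray(traces, dtype=float)
    steps = np.diff(np.asarray(slider_steps, dtype=float))
    if steps.size and np.ptp(steps) > 0.01 * np.abs(steps).mean():
        raise CalibrationDesignError("slider steps differ by more than 1%: unequal stepping")
    n_scans, n_rows = traces.shape
    if row_indices is None:
        row_indices = np.arange(n_rows, dtype=float)

    shifts = traces[0][None, :] - traces  # S_{i,j}
    s1 = shifts[1] if n_scans > 1 else np.zeros(n_rows)
    ideal = np.arange(n_scans)[:, None] * np.mean(s1)
    delta_x = np.mean(shifts - ideal, axis=1)
    delta_x[0] = 0.0

    rowpos = np.asarray(row_indices, dtype=float)
    t = rowpos[0] - rowpos  # T_{i,j} analogue on the row coordinate
    t1 = t[1] - t[0] if n_rows > 1 else 0.0
    delta_y = t - np.arange(n_rows) * t1
    return DistortionTable(delta_x=delta_x, delta_y=delta_y)


# ---------------------------------------------------------------------------
# forward renderer


@dataclass
class ScanStack:
    """Rendered (or captured) laser-line image stack with slider positions."""

    images: np.ndarray  # (n_scans, height, width)
    slider_positions: np.ndarray  # mm
    bit_depth: int = 8

    @property
    def n_scans(self) -> int:
        return self.images.shape[0]


def render_scan(
    surface: SurfaceGrid,
    geom: CameraGeometry,
    sigma_px: float = 2.0,
    noise_level: float = 0.0,
    seed: int | None = None,
    image_shape: tuple[int, int] = (480, 640),
    bit_depth: int = 8,
    peak_fraction: float = 0.85,
    distortion: DistortionTable | None = None,
) -> ScanStack:
    """Render one stripe image per surface column (scan position).

    The stripe centre in each image row is the exact forward model of the
    triangulation equations; the cross-section is Gaussian with width
    ``sigma_px``; optional additive Gaussian noise (fraction of full scale)
    and an optional distortion table emulate a real camera.  Deterministic
    from ``seed``.
    """
    H, W = image_shape
    rng = np.random.default_rng(seed)
    full_scale = 2**bit_depth - 1
    amp = peak_fraction * full_scale
    if np.any(surface.heights <= -geom.a2):
        raise FieldOfViewError("surface heights at or below -A2 cannot be imaged")
    images = np.empty((surface.shape[0], H, W), dtype=np.uint16 if bit_depth > 8 else np.uint8)
    rows_px = np.arange(H, dtype=float)
    for i in range(surface.shape[0]):
        z_col = surface.heights[i]
        yb = width_to_pixel(surface.y_coords, z_col, geom)  # stripe rows of grid points
        xb = height_to_pixel(z_col, geom)  # stripe columns of grid points
        if distortion is not None:
            # a distorted camera reports shifted coordinates
            xb = xb - distortion.delta_x[min(i, len(distortion.delta_x) - 1)]
        if yb[0] > yb[-1]:
            yb, xb = yb[::-1], xb[::-1]
        if yb[0] < 0 or yb[-1] > H - 1 or xb.min() < 0 or xb.max() > W - 1:
            raise FieldOfViewError(
                f"scan {i}: stripe leaves the sensor (rows {yb[0]:.1f}..{yb[-1]:.1f}, "
                f"cols {xb.min():.1f}..{xb.max():.1f})"
            )
        inside = (rows_px >= yb[0]) & (rows_px <= yb[-1])
        centers = np.interp(rows_px, yb, xb)
        img = amp * np.exp(
            -0.5 * ((np.arange(W)[None, :] - centers[:, None]) / sigma_px) ** 2
        )
        img[~inside] = 0.0
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level * full_scale, size=img.shape)
        images[i] = np.clip(np.round(img), 0, full_scale).astype(images.dtype)
    return ScanStack(images=images, slider_positions=surface.x_coords.copy(), bit_depth=bit_depth)


def reconstruct_surface(
    images: np.ndarray,
    slider_positions: np.ndarray,
    geom: CameraGeometry,
    distortion: DistortionTable | None = None,
    y_grid: np.ndarray | None = None,
    edge_margin: int = 2,
    min_window: int = 7,
) -> SurfaceGrid:
    """Assemble a height grid from a stripe image stack.

    Per image: the stripe's vertical extent comes from the edge detector,
    each interior row's stripe column from the sub-pixel peak detector
    (distortion-corrected when a table is given), and the triangulation
    equations give (z, y) per row; the slider provides x.  The scattered
    (y, z) samples of each scan are interpolated onto a common y lattice
    (``y_grid``, defaulting to the overlap of all scans).
    """
    images = np.asarray(images)
    n_scans = images.shape[0]
    slider_positions = np.asarray(slider_positions, dtype=float)
    per_scan: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_scans):
        img = images[i].astype(float)
        profile = img.max(axis=1)
        start, end = detect_line_edges(profile)
        r0, r1 = start + edge_margin, end - edge_margin
        if r1 <= r0:
            raise NoLineError(f"scan {i}: stripe too short after edge margin")
        rows = img[r0:r1]
        xb = stripe_peaks_rows(rows, min_window=min_window)
        row_px = np.arange(r0, r1, dtype=float)
        ok = np.isfinite(xb)
        xb, row_px = xb[ok], row_px[ok]
        if distortion is not None:
            xb = xb + distortion.delta_x[min(i, len(distortion.delta_x) - 1)]
        z = triangulate_height(xb, geom)
        y = triangulate_width(row_px, z, geom)
        per_scan.append((y, z))
    if y_grid is None:
        lo = max(y.min() for y, _ in per_scan)
        hi = min(y.max() for y, _ in per_scan)
        ny = min(len(y) for y, _ in per_scan)
        y_grid = np.linspace(lo, hi, ny)
    heights = np.empty((n_scans, y_grid.size))
    for i, (y, z) in enumerate(per_scan):
        order = np.argsort(y)
        heights[i] = np.interp(y_grid, y[order], z[order])
    return SurfaceGrid(heights, slider_positions, np.asarray(y_grid, dtype=float))


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationData:
    """Known height/width differences with their measured stripe pixels.

    Height part: ``dz[k] = z_k - z_ref`` with stripe columns ``x_pix[k]``
    and reference columns ``x_ref_pix[k]``.  Width part:
    ``dy[k] = y_k - y_ref`` with stripe rows, reference rows, and the
    (known) heights at both.
    """

    dz: np.ndarray
    x_pix: np.ndarray
    x_ref_pix: np.ndarray
    dy: np.ndarray
    y_pix: np.ndarray
    y_ref_pix: np.ndarray
    z_at_y: np.ndarray
    z_at_y_ref: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dz", "x_pix", "x_ref_pix", "dy", "y_pix", "y_ref_pix", "z_at_y", "z_at_y_ref"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def n_observations(self) -> int:
        return self.dz.size + self.dy.size

    @property
    def underdetermined(self) -> bool:
        return self.n_observations < 6 or self.dz.size < 2 or self.dy.size < 2


def calibration_objective(geom: CameraGeometry, data: CalibrationData) -> float:
    """Mean-squared residual of the known differences under the candidate
    geometry: ``FO = (FO1 + FO2) / 2``.

    FO1 compares height differences against the triangulation prediction
    (the lens-to-sensor terms cancel); FO2 compares width differences.
    A candidate whose principal point makes any displacement non-positive
    is infeasible and scores infinity.
    """
    disp = geom.pixel_size * (data.x_pix - geom.x_center)
    disp_ref = geom.pixel_size * (data.x_ref_pix - geom.x_center)
    if np.any(disp <= 0) or np.any(disp_ref <= 0):
        return float("inf")
    k = geom.a1 * geom.d
    r1 = data.dz - (k / disp - k / disp_ref)
    eta, a1 = geom.pixel_size, geom.a1
    pred_y = eta * (data.y_pix - geom.y_center) * (geom.a2 + data.z_at_y) / a1
    pred_y_ref = eta * (data.y_ref_pix - geom.y_center) * (geom.a2 + data.z_at_y_ref) / a1
    r2 = data.dy - (pred_y - pred_y_ref)
    return float(0.5 * (np.mean(r1**2) + np.mean(r2**2)))


def build_calibration_search_space(
    image_shape: tuple[int, int],
    focal: float,
    pixel_pitch: float | None = None,
    pitch_band: float = 0.01,
) -> SearchSpace:
    """Per-parameter intervals for the calibration search.

    Principal point within the sensor; pixel pitch within ``pitch_band`` of
    the nominal (derived from a 1/2-inch sensor width when not given);
    A1 in [1.8 f, 3.8 f]; A2 in [A1max, 10 A1max]; D in [A1max, 8 A1max].
    Gene order matches :meth:`CameraGeometry.as_vector`.

    The pitch band is narrow by design: sensor pitch is a lithographic
    datasheet constant, and the calibration objective is exactly invariant
    under a joint scaling of (pixel_size, a1) — the pitch interval is what
    pins that gauge direction, so its width propagates one-for-one into the
    a1 estimate.
    """
    if focal <= 0:
        raise ValueError("focal length must be positive")
    H, W = image_shape
    if pixel_pitch is None:
        pixel_pitch = 6.4 / W  # 1/2" sensor width spread over the columns
    a1_lo, a1_hi = 1.8 * focal, 3.8 * focal
    lower = np.array([0.0, 0.0, pixel_pitch * (1 - pitch_band), a1_lo, a1_hi, a1_hi])
    upper = np.array([float(W), float(H), pixel_pitch * (1 + pitch_band), a1_hi, 10 * a1_hi, 8 * a1_hi])
    return SearchSpace(lower, upper)


@dataclass
class CalibrationResult:
    geometry: CameraGeometry
    objective: float
    converged: bool
    ga_result: GAResult


def _feasible_parents(objective, space: SearchSpace, rng, incumbent=None) -> np.ndarray:
    """Four feasible parents (finite objective), optionally seeded with the
    incumbent: principal points right of the stripe score infinity and must
    be rejection-sampled away."""
    parents: list[np.ndarray] = []
    for _ in range(10_000):
        cand = space.sample(rng)[0]
        if np.isfinite(objective(cand)):
            parents.append(cand)
        if len(parents) == 4:
            break
    if len(parents) < 4:
        raise CalibrationDesignError("could not find a feasible initial population")
    if incumbent is not None:
        parents[0] = np.clip(incumbent, space.lower, space.upper)
    return np.stack(parents)


def calibrate(
    data: CalibrationData,
    image_shape: tuple[int, int],
    focal: float,
    config: GAConfig | None = None,
    pixel_pitch: float | None = None,
    pitch_band: float = 0.01,
    fo_threshold: float = 1e-6,
    n_stages: int = 300,
    shrink: float = 0.6,
    grow: float = 2.0,
) -> CalibrationResult:
    """Recover the camera geometry from known-difference calibration data.

    The genetic engine runs in restart stages with adaptive range
    reduction: each stage runs the unmodified engine over a box centred on
    the incumbent best, shrinking the box when the stage improves the
    objective and re-expanding it (within the full search space) when it
    does not.  A single run of the four-parent engine collapses its parent
    pairs within tens of generations and then has only axis-aligned and
    box-diagonal moves available, which cannot follow the strongly
    correlated valley this objective has in (x_center, d); the restart
    schedule recovers steady progress while keeping every move inside the
    published operator set.  ``n_stages = 1`` gives the plain single-run
    behaviour.

    Flags non-convergence when the final objective stays above
    ``fo_threshold`` (mm^2).
    """
    if data.underdetermined:
        raise CalibrationDesignError(
            "calibration data under-determined: need several height and width "
            "differences (>= 6 observations)"
        )
    space0 = build_calibration_search_space(image_shape, focal, pixel_pitch, pitch_band)
    config = config or GAConfig(max_generations=200, stall_window=50, stall_tolerance=1e-18)
    rng = np.random.default_rng(config.seed)

    def objective(vec: np.ndarray) -> float:
        return calibration_objective(CameraGeometry.from_vector(vec), data)

    full_width = space0.upper - space0.lower
    width = full_width.copy()
    best_vec: np.ndarray | None = None
    best_fo = np.inf
    last_result: GAResult | None = None
    for _ in range(n_stages):
        if best_vec is None:
            space = space0
        else:
            lo = np.maximum(space0.lower, best_vec - width / 2)
            hi = np.minimum(space0.upper, best_vec + width / 2)
            space = SearchSpace(lo, np.maximum(hi, lo + 1e-15))
        parents = _feasible_parents(objective, space, rng, incumbent=best_vec)
        result = run_ga(objective, space, config, init_parents=parents, rng=rng)
        last_result = result
        if result.best_fitness < best_fo * (1 - 1e-12):
            best_fo = result.best_fitness
            best_vec = result.best_vector
            width = width * shrink
        else:
            width = np.minimum(width * grow, full_width)
    assert best_vec is not None and last_result is not None
    geom = CameraGeometry.from_vector(best_vec)
    return CalibrationResult(
        geometry=geom,
        objective=best_fo,
        converged=best_fo <= fo_threshold,
        ga_result=last_result,
    )
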