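"""Fifth-order Bezier patch surfaces.

The last lower-surface model is a patchwork of tensor-product quintic Bezier
patches.  Patch ``(r, t)`` is controlled by the 6x6 block of control points
``P[5r+i, 5t+j]``, and adjacent patches share their border row/column of
control points exactly, so the assembled surface is C0 by construction.
Control points factor as ``P = W * z``: a dimensionless weight ``W`` scaling
the measured height ``z``, and the optimisation acts on the weights.

Parametric values are taken from the data lattice itself: within a patch
segment, ``u_i = (x[5r+i] - x[5r]) / (x[5r+5] - x[5r])``, so each measured
point has its own (u, v) and the fitted surface is compared to the data at
exactly those parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear
from scipy.special import comb

from .exceptions import DegenerateGeometryError, DivisionHazardError, GridError
from .grid import SurfaceGrid

DEGREE = 5

#: flat (row-major) indices of the 16 interior positions of a 6x6 block
INTERIOR_FLAT = np.array([6 * i + j for i in range(1, 5) for j in range(1, 5)])
_BORDER_FLAT = np.array(sorted(set(range(36)) - set(INTERIOR_FLAT.tolist())))


def bernstein_basis(i: int, u):
    """Quintic Bernstein polynomial ``C(5,i) (1-u)^(5-i) u^i``.

    ``u`` may be a scalar or array in [0, 1]; the six values at any ``u``
    sum to one (partition of unity).
    """
    if not 0 <= i <= DEGREE:
        raise ValueError(f"basis index must be in 0..{DEGREE}, got {i}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("parameter u must lie in [0, 1]")
    val = comb(DEGREE, i) * (1.0 - u) ** (DEGREE - i) * u**i
    return float(val) if val.ndim == 0 else val


def bernstein_matrix(u) -> np.ndarray:
    """Matrix ``B[s, i] = B_i(u_s)`` of all six basis functions at each u."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    return np.stack([bernstein_basis(i, u) for i in range(DEGREE + 1)], axis=1)


def compute_parametric_values(coords, i: int | None = None):
    """Chord parametric values of one 6-point patch segment.

    ``u_i = (c[i] - c[0]) / (c[5] - c[0])`` so the segment endpoints map to
    u = 0 and u = 1.  With ``i`` given, returns that single value.
    """
    c = np.asarray(coords, dtype=float)
    if c.shape != (DEGREE + 1,):
        raise ValueError(f"segment must have {DEGREE + 1} coordinates, got {c.shape}")
    if not np.all(np.diff(c) > 0):
        raise DegenerateGeometryError("segment coordinates must be strictly increasing")
    span = c[-1] - c[0]
    if span <= 0:
        raise DegenerateGeometryError("zero-length patch segment")
    u = (c - c[0]) / span
    if i is None:
        return u
    if not 0 <= i <= DEGREE:
        raise ValueError(f"segment index must be in 0..{DEGREE}, got {i}")
    return float(u[i])


def lattice_parameters(coords: np.ndarray) -> np.ndarray:
    """Per-point u values of a full 5k+1 coordinate vector, patch by patch."""
    coords = np.asarray(coords, dtype=float)
    n = coords.size
    if n % 5 != 1 or n < 6:
        raise GridError(f"coordinate count {n} is not 5k+1")
    u = np.empty(n)
    for r in range((n - 1) // 5):
        u[5 * r : 5 * r + 6] = compute_parametric_values(coords[5 * r : 5 * r + 6])
    return u


def eval_patch(control_block: np.ndarray, u, v):
    """Evaluate one quintic patch ``S(u, v) = B(u)^T P B(v)``.

    ``u`` and ``v`` may be scalars or 1-D arrays; with arrays the full
    tensor grid of values is returned with shape ``(len(u), len(v))``.
    """
    P = np.asarray(control_block, dtype=float)
    if P.shape != (6, 6):
        raise ValueError(f"control block must be 6x6, got {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("control block contains non-finite values")
    scalar = np.isscalar(u) and np.isscalar(v)
    Bu = bernstein_matrix(u)
    Bv = bernstein_matrix(v)
    out = Bu @ P @ Bv.T
    return float(out[0, 0]) if scalar else out


def patch_design_matrix(u6, v6) -> np.ndarray:
    """36x36 matrix mapping flattened control points to the 36 patch samples.

    Row ``s = 6*a + b`` corresponds to the sample at ``(u6[a], v6[b])`` and
    holds every basis product ``B_i(u6[a]) B_j(v6[b])`` — one equation per
    sample point with all basis functions evaluated at that sample.
    """
    Bu = bernstein_matrix(u6)
    Bv = bernstein_matrix(v6)
    if Bu.shape[0] != 6 or Bv.shape[0] != 6:
        raise ValueError("u6 and v6 must each hold 6 parameter values")
    return np.kron(Bu, Bv)


@dataclass
class BezierPatchModel:
    """Patchwork quintic Bezier model of a full lattice.

    ``weights`` has the same shape as the source grid; the control lattice is
    ``weights * heights``.  Patch ``(r, t)`` uses control rows ``5r..5r+5``
    and columns ``5t..5t+5``, so neighbouring patches share borders exactly.
    """

    source_grid: SurfaceGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.source_grid.require_patchable()
        if self.weights.shape != self.source_grid.shape:
            raise GridError(
                f"weights shape {self.weights.shape} does not match grid {self.source_grid.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise GridError("weights contain non-finite values")

    @property
    def patch_layout(self) -> tuple[int, int]:
        return self.source_grid.patch_layout

    @property
    def control_points(self) -> np.ndarray:
        return self.weights * self.source_grid.heights

    def control_block(self, r: int, t: int) -> np.ndarray:
        return self.control_points[5 * r : 5 * r + 6, 5 * t : 5 * t + 6]

    def evaluate(self) -> SurfaceGrid:
        """Evaluate the model at the lattice's own (u, v) parameters."""
        return eval_model(self)

    @classmethod
    def identity(cls, grid: SurfaceGrid) -> "BezierPatchModel":
        """The all-ones-weights model (control points equal the data)."""
        return cls(grid, np.ones(grid.shape))


def eval_model(model: BezierPatchModel, u_all: np.ndarray | None = None,
               v_all: np.ndarray | None = None) -> SurfaceGrid:
    """Evaluate a patchwork model at every lattice point.

    Shared patch borders evaluate identically from either neighbour because
    the border control row/column is shared and Bezier patches interpolate
    their boundary control curves at u (or v) in {0, 1}.
    """
    grid = model.source_grid
    if u_all is None:
        u_all = lattice_parameters(grid.x_coords)
    if v_all is None:
        v_all = lattice_parameters(grid.y_coords)
    if u_all.size != grid.shape[0] or v_all.size != grid.shape[1]:
        raise GridError("parametric grid does not match the model lattice")
    N, M = model.patch_layout
    P = model.control_points
    out = np.empty(grid.shape)
    for r in range(N):
        Bu = bernstein_matrix(u_all[5 * r : 5 * r + 6])
        for t in range(M):
            Bv = bernstein_matrix(v_all[5 * t : 5 * t + 6])
            block = P[5 * r : 5 * r + 6, 5 * t : 5 * t + 6]
            out[5 * r : 5 * r + 6, 5 * t : 5 * t + 6] = Bu @ block @ Bv.T
    return grid.with_heights(out)


def fit_weights_least_squares(
    z_block: np.ndarray,
    u6, v6,
    fixed_weights: np.ndarray | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    cond_warn: float = 1e8,
) -> np.ndarray:
    """Linear least-squares oracle for the 16 interior patch weights.

    The patch value is linear in the weights, so the mean-squared fit of the
    surface to ``z_block`` at the lattice (u, v) samples is an ordinary
    linear least-squares problem.  Corner and border weights are held fixed
    (1 by default, or the supplied ``fixed_weights``); optional per-weight
    ``bounds = (lo16, hi16)`` solve the box-constrained problem instead.

    Returns the full 6x6 weight block (fixed entries included).  This is the
    global optimum of the patch objective over the free weights and is used
    as the independent oracle against the genetic search.
    """
    z = np.asarray(z_block, dtype=float)
    if z.shape != (6, 6):
        raise ValueError(f"z block must be 6x6, got {z.shape}")
    W = np.ones((6, 6)) if fixed_weights is None else np.asarray(fixed_weights, dtype=float).copy()
    zf = z.ravel()
    if np.any(np.abs(zf[INTERIOR_FLAT]) < 1e-12):
        raise DivisionHazardError("zero height under a free weight (P = W*z is unscalable)")
    A = patch_design_matrix(u6, v6)
    # design columns for free weights carry the height factor (P = W z)
    A_free = A[:, INTERIOR_FLAT] * zf[INTERIOR_FLAT]
    rhs = zf - A[:, _BORDER_FLAT] @ (W.ravel()[_BORDER_FLAT] * zf[_BORDER_FLAT])
    cond = np.linalg.cond(A_free)
    if cond > cond_warn:
        warnings.warn(
            f"patch design matrix is ill-conditioned (cond={cond:.3g}); "
            "fitted weights may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    if bounds is None:
        w_free, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        res = lsq_linear(A_free, rhs, bounds=(lo, hi), tol=1e-14)
        w_free = res.x
    Wf = W.ravel()
    Wf[INTERIOR_FLAT] = w_free
    return Wf.reshape(6, 6)
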