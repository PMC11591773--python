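"""Last-to-footprint surface adjustment.

The adjustment works patch by patch on a shared 5k+1 lattice.  For each 6x6
block the signed mean gap E between the last surface z and the footprint h
shifts the block (``z <- z - E``: E > 0 moves the surface down, E < 0 up);
tangent-plane (G1) continuity across patch borders is restored by midpoint
constraints; a per-weight search interval is derived from the remaining
z-to-h gap; and the 16 interior patch weights are optimised by the genetic
engine against the mean-squared patch objective.  An outer loop repeats the
whole pass, with the fitted surface in place of z, until every per-patch
|E| falls below a tolerance or a modification cap is reached.

The contour step scales the last outline to the footprint outline before
any of this, and the quality gap of the result is the mean relative height
error in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bezier
from .bezier import INTERIOR_FLAT, BezierPatchModel
from .exceptions import DegenerateGeometryError, DivisionHazardError, GridError
from .ga import GAConfig, GAResult, SearchSpace, run_ga
from .grid import SurfaceGrid


# ---------------------------------------------------------------------------
# block-level operations


def mean_error(z_block: np.ndarray, h_block: np.ndarray) -> float:
    """Signed mean of (z - h) over the 36 points of a patch block."""
    z = np.asarray(z_block, dtype=float)
    h = np.asarray(h_block, dtype=float)
    if z.shape != h.shape:
        raise ValueError(f"block shapes differ: {z.shape} vs {h.shape}")
    return float(np.mean(z - h))


def shift_block(z_block: np.ndarray, E: float) -> np.ndarray:
    """Move a block toward the target by its mean error (z - E)."""
    if not np.isfinite(E):
        raise ValueError("mean error must be finite")
    return np.asarray(z_block, dtype=float) - E


def enforce_g1_borders(lattice: np.ndarray) -> np.ndarray:
    """Set every inter-patch border line to the midpoint of its flanking
    interior neighbours.

    Border index ``5r+5`` (row or column) becomes the mean of indices
    ``5r+4`` and ``5r+6``, which equalises the one-sided first differences
    across the border — tangent-plane (G1) continuity on the lattice.
    Outer boundary lines have no flanking pair and are left untouched.
    Applies identically to height lattices and control/weight lattices.
    """
    a = np.asarray(lattice, dtype=float).copy()
    nx, ny = a.shape
    if nx % 5 != 1 or ny % 5 != 1:
        raise GridError(f"lattice shape {a.shape} is not 5k+1 per axis")
    for b in range(5, nx - 1, 5):
        a[b, :] = 0.5 * (a[b - 1, :] + a[b + 1, :])
    for b in range(5, ny - 1, 5):
        a[:, b] = 0.5 * (a[:, b - 1] + a[:, b + 1])
    return a


def build_search_space(
    z_block: np.ndarray,
    h_block: np.ndarray,
    s_init_block: np.ndarray,
) -> SearchSpace:
    """Per-weight search interval for the 16 free (interior) weights.

    ``s_init_block`` is the patch evaluated with all weights 1.  Where that
    initial surface sits above the data, the weight may only shrink:
    ``[(z - 3|z-h|)/z, 1]``; where it sits below, only grow:
    ``[1, (z + 3|z-h|)/z]``.  Every interval therefore contains 1, so the
    starting model is always reachable.  A zero z-to-h gap collapses the
    interval to the fixed value {1}.
    """
    z = np.asarray(z_block, dtype=float).ravel()[INTERIOR_FLAT]
    h = np.asarray(h_block, dtype=float).ravel()[INTERIOR_FLAT]
    s = np.asarray(s_init_block, dtype=float).ravel()[INTERIOR_FLAT]
    if np.any(np.abs(z) < 1e-12):
        raise DivisionHazardError("zero height at a free-weight position")
    span = 3.0 * np.abs(z - h)
    lower = np.where(s >= z, (z - span) / z, 1.0)
    upper = np.where(s >= z, 1.0, (z + span) / z)
    return SearchSpace(lower, upper)


def init_population(space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Four parents drawn uniformly from the per-gene intervals."""
    return space.sample(rng, 4)


def assemble_weight_block(free_weights: np.ndarray) -> np.ndarray:
    """Full 6x6 weight block from the 16 interior genes.

    Corner and border weights are 1 during a patch fit; inter-patch borders
    of the assembled model are re-constrained afterwards by the midpoint
    rule on the control lattice.
    """
    W = np.ones((6, 6))
    W.ravel()[INTERIOR_FLAT] = free_weights
    return W


def make_patch_objective(z_block: np.ndarray, u6, v6):
    """Mean-squared patch misfit as a function of the 16 free weights.

    ``O = (1/36) sum_s (S(u_s, v_s) - z_s)^2`` with S linear in the weights;
    the fixed border contribution is precomputed so each evaluation is a
    single 36x16 mat-vec.
    """
    z = np.asarray(z_block, dtype=float)
    if z.shape != (6, 6):
        raise ValueError(f"z block must be 6x6, got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z block contains non-finite values")
    A = bezier.patch_design_matrix(u6, v6)
    zf = z.ravel()
    border = np.setdiff1d(np.arange(36), INTERIOR_FLAT)
    fixed_part = A[:, border] @ zf[border]  # border weights = 1
    A_free = A[:, INTERIOR_FLAT] * zf[INTERIOR_FLAT]

    def objective(w16: np.ndarray) -> float:
        r = fixed_part + A_free @ np.asarray(w16, dtype=float) - zf
        return float(np.dot(r, r) / 36.0)

    objective.design = A_free  # exposed for the least-squares oracle
    objective.fixed_part = fixed_part
    return objective


# ---------------------------------------------------------------------------
# whole-surface operations


def scale_contour(last: SurfaceGrid, footprint: SurfaceGrid) -> tuple[SurfaceGrid, float]:
    """Scale the last outline to the footprint outline.

    The scale factor is the ratio of the footprint's y extent to the last's
    (applied to both axes); heights are unchanged.  Returns the scaled grid
    and the factor.
    """
    _, ys = last.extent()
    _, yf = footprint.extent()
    if ys <= 0 or yf <= 0:
        raise DegenerateGeometryError("zero outline extent; cannot scale contour")
    eps = yf / ys
    return SurfaceGrid(last.heights.copy(), eps * last.x_coords, eps * last.y_coords), eps


def relative_error(model_surface: SurfaceGrid, reference: SurfaceGrid) -> float:
    """Mean relative height error in percent: ``100/(n m) sum |z - H| / H``."""
    z = model_surface.heights
    H = reference.heights
    if z.shape != H.shape:
        raise ValueError(f"grid shapes differ: {z.shape} vs {H.shape}")
    if np.any(H == 0):
        raise DivisionHazardError("reference surface contains zero heights")
    return float(100.0 * np.mean(np.abs(z - H) / np.abs(H)))


@dataclass
class AdjustmentConfig:
    """Outer-loop controls for the adjustment pipeline.

    tolerance : stop when every per-patch |E| (mm) is below this.
    max_modifications : cap on outer passes; the best model so far is
        returned (flagged) if the cap is hit.
    """

    tolerance: float = 0.05
    max_modifications: int = 50
    ga: GAConfig = field(default_factory=GAConfig)
    scale_contour: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_modifications < 1:
            raise ValueError("max_modifications must be >= 1")


@dataclass
class AdjustmentReport:
    modifications: int
    total_generations: int
    per_patch_abs_error: np.ndarray
    final_relative_error_pct: float
    converged: bool
    history: list[dict]

    def to_dict(self) -> dict:
        return {
            "modifications": self.modifications,
            "total_generations": self.total_generations,
            "per_patch_abs_error": self.per_patch_abs_error.tolist(),
            "max_patch_abs_error": float(self.per_patch_abs_error.max()),
            "final_relative_error_pct": self.final_relative_error_pct,
            "converged": self.converged,
            "history": self.history,
        }


def _patch_mean_errors(z: np.ndarray, h: np.ndarray, layout: tuple[int, int]) -> np.ndarray:
    N, M = layout
    E = np.empty((N, M))
    for r in range(N):
        for t in range(M):
            E[r, t] = np.mean(
                z[5 * r : 5 * r + 6, 5 * t : 5 * t + 6] - h[5 * r : 5 * r + 6, 5 * t : 5 * t + 6]
            )
    return E


def _apply_patch_shifts(z: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Shift every block by its own mean error.

    Interior points belong to exactly one patch; shared border lines are
    immediately overwritten by the G1 midpoint rule, so the shift applied
    there is immaterial.
    """
    out = z.copy()
    N, M = E.shape
    for r in range(N):
        sl_r = slice(5 * r, 5 * r + 6) if r == 0 else slice(5 * r + 1, 5 * r + 6)
        for t in range(M):
            sl_t = slice(5 * t, 5 * t + 6) if t == 0 else slice(5 * t + 1, 5 * t + 6)
            out[sl_r, sl_t] = out[sl_r, sl_t] - E[r, t]
    return enforce_g1_borders(out)


def adjust_surface(
    last: SurfaceGrid,
    footprint: SurfaceGrid,
    config: AdjustmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BezierPatchModel, AdjustmentReport]:
    """Fit the last lower surface to the footprint topography.

    Both grids must share the same 5k+1 lattice (use
    :meth:`SurfaceGrid.resample_to` and :func:`scale_contour` beforehand).
    Returns the fitted patch model (weights on the shifted surface) and a
    report with per-patch |E|, the relative error against the footprint,
    and the per-pass history.
    """
    config = config or AdjustmentConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    last.require_patchable()
    if last.shape != footprint.shape or not (
        np.allclose(last.x_coords, footprint.x_coords)
        and np.allclose(last.y_coords, footprint.y_coords)
    ):
        raise GridError(
            "last and footprint must share one lattice; resample the footprint "
            "onto the (scaled) last lattice first"
        )
    N, M = last.patch_layout
    u_all = bezier.lattice_parameters(last.x_coords)
    v_all = bezier.lattice_parameters(last.y_coords)
    h = footprint.heights
    z = last.heights.copy()

    best_model: BezierPatchModel | None = None
    best_E: np.ndarray | None = None
    best_max_E = np.inf
    total_gens = 0
    history: list[dict] = []
    converged = False
    mods = 0

    # first pass: the data itself defines the mean error; afterwards the
    # fitted model surface takes the place of z in the error, but the shift
    # is applied to the retained data lattice (feeding the smoothed fit back
    # in as data lets its approximation wiggle accumulate pass over pass)
    E = _patch_mean_errors(z, h, (N, M))
    for mods in range(1, config.max_modifications + 1):
        z = _apply_patch_shifts(z, E)

        weights = np.ones_like(z)
        base_grid = SurfaceGrid(z, last.x_coords, last.y_coords)
        s_init = bezier.eval_model(BezierPatchModel.identity(base_grid), u_all, v_all).heights
        pass_gens = 0
        for r in range(N):
            u6 = u_all[5 * r : 5 * r + 6]
            for t in range(M):
                v6 = v_all[5 * t : 5 * t + 6]
                sl = (slice(5 * r, 5 * r + 6), slice(5 * t, 5 * t + 6))
                space = build_search_space(z[sl], h[sl], s_init[sl])
                objective = make_patch_objective(z[sl], u6, v6)
                parents = init_population(space, rng)
                if mods > 1:
                    # warm start: carry the previous pass's weights as one
                    # parent so successive refits stay on one near-optimal
                    # weight vector (a fresh random population lands on a
                    # different one each pass and that refit noise swamps
                    # the outer mean-error contraction)
                    prev = prev_weights[sl][1:5, 1:5].ravel()
                    parents[0] = space.clip(prev)
                result = run_ga(
                    objective, space, config.ga, init_parents=parents, rng=rng
                )
                pass_gens += result.n_generations
                W = assemble_weight_block(result.best_vector)
                weights[sl][1:5, 1:5] = W[1:5, 1:5]
        total_gens += pass_gens
        prev_weights = weights

        # re-apply the continuity constraint on the control lattice
        control = enforce_g1_borders(weights * z)
        weights = np.where(np.abs(z) > 1e-12, control / np.where(z == 0, 1.0, z), 1.0)
        model = BezierPatchModel(base_grid, weights)
        fitted = bezier.eval_model(model, u_all, v_all)
        E_fit = _patch_mean_errors(fitted.heights, h, (N, M))
        max_E = float(np.max(np.abs(E_fit)))
        history.append(
            {
                "modification": mods,
                "max_abs_patch_error": max_E,
                "generations": pass_gens,
            }
        )
        if max_E < best_max_E:
            best_max_E = max_E
            best_model = model
            best_E = np.abs(E_fit)
        if max_E <= config.tolerance:
            converged = True
            break
        E = E_fit

    assert best_model is not None and best_E is not None
    final = bezier.eval_model(best_model, u_all, v_all)
    rel = relative_error(final, footprint)
    report = AdjustmentReport(
        modifications=mods,
        total_generations=total_gens,
        per_patch_abs_error=best_E,
        final_relative_error_pct=rel,
        converged=converged,
        history=history,
    )
    return best_model, report
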