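# Methods

## Surface model

The last lower surface and the footprint topography are height fields
`z(i,j)` on regular x–y lattices in millimetres. Patch fitting requires
`5k+1` points per axis so the lattice splits into 6×6-point blocks sharing
border rows/columns; grids of other shapes are rejected and a bilinear
resampling utility (`SurfaceGrid.resample_to` / `resample_shape`) is offered
separately. Registration between last and footprint is by contour scaling
plus bilinear resampling onto one lattice; no rigid registration is
attempted.

Each patch is a tensor-product quintic Bézier surface over its block, with
parametric values taken from the data lattice's chord ratios (so every
measured point has its own `(u,v)` and fitting compares model and data at
exactly those parameters, not at a uniform resample). Control points factor
as `P = W·z`. This makes corner constraints dimensionally consistent: fixing
the corner *weights* at 1 makes the surface interpolate the measured corner
heights (corner control values on a ~27 mm surface are ~27 mm, not 1).

Free parameters per patch are the 16 interior weights. Patch-border weights
are held at 1 during a fit; after every outer pass the G¹ midpoint
constraint is re-applied to the control lattice (border line = mean of its
two flanking lines, indices `5r+4` and `5r+6`), the only indexing that
equalises one-sided differences across the border. The whole-model outer
boundary weights stay at 1.

## Adjustment loop

1. Per patch: signed mean gap `E = mean(z - h)`; shift the block `z ← z - E`
   (E > 0 moves the surface down). Shared border lines are then overwritten
   by the G¹ midpoint rule, so the order in which neighbouring patches shift
   them is immaterial.
2. Per interior weight: a search interval from the remaining gap —
   `[(z - 3|z-h|)/z, 1]` where the unit-weight surface lies above the data,
   `[1, (z + 3|z-h|)/z]` where below. Every interval contains 1, so the
   starting model is always reachable; a zero gap collapses the interval to
   the fixed point {1}.
3. The genetic engine minimises the mean-squared patch misfit over the 16
   weights (patches in r-major raster order).
4. Outer loop: recompute the per-patch mean error with the fitted surface in
   place of `z`, and use it to shift the retained data lattice for the next
   pass. Stop when every `|E|` is below tolerance (default 0.05 mm) or at a
   cap of 50 modifications (best-so-far model returned, flagged).

Two numerical choices here matter and were verified explicitly.
*Retaining the data lattice*: feeding the fitted (smoothed) surface back in
as the next pass's data lets the smoother's approximation wiggle accumulate
— the surface visibly diverges within ~10 passes — whereas shifting the
retained data by the model's patch-mean error contracts geometrically
(factor ≈ 0.35/pass with deterministic least-squares fits). *Warm starts*:
each patch's population is seeded with the previous pass's weights as one of
the four parents; a fresh random population lands on a different
near-optimal weight vector every pass, and that refit noise (~0.05 mm in the
patch means) otherwise swamps the outer contraction.

The quality gap is the mean relative height error
`100/(n·m) Σ |z-H|/H` in percent; the absolute value is deliberate — signed
terms would cancel and understate the error.

### Self-adjustment and its floor

Adjusting a surface to itself is the exact identity only when the patchwork
reproduces the surface at unit weights. For affine fields it does (linear
precision), and the pipeline then converges with per-patch `|E|` at float
zero. For a generically curved surface the zero-gap search intervals pin all
weights at 1, so the best reachable surface is the unit-weight Bernstein
smoothing of the data, whose per-patch mean residual is ~0.05–0.1 mm at the
default foot curvature; the gap-proportional interval width self-limits
`|E|` at that scale. This is a property of the gap-derived search-space
rule, not of the optimiser; the relative error of curved self-adjustment
still lands near 0.1%.

## Genetic engine

Population: 4 parents, 6 children. Children: the pairs (P1,P2) and (P4,P3)
each produce two inside children `0.5[(P_a+P_b) ± β|P_a-P_b|]`; one child is
pulled from P1 toward the lower bound and one from P4 toward the upper bound
(`bound + β(parent - bound)`, used symmetrically for both). Spread factor:
`β = √(2α)` for `α ≤ 0.5`, else `√(2(1-α))`, one α per crossover event
shared across all genes. Both of those conventions are pinned by the bundled
two-generation reference trace: a single gap-weighted least-squares
back-solved β (0.47504 in generation 1, 0.47503 in generation 2) reproduces
all 64 inside-child cells of each generation to ~1e-4 mm, which also forces
the midpoint-symmetric grouping with the absolute value. The reversed β
orientation (always ≥ 1, children outside their parents) contradicts the
trace and is kept only behind `GAConfig.printed_beta_rule`; a per-gene-α
mode exists and is off by default. Back-solving β from a single child cell
is unreliable when the parent gap is small: the first trace row has a
0.031 mm gap, so its 4-decimal rounding alone moves the per-cell estimate
by ~0.005.

Selection is elitist within fixed pools (P1' best of {P1,P2}, P3' best of
{P3,P4}, P2' best of {C1,C2,C3}, P4' best of {C4,C5,C6}; ties to the lowest
index), which guarantees the best fitness is non-increasing. Mutation
proposes one fresh random vector against the worst parent and one fresh
single-gene redraw against a random parent, each accepted only on
improvement; acceptance counts are logged as run diagnostics. Children
leaving the box are clipped to the violated bound (only possible under the
reversed β rule). Stopping: best-fitness improvement below 1e-6 over 20
generations, cap 500 (defaults; the 1-D quadratic test uses a much larger
window because late progress comes from rare uniform redraws whose success
probability halves with each improvement). Degenerate genes (equal bounds)
are fixed and excluded from mutation.

On the 16-weight patch problem the engine is strong: across seeded synthetic
patches its final objective is within 0.1% of the box-constrained linear
least-squares optimum (`fit_weights_least_squares`, the independent oracle —
the patch value is linear in the weights, so the global optimum is exactly
computable and must dominate any candidate).

## Laser-line scanning

Triangulation: `z = A1·D/(η(x̄-x̄c)) - A2` — the parenthesisation under which
the lens-to-sensor terms cancel in height *differences* — and
`y = η(ȳ-ȳc)(A2+z)/A1 + η·ȳc`. The renderer is the exact inverse of these
two equations plus a Gaussian stripe cross-section (default σ = 2 px, 8-bit
quantisation, optional additive noise and per-line distortion offsets), so
`reconstruct(render(S)) ≈ S` isolates algorithmic errors from physical
fidelity. The default bench geometry (η = 0.06 mm/px, A1 = 20 mm,
A2 = 64 mm, D = 110 mm, 640×480 sensor) keeps a 25–30 mm surface on-sensor
with a height sensitivity of ~0.23 mm/px; the noise-free round trip on a
224-line scan has RMS ≈ 0.004–0.007 mm.

Stripe centres: a Bézier curve of order (window length − 1) is laid through
each row's pixel positions and intensities (the samples are its control
values — the curve approximates, not interpolates, interior samples), and
the centre is `x(u*)` at `I'(u*) = 0`, found by vectorised bisection
(tolerance 1e-6 in u) with concavity (`I'' < 0`) verified at the root. The
fitted window is symmetric about the argmax with half-width 2.5× the span of
pixels above background + 20% of the range (minimum 7 px): the Bernstein
curve is a strong smoother whose peak is pulled toward the window centre,
and at 1× expansion that pull leaves ~0.05 px of bias on Gaussian stripes —
the 2.5× window brings it to ~0.012 px. Bisection brackets start at
[0.05, 0.95] because quantised-to-zero tails make the derivative vanish
identically at the endpoints. Stripe extent per image comes from the extreme
discrete derivatives of the smoothed column profile.

Distortion: per-scan-line `δx` and per-row `δy` shift tables referenced to a
centre line (`δx` there ≡ 0), built from traces at equal slider steps (steps
differing by >1% are rejected); the ideal shift of line *i* is *i* times the
first-step shift, so the tables are identified up to the linear trend
absorbed by that first step.

## Camera calibration: what is and is not identifiable

Calibration minimises `FO = (FO1 + FO2)/2`, the mean-squared residuals of
*known* height and width differences under the candidate geometry, over six
genes (x̄c, ȳc, η, A1, A2, D) with data-independent bounds: principal point
within the sensor, A1 ∈ [1.8f, 3.8f] for the lens focal length f, A2 and D
as fixed multiples of A1's maximum, and η within ±1% of the nominal sensor
pitch. Two structural facts, both verified numerically:

1. **Gauge freedom.** FO is *exactly* invariant under `η → cη, A1 → cA1`
   (the additive `η·ȳc` terms cancel in differences), so only A1·D/η, η/A1,
   x̄c, ȳc and A2 are data-identified; η and A1 individually are pinned only
   by the η bounds. The pitch band is narrow by design — sensor pitch is a
   lithographic datasheet constant — and its width propagates one-for-one
   into the A1 estimate. The synthetic calibration target therefore
   differences every width mark against the first mark at the *first*
   height: equal-height width pairs cancel ȳc and A2 exactly and would
   leave them unidentified too.

2. **A stiff valley.** With η pinned, the Hessian of FO at the optimum has
   corr(x̄c, D) = 0.9997 (axis-scaled condition ~1e4 for a 10–28 mm gauge,
   still ~2e3 for a 100 mm one). The four-parent engine's moves are
   axis-aligned gene redraws, box-diagonal bound children, and steps along
   parent differences that collapse within tens of generations — none track
   such a valley. A single run plateaus around FO ~1e-2 mm² regardless of
   budget (a 100k-generation run improves it by ~10%). `calibrate()`
   therefore wraps the unmodified engine in adaptive range-reduction
   restarts (box re-centred on the incumbent, shrunk ×0.6 on improvement,
   re-expanded ×2 otherwise, 300 stages by default), which reaches FO
   ~1e-3–1e-4 mm² and parameter errors of a few to ~15% — but not the ~0
   objective that optimizers with adaptive search geometry (a downhill
   simplex, or population methods with difference-vector proposals) reach
   on the same objective and data. The recovery limit is thus a property of
   the operator set, not of the objective, the data design, or this
   implementation; the corresponding acceptance test documents it and
   fails honestly.

## Synthetic data

The footprint generator composes Gaussian bumps (heel +2.5 mm, metatarsal
pad +2.2 mm, toes +1.2 mm, arch −1.3 mm; widths 22–40 mm) on a 26.5 mm
plateau over a 250×90 mm outline, 31×21 lattice — heights stay in the
25–30 mm band a scanned last lower surface occupies, so worked-example
magnitudes are comparable. The last generator adds a constant offset
(default 1 mm) plus a smooth two-component random-phase cosine deformation
(default amplitude 1 mm, wavelength 150 mm) and returns the known gap field.
`make_model_footprint` builds targets that lie exactly in the patch-model
class (interior weights within ±3% of 1), for which the pipeline's recovery
error is well under 1%. All generators are deterministic from their seeds.

What the generators deliberately omit: statistical foot-shape variation,
left/right anatomy, scanner speckle/occlusion artefacts, and outline shapes
more complex than a rectangle's extent. Passing tests therefore demonstrate
the algorithms' correctness on smooth, well-registered, foot-scaled
surfaces — not robustness to real scan pathologies.

## Known limitations

- The calibration identifiability and optimiser limits above.
- Surfaces must be single-valued height fields on a regular lattice;
  undercuts and missing data are out of scope (a missing stripe row is
  interpolated only within a scan).
- The distortion model is the two shift tables; no parametric lens model.
- Patch borders are constrained (weights 1 + midpoint rule) rather than
  re-optimised, so the fit floor near borders is higher than at interiors.
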