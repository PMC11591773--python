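# lastfit

Custom footwear starts from the *shoe last*, and the last's lower surface must
mate with the wearer's plantar surface: a mismatch between the two concentrates
pressure and defeats the point of a custom insole. `lastfit` implements a
complete desk pipeline for that adjustment problem: it models the last lower
surface as a patchwork of fifth-order Bézier surfaces, optimises the patch
weights with a compact four-parent real-coded genetic algorithm whose search
space is derived from the gap between the last and the target footprint, and
supplies the surfaces themselves through a laser-line triangulation module
(sub-pixel stripe localisation, camera-geometry calibration, and a synthetic
scanner that replaces the physical rig).

## The model

Heights `z(i,j)` on a regular millimetre lattice are split into 6×6-point
blocks. Patch `(r,t)` is the tensor-product quintic

```
S_{r,t}(u,v) = Σ_{i=0..5} Σ_{j=0..5} B_i(u) B_j(v) P_{5r+i,5t+j},
B_i(u) = C(5,i) (1-u)^(5-i) u^i,
```

with control points factored as `P = W·z` — a dimensionless weight scaling the
measured height — and `(u,v)` taken from the data lattice's own chord
parameters. Adjacent patches share border control lines (C⁰ by construction);
tangent-plane (G¹) continuity is enforced by midpoint constraints on the lines
flanking each border.

For each patch the signed mean gap `E_{r,t} = mean(z - h)` against the
footprint `h` first shifts the block (`z ← z - E`), then each interior weight
gets a search interval from the remaining gap (`[(z-3|z-h|)/z, 1]` when the
initial unit-weight surface lies above the data, `[1, (z+3|z-h|)/z]` below),
and the genetic engine minimises the mean-squared patch misfit
`O = (1/36) Σ (S(u,v) - z)²` over the 16 interior weights. An outer loop
repeats the pass — the fitted model's patch-mean error driving the next shift —
until every `|E_{r,t}|` falls below tolerance. The quality gap is the mean
relative height error `100/(n·m) Σ |z-H|/H` in percent.

The engine itself keeps 4 parents and builds 6 children per generation: two
*inside* children per parent pair, `0.5[(P_a+P_b) ± β|P_a-P_b|]`, and one
*outside* child per pair pulled toward a search-space bound, with the spread
factor `β = √(2α)` (α ≤ ½) or `√(2(1-α))` drawn once per crossover event.
Selection is elitist within fixed pools and mutation accepts a proposal only
if it improves fitness. A bundled two-generation reference trace of this
crossover (16 genes, four parents, six children, fitness rows) pins the
operator algebra to ~1e-4 mm.

The scanner model recovers height from the lateral image displacement of a
vertical laser stripe, `z = A1·D/(η(x̄-x̄c)) - A2`, and width from the stripe
row, `y = η(ȳ-ȳc)(A2+z)/A1 + η·ȳc`; stripe centres are located to ~0.01 px by
the stationary point of a Bézier intensity curve laid through each row's
pixels. The renderer is the exact inverse of these equations plus a Gaussian
stripe profile, so reconstruction correctness is testable in isolation.

## Worked example

```bash
$ lastfit run-all --seed 0 --out-dir demo
relative_error=0.952% max|E|=0.0364 mm modifications=3
```

This simulates a footprint (a 31×21 lattice spanning 250×90 mm with heights in
the 25–30 mm plantar band), derives a last lower surface from it (1 mm offset
plus a smooth ±1 mm deformation), scales the last contour to the footprint
outline, and runs the patchwise adjustment. The three printed numbers are the
final quality gap (mean relative height error between the adjusted model and
the footprint; 0.95%), the worst per-patch absolute mean error (0.036 mm,
below the 0.05 mm stopping tolerance), and the number of outer modification
passes the loop needed (3). `demo/` holds the grids, the fitted model
(layout, weights, control points), a JSON report and a per-pass history CSV.

The scanning stages can be exercised the same way:

```bash
lastfit simulate --seed 0 --out-dir demo
lastfit render-scan --surface demo/footprint.tsv --out-dir demo/scans
lastfit reconstruct --scan-dir demo/scans --out demo/recon.tsv
```

On the noise-free default geometry the render→reconstruct round trip returns
the footprint with an RMS error of 0.007 mm.

## Layout

| module | contents |
| --- | --- |
| `lastfit.grid` | `SurfaceGrid` container, bilinear resampling |
| `lastfit.bezier` | Bernstein basis, patch/model evaluation, least-squares weight oracle |
| `lastfit.ga` | search spaces, crossover/selection/mutation operators, driver |
| `lastfit.adjust` | mean-error shift, G¹ borders, search-space construction, adjustment loop |
| `lastfit.laser` | triangulation, sub-pixel peaks, renderer, calibration, distortion tables |
| `lastfit.synthetic` | seeded footprint/last/calibration-target generators |
| `lastfit.worked_example` | bundled two-generation crossover trace |
| `lastfit.gridio`, `lastfit.cli` | TSV grids, JSON models/reports, PLY/OBJ export, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults, numerical
choices and known limitations (including a genuine identifiability limit of
the camera-calibration step).
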