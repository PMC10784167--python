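# Methods

## The fox optimizer and its contracted variant

Both optimizers minimize a real objective over a box. The population state
is the agent positions, a per-agent per-dimension "sound travel time"
matrix resampled uniformly in [0, 1] every iteration, and an elitist
best-so-far archive.

The exploitation chain is implemented literally, stage by stage: sound
speed `Sp = BestX / t` (times floored at 1e-12 so a zero draw cannot
divide by zero), sound distance `Sp ⊙ t`, fox–prey distance half of that,
pounce height `0.5·g·(mean(t)/2)²` with `g = 9.81`. Algebraically the
chain collapses to `Dist_fox_prey = 0.5·BestX`, independent of the time
draw; the intermediates are kept because each has its own testable
contract. The direction draw `p` against the 0.18 threshold selects the
scale `c1 = 0.18` (northeast pounce) or `c2 = 0.82`; both are configurable
within their admissible ranges `[0, 0.18]` and `[0.19, 1]`.

The exploration decay is `a = 2·(1 − it/Maxit)`. An alternative
formulation, `2·(it − 1/Maxit)`, *increases* with the iteration count and
would make exploration diverge rather than anneal; it is available behind
`FoxConfig(literal_a=True)` for comparison but is not the default, because
the factor's role — shrinking the random walk as the run matures — demands
decay.

Branching is per agent per iteration: each agent draws its own `r` and
(in exploitation) its own `p`. The step uses batch semantics — all moves
in an iteration are computed from the best-so-far at the iteration's
start, and the archive updates after all evaluations. Positions are
replaced unconditionally (no greedy acceptance); elitism lives entirely in
the archive, which never worsens. Out-of-box moves are clamped
(projection), the simplest boundary rule with a testable contract. A
non-finite objective value keeps that agent's previous position *and*
fitness, with a warning; every other evaluation counts toward the budget,
which is exactly `n_agents·(max_iter+1)` for a FOX run.

CFOA adds two mechanisms:

* **Lévy exploration.** The uniform factor of the exploration move is
  replaced by a Mantegna Lévy step `w = A/|B|^{1/ξ}` with
  `A ~ N(0, σ²(ξ))`, `B ~ N(0,1)` and
  `σ(ξ) = [Γ(1+ξ)·sin(πξ/2)/(Γ((1+ξ)/2)·ξ·2^{(ξ−1)/2})]^{1/ξ}`.
  Default `ξ = 3/2`. The closed form satisfies `σ(1) = 1` exactly, and the
  empirical tail index of |w| (Hill estimator over 10⁶ draws) matches ξ.
  Only the exploration displacement uses Lévy steps; the branch variable
  `r` stays uniform, since the displacement substitution is the one
  concrete formula the construction defines. |B| is floored at 1e-300 to
  keep steps finite.

* **Elimination.** After every `ep`-th iteration (so exactly
  `floor(max_iter/ep)` events per run) the `et` worst-fitness agents are
  replaced by uniform samples in the current box and re-evaluated (the
  replacements count toward the evaluation tally). Before resampling, any
  dimension in which a *surviving* agent's coordinate magnitude exceeds
  `th` percent of the box magnitude has its bounds scaled by
  `expand_factor = 1.25` about zero. Defaults `ep = 40`, `et = 30`,
  `th = 60` (a stated alternative of 80 for `th` is configurable);
  the expansion magnitude itself is unspecified by the construction, so
  any finite factor > 1 is admissible and 1.25 is the default. Bounds are
  therefore monotonically non-shrinking over a run.

### A structural property worth knowing

Every fox move is a *multiplicative* rescaling of the incumbent best:
exploitation proposes `0.5·BestX·Jump·c` and exploration proposes
`BestX ⊙ w·(MinT·a)`. Two consequences:

1. On objectives whose optimum is at the origin (sphere, rastrigin,
   ackley...), the dynamics contract geometrically and reach machine zero
   — benchmark results on such functions flatter any member of this
   family.
2. Around a *non-origin* optimum the moves cannot refine: a proposal close
   to the incumbent requires every component of `w·(MinT·a)` to be near 1
   simultaneously, which for heavy-tailed `w` has negligible probability
   in more than a couple of dimensions. Progress on non-origin optima
   comes from the uniform samples injected at initialization and by the
   elimination phase. This is why the hyperparameter-tuning harness (a)
   uses a zero-centered encoding and (b) defaults to a dense elimination
   schedule (below).

## Benchmarks and the trial harness

The registry ships eight classical analytic objectives (sphere,
rosenbrock, rastrigin, ackley, griewank, schwefel-2.21, the levy surface,
zakharov) with their documented boxes and known minima. The harness runs
any optimizer callable over consecutive seeds `base_seed..base_seed+n−1`
and reports Best/Mean/StD of the per-run final fitness (sample StD,
n−1 convention; a failed seed is logged and excluded). The only built-in
comparator is uniform random search at a matched evaluation budget; any
optimizer with the `(objective, bounds, seed) -> OptResult` signature can
be plugged in. Rotated/shifted competition suites are intentionally out of
scope — they require external displacement data and would not change what
the harness tests.

## Preprocessing

**CLAHE.** The image is reflect-padded to a multiple of the tile grid
(default 8×8), each tile's intensity histogram over L = 256 levels is
clipped at the limit T, the clipped histogram's CDF is spread over the
levels as `C'(k) = (L−1)·C(k)/n_tile`, and pixels are remapped by bilinear
interpolation between the four neighboring tile LUTs (nearest-tile merge
available). Two clipping modes exist: the default *literal* mode truncates
each bin at T and discards the excess, so the CDF normalizer is the
clipped total rather than the tile pixel count; the *redistribute* mode
spreads the excess uniformly (integer round-robin, total conserved, one
pass). The per-tile pixel count — not the whole-image size — normalizes
the CDF; using the image size would break the mapping for any multi-tile
grid. T can be given in absolute counts or as a fraction of the tile size
(`clip_unit`). A fully clipped-away tile falls back to the identity
mapping. With one tile and a non-binding limit the operation reduces
exactly to global histogram equalization, which the tests verify
pixel-for-pixel.

**Normalization and resize.** Min-max normalization maps to [0, 1]; a
constant image (no spread) maps to zeros with a warning. Resizing is
bilinear to a square target with the grayscale channel replicated;
both 227 and 512 are plausible targets depending on the downstream
network configuration, so the target is an argument with default 227 and
no privileged value.

**Augmentation.** One affine transform per call, composed in a fixed,
documented order — scale → shear → rotate → translate, about the image
center, reflections innermost — applied with bilinear resampling and zero
fill. Sampling intervals default to rotation ±7°, shear ±0.03,
translation ±35 px, per-axis scale 0.4–3, reflections off. The
composition order and fill are conventions fixed for reproducibility; the
transforms themselves are order-sensitive, so pipelines needing a
different convention should compose explicitly.

## Losses and metrics

Cross entropy, weighted cross entropy and focal loss use the *sum*
convention over samples (mean available), one-hot targets, and a 1e-12
probability floor before the logarithm. Unit weights reduce the weighted
form to plain cross entropy exactly; δ = 0 reduces the focal form; the
focal decay `(1−p)^δ` never increases a sample's contribution. The
class-weight scheduler maps per-class error rates `Er = 1 − TPR` through
ρ ∈ {identity, y³, e^y, e^{10y}, e^{100y}} and normalizes to sum to one;
an all-zero transform (possible under identity/cube) falls back to
uniform weights. The focal δ defaults to 2 — the conventional choice, as
the construction itself fixes no value. The class count is an argument
everywhere (the shipped phantom data has 3 classes; 4-class probability
vectors work unchanged).

Metrics come from an integer confusion matrix (true × predicted). Two
classes use the textbook binary formulas with class 1 positive; more
classes are reduced one-vs-rest and macro-averaged, with overall accuracy
as the diagonal fraction. Undefined ratios (empty denominators) are
reported as 0 with a warning. The depthwise-separable convolution cost
model is `C_nor = h·w·d_i·d_j·k²`, `C_sep = h·w·d_i·(d_j+k²)`, advantage
`d_j·k²/(d_j+k²) = C_nor/C_sep`, independent of the spatial extent.

## Hyperparameter tuning

The four scaling knobs — depth multiplier (0, 1], width multiplier (0, 1],
input resolution on the grid {128, 227, 256, 384, 512}, dropout [0, 0.5]
— are encoded in a zero-centered box `[-1, 1]^4`, mapped affinely to their
intervals, with the resolution coordinate snapped to the nearest grid
index on decode. The centering is load-bearing: the optimizer's moves
scale about the origin and its bound expansion scales about zero, so an
all-positive encoding would both bias the search toward the lower corner
and, under repeated expansion, slide the resampling box away from interior
optima entirely.

`tune` minimizes `objective(hp, seed)` over that box with CFOA. The
default budget is population 60, 200 iterations, elimination every 5
iterations replacing 40 agents — dense elimination because, per the
structural property above, uniform resampling is the mechanism that
reaches non-origin optima; with it the tuner recovers a known quadratic
optimum at (0.5, 0.75, 512, 0.2) to within 10% of each interval width on
~97% of probe seeds. For expensive objectives pass a smaller
`CfoaConfig`; results are cached per decoded hyperparameter tuple within
a run.

The shipped objective is a deliberately toy classifier: images are
resized (working resolution capped at 64 px to stay desk-scale), pooled
into a width-multiplier-sized grid of mean intensities plus
depth-multiplier-scaled gradient-magnitude pools and three global
statistics; features are dropout-masked with inverted scaling from a
seeded stream; a closed-form ridge fit (λ = 0.01) to one-hot targets with
argmax readout is trained on a stratified 80% split; fitness is 1 −
validation accuracy. Everything is deterministic given (dataset,
hyperparameters, seed). The stratified split allocates
`round(frac·n_class)` samples per class to training — the nearest-integer
rule that reproduces the 2451/613 bookkeeping of an 80/20 split of class
sizes 708/930/1426.

## Synthetic phantoms

The generator emulates the *structure* of a 3-class grayscale tumor MRI
collection: an elliptical bright "head" (sigmoid falloff) on a dark field
with additive Gaussian noise (default SD 8 on the 8-bit scale), plus a
class-conditional bright lesion — class 1 a single round peripheral blob,
class 2 a small central blob, class 3 a large multi-lobed irregular blob
— each recorded with a boolean mask. Records round-trip through one
legacy `.mat` container per record plus a manifest CSV; the reader also
accepts v7.3 (HDF5) containers and the `cjdata`-style field names
(image/label/tumorMask) used by the public collection this emulates. PNG
export is available.

What the phantoms deliberately do **not** emulate: anatomy, scanner
physics, intensity inhomogeneity, inter-patient variability, or
overlapping class appearance. The classes are linearly separable from
mean-intensity and lesion-area features by construction — which is what
makes the toy objective's near-zero fitness a meaningful smoke test of
the pipeline, and equally why green tests here say nothing about
classification accuracy on real MRI data.

## Problem sizes and numerical choices

Tests and the acceptance script use 64-px phantoms (80 per class where a
validation accuracy is measured, so the fitness granularity 1/48 resolves
the 0.05 scale being checked), 10-D benchmarks at population 60 / 200
iterations / 25 seeds, and 10⁶ draws for tail statistics. Tolerances:
σ oracle agreement 1e-4, identity contracts 1e-9, exact integer counts
elsewhere. Known limitations: the optimizer family's origin bias (above),
the single-pass excess redistribution in CLAHE, and the toy objective's
indifference to input resolutions above its 64-px working cap.
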