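# Methods

## Objective: Kapur's entropy over a 256-bin histogram

Images are 8-bit grayscale; the histogram always has 256 bins regardless of
the observed dynamic range, so the search domain is the fixed box
`[0, 255]^k`. For thresholds `t_1 ≤ … ≤ t_k` the classes are
`[0..t_1], [t_1+1..t_2], …, [t_k+1..255]` — a threshold belongs to the class
*below* it. Duplicated thresholds are legal and produce empty classes.
This convention was chosen because reported optima for this family of
methods routinely contain repeated levels and endpoint values; any
convention that forbids duplicates cannot represent them.

The objective is the sum of Shannon entropies of the class-normalized
histogram segments (natural log). Numerical conventions: `0·ln 0 := 0`, an
empty or zero-mass class contributes zero entropy. With prefix sums of
`p` and `p ln p` each class entropy is `ln A_i − S_i/A_i`, so a batch of
candidate threshold vectors evaluates in `O(batch · k)`.

The exhaustive oracle enumerates all non-decreasing `k`-tuples
(`C(256+k−1, k)` candidates) and is the ground truth for `k ≤ 3`; it
refuses instances above a configurable candidate limit (default 5·10⁶) and
breaks ties toward the lexicographically smallest tuple for reproducibility.

## Optimizer: eagle search with dynamic opposition

The population metaheuristic runs three phases per iteration:

* **select** (exploration): `P_best + α·r·(P_mean − P_i)`, `r ~ U(0,1)` per
  agent, `α = 2` (valid range `[1.5, 2]`).
* **search** (spiral exploitation): `P_i + m_i(P_i − P_{i+1}) + l_i(P_i −
  P_mean)`, where `(l, m)` are polar-spiral coordinates `θ = α_s π u`,
  `r = θ + R v`, `lr = r sin θ`, `mr = r cos θ` normalized by the maximum
  absolute raw value. Defaults `α_s = 10` (range `[5, 10]`), `R = 1.5`
  (range `[0.5, 2]`). The neighbour index wraps (agent `N−1` pairs with
  agent 0). The normalization uses absolute values with an all-zero guard:
  raw sinh/cosh coordinates can be negative or huge, so a plain maximum
  would be ill-defined.
* **swoop** (dive): `u·P_best + l1_i(P_i − c1·P_mean) + m1_i(P_i −
  c2·P_best)` with hyperbolic spiral coordinates (`r = θ`, sinh/cosh),
  `c1 = c2 = 2` (range `[1, 2]`).

Random draws are per agent (scalar), matching the per-agent indexing of the
phase formulas; candidates are clipped to the box and adopted per agent only
when fitter. The best position *ever evaluated* is recorded separately
(elitism), so the reported convergence curve is non-decreasing by
construction and its last entry equals the reported best fitness.

**Dynamic-opposite learning (DOL).** For `x` in `[lo, hi]` the opposite is
`x_o = lo + hi − x` and the dynamic opposite `x + w·r1·(r2·x_o − x)` with
fresh per-dimension `r1, r2 ~ U(0,1)` and weight `w = 3` (exposed in the
config), clipped to bounds. The DOBES variant applies DOL twice:

* at initialization, the fittest `N` of the `2N` union of random agents and
  their dynamic opposites survive (stable ranking, originals first on ties,
  so the refined population is never worse than the raw one);
* inside the search phase, each agent keeps the best of {current position,
  spiral candidate, dynamic opposite of the candidate} (per-agent greedy).

The plain BES baseline is the identical loop with both DOL steps disabled.

**Discrete repair.** Search is continuous; at every evaluation the position
is rounded half-up, clipped and sorted into a valid non-decreasing integer
threshold set (duplicates kept). Round-half-up is used everywhere integer
rounding occurs (repair, luminance conversion, class representatives) for
bit-exact reproducibility.

**Protocol.** Defaults: population 30, 100 iterations, 10 reruns; rerun `j`
is seeded `seed + j`, so a multi-rerun experiment is a pure function of the
base seed. `k` defaults to 3 in the pipeline front ends; benchmark-style
runs use `k = 8` via a flag.

## From thresholds to a region

The quantized "threshold image" maps each pixel to its class
representative; the default representative is the rounded intensity-weighted
mean of the class's own histogram mass, which minimizes MSE among per-class
constants (MSE being the reconstruction metric this family of methods
reports); `class_floor` (interval lower end) is available for visual parity
with typical figures. Binarization marks a configurable set of class
indices as foreground, defaulting to the single brightest class — in
contrast-enhanced T1 images the tumor is bright, but this is an inference,
hence configurable.

The morphology chain computes, in order: Canny edges of the mask (σ = 1,
hysteresis thresholds 0.1/0.2 on the 0/1 raster), dilation of the edge map
by a Euclidean disk (radius 2) to close gaps in the outlines, and
Moore-neighbor boundary tracing of the labeled regions (8-connected
foreground). Region repair then operates on the binary segmented image
itself: components smaller than `min_area` (default 1% of the image area)
are deleted, enclosed background holes are filled (4-connected background
flood from the border — the topological dual of 8-connected foreground),
and the largest surviving component is kept (ties broken by raster order).

Rationale: the connected components of a binary mask are already maximal,
so reconstructing regions *from* their dilated edge loops adds nothing on
binary input while growing every region by the dilation radius and — when
the thresholding stage leaves speckle noise near the target — merging
dilated speckle-edge fragments into large spurious components. Operating
the removal/filling steps on the mask makes the chain exact on clean input
(a solid region passes through unchanged) and robust to speckle, while the
edge products still supply the closed boundary curves of the boundary-
detection step (returned via `postprocess(..., return_stages=True)`).

## Quality metrics

MSE, PSNR (`10 log10(255²/MSE)`, `inf` for identical images), SSIM with the
canonical parameterization (11×11 Gaussian window, σ = 1.5, K1 = 0.01,
K2 = 0.03, L = 255; delegated to scikit-image with exactly those settings),
Dice overlap (both-empty ⇒ 1), and rerun statistics (max, mean, *population*
standard deviation — no Bessel correction, frozen for determinism). SSIM
between masks is computed after scaling to {0, 255}.

## Phantom generator

The phantom emulates what a histogram method sees in a contrast-enhanced
brain slice: concentric tissue bands at class means (20, 90, 160, 230) —
dark surround, brighter inward — one bright tumor disk (default center at
(5H/8, 3W/8), radius ≈ min(H,W)/6), five bright 2-px clutter specks kept
clear of the tumor, and additive Gaussian intensity noise (default σ = 8,
a moderately noisy acquisition), clipped to [0, 255] and rounded half-up.
Ground truth is the rasterized tumor disk. The generator is a pure
function of its spec (including the seed).

What it does *not* model: MRI physics (bias fields, partial volume),
anatomy, or texture. Passing the phantom suite therefore shows that the
optimizer finds entropy-optimal thresholds on well-separated multimodal
histograms and that the morphology chain isolates a compact bright region
against speckle — not that the pipeline segments arbitrary clinical images.

A note on the σ → 0 limit: with zero noise the histogram degenerates to
point masses, whose within-class entropy is zero, so the entropy optimum
*groups* spikes rather than separating them (consistent with the two-spike
single-threshold case, whose optimum keeps both spikes in one class). Mode
separation is the optimal behaviour only for spread modes; the test suite
asserts separation at the default σ = 8 and documents the degenerate
grouping at σ = 0.

## Problem sizes used in the checks

The automated checks run the optimizer at the full benchmark protocol
(30 agents, 100 iterations) for single histograms, 200 runs for the
exhaustive-oracle match rate (10 mixture histograms × k ∈ {1,2} × 10
seeds), 100–300 paired seeds at 30 iterations for the DOBES-vs-BES
ablation (the paired effect is of order 5·10⁻⁴ on a fitness of ≈14, so
small seed blocks are noisy; see the reported gap alongside both means),
10 full-pipeline phantom recoveries, and 100 random 32×32 masks for the
brute-force morphology cross-checks.

## Known limitations

* Kapur's objective can place a cut in the shoulder of a heavy mode
  (≈1.5σ above the adjacent band mean on the default phantom), leaving a
  few-per-mille speckle leak in the binary mask; the chain removes it, but
  foreground selection by "brightest class" remains histogram-driven, not
  spatial.
* The exhaustive oracle is exponential in `k`; beyond `k ≈ 3` only the
  stochastic search is practical, and its optimality can then only be
  checked against itself across reruns.
* The DOBES-over-BES advantage on easy landscapes is small and emerges
  reliably only over hundreds of paired seeds.
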