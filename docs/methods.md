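# Methods

## Problem

Multilevel thresholding partitions the gray range of an 8-bit image with
`Th` cut points `T_1 < … < T_Th` into `Th + 1` intensity classes.  Otsu's
criterion chooses the cut points that maximise the between-class variance

    sigma_B^2(T) = sum_k  w_k (mu_k - mu_I)^2 ,

where `w_k = sum_{i in class k} p_i` and `mu_k = sum_{i in class k} i p_i / w_k`
are the probability mass and mean gray level of class `k`, `p_i = n_i / N`
the normalised histogram, and `mu_I = sum_i i p_i` the global mean.  The
class rule is half-open throughout the package: pixel `g` belongs to class
`k` iff `T_k <= g < T_{k+1}` with sentinels `T_0 = 0` and `T_{Th+1} = L`
(`L = 256`).  The algebraically equivalent second-moment form
`sum_k w_k mu_k^2` differs from `sigma_B^2` by the constant `mu_I^2` and is
provided for cross-checking; both share the same argmax.

Exhaustive search over threshold tuples is exponential in `Th`, so for
`Th >= 3` the maximisation is handed to a stochastic swarm optimizer over
the continuous box `[0, L-1]^Th`; positions are decoded to integer
thresholds at evaluation time (round, clamp to `[1, L-1]`, sort, bump
duplicates to the next free integer, cascading back from `L-1` on
overflow).  Keeping the agents continuous keeps the optimizer generic; the
decode step makes the objective piecewise constant on unit cells.

## Optimizers

**Baseline COOT.**  `N` agents (default 30) are initialised uniformly in
the box; after evaluation they are sorted best-first and the first
`NL = ceil(0.1 N)` become leaders, the rest followers.  Per iteration
`t = 1 … Imax` with damping `B = 1 - t / Imax`:

* each follower, in index order, either moves toward its leader
  (`L + 2 R2 cos(2 pi R3)(L - x)`, probability `p_follow = 0.5`; follower
  `j` is assigned leader `1 + (j mod NL)`), performs a chain move to the
  midpoint of itself and the previously updated agent (probability
  `p_chain = 0.5` of the remainder), or moves toward a fresh uniform random
  point damped by `B R1`;
* each leader then orbits the elitist global best:
  `B R4 cos(2 pi R3)(gBest - L) ± gBest`, the sign chosen by `R5 < 0.5`.

All positions are clamped to the nearest bound after every update, and
`gBest` is updated after every objective evaluation (elitism), so the
per-iteration best-so-far trace is monotone by construction.  `R1…R7` are
drawn from a single seeded `numpy` Generator in a fixed order (per
follower: decision draw, then the operator's own draws; per leader: `R3`,
`R4`, `R5`), which makes runs bit-reproducible.

**ICOOT.**  After the COOT body, two greedy refinement passes:

1. *Lévy flight* — with probability `p_levy = 0.5` per agent, propose
   `x + alpha * step` where `step = 0.01 R6 sigma(beta) / |R7|^(1/beta)`
   (Mantegna's method, `R6, R7` standard normal per dimension,
   `beta = 1.5`, `alpha = 1`), and keep the fitter of the pair.  A literal
   multiplicative mode (`x ⊙ alpha·step`) exists behind a flag but
   annihilates positions when the step is small, so the additive walk is
   the default.
2. *Quasi-opposition* — with probability `jumping_rate = 0.3` per
   iteration, every agent is paired with a uniform draw between the box
   centre `c = (ub + lb)/2` and its mirror `x_obl = ub + lb - x`
   (order-normalised), again keeping the fitter.

Both passes draw nothing at all when their probability is zero, so ICOOT
with `p_levy = jumping_rate = 0` reproduces the baseline COOT trajectory
bit for bit at the same seed — a deliberately testable reduction.

Greedy (keep-fitter) replacement is used for both passes; the gating of the
quasi-opposition pass by a jumping rate, the per-dimension `R1`, the
leaders-first agent ordering, and the 1-based iteration counter inside `B`
are implementation choices where the published description of the scheme is
loose; each is exposed in `OptimizerConfig` so alternative schedules can be
tried.

## Quality metrics

Segmentations are rendered by replacing each pixel with its class's mean
intensity (rounded; an empty class falls back to its interval midpoint),
with an interval-midpoint mode for sensitivity checks, and scored against
the original image:

* **RMSE / PSNR** — `PSNR = 20 log10(255 / RMSE)` dB; identical images
  yield an explicit `+inf` sentinel (serialised as the string `"inf"`),
  never a cap.
* **SSIM** — by default the global-statistics form: one
  luminance/contrast/covariance comparison over whole-image moments with
  `C1 = 6.5025`, `C2 = 58.52252` (i.e. `K1 = 0.01`, `K2 = 0.03` at dynamic
  range 255).  Variances and the covariance share one arithmetic path so
  `SSIM(I, I) = 1` holds exactly in floating point.  An 11×11
  Gaussian-window mean-SSIM mode (scikit-image) is available for
  comparability with the wider literature.
* **FSIM** — pointwise similarity of phase-congruency maps
  (`S_PC`, constant `T1 = 0.85`) and gradient-magnitude maps
  (`S_G`, constant `T2 = 160`), pooled with weights
  `PC_m = max(PC_1, PC_2)`.  Gradients use the Scharr/16 kernels, the
  normalisation under which `T2 = 160` was calibrated for 0–255 images.
  Phase congruency uses a log-Gabor bank (4 scales from wavelength 6 at
  multiplier 2, 4 orientations, `sigma_onf = 0.55`), the
  energy-over-amplitude formulation with a Rayleigh noise floor estimated
  from the smallest-scale amplitudes (`k = 2` standard deviations).  Two
  different featureless images (both phase-congruency maps ~0) have no
  defined FSIM; the function raises, and the aggregate report records
  `fsim = null` instead.  Published FSIM figures depend on unstated
  implementation constants, so cross-paper FSIM values are comparable only
  in trend, not bit-for-bit.

## Synthetic fixtures

`synth_multimodal_image` emulates the multimodal histograms of the natural
and CT benchmark images this method is usually demonstrated on: a Gaussian
mixture of 2–6 modes rendered as contiguous horizontal bands (band heights
proportional to mode weights) with per-pixel noise, so segmentations are
visually checkable.  The default is three well-separated modes at
60/128/200 gray levels, sd 8, equal weights, 128×128 pixels, seed 0 —
chosen once as a realistic stand-in for a clean trimodal subject.  What it
does **not** emulate: spatial texture, gradients and correlated noise of
real photographs, so passing tests demonstrate correctness of the
optimisation and scoring machinery, not segmentation quality on natural
images.  `synth_two_delta_image` (half pixels at `low`, half at `high`;
odd pixel counts favour the top half) has a closed-form histogram and a
closed-form bilevel optimum `(high - low)^2 / 4`, making it an exact
oracle fixture.  Analytic sphere/rastrigin/rosenbrock functions with known
minima stand in for external benchmark suites when validating the
optimizers.

## Numerical choices

* Cumulative sums of `p_i` and `i p_i` are precomputed per histogram, so
  one objective evaluation is O(Th).
* Empty classes contribute zero variance (`mu_k` set to 0 with `w_k = 0`),
  the continuous limit of the criterion; no penalty is applied.
* The exhaustive oracle enumerates threshold tuples in lexicographic order
  (vectorised in 65k-tuple chunks) and returns the lexicographically
  smallest optimum; the stochastic optimizer is compared on fitness, not on
  thresholds, because optima are frequently plateaus.
* Boundary handling is clamp-to-nearest-bound; Lévy denominators equal to
  zero are resampled.
* Color inputs are converted by the standard luma transform; optional
  resizing is bilinear with anti-aliasing before histogramming.

## Validation set-up and problem sizes

The test suite and `scripts/acceptance.py` run entirely on the generators
above: the objective is checked against a direct partition-variance
computation on 200 random 256-bin histograms; ICOOT (30 agents × 200
iterations, 20 seeds) is required to hit the exhaustive optimum for
`Th ∈ {1, 2}` on the two-delta and default three-mode fixtures in ≥ 95% of
runs; ICOOT and COOT are compared at a matched 30 × 300 budget over 20
seeds (median Otsu fitness at `Th ∈ {3, 4, 5}`, mean sphere dim-10
minimum); and the CLI pipeline is re-run to byte identity.  These sizes
were chosen so the whole validation runs on a laptop-class single core in
a few minutes while leaving the comparisons statistically stable.  At
`Th = 5` on the three-mode fixture the objective is nearly saturated
(medians of the two algorithms differ by ~1e-3 of a unit on a value of
~3339), so the ICOOT-vs-COOT ordering there is a near-tie that can invert
on other fixture instances; on the default fixture it holds.

## Known limitations

* FSIM reproduces the standard structure but, like every FSIM
  implementation, its absolute values depend on the phase-congruency
  parameterisation; compare values only within one implementation.
* The optimizer loop is pure Python/NumPy per agent; it is fast enough for
  the intended histogram objectives (thousands of evaluations per second)
  but is not a vectorised population implementation.
* No ground-truth-mask evaluation, 2-D histograms, or entropy-based
  objectives (Kapur/Renyi/Tsallis); the criterion is Otsu's between-class
  variance only.
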