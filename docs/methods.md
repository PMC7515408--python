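# Methods

## Problem setting

Image fusion merges two co-registered single-channel images — a
multi-focus pair (complementary in-focus regions of one scene) or a
multi-modal pair (e.g., CT bone detail vs. MR soft tissue) — into one
image that should retain the salient content of both. Judging fused
output is hard because no ground-truth "ideal" fusion exists in practice;
`arifuse` implements *no-reference* quality metrics that score a fused
image F from F and its sources A, B alone.

## Probability model

All information-theoretic metrics are plug-in estimators on gray-level
histograms. An image is ingested as integers in `[0, 2^depth − 1]`
(default depth 8; color → BT.601 luminance; higher depths linearly
rescaled). Marginal distributions use plain normalised counting over a
uniform binning of that range (default 256 bins, i.e. one bin per 8-bit
level); the joint distribution of a pair counts co-located gray-level
pairs. No smoothing, kernel estimation or partial-volume interpolation is
applied — marginalising the joint reproduces the marginals exactly, which
several invariants rely on.

Plug-in MI estimators carry a positive independence bias of roughly
(occupied rows)(occupied cols)/(2·N·ln 2) bits for N pixels. At 256 bins
and desk-scale images this is a few tenths of a bit; tests that assert
"independent images score ≈ 0" therefore either quantise the noise to few
levels or use bias-aware bounds. This is a property of histogram MI
estimation itself, shared by every metric in this family.

## The Arimoto metric

The Arimoto entropy of order α > 0, α ≠ 1,

    A_α(p) = α/(α−1) · [1 − (Σ_i p_i^α)^(1/α)],

is a one-parameter generalisation of Shannon entropy (recovered in nats
as α → 1): nonnegative, concave, permutation-symmetric, maximised by the
uniform distribution with value α/(α−1)[1 − N^((1−α)/α)], and
pseudo-additive over independent variables,
A_α(X,Y) = A_α(X) + A_α(Y) − ((α−1)/α)A_α(X)A_α(Y).

The associated divergence is implemented as

    D_α(p‖q) = α/(1−α) · [1 − (Σ_i p_i^α q_i^(1−α))^(1/α)].

The exponent pair (α, 1−α) is deliberate: the variant with q^(α−1) seen
in some write-ups fails D(p‖p) = 0, can go negative for α > 1, and does
not reduce to KL as α → 1; it remains available behind an `as_printed`
flag for auditing. Orders within 1e−6 of 1 route to the Shannon-limit
code path rather than evaluating at the removable singularity.

Arimoto mutual information is D_α(joint ‖ product of marginals) over the
nonzero support of the joint, and the fusion metric is

    M_α(A, B; F) = I_α(F, A) + I_α(F, B),

the total Arimoto information the fusion carries about its sources. The
default order is α = 1.5: in order sweeps (the 10-point grid 0.2…2.0 is
built in) small orders compress the spread between mid-quality fusions
while orders near 2 can invert mid-ranks; 1.5 separates the synthetic
quality ladder most cleanly. An entropy-difference form of Arimoto
dependence (joint-entropy deficit under pseudo-additivity) is exposed as
a diagnostic; it coincides with the divergence form only at α → 1, and
the metric is defined by the divergence form.

All Arimoto/Tsallis values are log-free natural-unit quantities;
Shannon-family metrics default to bits. `MetricResult.units` records the
scale and the two per-source components, whose sum equals the metric
value exactly for the additive metrics.

## Comparison metrics

- **Shannon MI**: I(F,A) + I(F,B) in bits.
- **Normalised MI**: 2[I(F,A)/(H(F)+H(A)) + I(F,B)/(H(F)+H(B))] ∈ [0, 2].
- **Tsallis MI** of order q (default q = 1.85, the convention of the
  comparison literature; configurable):
  (1/(1−q))[1 − Σ p(x,y)^q (p(x)p(y))^(1−q)].
- **Petrovic Q^AB/F**: Sobel gradient magnitude and orientation are
  compared between each source and F; relative strength and orientation
  agreement pass through the published sigmoids
  (Γ_g=0.9994, κ_g=−15, σ_g=0.5; Γ_α=0.9879, κ_α=−22, σ_α=0.8; weight
  exponent L=1), and per-pixel preservation is averaged weighted by
  source gradient magnitude. Each sigmoid is normalised by its value at
  perfect preservation so that F = A = B scores exactly 1 — without this
  the constants cap the score at ≈ 0.975, which would make the
  perfect-fusion anchor depend on arbitrary gain choices. A fully
  edgeless source pair has nothing to preserve and scores 0 by
  convention; no metric ever returns NaN.

## Fusion fixtures

The six classical algorithms provide quality-graded stimuli, not
reference reproductions: averaging; PCA weighting (principal eigenvector
of the 2×2 covariance, nonnegative weights summing to 1, with a
variance-proportional fallback when anti-correlation gives the
eigenvector mixed signs); Laplacian pyramid (4 levels, 5-tap binomial
kernel [1,4,6,4,1]/16, reflection borders, max-|coefficient| detail
selection, averaged base); contrast pyramid (ratio-of-lowpass with a +1
offset against division by zero, selection by |ratio − 1|, multiplicative
reconstruction); blockwise DCT (8×8 orthonormal blocks, AC coefficients
winner-take-all by AC variance, DC averaged, edge-replication padding);
and guided-filter two-scale fusion (31-px mean-filter base + residual
detail; saliency = Gaussian-smoothed |Laplacian|, σ=5; hard winner maps
refined by a guided filter with the source as guide — radius 31 /
ε = 10⁻³·range² for the base weights, radius 7 / ε = 10⁻⁶·range² for the
detail weights — then normalised to sum to 1 per pixel).

Selection ties (equal |coefficient|, equal |ratio−1|, equal AC variance)
average the two candidates; this keeps every method symmetric under input
swap to within the ±1 gray level of reconstruction round-off, which a
preference-for-A rule would violate at exact ties. All outputs are
clipped to the depth range. Fusing an image with itself returns it within
±1 gray level for every method (the pyramid analysis/synthesis cycles are
algebraically exact; only final rounding remains).

## Synthetic data

The generator produces the statistical structure the metrics rely on,
fully procedurally and bit-reproducibly per seed — no bundled assets, and
no anatomical or photographic realism.

- **Latent scenes** (default 256×256): random rectangles/disks/bars
  overlaid on filtered noise plus sinusoidal gratings ("mixed"; also pure
  "texture" and "shapes"), affinely stretched to span the full gray
  range. The mixed 256×256 scene populates ≥ 200 distinct levels, so
  256-bin histograms are well exercised.
- **Multi-focus pairs**: the latent scene is the ground truth; source A
  is Gaussian-blurred (default σ = 3 px, a clearly visible defocus at
  this resolution) inside a region R — left/right halves, quadrant
  checkerboard, or a smooth random mask — and B in the complement, giving
  complementary regional sharpness exactly as real multi-focus pairs do.
- **Multi-modal pairs**: monotone gamma remaps of one latent structure
  (exponent γ for A, 1/γ for B; default γ = 1.8, a visibly different
  contrast rendering) with a fraction (default 0.25) of each modality's
  area replaced by modality-exclusive smoothed noise. Defaults leave the
  pair sharing several bits of MI; exclusive_fraction = 1 with γ = 1
  degenerates to independent images.
- **Degradation ladders**: the truth blurred at strictly increasing σ,
  the quality axis for monotonicity experiments (standard rungs
  0, 0.5, 1, 2, 4, 8 px).

What passing tests on these scenes does *not* show: behaviour under
misregistration, sensor noise, nonmonotone intensity relationships
(true CT/MR is only approximately monotone-related), or photographic
texture statistics. The generator's complementary-sharpness and
shared-structure properties are the assumptions the metric family itself
makes, no more.

## Evaluation protocol

Candidates are ranked per metric by descending value (rank 1 = best);
exact ties keep input order and carry an explicit flag. Against a
reference ordering (subjective rank in real studies; here the
full-reference RMSE-to-ground-truth order, which the generator makes
available) the package reports Kendall τ and Spearman ρ. On the standard
seeds, M₁.₅ ranks {truth, GF, CP, LP, DCT, PCA, averaging, heavy blur}
identically to the RMSE oracle (τ = 1), is strictly decreasing along the
blur ladder, and scores the ground truth above the averaging fusion by a
wide margin. `scripts/acceptance.py` recomputes all of these quantities
from scratch at a given seed (256×256 scenes, 1000-draw Shannon-limit
sweeps; ~2 s total).

## Numerical choices

- Zero-probability cells are skipped in all sums (0·log 0 := 0; avoids
  0^negative); support violations in divergences return +inf with a
  warning rather than raising.
- Shannon MI clips the tiny negative round-off its nonnegative sum can
  produce; generalized quantities normalise −0.0 to +0.0.
- α ≤ 0 is rejected; |α − 1| < 1e−6 routes to Shannon-limit paths.
- Histogram bin edges follow integer arithmetic (`level·bins ÷ 2^depth`),
  so binning is exact and platform-independent.

## Limitations

- Plug-in MI bias (above) makes absolute values bin- and size-dependent;
  comparisons are meaningful within one image geometry and bin count.
- The Tsallis order used by the comparison literature's tables is not
  fixed by any of them; q is exposed rather than canonised.
- Fusion fixtures favour clarity over state-of-the-art quality; they are
  deliberately spread in quality, not tuned.
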