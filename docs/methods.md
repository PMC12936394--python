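# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Trait model and comparative machinery

All comparative methods assume Brownian motion (BM) of mean pronotal width
on a rooted, bifurcating, ultrametric dated tree (branch lengths in Ma):
tip values are multivariate normal with mean `a·1` (root state) and
covariance `σ²C`, where `C_ij` is the depth of the MRCA of tips i and j.
The trait is analysed on the raw mm scale by default; a log option exists in
the CLI (`--scale log`) because body-size analyses are sometimes run on log
size, and the choice matters only for the absolute values of λ, K and the
ancestral states, not for the machinery.

- **Independent contrasts** are computed by pruning: at each internal node
  the contrast `(x_i − x_j)/√(v_i + v_j)` with the usual branch-length
  augmentation `v_i v_j/(v_i + v_j)` passed rootward. Contrasts are linear
  in the tip values; `contrast_matrix` extracts the (n−1)×n operator W by
  pruning the identity basis, which gives the fast path for permutation
  tests and the whitening identity `W C Wᵀ = I` used as an oracle in tests.
- **Ancestral states** are GLS/kriging predictors
  `â = μ̂ + cᵀC⁻¹(x − μ̂1)` with `c` the vector of shared path lengths
  between the node and each tip, `μ̂` the GLS mean and `σ̂² = q/n` the ML
  rate (q the GLS residual quadratic form). The 95% CI uses the prediction
  variance including the uncertainty of `μ̂`:
  `σ̂²[C_aa − cᵀC⁻¹c + (1 − cᵀC⁻¹1)²/(1ᵀC⁻¹1)]`. Per-edge linear
  interpolation of states is exported as a table (no gradient plotting).
- **Pagel's λ** multiplies the off-diagonal of C. The profile log-likelihood
  (root state and rate maximized out analytically) is optimized over
  [0, λ_max] with bounded Brent at tolerance 1e-8, where λ_max is the
  positive-definiteness limit (root height over the depth of the
  tipmost internal node — typically slightly above 1 on real trees), with
  the endpoints checked explicitly because the optimum is often at a
  boundary. Significance is the χ²₁ LRT against λ = 0.
- **Blomberg's K** uses the phylogenetically corrected (GLS) mean and the
  expected MSE ratio `(tr C − n/1ᵀC⁻¹1)/(n−1)`; its permutation test
  shuffles tip labels and compares the variance of contrasts (lower =
  stronger signal), with the add-one estimator
  `p = (1 + #{perm ≤ obs})/(n_perm + 1)` so p is never exactly zero.
  Implementation agrees with R phytools `phylosig` to at least four decimals
  on shared data.

Known limitation: the ML estimator of λ is noticeably negatively biased at
intermediate signal on trees of this size — calibration runs at 70 tips show
mean `λ̂ ≈ 0.44` for a generating λ of 0.5 (while λ = 0 and λ = 1 are
recovered to within 0.01). This is a small-sample property of the estimator
itself, shared by the reference R implementation, not an implementation
artifact.

## Size-distribution null models

Species means are binned into fourteen 0.5 mm bins on [4, 11] mm
(left-closed, right-open; the upper edge closed). A replicate distribution
"qualifies" on three criteria, using the same estimator and binning as the
observed data: mean ≤ 6.15 mm, skewness g₁ ≥ 1.83 (biased moment estimator,
divisor n), and an internal gap of ≥ 2 consecutive empty bins flanked by
occupied bins on both sides.

**Random selection.** Uniform draws on the 701-point two-decimal grid
4.00, 4.01, …, 11.00 (both endpoints included), 70 per replicate, 10,000
replicates.

**Speciation model.** One lineage starts at the reconstructed ancestral size
6.67 mm. Generations are synchronous; per generation each lineage first
survives extinction (p = 0.1), then speciates (p = 0.5) into two daughters.
Each daughter draws `r ~ U[1, 1.125]` and moves by the magnitude
`(r − 1)·parent` in a random direction — i.e. becomes `parent·r` or
`parent·(2 − r)` with equal probability; a daughter landing outside
[4, 11] mm keeps the parental size (the divergence event is cancelled for
that lineage). A replicate stops at the first generation with ≥ 70 lineages
and is uniformly subsampled to exactly 70; total extinction restarts the
replicate. Scheduling details (synchronous generations, extinction before
speciation, subsampling on overshoot, restart on extinction) and the
direction rule are design choices: the direction rule in particular admits a
multiplicative alternative (`parent/r` for the smaller daughter), which
yields a visibly lower mean-criterion proportion (~0.17 vs ~0.23-0.25); the
symmetric-additive rule implemented here is the reading consistent with the
model's published behaviour.

## Co-occurrence analysis

Coordinates (signed decimal degrees, WGS84) are projected with the world
cylindrical equal-area projection on the authalic sphere (R = 6 371 007.181
m): `x = Rλ`, `y = R sin φ`. Cells are `floor(x/200 km), floor(y/200 km)` —
the grid is anchored at the projection origin, a choice the original
GIS-based gridding leaves unspecified, so absolute cell counts are
reproducible only approximately by construction. Cells with fewer than 10
records are dropped (records at identical coordinates count individually).
Per-cell extremes use the *global* species mean widths of the species
present, not within-cell specimen means. Richness ≥ 7 is pooled as "7+".
95% CIs everywhere are normal-approximation mean ± 1.96·SE.

The assemblage null is vectorized: for each k, a (reps·50, k) uniform draw;
per-square min/mean/max; summaries over all squares of all replicates.
Closed forms used for verification: E[max of k U(4,11)] = 4 + 7k/(k+1),
symmetrically for the minimum.

## Sister pairs

Pairs are tree cherries with a sympatry label supplied as data. The
normality screen before each per-pair test is the D'Agostino skewness test
at α = 0.05 (the screen used by the original analysis is unnamed; this one
is auditable in the output via the `normal_a/normal_b` flags); species with
≤ 8 measurements pass the screen by default since the transformation is
undefined there. The ratio comparison uses the pooled-variance (Student)
t-test, giving df = n_pairs − 2 (Welch optional). The contrast for a pair is
standardized by its summed pendant branch lengths,
`|C| = |w̄ₐ − w̄ᵦ|/√(vₐ + vᵦ)` with `vₐ + vᵦ = 2 ×` pair age on an
ultrametric tree; the signed version (first-listed minus second-listed
species) feeds the one-sample directional-bias test. The ANCOVA is OLS of
|C| on time, status and their interaction; per-group slopes and p-values
come from the fitted coefficients and the linear-combination t-test.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the analyses assume, at the scale
of the real specimen dataset: 70 species; species means spanning
4.15–10.97 mm, right-skewed, with an empty (8, 9) mm interval and a ~7%
"giant" fraction above it; ~170 records per species (≈ 12,000 records);
within-species widths Normal(mean, CV 7%) reflected into [4, 11] mm
(reflection, not truncation, to avoid probability mass piling at the
bounds); range centroids drawn from a northern-temperate mixture (85% from
N(42.5°, 8°) latitude, the rest from a broad tail) around three continental
longitude clusters, with records scattered N(centroid, 2.5°); a pure-birth
dated tree (birth rate 0.05/Ma, giving a crown age near 10² Ma at 70 tips);
and sympatry defined as centroid distance < 500 km, matching the 200-km grid
scale downstream, with cherry partners placed adjacently with probability
0.42 so both sympatry classes occur.

Phylogenetic signal and the skewed, gapped marginal cannot both be exact:
tip values are BM on the λ-transformed tree, then rank-matched onto the
target marginal. The monotone reassignment preserves ordering and hence
most of the signal (λ̂ ≈ 0.85, K ≈ 0.4 on default datasets) but breaks
exact BM; estimator-calibration tests therefore use `simulate_tip_sizes`
directly, and dataset-level tests treat signal qualitatively.

The displacement control adds `boost × pair age` to the size difference of
sympatric cherries (clipped to the bounds). Calibration at 50 fixed seeds:
the ANCOVA interaction false-positive rate at boost 0 is ~4%, and detection
power at boost 0.2 mm/Ma is ~84%; power saturates at larger boosts because
boundary clipping caps the attainable divergence.

Passing tests on synthetic data show that the pipeline recovers structure it
is built to detect under its own assumptions. They do not address
collection bias (beyond the minimum-records filter), georeferencing error,
taxonomic noise, within-species geographic size variation, or non-BM trait
evolution — all present in real specimen data.

## Problem sizes and tolerances

Null models run at their study settings (10,000 / 1000 / 1000 replicates) in
seconds. Calibration suites use 100–200 replicates at 70 tips (λ, K) and 50
seeds (ANCOVA power), with Monte-Carlo-aware tolerances stated in each test.
λ optimization tolerance 1e-8; GLS oracles asserted at 1e-8; ultrametricity
checked at 1e-6 relative to root height; polytomies are resolved into
zero-length bifurcations (stable under input order) with a warning.
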