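# nicrosize

Macroevolutionary analysis of body size in burying beetles (genus
*Nicrophorus*), using mean pronotal width (mm) as the body-size proxy. The
package asks, at the scale of the whole genus, whether the distribution of
species sizes, their arrangement on the dated phylogeny, and their geographic
co-occurrence are consistent with neutral expectations — or bear the marks of
ecological character displacement, where co-occurring competitors diverge in
size.

It is written for comparative biologists who want the full analysis chain as
tested, scriptable components: occurrence-table I/O with literature-width
imputation, size-distribution statistics with two bespoke null-model
simulators, phylogenetic-signal estimation, equal-area richness gridding with
an assemblage null, sister-pair divergence tests, and a synthetic-data
generator that emulates the structure of the underlying specimen dataset so
every stage is testable without any downloads.

## The statistics at the core

**Size-distribution nulls.** Species mean widths `w̄ₛ` are binned into a
0.5 mm histogram on [4, 11] mm and scored for (i) mean `≤ 6.15` mm, (ii)
sample skewness `g₁ = m₃/m₂^{3/2} ≥ 1.83` (significance by the D'Agostino
normalizing transformation), and (iii) an internal two-bin (1 mm) gap. Two
generative nulls supply the reference distribution: uniform two-decimal
draws on [4.00, 11.00], and a speciation model in which lineages branch
(speciation 0.5, extinction 0.1 per lineage per generation) from an ancestor
at 6.67 mm, each daughter perturbed by a ratio `r ~ U[1, 1.125]` applied as
`×r` or `×(2−r)`, bounded on [4, 11] by cancelling out-of-bounds moves, until
70 species exist.

**Phylogenetic signal.** Under Brownian motion, tip values are multivariate
normal with covariance `σ²C`, `C_ij` the shared path length of tips *i*, *j*.
Pagel's λ scales the off-diagonal of `C`; `λ̂` maximizes the profile
likelihood and is tested by LRT against λ = 0. Blomberg's
`K = (MSE₀/MSE) / E[MSE₀/MSE]_BM` uses the GLS mean and a tip-shuffling
permutation test on the variance of independent contrasts. Ancestral states
are the GLS/kriging predictors with 95% CIs.

**Co-occurrence.** Records are projected with a cylindrical equal-area
projection and binned into 200 km × 200 km (40,000 km²) cells; cells with
< 10 records are dropped; per-cell min/mean/max of the species' global mean
widths are compared across richness classes 1..7+ by one-way ANOVA. The
random-assemblage null draws k uniform(4, 11) sizes per square (50 squares
per k, 1000 replicates); the expected maximum is `4 + 7·k/(k+1)`, so the
null divergence of the maximum saturates at 2.625 mm by k = 7.

**Sister pairs.** Cherries of the dated tree, labelled sympatric or not.
Per-pair Welch *t* (or Wilcoxon when a normality screen fails) with
Bonferroni correction; larger/smaller size-ratio comparison between sympatry
classes (pooled-variance *t*); and an ANCOVA of the absolute standardized
contrast `|C| = |w̄ₐ − w̄ᵦ|/√(vₐ + vᵦ)` on divergence time and sympatry with
interaction.

## Worked example

Generate a synthetic study and run the stages:

```
$ nicrosize simulate --seed 1 --out demo
wrote 11900 records, 70-tip tree, 23 pairs to demo/

$ nicrosize distribution --occurrences demo/occurrences.csv
n_species=70 mean=5.547 mm
histogram=[11, 17, 15, 13, 6, 3, 0, 0, 0, 0, 3, 0, 2, 0]
skew=2.1266 z=5.4411 p=5.29e-08
internal_gap=True bins=(6, 9)

$ nicrosize nullmodels --model speciation --reps 1000 --seed 1
criterion  proportion  reps
     mean       0.256  1000
     skew       0.000  1000
      gap       0.035  1000
```

The synthetic genus is right-skewed (skew 2.13, z = 5.44: far more small and
mid-sized species than large ones) with an internal gap in the histogram —
the structure the generator imposes. The speciation null shows how often
random bounded divergence alone produces a mean that low (0.256), a skew
that strong (0.000) or an internal 1 mm gap (0.035): strong skew is
essentially unreachable by neutral divergence, while a low mean and an
occasional gap are not.

```
$ nicrosize sisters --occurrences demo/occurrences.csv \
      --pairs demo/sister_pairs.csv --tree demo/tree.nwk
17/23 pairs significant at p < 0.002174
mean ratio sympatric=1.091 non-sympatric=1.068 t=0.67 df=21 p=0.5112
ANCOVA F=0.101 p=0.9583 adjR2=-0.140 interaction_p=0.6221 ...
```

With the generator's displacement boost at its default of zero, most sister
pairs differ in size (within-species spread is small relative to
between-species differences) but sympatric and non-sympatric pairs are
statistically indistinguishable — the correct null behaviour. Raising
`displacement_boost` in `SyntheticConfig` injects a sympatry-by-time
interaction that the ANCOVA then recovers.

`nicrosize all --synthetic --seed 1 --out results` runs every stage and
writes `results/results.json` with each statistic tagged by stage and seed.

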