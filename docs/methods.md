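# Methods

This document describes the statistical model, the estimation and
model-selection procedure, the forward simulator, the numerical choices
made in the implementation, and its known limitations.

## 1. Admixture models and the ALD decay curve

Two source populations (1 and 2) mix to form an admixed population whose
final ancestry fractions are `m1` (source 1) and `m2 = 1 − m1`. An
admixture history is a *migration schedule*: for each generation `g`
(counted backwards from sampling, `g = 1` the most recent), the fraction of
the population replaced by migrants from each source. Seven model classes
are supported:

| class  | schedule                                                            |
|--------|---------------------------------------------------------------------|
| HI     | a single pulse at generation `n` (hybrid isolation)                 |
| GA     | founding pulse at `n`, then equal constant inflow from both sources every generation `n−1 … 1` |
| CGF1   | founded as source 1 at `n`; constant one-way inflow from source 2 each generation |
| CGF2   | as CGF1 with the source roles swapped                               |
| GA-I   | GA inflow restricted to a window `[G_end, G_start]`, no migration after `G_end` |
| CGF1-I | CGF1 inflow restricted to `[G_end, G_start]`                        |
| CGF2-I | CGF2 inflow restricted to `[G_end, G_start]`                        |

Classic models are the one-parameter special cases of their interval
variants with `G_end = 1`; `HI` is any interval model with
`G_end = G_start`. Per-generation inflow rates are solved exactly so the
final ancestry equals `m1` (for CGF, `alpha = 1 − m1^{1/n}`, with the
founding generation itself counted as an inflow event; this makes the
one-generation CGF degenerate to HI exactly).

Each ancestry-switch boundary created `l` generations before sampling
decays under recombination as `exp(−l d)` at genetic distance `d` Morgans.
The admixture-induced weighted LD (ALD) curve is therefore a mixture

```
z(d) = theta0 + theta1 * sum_{l=1..J} C_model(l) * exp(-l d)
```

where the coefficient vector `C_model` follows from the migration schedule
by a forward recursion over generations (implemented in `camix.models`;
closed forms for the HI spike, the uniform GA window and the geometric
CGF window are used in hot paths and tested for exact equality with the
recursion). `theta0` absorbs residual background LD; `theta1` the overall
amplitude. `J` caps the modelled look-back (library default 500).

## 2. Weighted LD computation

For admixed panel `X` and source panels `Y1`, `Y2`, each site gets the
weight `w_s = f1_s − f2_s` (source allele-frequency difference). For every
pair of sites `(s, t)` on the same chromosome, the pairwise covariance of
the admixed alleles is accumulated into bins of genetic distance
(`BinSpec`: 0.005–0.3 M, bin width 2e-4 M by default; pairs closer than
0.5 cM are excluded because source background LD dominates there), weighted
by `w_s w_t`:

```
a(d) = sum_{|d_st - d| < h} cov(X_s, X_t) w_s w_t / sum w_s w_t
```

The reported curve is the combination `z(d) = a0 − m1·a1 − m2·a2`, where
`a0` uses the admixed covariance and `a1`, `a2` use the covariances
computed within each source panel — this subtracts source background LD in
expectation. Covariances use complete pairs only (minimum 4) and are halved
for diploid-coded input. A leave-one-chromosome-out jackknife produces one
curve per held-out chromosome alongside the full-genome curve
(`LDCurveSet`).

## 3. Fitting

Given a curve `z(d)` on bin midpoints and a coefficient vector, the fit is
ordinary least squares in `(theta0, theta1)` — linear because `C` is fixed.

- **Classic models** (one parameter `n`): `scan_onset` evaluates every
  `n = 1..J`. The candidate design columns for all `n` are built as one
  matrix product, so the scan is a single vectorized pass.
- **Interval models** (two parameters `G_end ≤ G_start`): `interval_search`
  runs in two phases. Phase 1 is a greedy shrink from `(1, J)` that
  repeatedly takes the better of the two proposals `(E+1, S)` and
  `(E, S−1)` while either improves the RSS. Phase 2 is an iterated local
  polish: all `(E', S')` within Chebyshev distance 8 of the current point
  are evaluated and the best strict improvement is taken until none exists.
  The polish is needed because the pure greedy can stall on genuine local
  minima a few steps wide of the optimum even on noiseless curves; with it,
  the search matches exhaustive enumeration on all validation cases
  (35 noiseless curves, J ≤ 120).
- **Reference fit**: a non-negative least-squares fit of *all* exponentials
  `exp(-l d)`, `l = 1..J`, with a free offset. This is the best any model
  in the family could do and lower-bounds every model's RSS. The free
  offset is profiled out exactly (column-centering + one NNLS + offset
  back-solve), which is the fixed point of the alternating
  offset/NNLS scheme.

## 4. Model selection

For a candidate set of models (typically `HI, GA-I, CGF1-I, CGF2-I` or the
classic quartet):

1. Fit every model to the full curve and to each of the `N` jackknife
   curves (same search settings).
2. Form Tukey pseudo-values of the log mean-squared error:
   `p_q = N * log msE_full − (N−1) * log msE_drop(q)`. Exact-zero msE
   (noiseless fixtures) is substituted by log machine-epsilon and flagged.
3. For every model pair, a two-sided Wilcoxon signed-rank test on the `N`
   paired pseudo-values (exact null distribution when there are no ties
   among the absolute differences, no zero differences, and `N ≤ 25`;
   normal approximation otherwise; all-zero differences give `p = 1`).
   Holm step-down adjustment across the pairs. With `N = 10` chromosomes
   the exact two-sided floor is `2/2^10`, i.e. 0.00195 raw.
4. **Decision rule** (`select_best`): if HI's median pseudo-value is not
   significantly *worse* (adjusted `p < 0.05` *and* median higher) than the
   best median, HI is selected outright — the simplest model wins unless
   rejected. Otherwise the best-median model and every model not
   significantly worse than it form the best set; a singleton is a
   determination, a larger set is reported as *undetermined*.
5. **Diagnostics** per model: msE of the full-curve fit with the
   low-quality flag at `msE > 1e-5`, and the quasi-F ratio of the model RSS
   to the reference (NNLS) RSS with rejection at `quasi-F > 1.5`. Both
   RSS zero defines quasi-F = 1; reference-only zero gives +inf.
6. Admixture-time summaries: HI reports the rounded mean of the jackknife
   point estimates; interval models report the generation range covered by
   a majority of the jackknife intervals (falling back to the full-curve
   interval, flagged, when no majority exists).

## 5. Forward simulator

`camix.simulate` evolves a population of haplotypes per chromosome under a
migration schedule. Each generation, every haplotype is either a new
migrant (pure-source ancestry tract) or is assembled from the current
population: breakpoints are Poisson with rate 1 per Morgan and each
inter-breakpoint segment is copied from an independently drawn haplotype.
Independent segment parents give exactly the `exp(-d)` per-generation
survival the exponential theory assumes (two alternating parents would
give `(1 + exp(-2d))/2` instead). Migrant status is drawn once per
individual per generation and shared across chromosomes, preserving the
cross-chromosome correlation the jackknife test relies on; breakpoints and
parent picks are independent per chromosome.

Two equivalent engines exist: a tract engine (explicit breakpoint lists,
used for BED output and as the oracle) and a marker engine that propagates
ancestry labels only at the SNP positions in bit-packed arrays (numba
kernel with a pure-numpy fallback). Both consume the identical RNG stream
and produce bit-identical panels; the marker engine is ~40x faster and is
what the study driver uses.

Genotypes are painted onto ancestry: per-site source allele frequencies are
drawn from a Balding–Nichols model around a shared ancestral frequency
(divergence `F = 0.15` by default), source panels are Bernoulli samples
from their frequencies, and admixed alleles are Bernoulli draws from the
frequency of the local ancestry's source. This synthetic-panel stand-in
(rather than copying real dense haplotypes) bounds the attainable ALD
signal-to-noise; see Limitations.

## 6. Model-determination study

`camix.study` runs the scripted experiment behind `scripts/acceptance.py`:
10 replicates each of HI(50), HI(100), GA(1–50), GA(1–100), CGF1(1–50),
CGF1(1–100), GA-I(30–100), GA-I(70–100), CGF1-I(30–100), CGF1-I(70–100),
all with final `m1 = 0.3`. Frozen settings: population 5000, ten 0.3-Morgan
chromosomes, 1000 sites per chromosome, 1000 sampled admixed haplotypes,
500 per source panel, divergence 0.15, ALD bin width 0.001 M, `J = 200`.
Each replicate is classified under the classic cores (HI, GA, CGF1, CGF2)
and the interval cores (HI, GA-I, CGF1-I, CGF2-I); a call is *correct* when
the selected class matches the truth (CGF variants collapse to their class;
GA is matched by GA-I under interval cores), *undetermined* when the best
set has several classes including the truth, *wrong* otherwise. The four
headline rates are: t1/t3 = % correct on the six classic truths under
classic/interval cores; t2/t4 = % wrong on the four interval truths under
classic/interval cores. Runtime is ~8 s per replicate, ~13 min for the full
study on one CPU. Seeds derive from a single `SeedSequence` per
(scenario, replicate, stage), so replicates are reproducible and
independent of execution order.

## 7. Numerical choices

- All-finite covariance accumulation uses a single Gram-matrix product;
  the slower NaN-aware complete-case path engages only when data are
  missing.
- Degenerate designs (zero-range regressor) are flagged and fit
  offset-only rather than raising.
- `interval_search` polish radius 8 was chosen from the observed greedy
  stall distances (≤ 6) with margin; it costs ~300 extra 2-parameter OLS
  solves per search.
- Exact Wilcoxon p-values come from `scipy.stats.wilcoxon`
  (`zero_method="wilcox"`); the test suite checks them against a
  brute-force enumeration of all `2^N` sign assignments.

## 8. Limitations

- **Panel density bounds model resolution.** With ~1000 synthetic sites
  per 0.3-Morgan chromosome, the measured ALD curve noise floor is
  msE ≈ 8e-11 at the study settings, while the *structural* misfit that
  separates the continuous models from each other (e.g. the best CGF1 fit
  to a true noiseless GA(1–50) curve) is 1–2 orders of magnitude smaller
  (msE ≈ 5e-12, and ≈ 5e-13 for CGF2). Consequently HI truths are
  identified reliably and interval truths collapse to HI essentially
  always, but GA/CGF truths frequently come out undetermined or as HI, and
  interval truths are almost never resolved as their own class even under
  interval cores. Reproducing the published continuous-model accuracy
  requires dense real source haplotypes (tens of thousands of sites per
  chromosome), which is outside this desk-scale generator's scope. Raising
  density to 2000–3000 sites per chromosome removes the HI collapse but
  leaves the GA/CGF family mutually undetermined.
- The simulator models a constant population size, uniform recombination
  (no hotspots or interference), sites in linkage equilibrium within
  sources, and no genotyping error or phasing noise.
- The decision rule tests medians of log-msE pseudo-values; with `N = 10`
  chromosomes the resolution of the signed-rank test is coarse (raw
  two-sided p-floor 0.00195), so close models are reported undetermined
  rather than force-ranked.
- Interval summaries use majority coverage across jackknives, which can be
  empty for highly unstable fits; the fallback is flagged in the output.
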