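# Methods

This note records the models implemented, the parameter conventions, the
design choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Units and conventions

* All site and window coordinates are **1-based inclusive**, relative to the
  analysed fragment.
* IUPAC ambiguity codes and `N` are **missing data**: excluded from site
  classification and handled by pairwise deletion in all distance and
  diversity computations. Haplotype collapsing is strict (literal identity)
  by default; a missing-tolerant mode merges sequences that differ only at
  missing positions.
* θ is the population mutation parameter **2 N_ef μ** of a maternally
  inherited haploid locus, per fragment per generation unless explicitly
  per site. One coalescent unit is N_ef generations.
* Substitution rates are per site per year; 1 % per Ma = 1e-8 /site/year.
  Defaults used by the pipeline: rate ≈ 1 %/Ma, fossil calibration
  T = 4.6 Ma (midpoint of a 4–5.2 Ma interval), generation time
  g = 9.2 years. All three are configurable.

## Diversity statistics

Haplotype diversity h = n(1 − Σp_i²)/(n−1) with the large-sample gene
diversity variance (Nei 1987 eq. 8.12). Nucleotide diversity π is the mean
over pairs of (differences / jointly non-missing sites); its SD uses the
no-recombination total variance (Nei 1987 eq. 10.7), the convention of the
standard single-locus tools. The printed SDs of the original analyses are
not reproducible without knowing the exact estimator each tool used, so SDs
are reported but not treated as checkable quantities.

## Neutrality tests

* **Tajima's D** uses the standard a1..e2 coefficient chain with S
  segregating sites.
* **Fu & Li's D\*, F\*** are the no-outgroup (starred) variants with the
  corrected published coefficients (the originals contain known errata).
  η counts minimal mutations (states − 1 per site), η_s counts mutations
  observed once (minor-allele-count-1 states, capped at states − 1 per
  site — a triallelic site with one singleton state contributes one
  singleton mutation).
* **Fu's F_S** computes S′ = P(K ≥ K_obs | θ = k̂) from the Ewens sampling
  formula, with |S(n,k)| by the unsigned-Stirling recursion carried in log
  space (exact for all practical n; validated against exhaustive
  permutation cycle counting for n ≤ 7). θ̂ is the mean pairwise difference
  count per fragment; K_obs the strict haplotype count. K_obs = 1 gives
  S′ = 1 and F_S = +∞, reported as a sentinel (no test possible).
* **R2** = sqrt(mean_i (U_i − k/2)²)/S with U_i the singleton mutations
  carried by sequence i.
* **p-values** are empirical, from constant-size Kingman nulls. Default
  conditioning is fixed-S: exactly S mutations placed on branches with
  probability proportional to branch length (a θ-conditioned Poisson mode
  is available; the legacy tools differ among themselves in conditioning
  and tail conventions, so their p-values are not exactly reproducible).
  The lower tail is the
  growth-sensitive direction for all five statistics and is the default.
  For F_S, a nominal α = 0.02 on this p-value corresponds to a 5%
  significance level.

## Mismatch distribution and sudden expansion

A pair of lineages coalescing x mutational-time units ago (τ-scale: 2ut)
differs at Poisson(x) sites. Under sudden expansion the coalescence-time
density mixes a pre-expansion equilibrium epoch (θ₀) shifted by τ with a
post-expansion epoch (θ₁), giving

F_i = Fhat_i(θ₁)·P(i+1, τ(θ₁+1)/θ₁) + e^{−τ/θ₁} Σ_{j≤i} Pois(i−j; τ)·Fhat_j(θ₀)

with Fhat_j(θ) = θ^j/(θ+1)^{j+1} and P the regularized lower incomplete
gamma. The default fit takes θ₁ = ∞ (two free parameters, the common
least-squares practice; the first term vanishes and the weight is 1); a
three-parameter mode frees θ₁. Tail mass beyond the largest observed class
is folded into the last class so expectations always sum to 1.

Fitting minimises the SSD between observed and expected relative
frequencies: grid search (τ ∈ [0, 25] step 0.25, θ₀ ∈ [0, 10] step 0.25)
followed by Nelder–Mead refinement (SSD tolerance 1e-8); the grid optimum is
kept if polishing does not improve it. The parametric bootstrap simulates
the fitted θ₁ = ∞ model exactly — no coalescence before τ, Kingman with
pairwise rate 1/θ₀ afterwards, Poisson(length/2) mutations per branch —
and refits each replicate on the grid only (no polish), trading a quarter
grid-step of τ resolution for a large constant-factor speedup. p_SSD is the
fraction of replicates with refit SSD ≥ observed; the raggedness p-value
and the τ percentile CI come from the same ensemble. A fit is flagged
non-converged when the optimizer fails or τ̂ hits the grid ceiling (the
analysis this mirrors also reports non-convergence on sparse data).

**Raggedness**: r = Σ(x_i − x_{i−1})² over relative frequencies with a zero
class appended at *both* ends. The boundary convention matters only for
degenerate distributions (all mass at one class ⇒ r = 2); it is fixed here
once and used consistently, including in bootstrap p-values.

**τ to years**: t = τ/(2 L·rate); CI bounds map through the same monotone
transform.

## Rate calibration

d_xy is the mean model-corrected distance (JC69, K2P, or TN93 closed forms;
TN93 base frequencies averaged over the pair at jointly non-missing sites)
over all between-group sequence pairs — over sequences, not haplotypes, by
default (a haplotype-weighted mode is the alternative reading; both are
provided since the source analyses do not state which they used). The SE is
the SD of d_xy over site-bootstrap replicates. Saturated pairs (non-positive
logarithm argument) are flagged, not silently dropped from the flag.

μ = d_xy/(2T). Two uncertainty layers: CI_fixed_T propagates
d_xy ± 1.96·SE at fixed T; CI_full additionally spans the fossil interval
[T_lo, T_hi], pairing extremes conservatively (lower d with upper T and
vice versa) — the only combination rule consistent with the reference
intervals this reproduces.

Tajima's relative rate test counts sites where each lineage is the odd one
out against the outgroup; χ² = (m1−m2)²/(m1+m2), 1 df; p = 1 when no
informative sites exist.

## TMRCA

**Thomson's estimator** T̂ = Σ i·ξ_i/(n μ_frag) needs a polarized,
infinite-sites-consistent unfolded SFS. The four-gamete filter first removes
sites with > 2 states, then iteratively removes, from each violating pair,
the site with the rarer minor allele (ties → higher position) until no pair
shows all four gametes; it reports which haplotypes merge as a consequence.
Ancestral states come from outgroup consensus (both outgroups agree and the
state occurs in the ingroup); conflicted sites fall back to the ingroup
major allele and are flagged. With the default deep calibrations
(4.6/9.5 Ma) the outgroups disagree through multiple hits at roughly a
fifth of segregating sites; resolved sites polarize at ≳99.8% accuracy,
flagged fallback sites at ~85%, overall ~96% (measured against simulator
ground truth). Dispersion is a nonparametric bootstrap over sites
(percentile CI) — assumption-light, in place of the closed-form variance of
the original description, which lives in a reference not reproduced here
and is left as a pluggable alternative.

**Conversions**: N_ef = θ/(2 L μ g) (fragment θ) or θ/(2 μ g) (per-site θ),
rounded to the nearest integer before use — this rounding reproduces the
reference conversions exactly. T_years = T_coal·N_ef·g with the 95% CI
approximated by ±2 SD in coalescent units, floored at zero.

**Classic skyline**: for each intercoalescent interval with i lineages and
duration γ_i (ultrametric input tree, tip-depth spread checked against a
relative tolerance of 1e-6), M_i = i(i−1)γ_i/2 estimates the
population-size scale in branch-length units; scaling to years is a
separate, explicit step.

**Demographic model fits**: interval log-likelihoods
log λ_i(t_event) − ∫ λ_i, λ_i(t) = i(i−1)/(2ν(t)), with ν(t) = N₀ (constant,
closed-form MLE), N₀e^{−ρt} (exponential), N₀(α + (1−α)e^{−ρt}) (expansion,
0 < α < 1 the ancient/current size ratio). All three intensity integrals
have closed forms (validated against quadrature to 1e-8); optimisation is
Nelder–Mead over log/logit-transformed parameters with three growth-rate
starts, parameters clipped to e^±30, and non-finite likelihoods rejected
(degenerate corners of the expansion model can otherwise overflow to +∞).
AIC = 2k − 2lnL with k = 1, 2, 3.

## Synthetic data

The generator emulates the statistical structure the analyses assume: a
haploid Kingman coalescent (constant size, or exponential growth by exact
deterministic time rescaling), infinite-sites mutations (Poisson θ/2 per
branch, distinct sites drawn without replacement), and outgroups evolved
from the true ingroup ancestral sequence under Jukes–Cantor *with* multiple
hits, since saturation is material at fossil-calibration distances. Presets
match the two dataset shapes the analysis chain targets (n=76/L=648/θ=2.7
and n=50/L=340/θ=0.9) plus a growth variant (ρ = 10 per coalescent unit,
the point estimate of the likelihood-based demographic analysis this
mirrors); region labels include one monomorphic subgroup of up to 24
samples, mimicking the monomorphic regional sample of the motivating data.

What it does **not** emulate: codon structure (simulated sequences are
random, so the stop-codon QC legitimately fails on them — QC is
report-only), rate heterogeneity among sites or lineages, recombination,
migration/structure, selection, and sequencing error. A green test on
simulator output therefore establishes the correctness of the estimator
pipeline under its own model assumptions, not robustness to their
violation.

All randomness flows from one seeded generator per entry point; the same
seed yields byte-identical FASTA/TSV/JSON output. The pipeline derives
per-stage seeds deterministically from the master seed and logs every seed
and replicate count.

## Known limitations

* Fu & Li p-values share the fixed-S null machinery; exact finite-sample
  agreement with any particular legacy tool's p-values is not claimed
  (conditioning and tail conventions differ among those tools).
* The mismatch τ CI is a parametric-bootstrap percentile interval validated
  by parameter-recovery coverage, not a reproduction of any specific legacy
  tool's interval construction.
* The four-gamete filter's site choice (rarer minor allele, ties high) is a
  deterministic convention; data assembled elsewhere may have used a
  different, unstated rule, so filtered site lists are comparable only via
  the haplotype-merge report.
* Neutrality p-values are one-tailed toward growth by default; two-tailed
  and upper-tailed options exist but table output reports the default.
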