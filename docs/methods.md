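# Methods

## Models

**Phenotype adjustment (animal model).**  Raw records can be pre-adjusted
with a pedigree-based mixed model containing arbitrary fixed effects and
random pen, litter and additive-genetic (animal) terms, the latter with
covariance **A** from the tabular method.  The adjusted phenotype is
ê + â per record: fixed and non-genetic random effects are stripped while
every phenotyped animal — genotyped or not — contributes to their
estimation.

**GBLUP.**  y′ = μ + Zg + e with g ~ N(0, **G**σ_g²),
**G** = **WW**′/m, and column i of **W** equal to
(m_i − 2p_i)/√(2p_i(1−p_i)); p_i is the empirical frequency of the
counted (minor) allele after QC, frozen at scaling time so that feature
submatrices reuse identical scaling.

**GFBLUP.**  y′ = μ + Zf + Zr + e with f ~ N(0, **G**_f σ_f²),
r ~ N(0, **G**_r σ_r²); **G**_f / **G**_r restrict **W** to the feature
marker set and its complement, so m_f **G**_f + m_r **G**_r = m **G**
exactly.  Using the all-marker **G** as the second component instead of
**G**_r is supported (`--second-component all`).

## REML estimation

Variance components maximize the restricted likelihood via
average-information (AI) updates:

* initialization: equal split of the sample phenotypic variance across
  all components;
* an AI step is step-halved (up to 1/16) while it would decrease the
  restricted log-likelihood; if every step fails, an EM step is taken
  (EM never decreases the likelihood);
* components are clamped at ε = 10⁻⁶ · var(y); a clamped component whose
  gradient still points outward is held at the bound and removed from the
  AI system so it cannot distort the step for the free components;
* convergence: |Δ logL| < 10⁻⁸ together with relative parameter change
  < 10⁻⁶ among free components, or a likelihood plateau sustained for
  three iterations (a flat ridge or boundary solution); max 100
  iterations, non-convergence raises an error carrying the likelihood
  trace;
* standard errors come from the inverse AI matrix at convergence.

Relationship matrices are never inverted: predictions use the
variance-matrix form û_k = σ̂_k² K_k Z_k′ P y, which is valid for singular
K (centered GRMs are always singular, and so is any GRM with fewer
markers than individuals).  PEV_k = σ̂_k² K_k − Var(û_k) with
Var(û_k) = σ̂_k⁴ K_k Z_k′ P Z_k K_k, matching the mixed-model-equation
C-inverse blocks when K is invertible.

For a model with a single identity-design random term (every GBLUP fit in
the pipelines) the covariance is eigendecomposed once and all REML
iterations run in the rotated basis in O(n) per step; replicated analyses
on a fixed panel reuse the decomposition (`ModelSpec(eig=...)`).

## Marker statistics

ŝ = W′(WW′)⁻ĝ and Var(ŝ) = W′(WW′)⁻Var(ĝ)(WW′)⁻W (diagonal), with
Var(ĝ) = **G**σ̂_g² − PEV.  Note the dimensional correction of the
trailing factor (W, not W′) in the variance sandwich.  For the
intercept-only GBLUP the expressions collapse — every marker column lies
in col(W), so ŝ = (σ̂_g²/m)·W′Py and Var(ŝ)_jj = (σ̂_g⁴/m²)·w_j′Pw_j —
and `gblup_marker_stats` computes the whole vector with a single O(n²m)
rotation and no n×n covariance; equality with the generic route is
enforced by test.

t_j = ŝ_j/√Var(ŝ)_jj is referred to a t distribution with
df_e = tr(**I**−**H**) degrees of freedom, H being the smoother
ŷ = (I − σ̂_e²P)y; df_e is real-valued (not rounded) and shared across
markers.  p-values are two-sided; the set statistics consume t², which is
side-agnostic.  These p-values differ from per-marker-refit GWAS
p-values but rank markers identically.

## Set testing

T_sum = Σ_{i∈set} t_i² (default) or T_count = Σ I(|t_i| > t₀), with t₀
defaulting to the two-sided 5 % t critical value at df_e.  The
competitive null rotates the genome-ordered t vector as a single circle
(chromosomes concatenated in map order): offsets are drawn uniformly with
replacement from {1, …, m−1} — the identity rotation is excluded to avoid
guaranteed ties — and the statistic is recomputed at the set's original
positions.  The empirical p counts ties toward the null (p = #(null ≥
observed)/n_perm), which is conservative; strict `>` is available.  1,000
rotations by default; an exhaustive mode enumerates all m−1 rotations.

## Feature classes

* **single-marker sets**: all markers with p below each cutoff of a
  decreasing grid (default 10⁻⁵ … 0.1; nested by construction);
* **block sets**: the genome partitioned into runs of 50 physically
  adjacent markers within chromosomes (a trailing short block is kept,
  optionally mergeable), each block tested by rotation, blocks below a
  cutoff unioned;
* **QTL sets**: each QTL interval reduced to its midpoint
  (⌊(start+end)/2⌋) and expanded 250 kb per side, inclusive, 1-based bp;
  a trait's set is the union of its windows; sets spanning fewer than 3
  markers (">2 SNPs") are dropped; a *rest* set (markers in no window)
  and an *all* set complete the class.  No multiple-testing correction is
  applied across sets; raw empirical p-values are reported.

## Quality control

Order: sample call rate (> 0.80) first, so near-empty samples cannot
distort marker statistics; then marker call rate (> 0.90), minor allele
frequency (> 0.01), 1-df chi-square HWE (p > 10⁻⁷) and a mapped-position
requirement; finally counts are re-oriented to the within-sample minor
allele (frequency ties keep the file's coding).  Missing genotypes that
survive QC stay as the sentinel in the integer count matrix and are
mean-imputed at centering time (a missing entry contributes 0 to W, i.e.
the count 2p̂) — arithmetically identical to imputing before centering
while keeping counts integral.

## Simulator

The generator emulates a closed pig nucleus population.  Defaults: 5
discrete generations of nested half-sib families (25 sires × 10 dams × 2
offspring; litter size auto-scales upward when more individuals are
requested, and the most recent n individuals are returned with their
generation labels), founder MAF uniform on (0.05, 0.5), 18 autosomes,
markers every 60 kb, recombination at 1 cM/Mb.  Founder haplotypes use a
latent AR(1) Gaussian copula with adjacent-marker correlation ρ = 0.7
(restarting at chromosome boundaries) — a first-order Markov LD structure
producing blocky LD; gene dropping adds crossovers per interval with
probability r = distance × 10⁻⁸.

Phenotypes: y = g₁ + g₂ + e with σ²_g1 = h²·h_f²·σ_P²,
σ²_g2 = h²(1−h_f²)·σ_P², σ²_e = (1−h²)·σ_P², σ_P² = 100.  The genomic
components are drawn in factor form, g_k = (σ_gk/√m_k)·W_k z with z iid
standard normal, which has covariance σ²_gk **G**_k *exactly* — no
eigendecomposition, truncation or PSD repair is needed, since
**G**_k = W_kW_k′/m_k is PSD by construction.

Causal architecture: 1,000 causal SNPs split into C1 (100, the feature)
and C2 (900).  *random*: both uniform without replacement.  *cluster*:
C1 drawn as 5 markers from each of 20 non-overlapping 50-marker regions
(sampled on the 50-marker grid to guarantee disjointness); C2 uniform
over the remainder.  Dilution adds k non-causal markers (∉ C1∪C2) to C1,
by default uniformly genome-wide; a *flanking* mode instead adds the
non-causal markers closest to C1 in map order (expanding windows), which
preserves LD with the causal clusters.  Null sets of sizes
100/500/1000/5000 (50 per size by default) are drawn among non-causal
markers.  The full factorial grid is 3 (n) × 3 (h²) × 4 (h_f²) × 2
(model) = 72 cells.

**What a green simulation test does and does not establish.**  The
synthetic panel reproduces family structure, blocky LD and the two-
component phenotype architecture, so calibration (false-positive rate),
variance-partition recovery and qualitative power behaviour transfer.
It does not reproduce a real SNP-chip's marker density or long-range LD:
with m = 5,000 markers an absolute dilution of 2,000 makes the diluted
set cover ~42 % of the panel, and a cyclic rotation of the competitive
null then captures nearly as much genome-wide causal signal as the
observed set itself — power at extreme absolute dilution is therefore
*structurally* lower than on a 33k-marker panel, where the same set
covers ~6 % (verified directly: the identical configuration at
m = 15,000 restores power ≈ 1).  Conclusions about absolute dilution
robustness only transfer at matched dilution *fractions* of the genome.

## Validation

Train/validation splits are cohort-based with a mandatory generation gap
(train cohorts ≤ b₁, validation ≥ b₂, b₂ > b₁ + gap).  Predictive
ability is the mean Pearson correlation between phenotype and total
genomic value (ĝ, or ĝ_f + ĝ_r for GFBLUP) over 100 subsamples of 1/5 of
the validation animals, drawn **without** replacement; degenerate draws
(constant vector) are skipped and counted.  The correlation is bounded by
√h².  Power/FPR experiments fix the genotype panel within a scenario
cell (the real-data analogue keeps one genotype resource across all
replicates) and redraw causal sets and phenotypes per replicate;
rejection uses p ≤ α with α = 0.05.

## Numerical choices and limitations

* Generalized inverses zero eigenvalues below 10⁻⁸ × the largest (the
  back-solve uses 10⁻¹⁰ relative truncation on WW′).
* Markers with effect variance at the numerical floor get t = 0, p = 1
  and a flag.
* GRMs are never blended ("bent") with the identity; singularity is
  handled structurally.
* Single-trait models only; no dominance/epistasis, no marker weighting,
  no genotype imputation between chip densities, no multi-allelic sites.
* The AI-REML flat-ridge convergence rule means a reported fit can sit
  anywhere on a likelihood plateau; only identifiable functions of the
  components (sums, ratios backed by distinct covariances) should be
  interpreted there.
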