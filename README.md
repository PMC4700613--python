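# gfblup

Genomic feature BLUP models and marker-set association tests for
quantitative traits in structured (livestock) populations.

## The problem

Standard genomic prediction (GBLUP) treats the genome as a black box: a
single random effect with covariance proportional to the genomic
relationship matrix **G** = **WW**′/m weights every SNP equally.  Prior
biological knowledge — for example, that a trait's known QTL regions
concentrate causal variation — is ignored.  The *genomic feature* BLUP
(GFBLUP) model splits the genomic effect in two:

    y = μ + Zf + Zr + e,   f ~ N(0, G_f σ_f²),  r ~ N(0, G_r σ_r²),  e ~ N(0, I σ_e²)

where **G**_f is built from the marker set defining the feature (e.g. all
SNPs within 250 kb of a trait category's QTL midpoints) and **G**_r from
the remaining markers.  Variance components are estimated by
average-information REML (generalized inverses throughout, since centered
GRMs are singular), giving the genomic heritability
ĥ² = (σ̂_f² + σ̂_r²)/(σ̂_f² + σ̂_r² + σ̂_e²) and the partition
ĥ_f² = σ̂_f²/(σ̂_f² + σ̂_r²).

To ask whether a marker set is *associated* with a trait at all, the
package back-solves single-marker effects from a fitted GBLUP,

    ŝ = W′(WW′)⁻ ĝ,   Var(ŝ) = W′(WW′)⁻ Var(ĝ) (WW′)⁻ W,

forms t-statistics on df_e = tr(**I** − **H**) effective residual degrees
of freedom, and tests the set statistic T_sum = Σ t_i² against a
*competitive* null: the genome-ordered statistic vector is cyclically
rotated (preserving the local LD-driven correlation of marker statistics)
and the statistic is recomputed at the set's original positions.  The
empirical p-value is the fraction of rotations at least as extreme as the
observed value.

A simulation module generates synthetic populations with blocky LD and
multi-generation half-sib family structure, two-component phenotypes
y = g₁ + g₂ + e with configurable heritability h², causal-feature share
h_f² and total variance σ_P² = 100, causal-set dilution, and null sets —
the machinery for power, calibration, variance-partition and
predictive-ability experiments.

## Worked example

```python
import numpy as np
from gfblup import (qc_filter, center_scale, build_grm, make_gblup_spec,
                    make_gfblup_spec, fit_reml, heritability, gblup_marker_stats,
                    cyclic_permutation_test, simulate_genotypes, select_causal,
                    simulate_phenotypes, SimScenario)

geno = simulate_genotypes(n=500, m=2000, seed=42)
geno, report = qc_filter(geno)           # call rate, MAF, HWE filters

C1, C2 = select_causal(geno.n_markers, model="cluster", seed=1)
scenario = SimScenario(h2=0.3, h2_f=0.5, n_obs=500, n_markers=2000)
ds = simulate_phenotypes(geno, C1, C2, scenario, rng=7)

w = center_scale(geno)
G = build_grm(w)
spec = make_gblup_spec(ds.y, G)
v = fit_reml(spec)
me = gblup_marker_stats(w, spec, v)      # back-solved t statistics
res = cyclic_permutation_test(me.t, C1, n_perm=1000, seed=3)
```

Output (printed by the statements above plus a GFBLUP refit):

```
panel: 500 boars x 1991 SNPs after QC
GBLUP variance components: {'genomic': 13.7, 'residual': 78.5}
genomic heritability h2 = 0.149
back-solved 1991 marker effects, df_e = 439.4
causal feature C1: T_sum = 128.4, empirical p = 0.034
random non-causal set: T_sum = 71.7, empirical p = 0.985
GFBLUP partition: h2 = 0.156  h2_f = 0.408
```

The 100 markers of the causal feature C1 carry an excess of squared
t-statistics that fewer than 4 % of random genome rotations match, while
an equally sized non-causal set is nowhere near significance.  The GFBLUP
refit attributes ~40 % of the (here noisily estimated, n = 500) genomic
variance to the feature — the simulated truth is 50 %.

A `gfblup` console script exposes the same steps as subcommands
(`qc`, `grm`, `fit`, `backsolve`, `features`, `settest`, `simulate`,
`validate`, `power`); run `gfblup --help`.

## Acceptance script

`scripts/acceptance.py` recomputes, from freshly simulated data,

* the false-positive rate of the rotation set test on non-causal sets
  (200 replicate datasets, n = 1000, m = 5000),
* the minimum power across dilution levels under the cluster causal
  model (h² = 0.3, h_f² = 0.5, n = 3000),
* the realized phenotypic variance against its configured value,

and writes them to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model details, simulator assumptions,
numerical choices and known limitations.
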