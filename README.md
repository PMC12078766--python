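# empdisp

Dispersal inference for emperor penguin (*Aptenodytes forsteri*)
metapopulations from genetic-cluster SNP data.

Emperor penguins breed at ~66 colonies around the Antarctic coastline.
Their long-term persistence under sea-ice loss depends on whether birds can
leave degrading colonies and where they settle — yet dispersal is almost
impossible to observe directly. `empdisp` implements a
mechanistic–statistical framework that infers dispersal *behavior* (random,
semi-informed or informed), the *mean dispersal distance* `d` and per-region
*emigration parameters* `pm` from a modest sample of biallelic SNP genotypes,
by coupling a deterministic metapopulation model to the spatial spread of
genetically differentiated clusters. It is aimed at population ecologists
and conservation geneticists working with structured metapopulations.

## The model

**Demography.** The female population vector `n` is updated annually by

```
n(t+1) = D(t) F(t, n(t)) n(t)
```

where `F` is a diagonal Ricker reproduction matrix, `f_i = exp(r_it (1 −
n_i/K_i))`, with colony-specific intrinsic growth rates `r_it` (forced, e.g.
by sea-ice conditions) and constant carrying capacities `K_i`; `D` is a
column-stochastic dispersal matrix. Emigration from colony `i` occurs at
rate

```
m_it = pm_i                                   (random departure)
m_it = min(1, r_it / ((1 − pm_i) rc*))  if r_it < 0, else 0   (informed departure)
```

where `rc* < 0` is the worst-case growth rate; settlement is either
kernel-weighted (`∝ exp(−dist/d)` over colonies within `3d`; random
settlement) or a deterministic argmax of growth rate (informed settlement).

**Genetics.** The population comprises `R` genetic clusters with fixed
allele frequencies at Λ biallelic SNPs (private alleles allowed). The
cluster-of-origin vectors `n^r` evolve under the *same* `D` and `F`
operators, giving mixture proportions `μ_τr(t) = n_τ^r(t)/n_τ(t)`. A sampled
genotype `G` has likelihood

```
P(G) = Σ_r μ_τr(t) · 2^k ∏_λ p_rλ(a1) p_rλ(a2)
```

under Hardy–Weinberg and linkage equilibrium (`k` = heterozygous loci).

**Inference.** Θ = (d, pm, μ-rows of uncharacterized regions) gets a flat
prior (`d` uniform on [250, 6500] km, `pm` uniform on [0,1], flat Dirichlet
μ) and is estimated by importance sampling; the three behaviors are compared
with the deviance information criterion `DIC = D̂ + V_D/2`, and model
adequacy is checked by Monte-Carlo 95% confidence regions over genotype
space.

A synthetic-data generator (`empdisp.synthetic`) reproduces the statistical
structure of the study system — colonies on a closed coastline, contiguous
regions, AR(1) growth-rate forcing with degradation episodes, Balding–
Nichols cluster divergence with private alleles, multinomial sampling and
HWE genotypes — so the whole pipeline is testable offline.

## Worked example

```python
from empdisp import Behavior
from empdisp.inference import PriorSpec, fit_behavior, posterior_summary, select_behavior
from empdisp.synthetic import generate_benchmark

scen, cmap, forcing, freqs, traj, ctraj, data = generate_benchmark(seed=1)
spec = PriorSpec(n_regions=4, n_clusters=4, M=5000, seed=1001)
sample = fit_behavior(data, freqs, cmap, forcing, scen.region_to_cluster(),
                      spec, Behavior.SEMI_INFORMED)
summ = posterior_summary(sample, cmap, forcing)
print(f"d: mean {summ['d']['mean']:.0f} km, 95% CI "
      f"({summ['d']['ci95'][0]:.0f}, {summ['d']['ci95'][1]:.0f})")
print(f"mean emigration rate: {summ['mean_emigration_rate']['mean']:.3f}")
```

prints (seed 1)

```
d: mean 420 km, 95% CI (297, 597)
mean emigration rate: 0.251
```

i.e. the posterior concentrates near the generating dispersal distance of
400 km, and on average a quarter of a colony's females emigrate per year
under this (deliberately harsh) benchmark forcing. Running
`select_behavior` on the same data ranks the behaviors by DIC and selects
semi-informed — the generating behavior — with random ~39 DIC units worse
and informed degenerate (its point-mass settlement cannot place the
immigrants that private alleles pin to specific clusters).

The same pipeline is available from the shell:

```bash
empdisp simulate --config cfg.yaml --out sim/
empdisp select --config fit.yaml --out out/
```

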