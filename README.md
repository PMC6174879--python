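# ucepop

Two-population divergence inference from UCE-like multilocus SNP data.

`ucepop` is a reusable, tested re-implementation of a population-genomic
workflow for a pair of recently diverged sister taxa sampled at a few
thousand sequence-capture loci (ultraconserved elements and similar
markers, ~1 kb each, a handful of diploids per population, complete phased
genotype matrices). It is aimed at researchers who want the whole chain —
from a phased VCF to demographic parameters in biological units — in one
scriptable package, together with a structured-coalescent simulator that
generates datasets of exactly this shape with known truth parameters.

The pipeline covers:

* **Summary statistics** — nucleotide diversity π, between-population
  distance d_xy and net distance d_A = d_xy − (π₁+π₂)/2, Weir & Cockerham
  (1984) F_ST at SNP/locus/overall level, a permutation *G*-test of
  differentiation, exact Hardy–Weinberg tests, observed/expected
  heterozygosity summaries, and DAPC-style individual assignment
  (PCA + linear discriminant).
* **Four-gamete filtering** — per-locus detection of intra-locus
  recombination and construction of non-recombinant sub-alignments by
  trimming sites and/or removing individuals, maximising retained
  haplotype-sites.
* **Folded joint SFS inference** — one biallelic SNP per locus (Z-linked
  loci excluded), folded two-dimensional site-frequency spectrum, and
  maximum composite-likelihood fitting of six two-population divergence
  models (panmixia; split with/without migration; isolation with growth
  and with/without migration; asymmetric-migration split), with delete-m
  jackknife confidence intervals.
* **Unit conversion** — substitution-rate calibration from outgroup
  divergence, generation time G = α + s/(1−s), and translation of
  diffusion-unit estimates (ν₁, ν₂, T, m, θ) into individuals, years and
  migrants per generation.

## The model

Parameters follow the dadi diffusion convention: an ancestral population
of size `Nref` splits at time `T` (units of `2·Nref` generations) into
populations of relative size `nu1`, `nu2`, exchanging scaled migration
`m = 2·Nref·f` (with `f` the per-generation migrant fraction). The
expected folded joint SFS under each model is computed by Monte-Carlo
coalescent expectation — each simulated branch contributes its length to
the frequency-class cell indexed by its descendant leaves in the two
populations — which is exact at these sample sizes up to Monte-Carlo
error. The data spectrum is fitted by maximising the Poisson composite
likelihood over unmasked cells, with the scale
`theta = 4·Nref·mu_gen·L` profiled out analytically. Conversions to
biological units:

```
mu_gen  = rate_per_year x G          Nref = theta / (4 mu_gen L)
N_i     = nu_i x Nref                T_years = T x 2 Nref x G
M_i     = m_i nu_i / 2   (migrants into population i per generation)
```

## Worked example

Simulate a study-shaped dataset (4 + 4 diploids, 600 variable + 180
invariant loci, split-with-migration truth ν₁=3.5, ν₂=6.0, T=1.4,
m=1.65), compute statistics, and fit models:

```python
import numpy as np
from ucepop import (SimulationConfig, DemographicParams, generate_dataset,
                    prepare_snp_matrix, build_folded_joint_sfs,
                    weir_cockerham_fst, divergence_stats, assign_individuals)
from ucepop.demography import compare_models

cfg = SimulationConfig(n_variable_loci_target=600, n_invariant_loci=180, seed=1)
ls = generate_dataset(cfg).locus_set
div = divergence_stats(ls)
fst = weir_cockerham_fst(ls)
print(f"pi = {div.pi_overall:.6f}, dxy = {div.dxy:.6f}, dA = {div.dA:.2e}")
print(f"F_ST = {fst.overall:.4f}")
print(f"diagnosability = {assign_individuals(ls, n_pcs=4).diagnosability:.2f}")

m = prepare_snp_matrix(ls, rng=np.random.default_rng(2))
data = build_folded_joint_sfs(m)
table, fits = compare_models(data, models=["neutral", "split_mig"],
                             n_starts=1, n_genealogies=4000, seed=3,
                             init=DemographicParams(nu1=1, nu2=1, T=1, m12=1, m21=1))
print(table[["model", "loglik", "theta", "converged"]].to_string(index=False))
```

prints

```
pi = 0.000558, dxy = 0.000567, dA = 1.96e-05
F_ST = 0.0338
diagnosability = 1.00
    model      loglik      theta  converged
split_mig  -69.473369  40.880674       True
  neutral -208.264272 171.694695       True
```

— per-site diversity ~5.6×10⁻⁴ with weak but real differentiation
(F_ST ≈ 0.03), all individuals assignable to their population, and the
generating split-with-migration model beating panmixia by ~139
log-likelihood units on 568 thinned SNPs.

Converting fitted diffusion-unit parameters to biological units from the
command line:

```sh
ucepop convert --theta 249.97 --nu1 3.52 --nu2 5.95 --t 1.44 \
    --m12 1.65 --m21 1.65 --rate 6.83e-10 --rate 6.67e-10 \
    --generation-time 2.7 --length 1103715
```

```
 parameter      estimate
      Nref  31067.293265
        N1 109356.872292
        N2 184850.394925
   T_years 241579.272427
migrants_1      2.904000
migrants_2      4.908750
```

i.e. an ancestral effective size of ~31,000 individuals, daughter
populations of ~109,000 and ~185,000, a split ~242,000 years ago, and
~2.9 / ~4.9 migrants per generation.

The other CLI subcommands (`simulate`, `stats`, `fourgametes`, `sfs`,
`fit`, `run`) wrap the corresponding library stages; `ucepop run
--config run.yaml` executes the whole pipeline reproducibly from one
config file (see `docs/methods.md`).

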