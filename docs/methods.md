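# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `ucepop`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Units and parameterisation

All demographic quantities use the diffusion convention: time in units of
`2·Nref` generations, population sizes as ratios `nu_i` to the ancestral
reference `Nref`, and migration `m_ij = 2·Nref·f_ij` where `f_ij` is the
per-generation fraction of population *i* that descends from migrants out
of population *j*. In these units the structured coalescent has pairwise
coalescence rate `1/nu_i(t)` within population *i* and per-lineage
backward migration rate `m_ij` from *i* to *j* (equivalently, Wakeley's
per-lineage rate `M/2` with `M = 4·N·f`). The migrant-number conversion
`M_i = m_i·nu_i/2` individuals per generation follows directly:
`N_i·f = (nu_i·Nref)·(m_i/2Nref)`.

## The coalescent kernel

Genealogies are simulated by an event-driven structured coalescent
(numba-compiled): competing exponential clocks for within-population
coalescence and migration, with all lineages merged into the ancestral
population (relative size 1) at `T` looking backward. The isolation-with-
growth models give each daughter population a backward size trajectory
`nu(t) = nu_i · exp(beta_i t)` with `beta_i = log(s_i/nu_i)/T`
(`s_1 = s`, `s_2 = 1−s` the ancestral split fractions); waiting times
under the time-varying rate are drawn by inverting the integrated hazard
in closed form, so no time discretisation is involved. Six models are
exposed: `neutral` (one panmictic population; labels inert),
`split_mig` (symmetric migration), `split_nomig`, `im` (growth +
bidirectional migration), `im_nomig`, and `split_asym_mig`
(constant sizes, independent `m12`, `m21`). The no-migration variants are
the corresponding models with migration structurally fixed at zero.

The kernel is validated three ways: closed forms (single-population
expected branch lengths `E[xi_i] ∝ 1/i`, Watterson's `E[S]`, pairwise
`E[T2]`), a naive event-by-event simulator written independently in the
test suite, and msprime run under the identical demography (branch-class
tables agree within Monte-Carlo error; the half-rate migration
convention is rejected decisively by this comparison).

## Mutation and dataset generation

Mutations follow infinite sites: `Poisson(theta_locus/2 × total branch
length)` mutations, each on a branch chosen proportionally to length,
each creating one biallelic site. Multiple hits are ignored — at the SNP
densities emulated here (~3 SNPs/kb) recurrent mutation is negligible.

`SimulationConfig` defaults emulate the study conditions this package
targets: 2 populations × 4 diploids, ~2,600 variable loci plus ~800
invariant loci, locus lengths Normal(1150, 330) truncated at 200 bp, a
5% Z-linked fraction (a flag only; Z loci are simulated like autosomes
since the flag exists purely as an exclusion filter downstream), and
`theta_per_site = 3.1e-4`, calibrated once so the default
split-with-migration demography (`nu1=3.5, nu2=6.0, T=1.4, m=1.65`)
yields ~3.6 SNPs per variable locus. A configurable fraction of loci is
built from two independent genealogies spliced at a uniform breakpoint,
producing genuine intra-locus recombination signal. Output is a phased
VCF v4.2 (GT `0|1`, constant GQ), a popmap TSV and an annotation TSV;
generation is bit-reproducible under a fixed seed.

What the generator does *not* emulate: genotyping error and missingness
(the container enforces a complete matrix, as the emulated workflow
filtered to one), linked selection and rate variation among loci beyond
tree-length variance, more than one recombination breakpoint per locus,
and sex-linked inheritance. Passing tests therefore demonstrate
correctness of the estimators and inference machinery under the stated
generative model, not robustness to these real-data complications.

## Statistics

* π uses the unbiased per-site heterozygosity `(1 − Σp²)·n/(n−1)` summed
  over sites and divided by the total surveyed length *including*
  invariant loci, mirroring a concatenated-alignment denominator.
  d_xy is the mean per-site between-population difference
  `1 − Σ p1·p2`; d_A = d_xy − (π₁+π₂)/2 by construction. These per-site
  averages are numerically indistinguishable from composite-likelihood
  distances at divergences of order 10⁻⁴ (a correction would appear at
  O(d²) ≈ 10⁻⁷).
* F_ST is the Weir & Cockerham (1984) variance-components estimator,
  summed over alleles per site; locus and overall levels use the ratio of
  summed components Σa/Σ(a+b+c). Monomorphic sites are excluded.
* The differentiation test sums per-SNP population × allele G statistics
  (2·Σ O·ln(O/E)) and permutes individuals (keeping both haplotypes
  together) across populations; `p = (1 + #perm ≥ obs)/(n_perm + 1)`.
* Hardy–Weinberg uses the exact conditional test (enumeration of
  heterozygote counts given allele counts, summing configurations no more
  probable than observed); monomorphic sites return p = 1 by convention.
  Populations are pooled by default; the "loci out of HWE" count uses an
  uncorrected 0.05 threshold. The paired Ho-vs-He comparison reports
  two-sided and both one-sided p-values, since a directional test is a
  legitimate reading of this comparison.
* Assignment projects the centred allele-dosage matrix onto 4 principal
  components by default and fits a linear discriminant. In-sample
  posteriors are the default (the convention for reporting
  group-membership probabilities), but at n = 8 individuals they overfit:
  `cross_validated=True` scores each individual from a model trained
  without it (leave-one-out) and is what behaves at chance level under
  panmixia — tested.

## Four-gamete filtering

Two biallelic sites are incompatible when all four gametes occur. Since
the exact internal objective of the classical filtering tool is not
published, this module defines a deterministic, testable objective:
maximise retained haplotype-sites (retained rows × retained SNP columns)
over all contiguous pairwise-compatible site windows crossed with all
removal sets of at most `max_remove = 2` individuals, preferring trimming
alone unless a removal strictly improves the score; ties break toward the
smaller window start and the earliest removal set in sample order. The
search is exhaustive within that space, verified against an independent
brute-force oracle on all loci with ≤ 6 SNPs, and the output always
passes a full compatibility re-scan. Removal operates on whole
individuals by default (both haplotypes), or on single haplotypes with
`unit="haplotype"`.

Limitation: with ~3.6 SNPs per locus, most spliced (recombinant) loci
carry too few informative sites per block to produce a four-gamete
violation; the detectable fraction saturates near 12% even when every
locus recombines. The filter's correctness properties (zero
incompatibility without recombination; monotone response to the
recombinant fraction) are tested; the absolute detected fraction in any
real dataset depends on its SNP-count distribution.

## Folded joint SFS

SNP preparation order is: Z-exclusion (annotation flag) → biallelic
filter (a locus with any >2-allele site is dropped whole, and logged) →
thinning to one SNP per locus (seeded-random by default, `first` for
determinism). Folding uses the half-mass convention: counts `(i, j)`
with `i+j` above half the total sample fold onto `(n1−i, n2−j)`, and
cells exactly at half total carry half mass on each side (collapsing on
self-complementary cells); the redundant half and the two monomorphic
corners are masked, masked cells hold zero, and folding is exactly
idempotent. Unmasked mass equals the SNP count to 1e-9. The text format
is three lines — `d1 d2 folded|unfolded`, row-major masses (shortest
round-tripping float representation), row-major mask bits — and
round-trips bit-exactly.

Jackknife replicates partition loci into `n_reps = 10` near-equal random
blocks (seeded); replicate *r* is the folded SFS of all loci outside
block *r*.

## Composite likelihood and optimisation

The expected spectrum per unit θ is the Monte-Carlo branch-class table
divided by 2 (a mutation falls on a class-(i,j) branch at rate θ/2 per
unit length), folded like the data. The Poisson composite log-likelihood
over unmasked cells profiles θ analytically
(`theta_hat = Σdata/Σmodel`); model cells at zero where data is positive
are floored at 1e-12.

Fitting runs Nelder–Mead on log10 parameters (box bounds enforced by a
quadratic penalty; defaults `nu ∈ [0.01, 100]`, `T ∈ [0.01, 10]`,
`m ∈ [0.001, 20]`, `s ∈ [0.01, 0.99]`) from `n_starts` perturbed starts.
An explicit initial simplex with 0.25 log10-unit steps is supplied
because scipy's default simplex degenerates for coordinates near zero —
exactly where log-parameters near 1 sit. One genealogy seed is fixed per
fit (common random numbers), making the Monte-Carlo surface deterministic
within a fit and the whole `FitResult` bit-reproducible. A fit is
declared converged when the best three starts agree within 0.5
log-likelihood units, mirroring the run-until-three-runs-agree
repeatability rule; for unstable models the reported comparison value is
the mean of the top five start likelihoods. Default Monte-Carlo sizes are
20,000 genealogies per likelihood evaluation during optimisation (the
package's tests and acceptance runs use 4,000–10,000 to keep a full
recovery-plus-model-selection study within minutes on one CPU; at the
9×9 spectrum of 8+8 haplotypes the resulting Monte-Carlo SE is small
relative to the likelihood differences that drive model choice, and
parameter-recovery accuracy at these settings is itself measured by the
acceptance tests).

Jackknife CIs refit each replicate once, initialised at the full-data
optimum, all with a common genealogy seed so the spread reflects data
variation only; the delete-m SE over g block estimates is
`sqrt((g−1)/g · Σ(est_j − mean)²)` and the CI is estimate ± 1.96·SE.
Diffusion-unit CI endpoints are pushed through the monotone conversion
maps rather than re-jackknifed in biological units.

## Calibration and conversion

Substitution rate: `(substitutions/sites)/(2·TMRCA)` per comparison,
averaged arithmetically across outgroup comparisons; substitutions from a
12-column alignment hit table are mismatch counts after keeping only the
best-scoring hit per locus (gaps excluded — mismatches are the only
substitution field in the standard tabular format). Generation time
`G = α + s/(1−s)`. The surveyed length L is an explicit input to the
conversions; the pipeline's default derives it as (total surveyed bp) ×
(proportion of SNPs retained after thinning), but a printed/authoritative
L can be supplied directly, which is recommended when reproducing
published tables (derived proportions rarely reproduce a printed L
exactly because intermediate counts are rounded or unreported).

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → stats → four-gametes → SFS →
demography → convert from a single YAML config; every stage writes its
artifacts (TSV/JSON/SFS text) under the output directory, stage failures
halt with a stage-labelled error while retaining partial outputs, and the
report embeds the full config echo, a config digest, per-stage seeds and
the package version. All randomness derives from the config seed, and two
runs with the same config produce identical payloads.

## Known limitations

* The Monte-Carlo expected SFS makes likelihood values noisy at the
  third-or-later significant figure for the default settings; model
  ranking and parameter recovery are robust to this (tested), but
  likelihood values should not be compared across different genealogy
  seeds or counts.
* Composite likelihood treats SNPs as independent; with one SNP per
  locus this is a good approximation, but the jackknife (not the
  likelihood curvature) is the honest uncertainty measure.
* Thinning to one SNP per locus weights loci, not SNPs; at ~3.6
  SNPs/locus the induced spectrum distortion is small but not zero.
* Only two populations, folded spectra, and biallelic sites are
  supported; Z-linked loci are excluded rather than modelled with their
  own inheritance scalar.
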