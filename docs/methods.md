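# Methods

## The model

`drivecage` models the multigeneration dynamics of an autosomal CRISPR/Cas9
homing gene drive that inserts into an essential gene (kynurenine
hydroxylase in an anopheline mosquito) and carries a recoded rescue copy of
it. Four alleles are tracked at the target locus:

| allele | meaning | cleavable | functional | marker |
|---|---|---|---|---|
| W | wild type | yes | yes | – |
| H | drive (rescue) | no | yes | GFP |
| R | in-frame resistant | no | yes | – |
| B | out-of-frame resistant | no | no | – |

The ten unordered diploid genotypes are followed separately per sex across
discrete, nonoverlapping generations with random mixing. Inheritance is
Mendelian except for two drive-specific steps:

**Germline homing.** In H/W heterozygous adults a fraction *c* of W alleles
is cleaved during gametogenesis. A cleaved allele is converted to H by
homology-directed repair with sex-specific probability *p*<sub>HDR</sub>;
otherwise it end-joins into R (probability *p*<sub>RES</sub>) or B. The
H/W gamete distribution is therefore

P(H) = ½ + ½·c·*p*<sub>HDR</sub>,  P(W) = ½(1−c),
P(R) = ½·c·(1−*p*<sub>HDR</sub>)·*p*<sub>RES</sub>,
P(B) = ½·c·(1−*p*<sub>HDR</sub>)·(1−*p*<sub>RES</sub>).

Homing needs both an H template and a W target: H/H, H/R, H/B and all
drive-free genotypes segregate Mendelianly.

**Maternal deposition.** Mothers carrying H load Cas9/gRNA complexes into
all of their eggs. After forming the zygote, each W allele is cleaved with
probability *p*<sub>MC</sub> and end-joins into R (probability
*p*<sub>MR</sub>) or B. Deposition is modelled as *complete allele
conversion*: the package deliberately does not represent partial somatic
mosaics at the genotype level, so "mosaic-eyed" individuals exist only as
an optional observation-noise class in the data generator. Two
granularities are implemented — per-allele independent cleavage (default)
and all-or-none per-embryo cleavage. They differ only for W/W zygotes of
drive mothers; with complete germline cleavage (c = 1) such zygotes never
occur, because drive mothers then never transmit W.

**Loads.** Reproduction is reduced in females only: by *s*<sub>H1</sub> /
*s*<sub>H2</sub> with one / two H copies and by *s*<sub>BB</sub> for the
B/B genotype (loss of gene function in both copies). Loads enter as
fecundity weights on mothers — frequency × (1 − load), renormalised. A
separate "viability" interpretation would weight females identically in
the expected recursion and is subsumed by the Poisson fecundity rate in
the stochastic simulator, so no second code path is provided. Offspring
phenotype frequencies are reported *before* loads act, matching larval
scoring in the cage protocol. White-eyed males pay no cost in this model.

### Default (fitted) parameter values

`DriveParams.cage_fit()` carries the point estimates from the published
nine-cage fit: c = 1, *p*<sub>HDR</sub> = 0.995 in both sexes (pinned by
single-generation crosses), *p*<sub>RES</sub> = *p*<sub>MR</sub> = 0.17
(tied, the identifiability choice of the fit), *p*<sub>MC</sub> = 0.937,
*s*<sub>BB</sub> = 0.998, *s*<sub>H1</sub> = *s*<sub>H2</sub> = 0.

## Simulators

The **deterministic recursion** propagates expected genotype frequencies:
mother weights = female frequencies × (1 − load); offspring distribution =
Σ over the 100 mother × father genotype pairs of the cross-specific
offspring distribution; sexes receive identical offspring distributions
(1:1 sex ratio). Frequencies are renormalised each generation and a
normalisation drift above 1e-8 before renormalisation raises an error.

The **stochastic cage simulator** layers four sampling stages per
generation on the same offspring tensor: (i) each female draws one mate
multinomially by male genotype frequency (monandry assumed; the mating
system of the experiments is not recorded), (ii) she lays
Poisson(λ·(1−load)) eggs, (iii) each egg's genotype is multinomial from
the cross distribution with Bernoulli(1/2) sex, and (iv) the next adult
census (default N = 200) is a multivariate-hypergeometric draw from the
larval pool jointly over (sex, genotype) cells. A scored subsample
(default 500 larvae) is drawn from the pool independently of the census
draw, mirroring the experimental protocol's separate draws. λ defaults to
50 eggs per female — the order of magnitude of anopheline egg batches;
cage results at N = 200 are insensitive to λ ≳ 20 because the
hypergeometric draw discards the surplus. Crashes (a missing sex, an
empty or insufficient pool) raise a `PopulationCrash` carrying the
generation index; the dataset generator records truncated, flagged series
instead.

All randomness flows through one seeded `numpy.random.Generator`;
replicate seeds are spawned from a master `SeedSequence`, so regeneration
from a manifest is bit-identical.

## What the synthetic data do and do not emulate

`ExperimentDesign` defaults reproduce the published trial: triplicate
cages at 1:1 / 1:3 / 1:9 heterozygous-drive:wild-type male release ratios
(50/25/10 drive males plus wild-type males to 100, plus 100 wild-type
females), 18 nonoverlapping generations, 500 scored larvae per generation
tallied into GFP±× black/white/mosaic categories. Because deposition is
complete conversion, the model produces no partial-eye mosaics; the
generator emits GFP−/mosaic = 0 by default, with an optional
observation-noise mode that reassigns a binomial fraction of model
GFP−/white individuals to the mosaic class (the transient mosaics seen in
real cages mid-sweep). Not emulated: overlapping generations, density
dependence, male mating-success variation, genotyping error, and
germline mosaicism from grandparental deposition. Passing tests therefore
validate the machinery under the model's own assumptions, not those
features of real cages.

## Inference

The likelihood treats, for every cage and generation, the three
observable categories — GFP+ (≥1 H copy), GFP−/black (no H, at least one
functional allele), GFP−/white (B/B) — as a multinomial draw of the
scored count with probabilities from the *deterministic* recursion for
that cage's seeding. Observed GFP−/mosaic counts are merged into
GFP−/white (they carry deposition-cleaved tissue) and rare GFP+/white
counts into GFP+ before fitting. Predicted probabilities are floored at
1e-9 and renormalised so categories that the model puts at exactly zero
keep the likelihood finite. An overdispersion factor φ ≥ 1 (quasi-
likelihood scaling) is available but off by default.

Sampling uses emcee's affine-invariant ensemble on the logit scale with
the Jacobian correction, giving uniform(0, 1) priors on every estimated
probability and load. Defaults: 32 walkers, 3000 steps, first half
discarded (≈48 000 retained draws), fully seeded. Convergence is reported
as split-chain R̂ and effective sample size (arviz) over walkers plus the
mean acceptance fraction; non-convergence is reported, never silently
fixed. By default c and the sex-specific *p*<sub>HDR</sub> stay fixed
(they are pinned by single-generation crosses) and *p*<sub>MR</sub> is
tied to *p*<sub>RES</sub>.

### Known statistical limitations (measured, not hypothetical)

* **Process-noise bias.** The likelihood conditions on the deterministic
  expectation, so cage-level genetic drift (census 200) is unmodelled
  shared noise. Realized cages that lag or lead the expected sweep push
  the deposition parameter toward values that mimic the timing shift;
  across independent nine-cage datasets at the default truth the
  *p*<sub>MC</sub> posterior median scatters roughly between 0.90 and
  1.00 (truth 0.937) with credible intervals that are too narrow. On
  correctly specified data (counts drawn from the deterministic category
  probabilities) the same machinery is well calibrated.
* **Boundary ridge.** *s*<sub>BB</sub> near 1 lies on a weakly identified
  ridge with *p*<sub>MC</sub>; even on correctly specified data its
  marginal 95% interval tends to sit just below a truth of 0.998. The
  coverage property test therefore uses an interior truth.

## Numerical and design choices

* Genotype order is canonical (WW, WH, WR, WB, HH, HR, HB, RR, RB, BB);
  the offspring tensor O[mother, father, child] is rebuilt per parameter
  set in ~0.1 ms, which keeps a full MCMC run within minutes.
* Gamete and offspring distributions are validated to sum to 1 within
  1e-12; population states within 1e-10.
* Negative gene-conversion estimates (transmission below 50%) are
  returned as computed with a warning, never clamped.
* Cross summaries report mean ± SEM across replicate tallies (the
  reporting unit of the experiments), not a pooled binomial.
* Deterministic 1:1 dynamics under the fitted parameters cross 95% GFP+
  introduction at generation 6 and plateau near 0.97–0.98; deposition
  converts most drive carriers into non-homing H/B and H/R heterozygotes,
  so low release ratios (1:9) approach the plateau slowly and cross 95%
  only around generation 23. The stochastic plateau implies roughly nine
  in ten 1:1 realizations reach a scored GFP+ of 95% by generation 12.
* Problem sizes in the test suite are the package's own choices for a
  fast, deterministic suite: ensemble-mean convergence is checked at
  census 2000 with 150–200 replicates over 3 generations; posterior
  calibration over 10 replicate datasets with 12-walker, 500-step chains.

## Command-line interface

`drivecage simulate | generate | fit | crosses` wrap the library; every
output directory contains a YAML manifest (parameters, seeds,
configuration, package version) sufficient to reproduce it exactly.
Stochastic subcommands require an explicit seed; logging goes to stderr.
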