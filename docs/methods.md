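# Methods

## The digenic model

The analysis treats disease status as the joint outcome of two loci: a
homoplasmic mitochondrial tRNA^Glu^ variant and a heterozygous damaging
allele in a six-gene nuclear modifier panel (*EARS2*, *TRMU*, *QRSL1*,
*GOT2*, *GLS*, *MSS51*).  Homoplasmy makes the mtDNA carrier frequency equal
to its allele frequency and makes transmission strictly maternal; nuclear
alleles are autosomal and Mendelian.  Under independence of the two loci in
the population, the probability of carrying both hits is the product of the
carrier frequencies, penetrance among mtDNA carriers equals the
modifier-panel carrier frequency (every double carrier expresses the
phenotype), prevalence is the product of mtDNA carrier frequency and
penetrance, and expected case counts scale prevalence by population size.

Assumptions worth keeping explicit: no linkage disequilibrium or haplotype
structure across panel sites; no ascertainment correction (families are
simulated, not sampled through probands, unless the caller filters);
penetrance does not depend on *which* modifier gene is hit or on allele
dosage beyond the presence of ≥ 1 allele.

## Carrier-frequency conventions

Three conventions are implemented because the field uses all three
interchangeably at small frequencies:

- **additive**: Σpᵢ, clamped to 1 — the "cumulative MAF" convention; this is
  the convention under which a panel-wide cumulative MAF of 0.32 is read as
  ~32% penetrance among mtDNA carriers.
- **hardy_weinberg_het**: 1 − Π(1 − 2pᵢ(1−pᵢ)) — at least one heterozygous
  genotype.
- **at_least_one_allele**: 1 − Π(1−pᵢ)² — at least one allele over the
  diplotype; this is what binomial genotype sampling converges to, and it is
  the form verified against exhaustive diplotype enumeration in the tests.

Note the three are *not* nested the way intuition suggests: as p → 0,
at_least_one_allele → 2Σp, i.e. twice the additive value, because a diploid
carries two chances per site.  The additive convention effectively counts
alleles, not carriers.  The tests assert the true ordering
(hardy_weinberg_het ≤ at_least_one_allele ≤ 2·additive) rather than any
false equivalence.  Penetrance derived from a cumulative MAF therefore uses
the additive convention, stated as such in outputs.

## Burden counting and comparison

An individual's burden is the sum of allele counts over the qualifying
(damaging, rare) panel variants plus one for the homoplasmic mtDNA variant.
Counting the homoplasmic variant as one allele (not two) keeps the affected
group mean on the ~2.3 scale produced by "one mtDNA hit + one nuclear hit",
which is the configuration of the typical digenic patient.

The default comparison is the pooled-variance two-sided Student's t, with
Welch and a label-permutation test as options.  The permutation p-value uses
the add-one estimator (1 + hits)/(1 + n_perm), which is never exactly zero.
Degenerate inputs are handled explicitly: equal means with zero within-group
variance give t = 0, p = 1; unequal means with zero variance give p equal to
the smallest positive float with a warning, since the t statistic is
undefined there.  Relatives are treated as exchangeable observations — no
kinship adjustment — which anticonservatively narrows p-values on family
data; this matches the plain t-test design the package models and is listed
as a limitation.

Power/calibration simulation draws per-individual counts as sums of
Binomial(2, maf) over the panel and adds Poisson(effect) alleles to the
affected group, so `effect_size` is exactly the mean allele-count shift.
Type-I error at the study's group sizes (22 vs 12) is checked against
3 Monte-Carlo SE of the nominal α.

## The simulator

`SimulationConfig` defaults encode the study conditions: 19 families,
two children each; mtDNA allele frequency 1×10⁻⁴ (founder mothers are
obligate carriers by default, since study families are ascertained as
homoplasmic); panel allele frequencies summing to 0.0135 for *EARS2*
(six rare variants), 0.09695 for the common *TRMU* allele and 0.32
panel-wide; 1,044 population controls.  Only the cumulative frequencies are
anchored; the per-variant split within a gene is a modelling choice.

The penetrance model has three free probabilities: π_digenic = 0.9 (mtDNA +
≥1 modifier allele), π_mt_only = 0.01, π_background = 0.001.  The data the
model emulates imply π_mt_only ≈ 0 and π_digenic high but do not quantify
them; these defaults make nearly every affected individual a double carrier
while allowing rare phenocopies.  Under these defaults the expected
affected-minus-unaffected burden separation among carriers is slightly above
one allele (the common TRMU allele makes the conditional mean allele count
among modifier carriers ≈ 1.3, not 1.0), which the tests accept within
3 SE of 1.

Randomness: one root seed; each component (cohort, controls, assays) draws
from an independent substream derived via `SeedSequence` from the root seed
and a stable string hash of the component name, so generating one table
never perturbs another and reruns are byte-identical.

What the simulator does **not** model: heteroplasmy, de-novo mutation,
linkage between panel sites, ascertainment through affected probands
(available as a caller-side filter only), genotyping error, and relatedness
between "unrelated" controls.  Passing tests therefore demonstrate the
statistical machinery under idealised transmission and independence, not
robustness to those real-data features.

## Composition fixture and expression coupling

The packaged `mt13_synthetic.faa` is a **synthetic stand-in** for the 13
mtDNA-encoded proteins: each record has the true residue length of its
protein (ND1 318 … ND5 603) and a fixed, field-plausible number of E and Q
residues, with the remaining positions drawn from a hydrophobic-rich
background composition and shuffled deterministically.  Complex I (ND)
subunits are modelled E/Q-richer, with MT-ND5 carrying the highest absolute
E+Q count, consistent with the biology the analysis rests on.  These are not
reference translations; conclusions that depend on exact real compositions
(e.g. a specific correlation coefficient) are out of reach by design, and
the tests only assert machinery properties (exact counting, r = 1 on
noiseless linear couplings, hand-checked Pearson arithmetic, slope-monotone
recovery) plus the ND-subunit ranking that the fixture encodes.

Simulated expression uses metric = intercept + slope · fraction_EQ + N(0, σ²)
per gene.  The default σ = 0.4 and |slope| = 30 put the population
correlation near 0.6 at n = 13 — the magnitude regime of interest.  A
negative slope encodes the log2-fold-change convention (more E+Q → more
decreased); drivers that correlate the *decrease magnitude* use the positive
slope.

## Assay models

Copy number per diploid cell is 2·2^ΔCt with ΔCt = Ct(nuclear reference) −
Ct(mt target); the leading 2 accounts for the two nuclear alleles.
Replicates are averaged at the ΔCt level by default (equivalent to a
geometric mean on the copy scale, matching the exponential chemistry); the
copy-scale arithmetic mean is available by flag and the choice is recorded
in the output, since the two differ under noise (AM ≥ GM).

Proteome regulation cutoffs are mean ± 2 SD (sample SD, n−1) of all
quantified log2 ratios, with a median/1.4826·MAD robust variant off by
default.  The simulator's default ratio distribution N(−0.61, 0.795) is
back-derived from the cutoff pair (−2.2, 0.98) as its midpoint and
quarter-range, so simulated tables reproduce that cutoff regime; injected
outliers sit at ±4 SD with significant ANOVA p.  Under a clean normal null
the expected flagged fraction is the 2-SD two-sided tail times α
(≈ 0.0455 × 0.05 ≈ 0.23%), assuming independence of ratio and p.

## Numerical and interface choices

- Exact arithmetic is kept separate from display: "1 in N" strings round to
  one significant figure in a formatting layer only.
- Rarity filtering is strict (<), treats a missing MAF as 0 (novel allele
  passes, with a warning) and rejects negative MAFs.
- Missing annotation flags on a missense variant raise rather than silently
  failing the variant.
- A variant with zero genotyped carriers is excluded from the segregation
  partition (counted in a log line); a carrier of unknown affection forces
  the variant to `shared`.
- The burden contrast in the pipeline is computed among mtDNA carriers (plus
  the control group), matching a homoplasmic-family design in which the
  affected/unaffected contrast is between carriers.
- Problem sizes in tests and the acceptance script (1,000 null simulations
  at n = 22 vs 12; 10,000-draw Monte-Carlo thresholds; 5,000–10,000-person
  frequency-recovery cohorts) are chosen to pin the checked statistics well
  inside their 3-SE bands while keeping a full run in seconds.

## Known limitations

- No kinship-aware association testing; family data violate the
  independence assumption of all three comparison methods.
- The additive (cumulative-MAF) penetrance identification ignores diploidy
  and multi-carrier overcounting; it is reported as the convention of the
  analysis it reproduces, not as the preferred estimator.
- The synthetic proteome fixture supports machinery validation only (see
  above).
- Ascertainment correction for penetrance estimated from affected-enriched
  families is out of scope; population-wide and within-family penetrance are
  different conditional probabilities and the simulator exposes both without
  adjudicating.
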