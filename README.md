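# rircd — digenic mtDNA–nuclear modifier analysis

`rircd` is an analysis toolkit for a digenic-inheritance question in
mitochondrial disease: why does a homoplasmic mt-tRNA^Glu^ variant
(m.14674T>C-like, population allele frequency ~1×10⁻⁴) cause a severe but
spontaneously reversible infantile myopathy (RIRCD) in only a minority of
carriers?  The working model is a **second hit**: a heterozygous damaging
allele in a nuclear gene that services mt-tRNA^Glu^ (aminoacylation by
*EARS2*/*QRSL1*, thiouridylation by *TRMU*) or glutamate/glutamine metabolism
(*GOT2*, *GLS*), plus *MSS51*.  The package implements the quantitative
backbone of that analysis and simulators for every input, so the whole
pipeline runs end-to-end on synthetic cohorts.

It is aimed at statistical/population geneticists working on reduced
penetrance of homoplasmic mtDNA variants, and at anyone who needs the small
assay computations (ΔCt copy number, proteome ratio thresholding) in a
tested, scriptable form.

## What it computes

**Variant triage** (`rircd.variants`).  A variant is *potentially
pathogenic* iff its consequence class is loss-of-function (splice-site,
frameshift, stop gain/loss) or it is a missense call that is predicted
damaging, evolutionarily conserved and inside a known InterPro domain.
Qualifying variants are restricted to rare alleles (default MAF < 0.005) and
partitioned by whether all carriers are affected, all unaffected, or mixed.

**Allele burden** (`rircd.burden`).  Per individual, the burden is

    B_i = Σ_v g_iv + 1{mt carrier},   g_iv ∈ {0,1,2}

summed over qualifying panel variants; the homoplasmic mtDNA variant counts
as one allele.  Group means (affected vs unaffected carriers vs population
controls) are compared with a pooled Student's t (default), Welch's t, or a
seeded permutation test with p = (1 + #{|Δ̄_perm| ≥ |Δ̄_obs|}) / (1 + n_perm).

**Digenic risk arithmetic** (`rircd.digenic`).  With mtDNA allele frequency
f_mt (carrier frequency = allele frequency under homoplasmy) and a nuclear
carrier frequency c_nuc:

    P(both hits)   = f_mt · c_nuc
    penetrance     = c_nuc            (every double carrier is affected)
    prevalence     = f_mt · penetrance
    expected cases = prevalence · N

Carrier frequencies from per-variant MAFs come in three conventions:
additive (Σp, the cumulative-MAF convention), Hardy–Weinberg heterozygote
(1 − Π(1 − 2p(1−p))) and at-least-one-allele (1 − Π(1−p)²).

**Composition vs expression** (`rircd.composition`).  Exact Glu (E) + Gln
(Q) residue counts per mtDNA-encoded protein, and Pearson/Spearman
correlation of E+Q content with a per-gene expression-change metric.  The
packaged 13-protein FASTA is a **synthetic stand-in** (true lengths,
modelled E/Q composition) — see `docs/methods.md`.

**Assay models** (`rircd.assays`).  qPCR copy number per diploid cell
= 2·2^ΔCt with ΔCt = Ct(nuclear reference) − Ct(mt target); proteome
regulation cutoffs at mean ± 2 SD of all quantified log2 ratios, gated by
ANOVA p ≤ 0.05, unique peptides and quantification in all replicates.

**Simulators** (`rircd.synthetic`).  Seeded generators for pedigrees with
maternal mtDNA and Mendelian nuclear transmission, a digenic penetrance
model, population-control genotypes, composition-coupled expression, Ct
tables and proteome ratio tables.

## Worked example

```
$ python analysis/01_simulate_cohort.py --seed 1
simulated 19 families -> 76 individuals, 57 homoplasmic carriers, 19 affected
plus 1044 population controls; outputs in results/simulated/

$ python analysis/03_burden_comparison.py --seed 1
affected vs unaffected carriers: 2.32 vs 1.16 alleles, t = 8.43, p = 1.8e-11
affected vs controls: 2.32 vs 0.58 alleles, t = 10.41, p = 3.2e-24
null rejection rate at alpha=0.05: 0.040 (+/- 0.006, 1000 sims)

$ python analysis/04_digenic_risk.py
P(mt & EARS2 modifier)  = 1.35e-06 (1 in 700,000)
P(mt & common TRMU)     = 9.69e-06 (1 in 100,000)
prevalence              = 3e-05 (1 in 30,000)
expected cases (at 1/30,000, 66,000,000) = 2200
panel cumulative MAF    = 0.32
biobank mt MAF          = 3.06e-05
```

Reading: affected carriers average about one damaging allele more than
unaffected carriers (the nuclear second hit on top of the shared mtDNA
allele).  Co-occurrence of the mtDNA variant with a rare *EARS2* modifier is
~1 in a million; with the common *TRMU* allele ~1 in 100,000.  At 30%
penetrance among carriers the predicted prevalence is 1 in 30,000 — over
2,000 expected cases in a UK-sized population — and a biobank carrier count
of 11/358,916 gives an mtDNA allele frequency of ~3×10⁻⁵.

The same stages are available as a CLI (`rircd simulate|filter|burden|
digenic|composition|copynumber|proteome|run`); `rircd run --seed 1` writes a
combined JSON + markdown report.

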