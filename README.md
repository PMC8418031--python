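# polydose

Allele-dosage genotyping of polyploid plants from qPCR cycle thresholds,
with polysomic segregation analysis.

## The problem

In a polyploid, a biallelic locus has more than three genotypes: a tetraploid
with a dominant allele A and a recessive allele a can be AAAA, AAAa, AAaa,
Aaaa or aaaa, and presence/absence markers cannot tell the heterozygous
classes apart. Breeding programmes that work with triploids and tetraploids —
the motivating case is flesh color in loquat (*Eriobotrya japonica*), where
red is dominant (A) over white (a) — need the **allele dosage**, the number
of A copies out of the ploidy, to pick parents and predict segregation.

`polydose` implements a quantitative genotyping workflow that gets the dosage
from ordinary SYBR qPCR on genomic DNA, plus the population-genetic machinery
to test Mendelian segregation of the called genotypes in polyploid crosses.

## The model

Each sample is measured with three assays: a reference amplicon with one copy
per haploid genome (input normalization), an allele-A-specific amplicon, and
a combined amplicon hitting both alleles. Relative copy numbers come from the
2^−ΔΔCt method against a calibrator of known genotype (a heterozygous diploid
Aa by default), scaled so the calibrator reads a₁ = 1, a₃ = 2:

- a₁ — relative copy number of allele A
- a₃ — relative copy number of A and a combined; a₂ = a₃ − a₁
- **b = a₁/(a₁ + a₂)** — the relative allele-A signal, with expectation
  n_A/ploidy, the allele-A fraction of locus copies
- θ = tan⁻¹(a₂/a₁) in degrees — an equivalent angular statistic (0° pure A,
  90° pure a)

Genotype calling is nearest-class assignment of b on the grid
{0, 1/m, …, 1} at ploidy m. Class separability is quantified as in the
original analysis: complete-linkage (farthest-neighbor) clustering of b and
one-way ANOVA across dosage classes.

Segregation testing uses the polysomic (autopolyploid) inheritance model:
the number of A alleles in a gamete of ploidy g from a parent of ploidy m
with n_A dominant copies is hypergeometric,
P(k) = C(n_A, k)·C(m−n_A, g−k)/C(m, g). Offspring distributions are
convolutions of the parental gamete distributions; with complete dominance
(white ⇔ zero A copies) this gives expected red:white ratios per
progeny-ploidy class, tested with a Pearson χ² goodness-of-fit (df = 1, no
continuity correction).

A mixture simulator reproduces the study's validation design: gDNA from AA
and aa homozygote pools mixed at 13 ratios (9:1 … 1:9 plus the pure pools)
spans the dosage range, and synthetic qPCR plates are generated by inverting
the 2^−ΔΔCt model with Gaussian Ct noise.

## Worked example

Generate a synthetic run that mirrors the published germplasm panel
(8 tetraploids, 14 triploids, 3 diploids, Aa calibrator), then genotype it:

```bash
polydose fixtures --seed 5 --out fx
polydose genotype fx/plate.csv fx/samples.csv --out calls --seed 5
```

```
Allele dosage genotyping
========================
samples: 25    calibrator: CAL_Aa (Aa)
reference CV by ploidy: 2x: 0.23%, 3x: 0.22%, 4x: 0.28%   (all < 3%: yes)
concordance with known genotypes: 100.0% (25/25)

sample_id  ploidy     a1      a2      b   b_sd   theta genotype  residual  ambiguous        flags
     A313       3 2.0914  0.0383 0.9820 0.0158  1.0486      AAA    0.0180      False
     A322       3 2.0540 -0.0458 1.0228 0.0346  0.0000      AAA    0.0228      False  negative_a2
     K374       3 1.3591  0.6739 0.6685 0.0361 26.3762      AAa    0.0018      False
     B356       3 0.7309  1.3227 0.3559 0.0126 61.0764      Aaa    0.0226      False
     ...
```

Reading the columns: the reference assay is stable across ploidies (CV well
under the 3% acceptance bound), so per-haploid normalization holds. A313's
b ≈ 0.98 sits on the AAA class expectation 1.0 (residual 0.018); K374's
b ≈ 0.67 matches AAa (2/3); a slightly negative a₂ for an all-A homozygote
is retained and flagged, not clipped. All 25 calls match the generating
genotypes. The same command works on real instrument exports in the same
four-column plate format.

The mixture validation and a segregation test:

```bash
polydose simulate-mixture --ct-sd 0 --seed 1 --out mix
```

```
simulated 13 mixtures x 3 replicates (ct_sd=0.0)
b  vs allele-A fraction: R^2 = 1.0000 (slope 1.000, intercept 0.000)
theta vs allele-A fraction: R^2 = 0.9953
```

Noise-free, b is exactly the allele-A fraction (identity fit); θ correlates
strongly but not perfectly because arctan is nonlinear in the fraction.

```python
from polydose import SegregationAnalysis, datasets

results = SegregationAnalysis(datasets.f1_flesh_color_counts()).fit()
print(results.summary())
```

prints, per cross and progeny-ploidy class, the observed red:white ratio,
the model-derived expected ratio and the χ² test — e.g. for the
AAaa × aa triploids (66 red, 14 white): observed 4.71:1, expected 5:1,
χ² = 0.04, P = 0.84 — consistent with polysomic Mendelian segregation.

## Layout

- `polydose.qpcr` — Ct records, 2^−ΔΔCt quantification, signal scaling,
  reference-stability CV
- `polydose.genotypes` — allelic configurations, genotype calling,
  clustering/ANOVA separability
- `polydose.mixture` — mixture-library design, plate simulation,
  proportion-vs-dosage regression
- `polydose.segregation` — gamete distributions, expected ratios, χ² tests,
  ploidy tabulation
- `polydose.io` — delimited-text schemas, run configuration, fixture
  generation
- `polydose.model` — `DosageGenotyper`/`GenotypingResults` and
  `SegregationAnalysis`/`SegregationResults`
- `polydose.datasets` — the published loquat tables as analysis-ready inputs
- `polydose.cli` — the `polydose` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
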