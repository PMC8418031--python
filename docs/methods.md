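# Methods

## Relative quantification and scaling

The dosage estimate rests on three assumptions:

1. **Reference stability.** The reference amplicon occurs exactly once per
   haploid genome at every ploidy, so at equal DNA input its Ct is
   ploidy-invariant. `reference_stability` checks this empirically as the
   per-ploidy coefficient of variation of reference Cts, with a default
   acceptance bound of 3% (configurable via `RunConfig.reference_cv_threshold`).
   Under this assumption, 2^−ΔΔCt of a target against the reference measures
   target copies *per haploid genome*, which is what makes dosages comparable
   across ploidies.
2. **Shared amplification efficiency.** All assays amplify with the same
   per-cycle factor (default 2.0, i.e. 100% efficiency; configurable on
   `AssayPanel.efficiency`, range (1, 2]). The package does not estimate
   efficiency from standard curves; if the two allele assays differ in
   efficiency the b scale is compressed or stretched but the class ordering
   is preserved.
3. **Known calibrator.** The calibrator's genotype fixes the scale:
   per-haploid relative quantities are multiplied by the calibrator's known
   per-haploid allele copies, normalized so a heterozygous diploid calibrator
   reads a₁ = 1, a₃ = 2 against itself. Any calibrator carrying at least one
   A copy works; the heterozygous diploid is the default because it carries
   both alleles at equal dosage.

Replicates are aggregated by **averaging Ct before differencing** (not by
averaging per-replicate quantities). The two choices differ only at second
order in the Ct noise; averaging in Ct space is the package's fixed contract.
Per-replicate b values (calibrator held at its replicate-mean Ct) are still
computed to report the replicate scatter `b_sd`.

Derived statistics: a₂ = a₃ − a₁ exactly; b = a₁/(a₁+a₂) whenever
a₁+a₂ > 0, otherwise NaN with a `no_signal` flag; θ = arctan(a₂/a₁) in
degrees with the a₁ = 0 limit defined as 90° and the a₂ ≤ 0 limit as 0°.
Negative a₂ (the combined signal below the allele-A signal) is *retained and
flagged*, never clipped: over-unity b values are a real phenomenon in the
motivating data (red homozygous diploids averaging b = 1.31, plausibly from
copy-number variation at the locus), and the caller handles them by clamping
to the nearest extreme class. No correction for copy-number variation is
applied.

**Limit of detection.** A relative quantity below `lod` (default 1e−3 of the
calibrator signal) is treated as absent template and set to zero, with a
`below_lod_*` flag. This is how "no amplification" wells — which instruments
report at the cycle ceiling — map back to a clean zero dosage; it also means
the package cannot distinguish allele fractions below ~0.1% from zero, which
is far below any dosage class of interest at ploidy ≤ 8.

## Genotype calling

`call_genotype` assigns the configuration minimizing |b − k/m| over
k ∈ {0..m}. Ties at exact midpoints resolve to the **lower dosage** and set
`ambiguous=True` (tolerance `tie_tol`, default 1e−9). The full class set is
always available, including the all-recessive homozygote, even where a
germplasm collection happens to lack it. Calling is idempotent on expected
values at every ploidy and is verified against a brute-force scan.

Separability diagnostics deliberately mirror the validation analysis of the
original study design: agglomerative clustering with complete linkage on the
scalar b (Euclidean distance, deterministic relabelling by ascending cluster
mean), and one-way ANOVA across classes, with F reported as +∞ (flagged)
when the within-class variance is exactly zero rather than dividing by zero.
ANOVA and clustering accept replicate-level b values; whether one feeds
replicates or sample means is the caller's choice.

## The synthetic-data generator

`simulate_plate` inverts the quantification model: a well whose target
occurs c copies per haploid genome gets
Ct = base − log_E(c) + ε, ε ~ N(0, ct_sd²), with per-assay baselines
(reference 20.0, allele assays 22.0 cycles at one copy per haploid — arbitrary
but realistic values for ~100 ng gDNA input) and the instrument ceiling of
40 cycles for zero-template wells. Defaults:

| parameter | default | rationale |
|---|---|---|
| `ct_sd` | 0.05 cycles | keeps reference CVs ≈ 0.2–0.3%, comfortably inside the 3% stability bound observed for real plates, and gives b replicate scatter of the order seen in the published panel (sd ≈ 0.01–0.08) |
| `efficiency` | 2.0 | perfect doubling; the study reports the allele assays as "basically the same" efficiency without a number |
| `replicates` | 3 | the study's design |
| mixture ratios | 9:1, 5:1, 3:1, 2:1, 3:2, 1:1, 2:3, 1:2, 1:3, 1:5, 1:9 + two pure pools | the published 13-member library; 2:1/1:2 are triploid surrogates, 3:1/1:1/1:3 tetraploid surrogates |

Mass mixing is taken to equal copy mixing (the two pools are diploids of the
same genome size). The default fixture roster reproduces the published
germplasm panel: 8 tetraploids and 14 triploids with their marker-confirmed
genotypes plus one diploid per dosage class and an Aa calibrator.

What the generator does **not** emulate: pipetting error, efficiency drift
between assays or across the dynamic range, inhibitors, primer
cross-reactivity, and genome-size differences between mixture pools. Passing
tests therefore demonstrate correctness of the estimation and calling
machinery under the stated noise model, not robustness of the wet-lab assay
itself.

## Polysomic segregation model

Gamete distributions assume **pure random chromosome segregation** in an
autopolyploid: hypergeometric sampling of g of the parent's m locus copies,
computed in exact rational arithmetic (`fractions.Fraction`), so masses sum
to 1 exactly and are validated against explicit enumeration of all C(m, g)
subsets up to m = 8. Double reduction and preferential pairing are out of
scope: both are real phenomena in autotetraploids, but modelling them needs
a multivalent-pairing rate parameter for which no estimate is available here,
and the null model already reproduces every expected ratio used in testing.

**Gamete-ploidy allocation.** For a progeny class of ploidy n from a cross,
the lower-ploidy parent contributes its normal reduced gamete
(g = ploidy//2, so a diploid gives 1) and the other parent contributes
n − g. For a 4x × 2x cross this yields tetraploid gametes of ploidy 1, 2, 3, 4
for 2x, 3x, 4x, 5x progeny respectively — i.e. off-ploidy progeny are
attributed to aberrant meiosis in the tetraploid parent, including the
unreduced 4n gamete behind pentaploids. Other routes (e.g. an unreduced
gamete from the diploid side) are expressible through explicit
`female_gamete`/`male_gamete` overrides on `CrossSpec`. One consequence: for
AAaa × aa the model's expected ratio for 4x progeny is 1:0 (a 3n gamete from
AAaa always carries an A); a published table lists 1:1 for that class
without derivation, and this package reports the model's value, flagging the
impossible observation instead of adopting the unexplained ratio.

**Chi-square.** Pearson Χ² = Σ(O−E)²/E with E from the expected ratio scaled
to the observed total, df = 1, **no Yates continuity correction** — the
uncorrected statistic is the one that reproduces the published per-class
values. A class with expected probability 0 contributes nothing when its
observed count is 0 (flagged `degenerate_class`, P reported as 1); an
observation in a zero-expectation class makes the statistic infinite.
Pooled "Total" rows test the summed observed counts against the
class-size-weighted sums of per-class expected counts; ratios are displayed
normalized to smaller-side = 1 with at most two decimals, and empty classes
print "/" placeholders.

## Numerical and formatting choices

- Noise-free plates round-trip exactly: b − p stays within ~1e−15 of zero
  through the log/exp pair. Plate *files* store Ct to 4 decimals (instrument
  precision), bounding file-mediated round-trips at ~2e−5 on b — irrelevant
  against the minimum class spacing of 1/m.
- Percentages and ratio displays round to 2 decimals; one published ploidy
  percentage (83.63 for 46/55) appears to have been truncated rather than
  rounded, so comparisons against printed values are made to ±0.01.
- All randomness flows through `numpy.random.default_rng(seed)`; fixture and
  simulation outputs are byte-identical for a fixed seed, and every written
  file carries a provenance header (version, config hash, seed).
- Problem sizes in the test suite are the study's own: the 13-member mixture
  library, the 22-line polyploid panel, the 8 cross families; property tests
  scan all configurations to octoploid and use 10³–10⁵ Monte-Carlo draws.

## Known limitations

- Single biallelic locus only; no multi-locus or linkage analysis.
- No standard-curve efficiency estimation; efficiency is a configuration
  input.
- The caller is maximum-proximity, not probabilistic: it reports residuals
  and ambiguity flags but no posterior over classes.
- The segregation model omits double reduction and preferential pairing, and
  so cannot explain heterozygosity-transmission biases between reciprocal
  crosses; it tests conformance to the polysomic null only.
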