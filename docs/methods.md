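# Methods

## Scope and data model

`hsctrace` operates downstream of alignment, cell calling and cell-type
annotation: its inputs are integer cell × gene count matrices (Matrix
Market + TSV metadata, held in memory as `AnnData`), per-cell receptor
chains (AIRR Rearrangement TSV, as emitted at barcode level by repertoire
assemblers such as TRUST4), a sample design table (patient, timepoint,
donor/recipient sex, aGvHD grade, remission status) and qPCR Ct tables.
Read assembly, integration, clustering, doublet detection and cell-type
annotation are deliberately out of scope; lineage and subtype labels are
consumed as metadata. Timepoint labels are free-form and ordered by the
sample design (`Graft`, `D30`, `D100` by default), never hard-coded.

## Cell quality control

Two preset tiers of exclusive upper bounds, applied with strict
inequality: broad (`n_genes < 8,500`, `n_transcripts < 60,000`,
`pct_mito < 25%`) for a first cleaning pass and stringent
(`< 5,000 / < 15,000 / < 10%`) for per-lineage reanalysis. `pct_mito` is
computed on raw counts before any filtering. No lower bounds are applied by
default; configurable minima exist but default to 0. All-zero cells are
flagged, not errors. Survivorship is reported per sample and conserves
counts exactly (kept + removed = input).

## Normalization and module scores

Normalization is counts-per-10,000 followed by `log1p` — the ecosystem
default behind the umbrella term "log-normalization". Raw counts are
retained in a layer; marker positivity (any UMI, i.e. normalized value
> 0) is therefore invariant to the normalization target. Positivity was
chosen as the only parameter-free definition of a marker-positive cell and
is recorded in output metadata.

The module score of signature *S* in cell *c* is the mean normalized
expression over *S* minus the mean over expression-matched controls. Genes
are ranked by dataset-mean expression (stable sort) and cut into `n_bins`
(default 25) equal-size bins; for each signature gene, `ctrl_size`
(default 50) control genes are drawn without replacement from its bin with
a fixed, recorded seed. Signature genes are excluded from control pools
unless exclusion would empty a pool, in which case the whole bin is used —
this makes a signature spanning the entire universe score exactly zero and
keeps small fixtures hand-computable. Missing signature genes are dropped
with a warning rather than zero-filled (zero-filling biases the signature
mean). Binning is performed over the whole dataset jointly by default;
`per_sample=True` repeats binning and the control draw within each sample.
The construction matches the scanpy `score_genes` scheme, which serves as
an independent cross-check in the test suite; the implementation here is
self-contained so the control draw is exactly reproducible.

Sex scores are two module scores: the 16-gene Y-linked set and the
*XIST*/*TSIX* set. The *ADGRG1* feature is the module score of the printed
20-gene program (*ADGRG1*, *GZMB*, *FGFBP2*, *CX3CR1*, *GZMH*, *EFHD2*,
*GNLY*, *NKG7*, *SPON2*, *CLIC3*, *PRF1*, *FCGR3A*, *ZEB2*, *KLRD1*,
*TRGC2*, *S1PR5*, *CST7*, *SSBP3*, *TTC38*, *PLEK*).

## Demultiplexing gate

No numeric thresholds exist for the qualitative "low Y, high X" gate, so
they are calibrated from data: cells of sex-matched transplants form the
negative control population, and `τ_Y`/`τ_X` are its 0.1% / 99.9% score
quantiles (linear-interpolation order statistics). Detection of male
recipients of female grafts uses the mirrored rule (high Y, low X) with
quantiles mirrored internally, calibrated on female controls. Design
choices, all recorded in the gate provenance: cells meeting exactly one
condition are `ambiguous` and counted as donor (conservative); sex-matched
samples are undecidable and flagged; recipient calls in graft samples are
false positives by construction and excluded from compositions but always
counted. Calibration is global by default (a per-patient variant is a flag
away in scoring, not the gate). Manual threshold override is possible by
constructing a `ScoreGate` directly.

## Clonotypes

Clonotype key = (locus, CDR3 amino-acid sequence); V/J calls are carried
as annotation, with a strict (V, J, CDR3) key behind `strict_key=True`.
Only productive chains of cells present in the (QC-passed) metadata are
counted; a cell with several distinct productive CDR3s of one locus joins
each clonotype once, and the event is logged. Expansion ranking sorts by
size descending with lexicographic CDR3 tie-break (deterministic), pooling
samples by default — "top clones" of a patient's post-transplant
repertoire. Overlap is a set intersection of CDR3 keys; it is symmetric
and bounded by min(|A|, |B|), both property-tested. Receptor chains are
keyed per locus only; paired αβ clonotypes are not modeled.

## Statistics

- Paired t (df = n−1) and Welch t (Welch–Satterthwaite df) via scipy,
  two-tailed. A paired comparison with zero-variance differences has no
  defined statistic and raises `ZeroVarianceError`; table-level operations
  catch it and flag the row `untested` — a p-value is never silently 0.
- Mann-Whitney U: exact enumeration when both groups have ≤ 8 untied
  observations, otherwise the normal approximation with midranks and tie
  correction.
- Bonferroni: `min(1, m·p)` with the family = the subtype panel of one
  comparison; the family size is recorded per row.
- Fold changes of fractions/proportions use pseudocount ε = 1/(n+1), n the
  relevant cell denominator, recorded per row; swapping contrast arms
  negates log2FC exactly.
- The cytokine screen tests treated vs baseline fractions across donors by
  paired t (testing per-donor log2FCs against zero is available via
  `test_on="log2fc"`); significance in the volcano is uncorrected p < 0.05.
  Donors without a baseline sample are dropped with a warning.
- Pseudobulk aggregation sums raw counts per (sample, lineage) group and
  conserves per-gene totals exactly; model fitting (e.g. DESeq2) is left
  to external engines that consume the exported table.
- 2^−ΔΔCt: technical replicates are averaged per (sample, gene) first;
  ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the reference-group mean
  ΔCt (GAPDH and the non-aGvHD group by default), so the reference group
  has geometric-mean RQ = 1 by construction (asserted).

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline must
resolve, not transcriptome manifolds. Defaults are the study conditions:

- **Cohort**: 10 patients — 5 female recipients of male grafts, 4
  male-to-male, 1 female-to-female; 5 with aGvHD grade II–IV; 2 who later
  relapse. Timepoints Graft/D30/D100, complete for every patient (chosen
  for paired-test determinism; the real cohort had missing samples).
  1,000 cells per sample by default; 5% recipient cells in post-transplant
  samples.
- **Counts**: negative binomial with gene-level base means, global
  dispersion r = 10 and a log-normal per-cell library factor (σ = 0.35).
  No explicit zero inflation — dropout arises from low means. The universe
  is 2,000 background genes with log-normal means (median transcripts per
  cell ≈ 4,100, ≈ 1,200 detected genes — the order of magnitude of real
  data, which matters because expression-bin control noise scales with
  universe size), 10 mitochondrial genes (~5% of counts), the sex genes,
  *MDGA1* and the *ADGRG1* program.
- **Sex genes**: Y-linked genes have mean 1.5 per gene in cells of male
  origin and exactly 0 in female cells; *XIST*/*TSIX* have means 4.0/1.0
  in female cells and 0.0005 in male cells (ambient-level leak).
  `sex_effect_scale` multiplies all of these for effect-size sweeps.
- **Clones**: per sample and locus, cells partition into clones with
  rank-power-law abundances (weight ∝ rank^−1, mean clone size 3);
  zero-size clones do not exist. Follow-up clones persist from the
  patient's graft repertoire at clone level with probability 0.6 for
  TRB/TRD (drawn without replacement), structurally 0 for IGH — so the
  shared fraction of follow-up clones is binomial(n_clones, p), the oracle
  the tests use. Productive chain detection rate 0.7, plus a 3%
  non-productive extra-chain rate.
- **Group effects** (post-transplant samples only; the graft is donor
  material): *MDGA1* mean ×2 in lymphocytes of aGvHD patients; *ADGRG1*
  program means ×0.4 in lymphocytes of relapsing patients (on top of a ×4
  cytotoxic-subtype elevation); optional subtype-proportion multipliers
  per clinical group (e.g. Treg depletion).
- **Cytokine panel**: 12 donors × (PBS + 90 cytokines) × 3 cell classes ×
  2,000 cells, one sample per (donor, condition); each donor's baseline
  *MDGA1* mean (5% positivity) is drawn once with a log-normal donor
  effect (σ = 0.2) and shared between arms, so paired contrasts are exact.
  The panel matrix carries *MDGA1* plus a small background panel — enough
  for normalization and positivity, keeping 10⁷-cell panels tractable.

Everything is deterministic under a fixed seed, and the truth tables
(origin, origin sex, lineage/subtype, clone identity and persistence) are
sufficient to score every downstream call without re-derivation.

**What passing tests do and do not show.** The generator has no batch
effects, ambient RNA beyond the XIST leak, doublets, UMI saturation or
correlated gene programs; cell-type labels are exact. Recovery results
(e.g. recipient-call precision/recall ≈ 1 at default effect sizes) bound
what the method achieves when its model assumptions hold, not its
performance on real tissue.

## Operating characteristics of the screen

Type-I error is measured over independent single-cytokine replications
(each with its own donors and baselines) because in a shared-baseline
panel the per-cytokine tests are strongly correlated through the common
PBS samples — a single panel's hit rate is then a poor estimate of the
test's level. Measured at defaults: null hit rate ≈ 0.05 over 200
replications; a planted two-fold induction is detected (positive log2FC,
p < 0.05) in ≈ 100% of 50 replications with mean log2FC ≈ 0.95 (slightly
under 1 because positivity is a concave function of the underlying mean).

## Numerical conventions

Quantiles are linear-interpolation order statistics (`numpy` default).
Sorting is stable everywhere ties can occur; clone ranking breaks ties
lexicographically. All-zero cells normalize to all-zero rows and are
flagged. Scores are float64; an all-zero cell's module score equals minus
its control mean and is finite. Seeds: every stochastic component
(generator, control-gene draws) takes an explicit seed and is
byte-reproducible under it.

## Known limitations

Demultiplexing is undecidable for sex-matched transplants by design.
The gate quantiles assume the control population is large (≥ 100 cells
enforced; thousands recommended). The generator's group effects are
multiplicative shifts on named genes — adequate for positivity and score
statistics, not for DE-method benchmarking. Bonferroni families are
per-panel; no hierarchy across figures is modeled.
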