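# Methods

`lfqenrich` implements the statistical pipeline used to define a set of
proteins enriched in a purified organelle fraction from replicated label-free
quantification (LFQ) protein-intensity tables. The experimental layout it
models is a flow-sorted midbody-remnant fraction (MBR+) compared against
three controls — GFP-negative size-matched particles (MBR−), a
centrifugation-enriched fraction (MBRE) and total cell lysate (Total) — each
prepared by two routes (in-gel digestion; eFASP in-solution digestion) that
are analyzed separately, giving up to six MBR+ vs control comparisons.

## Processing model

1. **Identification filters.** Rows flagged as decoys, contaminants or
   "only identified by site", and proteins with fewer than
   `min_unique_peptides` (default 1) unique peptides, are removed. The
   surviving set is the MS-identified background used later for cluster
   over-representation.
2. **Quantified-value filter.** A protein is kept when at least one
   fraction × prep condition holds ≥ `min_quantified_per_condition`
   (default 2) observed values. The complementary reading (requiring two
   values in *every* condition) would leave no protein with an empty
   condition and the presence/absence rule below could never fire, so it is
   not used; the threshold is configurable.
3. **Log2 transform and median centering.** Observed intensities are
   log2-transformed (zeros are treated as missing beforehand, following the
   MaxQuant convention that a zero LFQ value means "not quantified"). Each
   sample is then shifted so that its median equals the mean of the
   per-sample medians of its condition. Any common per-condition target
   yields identical within-condition log-ratios; the mean-of-medians target
   makes the operation idempotent and keeps each condition's overall level.
4. **Presence/absence partition.** Per comparison, a protein quantified in
   ≥ `min_quantified_per_condition` replicates of one condition and never
   detected in the other is set aside as a presence/absence call
   (no p-value). Proteins detected on one side only but below the
   quantification threshold are discarded for that comparison; proteins
   with data on both sides are tested.
5. **EM imputation.** Remaining missing values in the tested block are
   imputed under a multivariate normal over the sample columns (proteins
   as independent observations) fitted by expectation–maximization
   (relative log-likelihood tolerance 1e−6, maximum 500 iterations, ridge
   escalation from 1e−6 × mean diagonal on a singular covariance). The
   default fill is a single seeded draw from the conditional normal of the
   missing coordinates given the observed ones, reproducing the stochastic
   behaviour of classical normal-model imputation; a deterministic
   conditional-mean mode is available. Observed cells are never altered.
   Imputation is fitted per comparison on the tested block only, mirroring
   the processing order (presence/absence set aside first).
6. **Fold-change gate.** Proteins with |log2 FC| < log2(1.3) are excluded
   from testing ("fc_filtered"). The gate is magnitude-based; the
   enriched-direction requirement is applied at set composition.
7. **Moderated t-test.** For each gated protein, the pooled two-group
   variance s²_g (d_g = n₁ + n₂ − 2) is shrunk toward a prior s0² with
   prior degrees of freedom d0 estimated by matching the first two moments
   of log s²_g under the scaled-F sampling model (trigamma inversion by
   Newton iteration). The statistic t = log2FC / √(s̃²(1/n₁ + 1/n₂)) with
   s̃² = (d0·s0² + d_g·s²_g)/(d0 + d_g) is referred to Student's t with
   d0 + d_g degrees of freedom (normal tail at d0 = ∞; ordinary pooled t at
   d0 = 0). Hyperparameters are fitted per comparison on the gated set.
8. **Adaptive Benjamini–Hochberg.** π0 is estimated by the robust
   mean-based estimator min(1, 2·mean p) (default) or the Storey λ = 0.5
   tail estimator, floored at 1/m to keep the adjustment defined, and the
   step-up adjustment p_adj(i) = min_{j≥i} min(1, π0·m·p(j)/j) is applied
   to the gated p-values. Proteins with p_adj < `fdr_level` (default 0.05)
   are significant; those additionally enriched toward MBR+
   (log2FC ≥ log2 1.3) are "significantly enriched".
9. **Merged volcano and enriched set.** Across comparisons, each protein
   is summarized by its maximum available log2 fold change and the Fisher
   combination of its available p-values (−2Σln pᵢ ~ χ²_{2k}); both are
   computed only from comparisons where data exist. A protein enters the
   enriched set if it is significantly enriched in ≥ 1 comparison
   (DIFFERENTIAL reason) or is quantified in MBR+ while absent from
   ≥ `absent_rule_min_controls` distinct control fractions (ABSENT_IN
   reasons; default 1, the stricter two-fraction variant is a
   configuration choice). Exclusive intersection counts of the
   per-comparison significant sets (UpSet semantics) and overlap fractions
   with external protein lists are exported alongside.
10. **Cluster over-representation.** Membership of the enriched (or any
    target) list in user-supplied functional clusters is tested against
    the MS-identified background with exact upper-tail hypergeometric
    probabilities. Multi-label proteins count in each cluster; raw
    p-values are reported (the display cutoff is a reporting threshold,
    not an adjustment).

## Synthetic data

The generator draws, per protein: a variance σ²_g from the scaled
inverse-chi-square prior s0²·d0/χ²_{d0} the moderated test assumes
(defaults d0 = 10, s0² = 0.0225, i.e. a typical replicate SD of 0.15 log2
units ≈ 11% CV with modest spread — the reproducibility expected of
repeated preparations of one cell pool on one instrument); a baseline
μ_g ~ N(25, 2²) in log2 units (a typical LFQ dynamic-range ballpark); and
per-sample log2 intensities μ_g + effect·[MBR+] + N(0, σ²_g). A fraction
`frac_enriched` (default 10%) of proteins draws a positive MBR+ effect
uniformly from [log2 1.3, 3]; a fraction `frac_absent` (default 3%) is
fully masked outside MBR+. Cells are then censored with probability
expit((21 − value)/1) — a left-censoring logistic placed 2 SD below the
baseline mean, the standard model of intensity-dependent non-detection in
LFQ — plus a completely-random missingness rate (default 2%). Raw-scale
values are 2^(log2 value) with missing cells encoded as 0 on export.

What the generator does *not* emulate: peptide-level quantification and
razor-peptide assembly, correlated (batch-like) sample effects, shared
peptides between protein groups, and abundance-dependent variance trends.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions, not performance on any real dataset.

Evaluation against truth counts a call as correct when the protein is
truly enriched, or truly absent-in-controls and called through the absence
branch; the differential-branch FDP is the fraction of truly-null proteins
among proteins carrying a DIFFERENTIAL reason.

## False-discovery behaviour of the gate-then-test design

Two properties of the emulated procedure are worth stating explicitly,
because the test suite measures both (problem sizes: 2000 proteins, four
fractions × 5 replicates, 50 replicate simulations):

- Within a single comparison, the FDP among significantly-enriched calls
  is controlled at the nominal 5% level (measured ≈ 2–3%).
- The union of calls across comparisons is *not* controlled at 5%
  (measured ≈ 8–9% over three comparisons at the default noise level, and
  considerably higher when the 2-replicate in-solution comparisons are
  included). Two mechanisms drive this. First, applying the 1.3-fold gate
  *before* testing selects exactly the null proteins whose fold-change
  estimates drifted ~3 SD from zero; conditional on passing the gate their
  p-values are small, and no subsequent step-up adjustment can screen
  them. Second, false calls are nearly independent across comparisons
  while true calls coincide, so the union multiplies false calls without
  multiplying true ones. Both are structural consequences of the
  gate-then-test-then-union design, not of the implementation; they
  disappear when replicate noise is small relative to the gate
  (per-replicate CV ≲ 7%).

## Numerical choices and edge cases

- EM starts from observed-column moments with a diagonal covariance; the
  observed-data log-likelihood is non-decreasing across iterations and is
  the convergence criterion. Rows or columns with no observed value are
  rejected rather than guessed.
- Variances equal to zero (possible for degenerate constant rows) are
  excluded from the prior fit with a warning; if the observed spread of
  log-variances is not larger than its sampling expectation, d0 = ∞ and
  the moderated test degenerates to a z-test against s0².
- Comparisons where fewer than two proteins pass the gate report statuses
  only, with a warning.
- p-values are clipped away from exact 0/1 only by floating-point
  underflow limits; adjusted p-values are exactly reproducible, and ties
  share an adjusted value.
- All randomness (generator, conditional-draw imputation) flows from a
  single integer seed; per-comparison substreams are spawned
  deterministically, so identical inputs and configuration give
  byte-identical output files.

## Known limitations

- Single imputation treats imputed cells as observations, understating
  uncertainty for proteins with many missing values — faithful to the
  emulated workflow, but a multiple-imputation extension would be more
  honest about variance.
- The normal imputation model ignores the left-censoring mechanism that
  generated the missingness (deliberately, to mirror the emulated
  procedure); imputed values for censored cells are biased upward, which
  slightly shrinks fold changes of low-abundance proteins.
- The absence branch has no error control: a protein can be "absent" from
  a control purely by censoring chance, and such calls are only bounded by
  the quantification threshold on the present side.
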