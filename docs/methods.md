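# Methods

## The attribution model

The pipeline treats receptor-specific signature discovery as a boolean
inference over a panel of cell lines. Its assumptions, in decreasing
order of importance:

1. **Known, binary receptor repertoires.** Each cell line either expresses
   a receptor (enough for signaling) or does not; intermediate expression
   is not modelled. The `derive_receptor_profile` helper thresholds
   receptor probe fluorescence into this binary matrix, but the threshold
   is a user responsibility (see *Numerical choices*).
2. **Penetrant, cell-autonomous responses.** A gene downstream of
   receptor R responds in every R-positive line; failure to respond in
   one positive line removes it from the signature (the intersection is
   an AND, not a vote).
3. **Fold change is the evidence.** A probe set is up-regulated in a line
   when mean treated / mean control fluorescence strictly exceeds 1.3.
   There is no variance model and no per-probe p-value: with duplicate
   arrays per condition the design has no power for moderated statistics,
   and the attribution rule, not the per-line call, supplies specificity.
4. **Unrelated lines cancel cell-type effects.** Requiring at least two
   positive lines from different cancers of origin (default
   `min_positive = 2`) makes a cell-type-specific response — present in
   one line only — ineligible, and at least one negative line
   (`min_negative = 1`) excludes ubiquitous ligand responses. A receptor
   whose presence pattern fails these rules, or duplicates another
   receptor's, is *not identifiable*; attribution refuses it unless
   forced, and a forced result is flagged as not receptor-specific.

The negative-line condition is "not up-regulated" (unchanged *or* down)
by default; a strict mode requiring "unchanged" exists for users who want
to exclude genes repressed through other receptors. The mirror analysis
on down-regulated calls is available via `direction="down"` but is off by
default: down counts are reported, only up genes are analysed.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `up_threshold` | 1.3 | fold | the stated calling rule; strict `>` (a fold of exactly 1.3 is unchanged — a `>=` rule would shift counts) |
| `down_threshold` | 1/1.3 | fold | only the up rule is stated; the reciprocal is symmetric on the log scale and exposed as a parameter |
| `floor` | 1.0 | fluorescence | both fold-change numerator and denominator are floored so background-level probes cannot yield infinite folds; floored probes are reported |
| `min_positive` / `min_negative` | 2 / 1 | lines | the identifiability rules above |
| presence threshold | 3 × 10th percentile of the line's probe distribution | fluorescence | no principled absolute cutoff exists for "expressed"; a background-relative default is used and always echoed in the design metadata |
| Dunn adjustment | Bonferroni over all k(k−1)/2 pairs | — | matches the common Prism behaviour; the method tag is stored so results are auditable |
| `exact_n_max` | 9 | samples | exact Spearman p by full n! enumeration up to 9! ≈ 3.6 × 10⁵ permutations; beyond that the t-approximation is accurate and enumeration is pointless |

Quartile stratification is rank-based with a fixed remainder rule: with
n = 4q + r, the r extra samples go to the lowest-labeled quartiles, so
n = 234 always splits 59/59/58/58 and sizes never differ by more than
one. Ties are broken by stable input order; a tied value spanning a
boundary triggers a warning, since its members' quartile labels are then
an artifact of row order.

Log2-scaled input (flagged by the reader, auto-detected for GEO Series
Matrix files) is un-logged at the fold-change step,
fold = 2^(mean_log_treated − mean_log_control), with no floor — log
values are already background-stabilised.

## What the simulator emulates — and what it does not

`simulate_attribution_dataset` plants `n_planted_per_receptor` genes for
every receptor with at least one positive line (disjoint sets). Control
fluorescence is `baseline_mean` (default 500 arbitrary units, a typical
mid-range array signal) times unit-mean lognormal noise with coefficient
of variation `noise_cv`; treated fluorescence multiplies in the
`effect_size` (default 2.0) in receptor-positive lines only. Each of the
`n_replicates` arrays (default 2, duplicate hybridizations) and each of
the `n_duplicate_probesets` probe sets per gene gets independent noise.
Optional `n_context_specific` genes respond in a single line, exercising
the min-positive-line guard. The default `noise_cv = 0.05` is a free
choice — replicate variance of the motivating arrays was never published —
representing tight duplicate hybridizations; the acceptance checks use it
as the study condition, not as a measured quantity.

`simulate_cohort` draws a bivariate Gaussian copula with Pearson
parameter r = 2·sin(πρ/6), which makes the *population* Spearman equal
the target ρ exactly after the monotone lognormal marginal transforms;
sample estimates at n = 234 scatter with SD ≈ 0.065. Marginal CVs default
to 0.8, a right-skew typical of normalized qPCR ratios across tumors.
`simulate_intervention` draws lognormal measurements at the stated group
means and common CV; n = 8 animals per group and CV 0.25 are free
defaults in the range such experiments report.

Real data differ in ways the simulator deliberately ignores: correlated
noise across probe sets on one array, intensity-dependent variance,
background regulation of unplanted genes (fold exactly 1 in expectation
here), partially penetrant responses, annotation gaps, and batch
structure in cohorts. Passing tests therefore demonstrate that the
*logic* is correct and calibrated under its own assumptions — not that
the thresholds are optimal for any particular platform.

## Numerical choices

- Fold changes, calls and attribution are exact boolean/ratio operations;
  the only tolerances in the test suite belong to sampling distributions.
- Kruskal–Wallis H comes from `scipy.stats.kruskal` (tie-corrected).
  Dunn's z uses pooled mid-ranks with the tie term
  Σ(t³−t)/(12(N−1)); with two groups and no ties it reduces exactly to
  the normal approximation of the Wilcoxon rank-sum test, which the suite
  verifies. All observations tied yields H = 0, p = 1 by convention.
- Exact Spearman p counts permutations with |ρ| ≥ |ρ_obs| − 10⁻¹² to
  absorb floating-point ties in the enumeration.
- The unpaired t-test is pooled-variance Student by default (a Welch flag
  exists, since real group variances often differ); zero variance in both
  groups with equal means returns p = 1 by convention and is flagged.
- Percent decrease is reported at full precision and additionally rounded
  to the nearest integer for display. On the published tumor-mRNA group
  means the computed value is 27.4%, which does not round to the
  originally printed 28%; the computed value is reported, never forced.
- Simulation is deterministic given the seed (`numpy.random.default_rng`);
  identical config + seed gives bit-identical tables.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at the study's stated scale where one exists (1000 genes with 50 planted
per receptor over the 3-line/4-receptor design; a 234-sample cohort) and
at small n for the enumeration/permutation oracles (n = 5 Spearman
enumeration, 10⁴-permutation Kruskal–Wallis oracle on 30 samples,
100–400 seeds for calibration rates). A full run takes well under a
minute on one CPU.

## Known limitations

- Binary presence/absence discards receptor dosage; a weakly expressed
  receptor in a "positive" line can silently empty a signature.
- The 1.3-fold rule with duplicate arrays has no error control per line;
  specificity comes only from the cross-line intersection, so with many
  lines the AND becomes conservative and with few lines it is permissive.
- Gene collapse counts *distinct annotated symbols*; unannotated probe
  sets are counted separately (never dropped), and whether a published
  distinct-gene count included them is generally unknowable.
- The exact reproduction of deposited-accession counts depends on the
  deposited scale (linear vs log2) and the flooring convention, neither
  of which is recorded with the data; the reader's scale flag lets both
  be tried.
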