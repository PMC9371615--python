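# Methods

## Data model and conventions

The pipeline's entry object is a phosphosite × sample intensity matrix in
the expanded-site-table convention: one row per (protein accession, residue
position, multiplicity) triple, so each phosphorylation multiplicity state
is an independent row. Raw intensities are arbitrary MS units; a cell that
is 0 or blank in the input table means "not detected" and is stored as
missing — never as a number — because the detection-pattern classification
and the MNAR imputation both need a real missingness concept. Rows flagged
as reverse decoys or potential contaminants are dropped at read time.
Tables are UTF-8 TSV with "." decimals, fixed so outputs are byte-stable.

## Preprocessing

Present intensities are log2-transformed and each sample column is centered
by subtracting the median of its *present* values. Using present values
only matters because missingness is abundance-dependent: including imputed
or zero-filled cells would drag the centers down by each sample's dropout
rate rather than its loading. Median normalization is idempotent and does
not change which cells are present.

Sample QC computes, for every included sample, the mean pairwise Pearson
correlation with all other included samples over pairwise-complete present
values. Pairs sharing fewer than 3 values are recorded as incomputable and
contribute nothing. The original analysis excluded one control sample "due
to poor correlation" without stating the metric or cutoff, so QC here is
deliberately flag-only (default threshold 0.7 on normalized log2 values,
both configurable); removing a sample is always an explicit configuration
action, which keeps the analysis decision auditable.

The validity filter keeps a site when at least one group has ≥ `min_valid`
(default 3) present values. It applies to post-exclusion included samples,
since the motivating study filtered after dropping the poor-correlation
replicate.

## Downshifted-Gaussian imputation

Missing log2 values in column *j* are replaced by independent draws from

    N( μ̂_j − downshift · σ̂_j ,  (width · σ̂_j)² )

with `downshift = 1.8` and `width = 0.3` by default, where μ̂_j and σ̂_j are
the present-value mean and sample SD of the column. Statistics are
per-sample by default (a `global` mode uses whole-matrix moments); the
per-column choice preserves column-wise MNAR semantics when samples differ
in depth. A column with missing cells but fewer than two present values
falls back to global moments with a logged note rather than failing, which
keeps sparse fixtures usable.

Randomness is governed by one mandatory master seed; each column's stream
is derived from (seed, sample id) via a CRC of the sample name, so results
are invariant to column processing order and identical seeds give identical
matrices. Present cells pass through bit-identical.

## Permutation-FDR two-sample test

Per site, the statistic is the pooled-variance two-sample t,
`t = (x̄₁ − x̄₂) / (s_p √(1/n₁ + 1/n₂) + s₀)`, with the SAM-style fudge
factor `s₀ = 0` by default. Reference two-sided p-values always come from
the t distribution at the unregularized statistic; significance never uses
them — it derives solely from the permutation FDR, matching the calling
criterion of permutation-based analyses. Zero pooled variance with zero
difference defines t = 0; with nonzero difference and s₀ = 0 the statistic
is ±∞ and ranks first.

Group labels are permuted over distinct assignments of samples to the first
group: exhaustively when the count C(n, n₁) is at most `exhaustive_below`
(default 1000 — a 4 vs 5 design has 126 labelings and is always
exhaustive, identity included), otherwise `n_perm` (default 250) uniform
random labelings excluding the identity. For each observed |t| taken as a
threshold (sites ranked by descending |t|, ties broken by row order) the
raw FDR estimate is

    mean over permutations of #{ permuted |t| ≥ threshold }
    ─────────────────────────────────────────────────────── , clipped to [0, 1].
              #{ observed |t| ≥ threshold }

Each site then receives the smallest raw estimate at its own or any weaker
threshold — a cumulative minimum taken from the bottom of the ranking — so
the reported FDR is monotone non-decreasing in rank, and a site is called
significant when that value is ≤ q (default 0.05). Because the permuted
distribution pools all sites, genuinely shifted sites contaminate the null
and the estimate is conservative; this is the standard behavior of the
construction, not corrected for here (no π₀ estimation).

## Presence/absence classification

A site is enriched in group A when detected in ≥ `min_in(A)` of A's
included samples and ≤ `max_out` of the other group's, and symmetrically
for B; defaults are `min_in = group size − 1` and `max_out = 1`, which with
4 vs 5 samples reproduces the literal thresholds (3–4 of 4 with 0–1 of 5,
and 4–5 of 5 with 0–1 of 4). Parameter validation requires
`min_in > max_out` in both groups so the two labels are mutually exclusive
by construction. Classification runs on the raw detection pattern before
imputation — imputation destroys the pattern — and independently of the
validity filter, whose ≥ 3 requirement the "in" thresholds already imply.
Because the row granularity is site × multiplicity, enriched counts are
reported both at row level and with multiplicity states collapsed, and
enriched rows collapse further to deduplicated protein sets.

## Term enrichment

Over-representation of a term annotating K of N background proteins, with k
hits among n selected, is the upper hypergeometric tail P(X ≥ k). The
background defaults to all proteins with at least one site passing the
validity filter; the correction is Benjamini–Hochberg over all tested terms
at α = 0.05. Both choices are declared package defaults — the original
network-tool analysis did not publish its background or correction — and
both are configurable. Only over-representation is tested. Annotations are
taken as given: no ontology-graph propagation.

## Synthetic data generator

Each simulated site i has baseline log2 abundance drawn from
N(`baseline_mean` = 23, `baseline_sd` = 2), values
`x_ij = baseline_i + effect_i·[j ∈ group B] + ε_ij` with measurement noise
ε ~ N(0, `residual_sd` = 0.5), and detection sampled from the logistic
model P(detect | x) = 1/(1 + exp(−(x − m)/s)) with midpoint `m = 20` and
scale `s = 1`; detected cells become raw intensity 2^x, undetected cells
are written as 0. At these defaults overall missingness is ≈ 12–15%,
concentrated at low abundance — the left-censoring that motivates
downshifted imputation. Group sizes default to 4 and 5 so the literal
presence thresholds are exercised. A fraction `effect_fraction` (default
0.1) of sites is shifted by `effect_size` (default 1.0 log2 units = two
residual SDs, random sign); a fraction `presence_absence_fraction` (default
0.05) is expressed in one group and placed at m − 6·max(s, 1) — below the
detection floor — in the other. An optional annotation model emits terms
whose members are drawn preferentially from affected proteins, for
enrichment-recovery tests. Site baselines, effects, classes, protein
assignments and detection are all driven by one seed; identical parameters
and seed give byte-identical tables.

What the simulator does **not** emulate: correlated peptides from shared
proteins, batch or run-order drift, intensity-dependent variance,
ragged multiplicity states, and non-Gaussian abundance tails. Passing
calibration tests on this generator therefore shows the statistical
machinery keeps its promises under its own assumptions, not that those
assumptions hold for any particular instrument run.

## Validation experiments

`phosphodiff.calibration` packages two self-checks. `fdr_calibration`
simulates replicate datasets at the defaults above (with the
presence/absence fraction set to 0, so ground truth is binary
null/shifted), runs filter → imputation → permutation test, and averages
the per-replicate false-discovery proportion (defined as 0 when nothing is
called). Across replicates the mean FDP sits at ≈ 0.04–0.05, within the
q = 0.05 target; per-replicate FDP is coarse because a 4 vs 5 design with
two-residual-SD effects yields only a handful of calls per 1000 sites — an
honest reflection of the low power of such designs, consistent with the
handful of statistically regulated peptides the motivating study reported.
`imputation_moments` masks half of a large Gaussian column and recovers the
configured downshift and width to two decimals. `scripts/acceptance.py`
re-runs both and writes the numbers as JSON.

## Numerical choices and edge cases

- Degenerate t statistics (zero pooled variance) are defined explicitly
  rather than propagating NaN; ±∞ sorts above every finite |t| and the
  threshold comparison `|t| ≥ threshold` treats ∞ ≥ ∞ as true.
- FDR thresholds are evaluated with sorted-array bisection; ties in |t|
  share one threshold count, and rank ties break by input row order so
  output is deterministic.
- The master seed must be below 2³¹; replicate seeds in the calibration
  experiment are derived modulo 2³¹.
- Problem sizes in the shipped tests (20 replicates × 1000 sites for
  calibration, 10⁵ values for imputation moments) were chosen as the
  smallest giving stable Monte-Carlo estimates at the asserted tolerances.

## Known limitations

- Exactly two groups; no paired designs, no covariates, no
  empirical-Bayes variance moderation.
- The permutation count is small in tiny designs (126 distinct labelings
  for 4 vs 5), bounding the resolution of FDR estimates at ~0.008.
- Protein collapsing is accession-based; no protein-group inference.
- Reproduction of the motivating study's exact significant-peptide count
  depends on its unpublished imputation seeds and permutation settings and
  is treated as approximate by design.
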