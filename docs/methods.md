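# Methods

## Experimental design being modeled

The pipeline targets a two-color microarray experiment in which tumor cells
are cultured at control pHe 7.4 and at two acidic pHe levels (6.8, mild
acidosis; 5.9, severe acidosis) in quadruplicate, and the question is which
genes each acidosis level induces or represses, how those gene sets overlap,
and whether the responsive genes carry prognostic weight in human tumors.
Inputs are assumed pre-normalized (contractor- or platform-normalized
intensities); no background correction or between-array normalization is
performed here, and vendor raw files are out of scope.

## Differential expression

Linear intensities are floored at ε (default 1.0) and log2-transformed; a
matrix can also be supplied already on log2 scale. The fold change of a
test condition against control is the **geometric-mean ratio**: the
arithmetic mean of log2 values per group, differenced and back-transformed.
Two-color array measurements are ratio data and downstream volcano plots
are in log2 units, so the log-scale mean is the natural estimator; an
arithmetic-mean ratio is available (`mean="arithmetic"`) for sensitivity
analysis. The flooring guarantees a positive control mean, so fold changes
are always finite and positive.

Per-gene testing is a two-sided pooled-variance Student's t-test
(df = n1+n2−2); Welch's form is available behind a flag. Degenerate rows —
both groups zero-variance — get p = 1 (equal means) or p = 0 (unequal),
with a flag rather than a silent NaN. No multiple-testing correction is
applied by default (volcano tables show raw p); a Bonferroni column
(factor = number of genes tested, capped at 1) is available.

Selection at threshold θ > 1 is boundary-inclusive: up-sets take FC ≥ θ,
down-sets FC ≤ 1/θ ("fourfold or more" / "fourfold or less"). The
comparison runs on log2 scale with an absolute tolerance of 1e-9 so a gene
whose true effect sits exactly on the boundary is not excluded by float
round-off in the group means. Selection is by fold change only; test
significance is not additionally required. Venn partitioning of two
same-direction, same-threshold sets is exact set algebra.

Top-N ranking (default N = 100 per direction) orders genes by |log2FC|
descending within a direction; ties break by smaller p-value, then
lexicographic gene symbol. The tie-break is a determinism requirement, not
a scientific claim — any stable rule would do.

## Signature comparison

External signatures enter as gene → {high, low} tables with a declared
universe; no re-analysis of the underlying datasets is performed. Ortholog
mapping is table-driven; when no table covers a symbol, an optional
fallback uppercases it (the common mouse→human symbol convention), and
unmapped symbols are reported, never silently dropped.

The 2×2 contingency counts signature-classified genes inside the up and
down sets (genes in neither set, or unclassified, are excluded — the table
has exactly the two modulated columns). Pearson's chi-squared with df = 1
is used without continuity correction by default (cell counts in this
application are large); Yates' correction is switchable. A zero margin
returns a degenerate flag instead of a statistic.

Rank concordance is Spearman's ρ between the reference ordering (position
in the descending signature list) and the log2 fold changes of the shared
genes (≥ 3 required), with a permutation p-value from ≥ 1,000 seeded
shuffles of the fold changes, two-sided with the (1+k)/(1+B) correction.

## Hit scoring

Prognostic annotations are categorical per (gene, tumor type): direction
∈ {unfavorable, favorable, none}, a significance flag, and an optional
effect magnitude ≥ 0 measuring distance from prognostic neutrality (e.g.
|HR−1| or a survival-difference fraction — the semantics belong to the
annotation source). This categorical operationalization matches
database-style survival annotation; no survival models are fit.

- **Strict hit**: induced gene with unfavorable-significant annotation, or
  reduced gene with favorable-significant annotation.
- **Inversion-tolerant hit**: the reverse direction, significant, with
  magnitude ≤ tol (default 0.20). The bounded quantity is deliberately
  pluggable (`inversion_predicate`) because "within 20%" admits several
  metrics; a reversed entry without a magnitude counts false with a
  warning. tol = 0 collapses tolerant onto strict whenever magnitudes are
  positive.
- Missing (gene, tumor) annotations count as non-hits but are tallied
  separately (`n_missing`, status "missing" in the hit matrix) so coverage
  bias stays visible.

Per tumor, strict and tolerant tallies are summed over the top-N induced
and top-N reduced lists; dominance is `induced_type` / `reduced_type` by
strict-majority comparison of the two strict tallies (margin configurable,
default 0 → ties are `balanced`). Tumors are ranked by strict total,
ties alphabetical. A gene's hit rate is its strict-hit count divided by
the number of tumor types evaluated; genes at rate ≥ 0.5 are carried to
stage-concordance counting, where an induced gene is concordant in a tumor
when its expression is significantly higher in late pathological stage
(reduced: lower), reported as k-of-n per gene.

## Synthetic data generator

`simulate_expression` draws per-gene baselines ~ N(baseline_log2_mean,
baseline_log2_sd), adds a planted effect ±effect_log2 in the conditions a
gene's class covers, and replicate noise ~ N(0, noise_sd_log2), all on
log2 scale (multiplicative on intensities, matching ratio-type array data).
Defaults are the study conditions: three pH conditions, n = 4 replicates,
effect_log2 = 2.0 (fourfold), and planted class counts
(up: 25 / 85 / 131, down: 63 / 118 / 82 for A-only / both / B-only)
mirroring the fourfold Venn structure of the acidosis experiment. Values
the design leaves open were fixed once at realistic levels: n_genes =
20,000 (the order of a 4×44K array after probe collapse), noise_sd_log2 =
0.25 (typical replicate scatter for normalized arrays), baseline
N(8, 2²) log2 intensity. Note the planted effect equals the fourfold
threshold, so under noise roughly half the planted genes cross the 4×
boundary — exact planted recovery is asserted on noiseless runs (or at the
2× cut, where the margin is 1.0 in log2 and the miss probability at the
default noise is negligible).

Annotation simulators are Bernoulli processes with planted per-tumor
concordance q: concordant-significant with probability q, otherwise
inverted-significant (with magnitude ~ U(0, 0.4)) with probability
`inversion_fraction`, else neutral; entries go missing at `missing_rate`.
Hit totals are therefore Binomial(200, q) and recovery is checked against
exact binomial intervals. The default tumor panel is the eight-type set
(breast, colorectal, prostate, gastric, liver, lung, head-and-neck,
melanoma). All generators draw from numpy `SeedSequence` substreams of one
seed, so runs are deterministic and components independently re-runnable.

What the generator does **not** emulate: array spatial artifacts, dye
bias, probe cross-hybridization, correlated gene modules, heavy-tailed
noise, or annotation errors correlated across tumor types. Passing tests
therefore demonstrate correctness of the computations and calibration
under the stated model, not robustness to real-array artifacts.

## Numerical choices and degenerate inputs

- Linear values < ε floored before log transform (warning-counted).
- Selection boundary tolerance 1e-9 on log2 scale (see above).
- Volcano −log10(p) capped at 300 for p = 0.
- Zero-margin contingency tables and zero-variance t-tests return flagged
  degenerate results instead of raising.
- Empty gene lists, empty annotations and unannotated tumors yield
  all-zero results, not errors.
- Permutation and simulation sizes in the test suite are scaled to run on
  a single CPU in seconds while keeping binomial/normal approximations
  comfortably valid; the acceptance script uses 20,000-gene matrices and
  10,000-gene null panels.

## Limitations

- Fold-change-only selection ignores variance; a gene with a large but
  noisy ratio enters the sets. This mirrors the modeled workflow; moderated
  (empirical-Bayes) testing is deliberately out of scope.
- The 20% inversion tolerance is a convention on an annotation-supplied
  magnitude, not an estimated quantity; conclusions drawn from tolerant
  tallies inherit whatever metric the annotation source used.
- The uppercase ortholog fallback is a heuristic; genuine one-to-many or
  renamed orthologs require a table.
- Chi-squared p-values assume independent genes; co-regulated modules
  violate this, so signature contingency p-values on real data are
  anti-conservative.
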