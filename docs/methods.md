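# Methods

## Model and assumptions

`eshrd` assigns each gene a cell-type specificity class from a cell-sorted
reference expression panel, then reads a bulk differential-expression (DE)
table through those labels. The core quantity is the per-gene, per-cell-type
enrichment score

    ES_c(g) = x_c(g) / mean_{c' != c} x_{c'}(g)

where `x` are the panel's fpkm values. ES is a pure ratio, so it is invariant
to rescaling a gene's row (sequencing depth, transcript length) and to the
ordering of cell-type columns. The classification assumes:

* the reference panel's cell populations are reasonably pure — residual
  contamination (e.g. the documented ~5% microglial content of OPC fractions
  in the source panel) is **not** corrected;
* relative specificity transfers across species when an ortholog map is used
  (one-to-one orthology is taken at face value; ambiguous many-to-many
  mappings are dropped rather than guessed);
* bulk DEG direction (sign of log2FC) is attributable to the labelled cell
  class — the concordance module exists precisely to check this against
  cell-resolved data.

## Classification rule and numerical choices

With `ES_high = max_c ES_c`, define H = {c : ES_c >= alpha_high * ES_high}
and L = {c : ES_c <= alpha_low * ES_high} (defaults 0.75 / 0.25). If H and L
cover all cell types the gene's label is H (cell-specific at |H| = 1,
multiple-cell-specific at |H| > 1); any ES strictly inside the open band
makes the gene *mixed*. Boundary values belong to H/L, making the three
classes a true partition; a gene whose every cell type is high (uniform
expression) is relabelled mixed, since "expressed everywhere" is the
operational meaning of that class. Ties at the maximum need no tie-break:
all tied cells are in H by construction.

Note a consequence of the geometry: raising `alpha_low` toward `alpha_high`
*shrinks* the strictly-interior band, so genes can only leave the mixed class,
never enter it; non-mixed labels are preserved exactly (H is unchanged and
H ∪ L only grows).

Degenerate inputs: values below the detection floor are raised to the floor
(default 0.1 fpkm) before scoring, so denominators are strictly positive;
genes at or below the floor in every cell type are removed beforehand, and a
filter that removes *everything* is an error (it signals wrong units).
Duplicate gene rows at ingestion and many-to-one ortholog collisions are
resolved by per-column arithmetic means (unbiased, order-independent), with a
logged warning; one-to-many ortholog entries duplicate the source row under
each target ID; duplicate gene IDs within one DE table are an error rather
than silently de-duplicated.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `floor` | 0.1 | fpkm | detection floor of the reference panel; also the positivity clamp before scoring |
| `alpha_low` / `alpha_high` | 0.25 / 0.75 | fraction of ES_high | the low/high thresholds defining the three classes |
| `fdr_threshold` | 0.05 | — | DEG selection, strict `<` |
| `n_perm` | 50,000 | draws | permutation count for the enrichment test |
| significance rule | 95% | fraction of draws | enrichment flagged when observed > resampled in ≥ 95% of permutations |
| sweep grid | 0.05 → 1.00, step 0.001 | FDR | 951 inclusive cutoffs for the concordance validation |
| log2FC cutoffs | 0, 0.25, 0.50, 1.00 | — | cell-resolved comparison without a p-value filter |
| low-support flag | n < 10 | genes | concordance points on fewer overlapping genes are flagged, not removed |

## Permutation enrichment

For each dataset and class, each of `n_perm` iterations draws |DEG set| genes
*without replacement* from the universe and counts members of the focal class
(a resample is a gene set, like the DEG set). The universe is the set of
genes in the DE table that received a classification — enrichment is relative
to what was measurable in that dataset, not to the whole reference panel.
The empirical p carries the +1 correction, `(1 + #{resampled >= observed}) /
(n_perm + 1)`, so it is never exactly zero; the significance flag applies the
separate ≥ 95% strict-greater rule and is recorded alongside p. Per-class
sub-seeds are derived from the master seed and a CRC of the class name, so
adding a class to a scan never perturbs another class's draws. As `n_perm`
grows the empirical p converges to the hypergeometric upper tail; the test
suite checks agreement within three Monte-Carlo standard deviations at
50,000 draws, and null calibration (uniformly drawn DEG sets flag ≤ 10% of
classes at the nominal 5% rule over 50 replicate scans).

## Concordance validation

The FDR sweep filters **both** tables at each cutoff by default (symmetric
treatment; `filter_side` can restrict filtering to one table), restricts to
the focal collapsed class, intersects, and computes the percentage of
same-sign log2FC pairs plus Spearman's rho (average ranks for ties,
two-sided p). Pairs where either log2FC is exactly 0 have no sign and are
excluded from the concordance denominator; a constant vector leaves rho
undefined (reported as missing, as is concordance on an empty overlap). The
|log2FC|-cutoff comparison filters only the cell-resolved table by effect
size, with no p-value filter, against the bulk table's focal-class DEGs.

## Synthetic data: what it emulates, what it does not

`generate_panel` plants genes on a constant background (1 fpkm):
cell-specific genes carry `specificity_fold` × background (default 50) in
their focal cell; multiple-cell-specific genes carry it in each member cell;
mixed genes carry it in one anchor cell plus a second cell solved (quadratic
in the score definition) to sit at exactly half of ES_high — the interior of
the mixed band. Class proportions default to a mixed-dominated panel (70%
mixed, the rest spread over singleton classes and one oligodendrocyte pair),
mirroring real brain reference panels where mixed is by far the most
prevalent class. Noise is multiplicative log-normal with coefficient of
variation `noise_cv` (default 0.2 — a realistic scale-proportional expression
noise level), mean-one so expectation is preserved; values are clamped at the
floor. With `noise_cv = 0` the construction is exact and classification
recovers every planted label — a green recovery test therefore establishes
the correctness of the scoring/classification pipeline, *not* robustness to
real-data features the generator omits: correlated noise across cell types,
heavy-tailed expression, compositional contamination between sorted
fractions, and ortholog-mapping error.

`generate_de_table` draws the DEG set uniformly from the classified genes
(optionally weighted per class to plant enrichment), assigns DEG direction
per-class by a Bernoulli `up_probability`, DEG magnitudes as
|Normal(1.0, 0.5)| log2FC, null log2FCs as Normal(0, 0.2), null p-values
uniform and DEG p-values from Beta(0.05, 1) — sharply sub-uniform, so nearly
all planted DEGs survive Benjamini–Hochberg selection at FDR < 0.05. The FDR
column is computed by the BH step-up rule (via statsmodels, verified against
a brute-force evaluation of the definition in the tests). The generator does
not simulate read counts, library-size effects or covariate structure: the
method consumes fpkm summaries and DE statistics, not reads.

## Design choices where the design was open

* **Floor filter** implemented as "all values ≤ floor" rather than exact
  equality with the floor — robust to panels whose unexpressed genes sit
  below, not at, the detection floor.
* **Permutation sampling size** is the full DEG-set size of the dataset, not
  the class-specific DEG count; the latter reading makes the comparison
  degenerate (a sample sized to the observation).
* **Sweep filtering side** defaults to both tables at the same cutoff;
  configurable because the symmetric choice is a convention, not a theorem.
* **UNCLASSIFIED DEGs** (absent from the classification table) are reported
  separately and excluded from prevalence denominators.
* **Low-overlap concordance points** are flagged, not dropped, so users see
  the full curve.
* **Uniform genes** are labelled mixed, not as an all-cell multi class.

## Known limitations

* No correction for reference-panel cross-contamination between sorted
  fractions.
* Ortholog-map version strongly affects the classified gene set; exact gene
  counts are not reproducible across map versions.
* The permutation test is one-sided (over-representation only).
* Probe-level microarray references are unsupported; the panel must be a
  gene-level non-negative expression matrix.
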