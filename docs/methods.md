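# Methods

## The swapping model

All methods in this package assume the free-index-primer mechanism of
barcode swapping: during flow-cell seeding, leftover sample-index primers
extend on cDNA molecules of other libraries, so each sequenced read
independently carries, with some probability f, a sample barcode other
than its own. Three consequences follow and are exploited separately:

* In plate experiments a read's identity is a (row barcode, column
  barcode) pair and a single swap changes exactly one of the two, so
  swapped reads from a library land preferentially in combinations sharing
  one barcode with it.
* In droplet experiments the cell barcode and UMI are attached inside the
  droplet and never free in solution; only the sample index swaps. A
  swapped read therefore keeps its (cell barcode, UMI, gene) identity
  intact and reappears under the same key in another sample.
* Double swaps (both barcodes, or two consecutive events) occur at order
  f² and are neglected everywhere, including in the simulators.

## Impossible-combination regression

With two plates of disjoint barcode sets, the impossible combinations form
a built-in negative control. For impossible combination t, the donor pool
for single swaps into t is A(t), the summed library sizes of expected
combinations sharing exactly one barcode with t. We fit

    observed(t) = intercept + m · A(t)

by OLS. An intercept is fitted deliberately: free-floating contamination or
low-level misassignment adds a roughly constant floor to every
combination, and the slope is robust to it; the intercept is reported as a
diagnostic. Combinations with A(t) = 0 stay in the fit — they constrain
that intercept.

The slope m is a *per-destination* rate. A read that swaps one barcode can
reach (R_total − 1) row-swap and (C_total − 1) column-swap destinations,
so under destination-uniform swapping the total swapped fraction is
f = m · D with D = (R_total − 1) + (C_total − 1), and the standard error
scales by the same D. D is recorded in the estimate's diagnostics so any
alternative destination convention can be converted after the fact. For
two 96-well plates (16 rows, 24 columns in total), D = 38.

The estimator is invariant to barcode relabelling and to uniform scaling
of all library sizes (both axes scale together), which the tests check
directly. It requires at least two plates, at least three impossible
combinations, and non-constant A(t); violations raise typed errors rather
than returning degenerate fits.

## Cross-platform model

When the same libraries are sequenced on a low-swapping and a
patterned-flow-cell machine, the reference run approximates the
pre-swapping truth. For each cell i on one plate we build three gene-length
predictors from the reference matrix — x_i (the cell itself), s_i (sum of
cells sharing exactly one barcode), n_i (sum of cells sharing none) — and
fit a single plate-level model pooled over all (gene, cell) observations:

    y(g, i) = a·x_i(g) + b·s_i(g) + c·n_i(g),   a, b, c ≥ 0,

by nonnegative least squares. Nonnegativity encodes that contributions of
reads cannot be negative and stabilises the near-collinear n_i term. The
plate's swapped fraction is the fitted read share contributed by other
cells, (bS + cN)/(aX + bS + cN), where X, S, N are the grand totals of the
three predictors. Before fitting, the reference matrix is rescaled so its
grand total matches the swapped matrix, which removes sequencing-depth
differences from the coefficient a.

The standard error is a nonparametric bootstrap over cells (default 200
resamples, seeded): cells are resampled with replacement, their fixed
predictor triples re-stacked and the model refit. Predictors are *not*
recomputed from the resampled plate — the bootstrap targets sampling
variability of the fit, not of the plate layout.

The model is identified only up to what the data constrain: if the
reference and swapped matrices are identical the unique solution is
(1, 0, 0) and the fraction is exactly 0; data generated exactly from the
model are recovered to numerical precision (both are test cases).

## Gene-wise swapping test

Per gene g, OLS across cells of y(g, i) on x_i(g) and s_i(g) — two terms,
no intercept and no n_i term, since no-shared-barcode contributions are
second order at the per-gene scale. The swapping coefficient is tested
two-sided (t, n − 2 df) and p-values are Benjamini–Hochberg adjusted over
tested genes. Genes with an all-zero reference profile, fewer cells than
parameters, or a rank-deficient design are reported untested rather than
silently dropped. A numerically perfect fit (residual variance below
10⁻¹² of the response scale) is resolved deterministically: the swapping
term is declared zero or nonzero by direct comparison instead of an
ill-conditioned t-statistic.

Calibration is verified under a homoskedastic Gaussian null, where the
t-test is exact; with heteroskedastic count noise the test is approximate,
which is acceptable for its screening purpose (counting affected genes).

## Free-barcode association

Per-plate swap fractions are regressed on the plate's free-barcode to
sequencable-cDNA concentration ratio (OLS with intercept, two-sided t-test
of the slope, ≥ 3 plates required). The result object stores the design
moments needed to reconstruct the 95% confidence band of the fitted line.
Concentration ratios are taken as given numbers; quantifying them from
electrophoresis traces is out of scope.

## Droplet methods

**Sharing test.** For each sample pair, the overlap k of observed barcode
sets (sizes n_a, n_b, pool N) is tested against the hypergeometric upper
tail P(X ≥ k) = sf(k − 1; N, n_b, n_a), BH-adjusted across pairs. The
pool defaults to the explicit whitelist size N = 737,280 (the standard 10x
cell-barcode whitelist); conditioning on N rather than on the union of
observed barcodes is the package default because the whitelist is known in
practice. Exact tails can underflow double precision at extreme overlap;
p-values are floored at the smallest positive normal double so the
(0, 1] invariant holds.

**Cell-exclusion cost.** Discarding every barcode seen in ≥ 2 samples
costs, in expectation, 1 − (1 − c/N)^(S−1) of all cell libraries: each of
the other S − 1 samples independently draws a given barcode with
probability c/N (draws are without replacement within a sample,
independent across samples). The Monte-Carlo counterpart draws the
barcodes explicitly (default 10 repetitions, seeded) and reports the mean
excluded fraction with its Monte-Carlo standard error, so agreement checks
are self-scaling. At S = 30, c = 20,000, N = 737,280 both give ≈ 55%.

**Molecule exclusion.** Molecules are grouped across samples by exact
(cell barcode, UMI, gene) identity; gene IDs are opaque and multi-mapped
molecules are assumed resolved upstream. Single-sample groups are
retained. In a multi-sample group with read shares f_s, if max f_s ≥
min_frac (default 0.8) the molecule is kept only in the argmax sample;
otherwise it is removed from every sample. min_frac ≤ 0.5 is rejected:
for min_frac > 0.5 the majority sample is necessarily unique (two samples
at ≥ min_frac would need more than the group's total reads), so no
tie-breaking rule exists or is needed. The boundary is inclusive — a
sample holding exactly 80% of reads at the default keeps the molecule.

The algorithm never alters a retained record's read count, never adds
records, and is idempotent (its output contains no multi-sample groups).

**Cleaning performance metrics.** Against simulator truth labels, *recall*
is the fraction of swapped-in records removed from their recipient sample
under either removal class; *precision* is, among records removed with an
identified majority origin elsewhere, the fraction truly swapped-in.
Removals of the origin's own record in unresolved groups are a deliberate
conservative discard — the algorithm is not claiming those records are
swapped — so they are reported separately (`removed_unresolved`) rather
than counted as classification errors.

**Cell calling.** A plain UMI-count threshold (barcodes with ≥ min_umis
distinct molecules). This is the thresholding component only; it does not
model the ambient-RNA profile of empty droplets and is not a substitute
for a dedicated empty-droplet caller in real analyses.

## Simulators

**Plate.** Each expected combination draws a true library size from a
negative binomial (mean 5208 reads, shape 5 → CV ≈ 0.45, chosen as a
realistic spread of per-well depths at ~10⁶ reads over two 8×12 plates);
reads are assigned to 100 genes with lognormal abundance weights. Each
read swaps with probability f (default 0.02, the patterned-flow-cell
regime); a swapping read picks its row or column barcode with equal
probability and replaces it with a uniformly chosen other barcode of the
same axis, on any plate. Reads are conserved, and swapped reads may land
in expected combinations of the same plate — only the cross-plate ones are
directly observable, exactly as in a real two-plate design. With equal
axis probabilities the per-row and per-column destination rates differ
slightly when R ≠ C; for the default geometry the induced relative bias in
the m·D estimator is ≈ 0.2%, far below its standard error, and the exact
destination convention is recorded in diagnostics.

**Cross-platform.** One plate's true counts are drawn per (gene, cell)
from a negative binomial (500 genes, mean 5 per gene-cell, shape 0.5,
≈ 2500 counts per cell); the reference platform reports them unchanged
(its own ~0.2% swapping is negligible against the ~2.3% signal), and on
the swapping platform each read moves with probability f to a uniformly
chosen cell sharing exactly one barcode. Swaps stay within the plate, so
the injected f is exactly the expected swapped fraction.

**Droplet.** Defaults are the validation conditions used throughout: S = 4
samples × 2000 cells drawing 16-mer barcodes without replacement from the
737,280-sequence pool; molecules per cell NB(200, shape 2); genes from a
1000-gene lognormal profile; 10-mer UMIs drawn uniformly (collisions are
allowed, aggregated and labelled — the cleaning algorithm must tolerate
them); reads per molecule 1 + Poisson(5), i.e. mean 6, a typical
sequencing-saturation regime in which most molecules are covered by
several reads. Each read swaps its sample label with probability f
(default 0.02), uniformly to another sample, keeping its molecular key.
Output records carry the origin sample and a swapped-in flag; when a
swapped-in read coincides with an existing record the merged record is
labelled by its largest contributor. `donor_frac` plants donor-only large
cells (barcode unique to sample 1, molecule count × 10) to reproduce the
artefactual-cell-library scenario; their recipient images carry ≈
(S−1)·(1 − (1 − f/(S−1))^r) of the donor's molecules.

What the simulators deliberately omit: biological covariance between
genes, ambient RNA and empty droplets, barcode sequencing errors, UMI
error collapsing, and any physical model of primer-extension kinetics.
Passing tests therefore demonstrate that the estimators and the cleaning
algorithm are correct under the stated swapping mechanism — not that they
are robust to every artefact of real data.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeds carried in
  config objects; identical config + seed reproduces output exactly.
* Counts are exact integers end to end; MatrixMarket files are written
  with the integer field so round trips are bit-exact.
* The UMI-threshold demonstrations use thresholds scaled to the simulated
  cell size (e.g. 50 UMIs against ~200-molecule cells), playing the role a
  1000-UMI minimum plays for real 10x cells an order of magnitude larger.
* Validation problem sizes — two 8×12 plates at ~10⁶ reads, 16 simulated
  plates for the cross-platform spread, 4 × 2000 cells for cleaning — were
  chosen as the smallest configurations at which each method's standard
  error cleanly separates the regimes being compared.
* Typed exceptions (`DesignError`, `FormatError`, `EstimationError`)
  distinguish invalid designs, malformed files and unidentifiable fits.

## Known limitations

* The m·D conversion assumes destination-uniform single swaps; strong
  destination preferences would bias the total fraction while leaving the
  per-destination slope interpretable.
* The cross-platform bootstrap resamples cells against fixed predictors;
  it underestimates uncertainty from the neighbour-sum construction itself
  on very small plates.
* The gene-wise test's t-statistics are approximate under count
  heteroskedasticity.
* The sharing test treats barcode draws as uniform over the whitelist;
  real whitelists have mild abundance biases that make the test slightly
  anticonservative at extreme sample sizes.
* Cleaning trusts exact key identity: sequencing errors in barcode or UMI
  split molecules and can hide swapped reads from the grouping; upstream
  error correction is assumed.
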