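# Methods

## Scope and model

`cotransmit` quantifies neurotransmitter co-expression in single-cell RNA-seq
count matrices by thresholding marker-gene expression. The procedure is the
one used throughout the re-analysis literature on dual-transmitter neurons:

1. **Normalization.** Counts are per-cell log-normalized:
   `x = ln(1 + c·s/T)` with scale factor `s = 10,000` by default. The
   logarithm is natural (the convention of this normalization; stated here
   explicitly because published methods sections often omit the base). Cells
   with zero total are mapped to all-zero rows rather than erroring, so
   degenerate inputs flow through. The transform preserves the zero pattern
   and is strictly increasing in the count within a cell, which is what makes
   threshold rules well-defined.
2. **Gating.** Neurons are selected by a boolean rule over per-gene
   thresholds (`nSyb > 1 and elav > 1 and Syt1 > 1`), or by an explicit cell
   whitelist for atlases whose neuronal set was defined upstream by
   clustering. Rules use strict `>` as printed; `>=` is available. Commas in
   published rule strings are accepted as synonyms for the adjacent keyword
   connective (`a > 1, b > 1 and c > 1` is a three-way AND); where a printed
   comma list reads most naturally as a union (the zebrafish and mouse
   neuron-selection rules, which enumerate the markers of *all* classes),
   the shipped fixture spells `or` explicitly and flags the interpretation
   in a comment. Genes absent from a matrix evaluate FALSE with a warning
   rather than erroring, because panels span genome annotation versions.
3. **Classification.** A cell is positive for a class iff ANY of the class's
   marker genes exceeds the threshold (default 1, on the normalized layer
   for real data). OR-over-markers is the semantics under which a partial
   panel — one marker missing from an older annotation — remains usable.
4. **Counting.** Per-cell class sets are tallied over the subset lattice in
   two conventions: `exclusive(S)` (cells whose set equals S; the UpSet bar)
   and `inclusive(S)` (cells whose set contains S; the way in-text dual
   counts are usually quoted). The two are connected by the superset-sum
   (zeta) transform and its Möbius inverse, implemented in O(k·2^k) integer
   arithmetic. Both are always reported with explicit column names because
   published figures and text mix the conventions silently.

The Möbius inversion doubles as a consistency check on published numbers:
inclusive counts are realizable by some cell population iff they are
monotone (S ⊆ T ⇒ inclusive(S) ≥ inclusive(T)) and every implied exclusive
count is non-negative. For the Ciona worked example (644 neurons; 495/152/19
per class; 134/18/2 pairwise; 2 triple) the inversion is non-negative with
exactly one glutamate-only cell and 130 cells outside all classes — whereas
an exclusive reading of the same numbers would force 19−18−2−2 < 0
glutamate-only cells. That arithmetic is what justifies treating such
in-text counts as inclusive.

Cross-dataset comparisons (larval vs adult brain, young vs aging brain) are
expressed as percentages of each dataset's neuron total. A two-proportion
normal-approximation confidence interval for the difference is emitted as
descriptive output only; the pipeline draws no automated inferential
conclusions from it.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `scale_factor` | 10,000 | per-cell normalization target (counts per `s` total) |
| `threshold` | 1 | expression cutoff for marker positivity |
| `layer` | `normalized` | which layer thresholds read (`counts` available) |
| gating rule | per dataset | boolean neuron-selection expression |
| case policy | exact, case-sensitive | gene-ID matching; optional case-insensitive switch |

Thresholds apply to the normalized layer by default because the published
`> 1` rules follow pipelines whose cell-selection reads log-normalized
data; the layer is configurable because methods sections rarely state it.

Marker panels are data, not code: YAML fixtures under
`cotransmit/panel_fixtures/` list each class's genes in
`"primary_id (alias1, alias2)"` notation, resolved against a matrix's gene
universe in order. The fixture files put the identifier the source matrices
actually carry first (e.g. `unc-25 (Gad)`, `dd_Smed_v4_12653_0_1 (Gad)`);
cross-class gene sharing is rejected unless explicitly allowed; a class
whose markers are all absent is excluded with a warning, never an error.
Aminergic subtypes (serotonergic, dopaminergic, tyraminergic/octopaminergic)
can be declared as separate classes and merged afterwards by a
class-group mapping; merging is a union over membership columns.

## Synthetic data: what it emulates and what it does not

The generator plants a class subset per cell (drawn from a prevalence table
over the panel's class universe, including the empty set) and draws each
gene count from a negative binomial: mean `mu_marker` (default 50) when the
gene's class is planted in that cell, `mu_background` (default 0.01)
otherwise; background genes (default 20) always use `mu_background`. The
dispersion parameter `r` (default 1) gives variance `mu + mu²/r`.
Independent Bernoulli dropout (default 0.05) zeroes entries post-sampling —
the simplest mechanism that stresses the OR-over-markers rule. The default
panel has 4 classes × 4 markers; 4 markers per class sits inside the 1–8
range of the real species panels and makes a planted class essentially
impossible to miss under strong separation (all four markers would have to
draw zero together, probability ≈ (1/51)⁴ ≈ 1.5e-7 at `mu_marker=50, r=1`).

Draws are made with `numpy.random.Generator` (PCG64, recorded in the truth
object) in a fixed order — one NB draw of the full cells × genes array in
row-major order (cells outer, genes inner), then one uniform draw of the
same shape for dropout — so a seed fully determines the dataset.

Deliberately **not** modeled: sequencing-depth / library-size variation,
batch effects, doublets, ambient RNA, gene–gene correlation. The most
consequential omission is depth: synthetic per-cell totals are ~50–600
counts, orders of magnitude below real cells. Consequently the
log-normalized scale is not calibrated the way it is for real data — with
`s = 10,000` and `T ≈ 200`, even a singleton background count maps to
`ln(1 + 50) ≈ 3.9`, far above a threshold of 1, whereas in a real cell with
`T ≈ 10⁴` the same singleton maps to `ln 2 ≈ 0.69`, below it. **Recovery
studies on synthetic data therefore threshold the raw count layer**, where
`count > 1` cleanly separates mean-50 marker counts from mean-0.01
background (P(background count > 1) ≈ 1e-4). This is a property of the
depth-free simulation, not of the pipeline: on real matrices the normalized
layer remains the default and the appropriate choice. Passing recovery
tests show the classification and counting machinery is exact and unbiased
under the planted model; they do not validate threshold calibration against
real sequencing depth, ambient contamination, or correlated dropout.

Recovery is scored per class (sensitivity, specificity), per subset
(planted vs called exclusive frequency), and overall (exact-subset
accuracy). Under dropout `d`, a class with `k` markers is called in a
planted cell unless all `k` marker draws vanish, so called inclusive
frequencies track `planted·(1−d^k)` up to the NB zero mass
`(r/(r+μ))^r` per draw; the test suite asserts agreement within 3 binomial
standard errors, pooling 10 simulation seeds (50,000 cells) so that the
check tests bias rather than single-seed noise. A never-planted class has
no meaningful thinning target (and a binomial SE of zero); its called
frequency is instead bounded by the analytic background-crossing ceiling
`k·(1−d)·P(NB(mu_background, r) > 1)` plus 3 SEs. Exact-subset accuracy of
1.0 is asserted only in the noise-free regime (`dropout=0,
mu_background=0`), where misclassification requires all four markers of a
planted class to draw zero simultaneously (~6e-4 expected events per
5000-cell dataset).

## Numerical and I/O choices

- Combination counting packs each cell's membership row into a bitmask and
  tallies with one `bincount`; the inclusive map follows by the superset-sum
  transform. Everything is `int64`; lattices are capped at 20 classes.
- Matrix Market triplet directories are read with orientation detection:
  the 10x dialect (genes as rows) is recognized by matching dimensions
  against the barcode/feature table lengths and transposed to the internal
  cells × genes orientation. Duplicate gene IDs are aggregated by summation
  (order-invariant, preserves totals) with a warning; duplicate cell IDs
  are an error. Dense delimited tables are supported with an explicit
  orientation flag.
- Tabular outputs are TSV, UTF-8, Unix newlines. Combination tables sort by
  descending exclusive count with lexicographic tie-break on the subset
  label; subset labels join class names with `+` in panel-declaration order
  and the empty set prints as `(none)`. Zero-count subsets are omitted
  unless explicitly present in the counts object; the empty set is always
  reported. Re-running a command with an identical configuration
  byte-reproduces all TSV artifacts.
- `ExpressionMatrix` is a thin container over `scipy.sparse` CSR with
  to/from `AnnData` converters for interoperability; the normalized layer,
  when present, must share the counts' zero pattern (enforced).
- Gating-rule parsing is a small recursive-descent parser with standard
  precedence (NOT > AND > OR, left-associative); syntax errors carry the
  character position. Each comma is replaced by the nearest following
  explicit connective at the same parenthesis depth (falling back to the
  nearest preceding one, then AND).

## Known limitations

- Reproducing published per-dataset counts end-to-end requires downloading
  the original atlases and, for several species, the authors' cell
  whitelists from upstream clustering; the package supports both inputs
  (accession-sized matrices, whitelist files) but ships neither. The test
  suite therefore validates the machinery on worked examples with printed
  inputs and on synthetic data.
- Thresholding is a deliberately simple classifier: no ambient-RNA
  correction, no doublet handling, no probabilistic assignment. Counts near
  the threshold are sensitive to normalization depth.
- Percentage comparisons between datasets are descriptive; the emitted
  confidence intervals use the normal approximation and ignore any
  cell-level dependence.
- Variable-gene selection, PCA, clustering and UMAP embedding are out of
  scope; matrices arrive at this pipeline after (or instead of) such
  preprocessing.
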