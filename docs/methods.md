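# Methods

## Model and scope

`gemtx` operates on constraint-based metabolic models: a stoichiometric
matrix *S* (metabolites × reactions), flux bounds *lb ≤ v ≤ ub* in
mmol·g⁻¹·h⁻¹, a biomass objective reaction, and GPR Boolean rules linking
genes to reactions. All optimization is standard FBA/FVA linear programming
(steady state *S v = 0*), delegated to cobrapy/optlang (GLPK backend). The
package's own contribution is everything around the LP: expression
thresholding, GPR-based gene mapping, the constraining strategies, and the
reporting analyses. Reactions are classified by their bounds as
*irreversible* (lb ≥ 0), *backward irreversible* (ub ≤ 0) or *reversible*;
this classification drives which bound an expression cap touches.

Model pruning (removing blocked reactions from the stoichiometry) is out of
scope: silenced reactions keep their rows and columns and only their bounds
go to zero.

## Thresholding

Gene status is a strict partition: every measured gene is exactly one of
*expressed* or *suppressed*.

- **Ties**: "above a threshold" is read strictly; a value equal to the
  threshold is not expressed. For LT2 the boundary values fall into the
  locally decided middle zone (boundaries inclusive to the middle).
- **Percentile globals** are resolved against the pooled expression values of
  *all* loaded samples (zeros included), with linear interpolation between
  closest ranks (inclusive, `numpy.percentile` default). One run therefore
  uses one resolved global, so classifications are comparable across samples.
- **Local thresholds** are the arithmetic mean of a gene's values over the
  same-phenotype samples in which it was measured; at least two samples are
  required, otherwise the classifier instructs the user to fall back to GT1.
  Locals are computed within a phenotype, never across phenotypes.
- **Fallbacks**: an LT1 gene above the global cutoff with no computable local
  threshold keeps the global decision (expressed); an LT2 middle-zone gene
  with no local threshold is called suppressed (the conservative choice —
  the middle zone is "possibly active" and without replicate evidence we do
  not promote it). The deciding threshold for every gene is recorded in the
  classification and exported to the report.

## GPR mapping

GPR strings are parsed with `and` binding tighter than `or`, case-insensitive
keywords, and arbitrarily nested parentheses (full recursion). The numeric
operators are defined **n-ary over flattened same-operator chains**:
`a and (b and c)` is one `and`-node over (a, b, c). For MIN/MAX/SUM this is
ordinary associativity; for the geometric mean it is a genuine semantic
choice, since a pairwise-nested GM is not associative — the flattened reading
is the one under which "the geometric mean of the AND operands" is well
defined. Duplicate gene ids inside a node are kept as written (this affects
SUM), because evaluation follows the model's GPR text verbatim.

Missing genes: by default an unmeasured operand is skipped (one unmeasured
isozyme does not nullify a reaction); a node with no measured operands, and
any reaction with an empty GPR, is *undefined* and never constrained. The
strict alternative (`missing_policy="undefined"`) makes any missing gene
undefine the whole rule. The geometric mean of a zero operand is 0 (the limit
of the formula); no epsilon is injected anywhere.

## Context-specific constraining

Mapped values are applied as **magnitude caps**, never as lower bounds:
irreversible `ub ← min(ub, v)`, backward irreversible `lb ← max(lb, −v)`,
reversible (all-reactions option only) both. Bounds therefore only tighten,
which gives two invariants the tests assert: every audited interval is a
subset of its predecessor, and the context FBA optimum never exceeds the
source optimum under the same medium. No unit conversion is applied between
read counts and mmol·g⁻¹·h⁻¹ — values are used verbatim, which is a
documented caveat of expression-as-bounds integration; a linear `scale`
factor (default 1.0) is exposed for users who have a calibration.

**Medium**: listed exchange bounds are set as given; with `close_unlisted`
every other exchange's uptake (negative lower bound) is closed while
secretion stays open. Command-line `--bound R:LB:UB` entries override file
values. The optional `growth_rate` row of a medium file is carried on the
`MediumComposition` object for user scripts; it does not itself constrain the
model.

**Growth-neutral deletion**: each suppressed gene is tested individually by
single-gene deletion against the medium-constrained wild type; a gene is
deleted only when its grRatio equals 1 within 1e−6. Deletion semantics are
Boolean: a reaction is blocked (bounds (0,0)) iff its GPR is unsatisfiable
with the deleted genes set false — one isozyme of an `or` pair never blocks,
any subunit of an `and` complex always does. Genes are tested independently
(mirroring the standard single-deletion screen), so two individually neutral
isozymes that are both suppressed are both deleted and jointly block their
reaction; this is intentional and covered by a test. Skipped essential genes
are audited.

**Minimum-growth option**: the phrase "minimum growth requirements" is
operationalized as follows (the design was genuinely open — literally
minimizing biomass yields 0 in any model with closable exchanges). An
auxiliary model with only medium bounds and growth-neutral deletions applied
is solved by FBA; growth is fixed at that optimum and each reaction's
requirement is its minimum attainable |v| there, read off FVA at fraction
1.0 (zero when the FVA range straddles zero, else the nearer range edge; the
magnitude, not the signed value, is used for backward-irreversible
reactions). A mapped cap is applied only when it is at least the
requirement; otherwise the reaction is left unconstrained and audited as
skipped. An infeasible auxiliary model raises a diagnostic listing the active
medium/deletion constraints.

## Analyses

- *Non-flux reactions*: FVA range entirely within ±1e−6 **and** an
  expression-derived audit cause (cap or deletion). The cause filter keeps
  structurally blocked reactions of the source model out of the report.
- *Rate-limiting reactions*: an applied expression cap equal (within 1e−6) to
  the FVA extreme in the capped direction — the transcriptome bound, not the
  network, limits the rate. Only reactions carrying an expression-bound audit
  entry are eligible.
- *Expression comparison*: ratio A/B per gene, first-listed dataset versus
  each other; a pseudo-count of 1 read is added to both sides whenever either
  value is zero (configurable); `min_fold` (default 1.0, i.e. any difference
  counts) gates the up/down call. Identical gene sets are required — no alias
  resolution, ids match case-sensitively.
- *Flux shifts*: per reaction, ratios of FVA minima and maxima (A/B) with the
  direction from the max ratio; a flux present (>1e−6) on one side only is
  `new` (in A) or `lost` (sentinel ratios ∞ and 0, so that swapping the
  phenotypes inverts every ratio).

## Synthetic data

The toy model generator emits a linear uptake→biomass chain (unit
stoichiometry, uptake capacity 10 by default) with optional redundant
parallel branches, an isozyme-gated step (`gA or gB`) and a complex-gated
step (`gC and gD`). Every generated model is valid and has a positive FBA
optimum, and every LP answer on it (bottleneck capacities, FVA ranges,
deletion ratios) is hand-computable, which is what the test oracles use.

The transcriptome generator draws per-gene counts from one of two log-normal
components — the standard shape for RNA-seq read counts — with defaults
meanlog 3 (low) and 7 (high), sdlog 0.5, three samples, and deterministic
labels (first half of the genes high). Separating the modes by ~1000× and
placing LT2 percentile globals in the gap recovers the planted labels
exactly; tests use this as ground truth. What the generator does **not**
emulate: library-size differences between samples, overdispersion beyond the
log-normal, correlated genes within pathways, or any coupling between a
gene's expression and its reaction's flux capacity. Passing tests therefore
demonstrate the correctness of the bookkeeping and the LP layer on separable
data, not biological recovery performance on real transcriptomes.

## Numerical choices

- Flux zero tolerance 1e−6 throughout (non-flux, detection limits,
  rate-limiting equality); grRatio neutrality tolerance 1e−6; GPR evaluation
  checked against the independent oracle at 1e−12 relative.
- FVA default fraction of optimum 1.0 (the usual flux-variability default),
  CLI-exposed via `--fraction`.
- The FBA flux vector is one optimum among possibly many; only the objective
  value is unique. FVA is used wherever alternate optima matter.
- Problem sizes: tests and the acceptance script run on toy networks of ≤ 7
  reactions and synthetic transcriptomes of ≤ 100 genes × 3 samples, where
  every expected number is hand-computable; the pipeline itself is
  size-agnostic (genome-scale models enter through the same SBML reader).

## Known limitations

- Expression values as flux caps inherit the unit mismatch discussed above.
- `.mat` models are not read; convert to SBML first.
- No MILP-based integration (iMAT/MADE-style), no model extraction
  (mCADRE/INIT-style pruning), no pFBA/MOMA/sampling, and no upstream
  RNA-seq processing or differential-expression statistics — inputs are
  assumed to be per-gene counts already matched to the model's gene ids.
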