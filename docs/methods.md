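# Methods

## Standardization model

Each prediction database evaluates miRNA–gene interactions on its own
scale.  The standardized evaluation is a linear map of the native value:

| database      | mode    | native range | scale | offset | evaluation |
|---------------|---------|--------------|-------|--------|------------|
| miRWalk       | binary  | —            | 1     | 0      | {0, 1}     |
| TargetScan    | binary  | —            | 1     | 0      | {0, 1}     |
| DIANA microT  | numeric | 0–1          | 1     | +0.5   | [0.5, 1.5] |
| miRDB         | numeric | 0–100        | 0.01  | +0.5   | [0.5, 1.5] |
| miRmap        | numeric | 0–100        | 0.01  | +0.5   | [0.5, 1.5] |

All constants are unitless.  Two modelling commitments deserve note:

* **The +0.5 offset applies only to listed entries.**  An absent pair
  contributes 0, not 0.5; otherwise the lower end of the overall-score
  interval (0, 39) would be unreachable.
* **Explicit non-predictions are kept** as evaluation 0 rather than
  dropped, so downstream consumers can distinguish "evaluated and
  rejected" from "never evaluated".
* **Duplicate (miRNA, gene, database) rows collapse to the maximum**
  evaluation: databases may list several binding sites per pair, and the
  evaluation encodes prediction strength, not site count.

Dialects are fully config-driven (delimiter, column names, mode, scale,
offset, native range) because export formats drift between database
versions; the stock dialects above are defaults, not assumptions.
Whether DIANA microT's native 0–1 score should also be rescaled before
the offset is not determinable from first principles; the default applies
scale 1, and the dialect config can override it.  miRWalk is treated as
binary (presence/absence) rather than via its own binding probability,
again overridable through the dialect config.  Score cells containing a
decimal comma are treated as unparseable rather than coerced: a
locale-mismatched export should trip the >50%-unparseable fatal check,
not be read as thousands-separated numbers.

## Name harmonization

miRNAs with identical mature sequence are one identity.  The canonical
key is the lexicographically smallest case-folded alias among **all**
names the sequence table assigns to that sequence — deterministic,
source-order independent, and stable across datasets in which some alias
never appears.  Without a sequence table, harmonization degrades to
case-folding; true typos are not repaired.  Applying the map is
idempotent, and alias merging re-deduplicates by the max rule, so record
counts never increase.

## Scoring and ranking

Per miRNA: gene score = Σ evaluations over databases; interaction score
I = Σ gene scores over the configured panel (six genes by default, giving
I ∈ [0, 39]); expression raw = Σ of normalized expression over the
configured regions (sum, not mean — a config switch allows mean);
expression score E = raw × factor, where the factor defaults to
0.4 × number of panel genes = 2.4; total T = I + E exactly.  Missing
expression data scores 0 with a warning rather than excluding the miRNA:
candidates with partial data remain ranked.  Scores are carried at full
float precision; printed reports round to two decimals, which is why
independently rounded components can disagree with their rounded sum by
±0.01.

Ranking is descending by T with deterministic tie-breaks (higher I first,
then lexicographic key); ranks are a gap-free permutation of 1..N.  The
top-k selection (default 10) is a pure prefix of the ranking.

## Relative quantification and group comparison

rq = 2^−(ΔCq − calibrator), ΔCq = Cq_target − Cq_reference (cycles).
Amplification efficiency is fixed at 2 per cycle (the Livak assumption);
no efficiency correction is estimated.  The calibrator rule defaults to
the per-assay mean of the control group's ΔCq, which makes the control
group's geometric mean rq exactly 1 — the natural anchor when the
question is case-vs-control; `global-mean` and `named-sample` rules are
available.  Subjects missing either Cq are excluded with a warning; an
optional replicate column averages technical replicates within subject
before analysis.  Cq values ≥ 40 cycles are flagged as near-undetermined
but not removed.

The D'Agostino–Pearson omnibus K² = Z_skew² + Z_kurt² is computed from
the standard transforms (D'Agostino 1970; Anscombe–Glynn 1983) with p
from χ²(2).  It is implemented directly because the scipy routine guards
an exactly-zero transformed skewness by substituting 1, which breaks the
identity Z_skew = 0 for perfectly symmetric samples; on any sample with
nonzero skewness the two implementations agree to 1e-8 (verified in the
tests).  Samples with n < 8 or zero variance are "not assessable"
(NaN, NaN), not an error.  The normality screen is reported but gates
nothing: the comparison is always the two-sided Mann–Whitney U test.

Mann–Whitney reporting follows the convention of common graphing
software: U = min(U₁, U₂) ∈ [0, n₁n₂/2].  p-values are exact (full null
distribution) when both groups have ≤ 8 observations and no ties, else
the tie-corrected normal approximation with continuity correction.  The
exact path is verified in tests against brute-force enumeration of all
C(n₁+n₂, n₁) rank assignments.  No multiple-testing correction is applied
by default — the intended use is an explorative screen — with
Benjamini–Hochberg as an opt-in.  Reported medians are medians of rq.

## Synthetic data

The generator emulates the three input kinds with known ground truth:

* **Exports** — each miRNA–gene pair is listed by a database with
  probability 0.15 (background) or 0.9 (planted regulators, default 5 of
  50 miRNAs); numeric native scores are Beta-distributed (background
  Beta(2,2), planted Beta(8,2)) rescaled to the dialect's native range —
  bounded and shape-tunable, matching score semantics.  Alias groups
  plant synonym sets sharing one 22-nt sequence.
* **Expression** — log-normal per region (meanlog 0.8, sdlog 0.6,
  unitless normalized scale), chosen so the two-region raw sum typically
  falls in the (0, 10) band of variance-stabilized brain values; 20% of
  miRNAs are missing entirely (the partial-data case).
* **Cq tables** — target Cq ~ Normal(28, 1) cycles per subject, with the
  case group shifted by −log2(fold change); reference Cq ~ Normal(20,
  0.1).  Noise is Gaussian on the cycle (log2-expression) scale, the
  standard qPCR error model, which makes fold-change planting additive.
  Default design: 20 cases and 20 controls.

Determinism: all randomness flows through seeded streams derived from the
manifest seed (one independent stream per output kind), so a given
(seed, manifest) pair reproduces byte-identical files.

What the generator does **not** emulate: sequence-determined binding
(scores are planted, not derived from seed matches), correlated errors
between databases, batch or plate effects in qPCR, and RNA-quality
covariates.  Passing recovery tests therefore show that the pipeline's
arithmetic and ranking recover a signal of the modelled form, not that
the score identifies true regulators in real data.

## Problem sizes

The default universe is 50 miRNAs (6 panel genes, 5 databases), which
keeps every property and recovery test fast while leaving ~250 scored
candidates' worth of records per universe; a `--full-scale` preset
generates 2511 miRNAs for full-scale runs.  The statistical guarantees
are measured at: 1000 null replicates (type-I rate), 200 planted-effect
replicates (power of a 2-fold change at Cq sd 1, n = 20/group), and 20
seeded universes for planted-regulator recovery.

## Known limitations

* The prioritization is a heuristic; component weighting (the 2.4 factor)
  is taken as given, and no claim is made that the two components each
  contribute 50% on any particular dataset.
* Frozen local exports only; no live database querying, and no
  cross-version miRBase accession lifting.
* Single-reference normalization; multi-reference geometric-mean
  normalization and efficiency estimation from standard curves are out of
  scope.
* The expression bound (0, 10) is an empirical property of the consumed
  table, not enforced.
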