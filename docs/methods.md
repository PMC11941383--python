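# Methods

## Model

The package implements fuzzy PROMETHEE: a PROMETHEE I/II outranking analysis
preceded by a fuzzy preprocessing step that converts linguistic evaluations
and weights into crisp numbers.

**Triangular fuzzy numbers and defuzzification.** A triangular fuzzy number
is stored as its three abscissae (lower, mode, upper) with
lower ≤ mode ≤ upper; the degenerate crisp case is allowed. The spread form
(N, a, b) used by the Yager index — peak N = mode, left spread
a = mode − lower, right spread b = upper − mode — is derived on demand, so
there is a single canonical storage form. The Yager index
(3N − a + b)/3 is algebraically identical to the centroid
(lower + mode + upper)/3; the test suite uses the centroid as an independent
oracle and checks the identity to 1e−12. Consequences relied on elsewhere:
the defuzzified value always lies within the support, symmetric triangles
defuzzify to their mode, and shifting all three abscissae by c shifts the
value by c.

**The linguistic scale.** The default five-level scale is
VH=(0.75, 1, 1), H=(0.50, 0.75, 1), M=(0.25, 0.50, 0.75), L=(0, 0.25, 0.50),
VL=(0, 0, 0.25), giving defuzzified values 11/12, 3/4, 1/2, 1/4, 1/12 —
strictly increasing from VL to VH. The scale is data, not code: a config
file may supply any term → triple mapping, and a term missing from the
active scale is a hard error, never silently imputed.

**Decision matrix.** An n × K grid of cells, each either numeric or
linguistic; mixed columns are permitted but the generator and fixture keep
each criterion homogeneous, as real decision tables do. Missing cells are
rejected at construction — the outranking formalism assumes a complete
matrix, and imputation would manufacture preferences. Each criterion carries
a direction (maximize/minimize), a weight (linguistic term or positive
number) and a preference-function spec.

**Weight normalization.** Linguistic weights are defuzzified and the whole
weight vector is divided by its sum. The normalization is a deliberate
design choice: it bounds the aggregated preference index π in [0, 1], makes
flows comparable across problems with different K, and is the standard
PROMETHEE convention. Under the packaged weight design (10 VH, 7 H, 3 M)
the normalized weights are 11/191 ≈ 0.05759 per VH criterion, 9/191 ≈
0.04712 per H, and 6/191 ≈ 0.03141 per M.

**Preference functions.** All six classical types are implemented (usual,
U-shape, V-shape, level, linear, Gaussian); only monotone non-decreasing
functions of the advantage d, with P(d) = 0 for d ≤ 0. The Gaussian type
1 − exp(−d²/2s²) is the default because it grades preferences continuously
instead of jumping between 0 and 1. Its spread defaults to "auto": the
sample standard deviation (divisor n − 1) of the criterion's resolved
column, re-estimated from whatever grid the engine is given. Auto spread
makes the analysis invariant to positive rescaling of any single criterion
column (d and s scale together) and, combined with differences d being the
only way data enter, to translation of any column. A constant column has
spread 0 and contributes zero preference everywhere, which is consistent:
all its pairwise differences are zero. The other kinds exist mainly because
hand-checkable examples and dominance arguments are much easier with the
usual function; explicit numeric s always overrides auto.

**Flows, preorder, ranking.** π(a, b) = Σ_k w_k P_k(d_k(a, b)) with zero
diagonal; Φ⁺ and Φ⁻ average the rows and columns of π over the n − 1
opponents; Φ_net = Φ⁺ − Φ⁻ sums to zero by construction (checked to 1e−9).
The PROMETHEE I partial preorder classifies each ordered pair: preferred
when at least as strong and at most as weak with one side strict,
indifferent when both flows tie, incomparable when the flows disagree in
direction; the converse of "preferred" is reported as "outranked" so the
relation grid is explicit from each row's perspective. Flow equality uses
an absolute tolerance of 1e−9 — exact float equality would make
indifference unreachable. The complete PROMETHEE II ranking sorts Φ_net
descending with competition ranks (ties share the better rank, stable in
input order, and are flagged). Unicriterion net flows
φ_k(a) = (1/(n−1)) Σ_b [P_k(d_k(a,b)) − P_k(d_k(b,a))] satisfy
Σ_k w_k φ_k = Φ_net (checked to 1e−9) and provide the per-criterion
strength/weakness profile.

## Sensitivity analysis

Targeted weight changes replace named criteria's weights and re-rank;
renormalization happens downstream, so a change that preserves all weight
ratios leaves the ranking untouched. The packaged replication experiment
sets six criteria — accuracy, diagnostic sensitivity, cost per instrument,
cost per run, throughput, loading volume — to High. The study design that
motivates this experiment describes the change as "Very High to High", yet
its own weight table already lists cost/run and throughput as High and
loading volume as Moderate; the experiment therefore implements "set these
six to High" regardless of prior value, which is the only reading
consistent with both statements. The sensitivity rerun re-estimates Gaussian
spreads from the (unchanged) matrix — a no-op, stated for completeness.

Rankings are compared by per-alternative rank displacement, the list of
pairwise net-flow order reversals, and Kendall's τ-b on the two net-flow
vectors (τ-b handles ties; the comparison is about order, not flow
magnitudes). Monte Carlo stability perturbs each normalized weight
multiplicatively by (1 + u), u ~ Uniform(−ε, +ε), renormalizes, re-ranks,
and tabulates rank frequencies; a single seeded generator per call makes
tables bit-reproducible.

## Synthetic data

The study structure emulated by the generator: 15 alternatives × 20
criteria, weight multiset {VH×10, H×7, M×3}, five minimized (cost-like)
criteria, and a roughly even split between numeric and linguistic columns
(`fraction_linguistic_cells` applies per criterion, since a qualitative
attribute is qualitative for every alternative). Numeric columns alternate
between lognormal draws (heavy-tailed, emulating instrument costs and error
rates) and uniform draws (bounded scores such as accuracy percentages);
linguistic columns draw uniformly from the five terms. These distributional
choices are assumptions — the original measurements, compiled from vendor
websites, were never published — so the fixture reproduces the problem's
structure (dimensions, labels, weights, directions), not its numerical
ranking, and no comparison against the published flow values is attempted
beyond their own printed arithmetic.

The packaged fixture names the 15 platforms after the published ranking
table and labels criteria C1–C20. The published criterion legend lists both
C10 and C12 as "cost per instrument" and omits mutation detection (which
the weight table lists as High); the fixture resolves the duplication by
assigning C12 to mutation detection ability, recovering exactly the 20
distinct weighted criteria. Directions follow the smaller-is-better
reading of the cost-like criteria: processing time/run, cost per
instrument, cost/run, error rate, and loading volume are minimized.

`plant_dominant_alternative` provides a recoverable ground truth: the
target becomes weakly best in every column (numeric cells pushed strictly
past the optimum by 5% of the column spread, linguistic cells set to the
best term) — dominance guarantees rank 1 under any positive weights and any
monotone preference functions, independent of weight perturbations. Passing
the planted-recovery tests therefore validates the engine's ordering logic,
not any claim about real sequencing platforms.

## Numerical and I/O choices

- Floating-point test comparisons use absolute tolerance 1e−9 unless a
  tighter identity (1e−12) is being asserted.
- Internal computation is full precision; reports round half-to-even to 4
  decimals at the presentation layer only, with a full-precision companion
  CSV for machine consumption.
- CSV dialect: comma-separated UTF-8, first column the alternative id,
  linguistic tokens case-insensitive among VH/H/M/L/VL and full words,
  surrounding whitespace tolerated. Cell parse errors carry row/column
  coordinates.
- Problem sizes in the test suite: 100 random matrices up to 8 × 6 for the
  oracle-equivalence and conservation suites, 50 seeds of the 15 × 20
  structure for dominance recovery, 200-draw Monte Carlo for
  reproducibility — sizes chosen so the whole suite runs in seconds while
  the brute-force oracle remains a literal, unvectorized transcription.

## Limitations

- The generator models no correlation between criteria; real platform
  specs are strongly correlated (e.g. throughput with output per run), so
  synthetic rankings are more "random" than real ones.
- Group decision-making (multiple decision-makers), PROMETHEE V/VI, exact
  weight-stability intervals, and principal-plane visualizations are out of
  scope.
- Fuzzy arithmetic beyond defuzzification (fuzzy addition/multiplication
  chains, trapezoidal memberships, alternative defuzzifiers) is not
  implemented: the method uses triangular sets and the Yager index only.
- The published flow values themselves are not reproducible from scratch —
  the underlying decision matrix is unpublished — so agreement with them is
  only checked where their own printed columns are internally consistent.
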