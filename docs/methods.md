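# Methods

## The transformation

An ordinal feature *x* of length *n* ≥ 2 over a totally ordered set is
encoded as the vector of all *m* = *n*(*n*−1) ordered pairwise comparison
outcomes: ascending (`<`), descending (`>`) or tie (`=`). Pairs are
enumerated by a column-wise scan of the *n*×*n* comparison matrix with the
diagonal skipped, the pair at position *j* being (*a_j*, *b_j*) =
(row, column); for *n* = 3 this gives (2,1), (3,1), (1,2), (3,2), (1,3),
(2,3). Any consistent enumeration would serve; this one is frozen because
it fixes the on-disk row order of transformed files. Whether matrix entry
(*r*, *c*) means "*x_r* versus *x_c*" or the reverse is equally arbitrary;
we compare *x_row* against *x_column*, and the two conventions give
mirror-equivalent frames that differ only byte-wise.

Both directions of every pair are stored. The redundancy (the state at
`swap(j)` is the mirror of the state at *j*) costs a factor of two in
memory but keeps the external contract simple — every object's pairs can
be read off contiguously per column block, Copeland scoring needs only
outgoing pairs, and merged frames stay rectangular.

Indices are 1-based in all file formats and 0-based internally.

### Ties and missing values

The tie state is the primary semantics (`tie_policy="keep"`): genuinely
indistinguishable values are informative. When ties are resolution
artefacts of the measurement instead, two remedies are provided: encoding
those comparisons as missing (`tie_policy="missing"`), or `jitter_ties`,
which adds uniform noise with amplitude one quarter of the smallest gap
between distinct values — strictly below half the gap, so every non-tied
relation is preserved exactly while tied values separate almost surely
(draws are repeated in the measure-zero event of a residual tie).

Missing input values propagate to missing pair states rather than
erroring; all information scores then use listwise deletion over the
variables entering the score (complete-pair or complete-triple analysis).
This is what makes scores on merged multi-batch frames automatically
restrict themselves to within-batch evidence.

Unordered categoricals carry no order to encode and are rejected with a
pointer to `expand_categorical`, which produces one 0/1
category-vs-other indicator per level (binary and ordinal features are
totally ordered already and transform directly).

## Information scores

All estimators are plug-in (maximum-likelihood) in natural logarithm, so
the closed-form statements hold verbatim: a tie-free transform has entropy
log 2 exactly (the pair states split evenly by antisymmetry); ties raise
the entropy up to log 3 — attained when the three states are equally
frequent, e.g. the balanced binary pattern at *n* = 4 — and further ties
lower it back towards 0.

Between two tie-free transforms, MI is an exact finite-sample function of
the Kendall τ, I_K(τ) = τ log √((1+τ)/(1−τ)) + log √(1−τ²), even in τ,
increasing for τ > 0 and capped at log 2. τ itself is computed through the
shared pair enumeration as (concordant − discordant)/*m* with tied (or
missing) pairs neutral — the tau-a convention, which coincides with the
classical coefficient on tie-free data, the only case the closed form
addresses. Against a binary feature the MI equals
2ab/(n(n−1)) · (A log(A/(1−A)) + log(2−2A)) in the AUROC A and class
sizes a, b; the endpoints A ∈ {0, 1} are evaluated as the continuous
limit 2ab/(n(n−1)) · log 2, and U = ab(1−A) links to the rank-sum test.
Both identities are verified to 1e−12 in the test suite.

Conditional MI is H(XZ) + H(YZ) − H(XYZ) − H(Z); joint MI treats a pair
of features as one variable; interaction information is defined as
I(X;Y) − I(X;Y|Z), so that synergy (conditioning reveals dependence) is
negative. MI, CMI and joint MI are clipped at 0 against floating-point
round-off; interaction information is signed and never clipped.

Quantisation baselines: equal-width splits [min, max] into *k* equal
intervals (last right-closed); equal-frequency cuts at the *i*/*k* sample
quantiles with linear interpolation (the convention of `numpy.quantile`),
collapsing duplicate edges under heavy ties. Equal-frequency labels are
invariant to strictly increasing transforms; equal-width labels are not.

## Inverse transformation

Copeland scoring: object *i* receives +1 for every ascending and −1 for
every descending pair (*i*, ·); objects ordered by decreasing score
recover the ranking. The direction is forced by the encoding — the
smallest value ascends in all its pairs and ends up with score *n*−1 — so
rank 1 is the smallest value. Tied scores share the minimum (competition)
rank, the convention of standard rank tests, so a recovered ranking is
comparable with `scipy.stats.rankdata(x, method="min")`.

Invalid pair vectors are never rejected: the transform is non-surjective,
so data assembled from predictions or edits can encode, say, a
three-observation cycle. Copeland scoring is the declared heuristic for
such inputs (the cycle collapses to all-equal ranks) and a validity report
— mirror consistency under pair reversal, acyclicity of the strict-order
digraph, missing count — is attached to every inversion. Graph-theoretic
consensus methods from social choice theory (Schulze, ranked pairs) could
recover richer structure from fuzzy inputs; they are out of scope here.

Fuzzy votes (per-pair probabilities of the three states, summing to ≤ 1
with the residual treated as missing) are scored as Σ (p_asc − p_desc)
over outgoing pairs. Rows are scored as given, without symmetrising mirror
pairs first: consistent inputs list both directions and are automatically
symmetric, and asymmetric inputs are genuine evidence we do not want to
average away silently.

## Batch merging

Frames transformed independently per measurement batch are merged by
concatenating observations (input order, for determinism), rebuilding the
pair index over the union, copying within-batch pair states and marking
every cross-batch pair missing — those order relations were never
observed. Per-batch strictly increasing dis-calibrations therefore leave
the merged frame bit-identical, and complete-pair deletion makes every
downstream score depend only on within-batch comparisons. Two batches of
18 and 19 observations yield 648 observed states out of 1332 rows (≈49%):
the price of integration is roughly half the pairwise information, not a
bias. Batch labels are kept per observation so inversion can be run per
batch; cross-batch rank imputation is deliberately not attempted.

## Ranking agreement

MI feature rankings are compared with a reference set *G* by the maximum
Jaccard index over all threshold cuts of the scores,
Jmax(G, s) = max_t J(G, {x : s(x) > t}). The sweep visits each distinct
score value, so tied features cross a threshold together — the strict
inequality makes this the exact maximum, which a naive top-*k* sweep can
miss. J(∅, ∅) is defined as 1 (two empty selections agree perfectly).

## Synthetic study designs

The generators are first-class, seeded, bit-reproducible code.

**Bivariate normal.** Standard normal marginals with correlation *r*
(Cholesky construction). The harness compares MI estimators — transform
MI, 3/5-bin quantisation (both binning flavours), and the Gaussian closed
form at the sample Pearson ρ — over a grid of *n* and *r* with 100
replicates by default, summarised as 5/25/50/75/95 percentile bands. The
expected transform MI at correlation *r* follows from Greiner's relation
τ = (2/π) arcsin *r*. Nearest-neighbour differential-MI estimators (KSG
and its local-nonuniformity correction) are published third-party methods
and are not reimplemented; the harness's estimator set is a strict subset
of the usual comparator panel.

**λ-mixture system.** Independent a, b, c ~ U(0, 1) and a decision
y = aλ + b(1−λ) (linear) or max(aλ, b(1−λ)) (non-linear), *n* = 200, λ on
a default grid 0, 0.1, …, 1. On the transformed system the harness
records I(A;Y), I(B;Y), I(A,B;Y), I(A;B|Y), the noise baseline I(A;C|Y)
and the interaction information I(A;B;Y). At λ = 0 the decision's
transform equals b's, so I(B;Y) = log 2 exactly. The asserted behaviour
is the conditional-MI dominance over the baseline and the joint MI
exceeding both marginals near λ = ½; the full interaction-information
curve is reported but its extremal λ is not asserted, since the
construction is symmetric under λ ↔ 1−λ while single realisations are
not.

**Batch dis-calibration.** A graded-relevance panel emulating a small
biomedical assay: 37 observations (a typical small-cohort size) and 20
features mixing the decision y ~ U(0,1) with independent noise at weak
weights spread over [0, 0.6], each feature warped by a random monotone
power (exponent log-uniform in [1/3, 3]) standing in for the
heterogeneous skewed scales of real measurements. The warps change no
pairwise-order quantity, but they make features respond differently to a
raw-value distortion — with identically distributed features a
multiplicative batch effect shifts all MI scores almost uniformly and
barely perturbs the ranking, which would make the comparison vacuous. Per
replicate the table is split in half, one half's features are tripled,
and the MI ranking against the decision is computed two ways: transform
the naively re-merged raw table, or merge the per-half transforms. Both
score vectors are compared with the undistorted reference by Spearman
correlation; over 20 replicates the merge-after-transform route wins
essentially always (median agreement ≈97% versus ≈92% for the naive
route in our runs), the directional result the merging scheme exists for.

## Problem sizes and numerical choices

Default experiment sizes (50 replicates at *n* = 100 for the bivariate
design, 50 at *n* = 200 for the multivariate one, 20 replicates of the
37×20 integration design, brute-force enumerations up to *n* = 7) keep
the full suite and the acceptance script in the seconds-to-minutes range
while leaving the asserted effects far from their decision boundaries.
The closed-form identities are asserted at 1e−12, i.e. floating-point
exactness, not statistical tolerance. All randomness flows through
`numpy.random.default_rng` seeds; experiment harnesses derive independent
child streams from a single seed.

## Known limitations

* The transform discards everything but ranking: non-monotone bivariate
  relationships (e.g. x versus x²) are invisible — by design, as the
  corresponding null is far more robust at small *n*.
* Pair states are artificially correlated across pairs sharing an
  observation; methods assuming i.i.d. rows (most learners, naive
  standard errors) need adaptation, and no significance calculus is
  provided here.
* Memory and time grow as *n*²; the implementation is aimed at the
  small-*n* regime (hundreds of observations), with no streaming path.
* Partially ordered value sets are unsupported; unordered categoricals
  must be expanded into indicators, which loses nothing for binary
  features but multiplies columns for many-level ones.
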