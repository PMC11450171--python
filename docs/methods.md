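# Methods

## The assay and its quantities

A paired-enhancer reporter screen fuses every ordered pair of candidate
sequences (5′ candidate — inert spacer — 3′ candidate) into a self-transcribing
reporter downstream of a core promoter. Transcription of each construct is read
out as UMI-collapsed RNA counts over input (plasmid) counts. All activities in
this package are log2 fold changes over the basal promoter output:

* **pair activity** — log2 RNA/input fold change of one construct, after
  normalisation and centring (below);
* **individual activity** — a candidate's mean pair activity across its
  combinations with robust negative controls on the opposite side. Because a
  control contributes no activation, these pairings isolate the candidate's
  own contribution.

## Quantification

Reads are assigned by direct end-matching: read 1 must match a construct's 5′
end forward, read 2 the 3′ end reverse-complemented, each within a Hamming
budget (default 3 substitutions per read; indels are not modelled because the
constructs are short, known and enumerable). A read matching two candidate
ends at the same minimal distance is ambiguous and dropped. UMIs are collapsed
by exact string identity per (pair, replicate, channel); collapse is
order-independent and UMIs containing N are discarded. Mismatch-tolerant UMI
merging is deliberately not the default: exact collapse is conservative and
reproducible, and the error regimes where network merging matters are outside
the simulator's scope.

Only heterotypic pairs with at least 5 input UMIs in **every** input replicate
enter the analysis; homotypic fusions confound the two positions and are
excluded.

## Activity normalisation

With a single pseudocount, per-sample size factors are computed by
median-of-ratios (the median across pairs of each sample's counts over the
per-pair geometric-mean reference). The pair activity is the mean over RNA
replicates of log2 normalised counts minus the mean over input replicates.
Because size factors absorb any global shift, the zero point is fixed by
subtracting one scalar so that control/control pairs average exactly zero —
the basal promoter defines zero activity. At least two replicates per channel
and at least one observed control/control pair are required.

**Robust controls.** Each negative control's mean activity over its
control/control pairs is standardised per side (sample SD, n−1); controls with
z outside [−1, 1] are discarded as occult actives. If the SD is zero all
controls are retained. Individual activities are reported only for candidates
with ≥ 10 robust-control partners on the relevant side.

**Active calls.** Per candidate and side, a 2×2 contingency table compares the
summed RNA and input UMIs of the candidate's robust-control pairs against
those of the (robust) control/control pairs; the one-tailed Fisher exact
p-value is the hypergeometric upper tail, corrected per side by
Benjamini–Hochberg. A candidate is *active* iff log2 activity > 1 **and**
FDR < 0.05. The exact contingency construction is a design choice (count-based
Fisher tests are the standard for reporter screens); it is isolated in
`activity.call_active`/`fisher_greater` so alternatives can be swapped. Note
that a one-tailed Fisher test of a table with identical row proportions is
*non-significant* (p ≥ ~0.5) rather than exactly 1; p = 1 arises when the
candidate row has zero RNA counts.

## Cooperativity models

For individual activities A (5′) and B (3′), with pairs containing any control
excluded:

* additive: P = log2(2^A + 2^B − 1). The log argument is clamped at 2⁻³⁰
  (with a warning) — reachable only when both activities are deeply negative,
  outside the modelled regime.
* multiplicative: P = A + B.
* fitted: OLS of observed on (1, A, B, A·B); adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = 3.

R² is defined as 1 − SS_residual/SS_total throughout. This is deliberate: the
ratio SS_regression/SS_total is non-negative by construction, yet fixed-law
predictions (not fitted to the data) can be arbitrarily worse than the
observed mean, which only the residual form expresses as a negative R².

In the best-model comparison, a pair counts as multiplicative-better iff
|obs − P_mult| < |obs − P_add| strictly; ties go to additive, which is
conservative against the super-additivity conclusion. The headline fraction is
computed over pairs whose members are both active (5′-active AND 3′-active).

**Saturation analysis.** Anchors are *weak* (individual activity in (1, 1.5])
or *strong* (above max(individual activity) − 1), on either side. For each
class, the mean observed pair activity is computed per partner; the
least-squares slope of that curve against partner activity is ~1 when fold
changes multiply freely and falls below the weak-anchor slope when the
promoter saturates. When the activity range is so compressed that the two
class definitions overlap, weak takes precedence (a "strong" anchor at
activity 1.2 is not meaningfully strong); in realistic screens the classes are
disjoint.

## Motif analyses

**Scanning.** PWM log2-odds scores against a background base composition are
discretised on a lattice of 10⁻⁴ log2-odds units. The exact null distribution
of the window score under i.i.d. background bases is computed by dynamic
programming over that lattice, and the match threshold is the smallest score
whose null exceedance probability is ≤ the p-value cutoff (default 5×10⁻⁴).
Both strands are scanned (the reverse strand via the reverse-complement
matrix, which makes scanning exactly strand-symmetric) and overlapping windows
count independently. For sharply peaked short matrices, no threshold may
achieve the cutoff except above the maximum score; in that case the maximum
score itself is used, so perfect consensus matches remain detectable —
the strictest achievable calibration. Zero matrix cells receive a 10⁻³
pseudo-probability before log-odds.

**Enrichment.** Per motif and candidate group, a two-tailed Fisher test on
(sequences with ≥ 1 match vs without) × (group vs random controls), BH-FDR
across all motif×group tests; motifs are kept iff any group FDR < 10⁻⁵ and the
motif has ≥ 5 total matches in the candidate pool.

**Combination grids.** For motifs (m, n), the *with* group is pairs whose 5′
member matches m and 3′ member matches n (binary "contains", not
count-weighted); the *without* group lacks both. The effect is mean(with) −
mean(without), for pair activity and model residual separately. A difference
of log2 means — not a ratio — keeps both effects on the same log2 axis.
Entries with fewer than the minimum pairs (default 5) in either group are
undefined (NaN).

**LASSO.** Features (motif counts, 5′ and 3′ blocks) are standardised to unit
variance within each training split; the penalty is selected from the grid
10^(2, 1.9, …, −3) by 5-fold inner cross-validation using the one-standard-
error rule (the largest penalty within one SE of the minimum CV error — chosen
for sparsity and stability; `selection="min"` restores the minimum-error
rule). Performance is the mean ± SD of R² over 9 non-overlapping outer folds;
reported coefficients come from a full-data fit at the full-data inner-CV
penalty, back-transformed to the original count scale with exact zeros
preserved. A constant target yields an intercept-only fit with CV R² reported
as 0 by convention.

## The synthetic-data generator

The simulator provides ground truth for every pipeline stage. Defaults are the
package's study conditions:

| parameter | default | units / meaning |
|---|---|---|
| n_enhancers / n_controls | 300 / 100 | pool composition |
| activity_law | Uniform(0, 4) | true enhancer log2 activities ("wide range"); controls exactly 0 |
| replicates | 2 input + 2 RNA | minimum the normalisation accepts |
| mean_input_depth | 100 | expected input UMIs per pair |
| nb_dispersion | 0.1 | NB dispersion d, variance μ + μ²d; d = 0 is Poisson |
| abundance_sd | 0.25 | log2 SD of log-normal library representation skew |
| noise_sd | model-specific | per-RNA-replicate biological log2 noise on pair activity |

Counts are negative binomial: input means are abundance × depth; RNA means are
abundance × depth × 2^(pair activity + noise). The dispersion default is a
judgment call (UMI-collapsed reporter counts are modestly overdispersed), not
an externally measured value. Biological noise is applied in log2 space,
matching the log-scale error term of the fitted model, independently per RNA
replicate.

Pair activities follow the configured regime. The **interaction** regime's
coefficient map β₀ + β₁A + β₂B + β₃AB describes how two *enhancers* combine;
pairs containing a control combine multiplicatively (the control contributes
0), keeping control/control pairs at the basal zero. This is the only
generative convention consistent with the assay's anchoring: activities are
*defined* relative to control/control pairs, so a regime that moved controls
off zero would make its own intercept unidentifiable after centring. The
**saturating** regime uses a smooth harmonic (soft-minimum) cap,
log2(2^(A+B)·2^cap / (2^(A+B) + 2^cap)): monotone in each argument, bounded by
the cap, and indistinguishable from multiplicative far below it. The true
saturation form in cells is unknown; any smooth saturating alternative would
serve equally.

The optional read emitter writes paired FASTQ with the UMI after the last ':'
of the read name, a configurable number of duplicate read pairs per UMI and
i.i.d. per-base substitution errors. It does **not** emulate PCR bias
chemistry, indels, quality-score structure, fragment-length variation or
flow-cell artifacts. Likewise the count model omits batch effects between
replicates and any sequence-driven activity (motif content and activity are
independent unless a test plants a signal). Passing tests therefore
demonstrate correctness of the inference machinery under the stated
statistical model — not robustness to every artifact of real screens.

## Numerical and scale choices

* All simulations are deterministic given a single integer seed; byte-identical
  count tables and FASTQ follow from identical configurations.
* Test and demonstration problem sizes (150–300 enhancers, 60–100 controls,
  depth ~100) were chosen as the smallest screens at which individual-activity
  estimation, regime discrimination and coefficient recovery are
  well-conditioned; the design enumeration itself is exercised at the full
  1000-candidate, 10⁶-pair scale.
* OLS is rank-checked before fitting and rejects collinear designs naming the
  offending columns; fits are validated in tests against explicit
  normal-equations solutions.
* Fisher p-values are hypergeometric tail sums (validated against exhaustive
  enumeration); an empty table returns p = 1.
* Motif paste/mutate variants use rejection sampling against the forbidden-PWM
  set with a configurable attempt budget (default 1000); overlapping match
  intervals are merged before replacement so the result is order-independent.

## Known limitations

* Individual activities inherit a small attenuation from measurement noise in
  the control pairings (error-in-variables); at the default depth and control
  count the bias on fitted coefficients is ≪ 0.01.
* The fold-change estimator is the explicit pseudocount/median-of-ratios mean
  — not a shrinkage estimator; very low-count pairs are noisy and are handled
  by the input filter rather than by moderation.
* The Fisher-table construction for active calls and the exact UMI-collapse
  policy are documented interpretations with clean seams for substitution.
* Reported empirical numbers (worked example, acceptance output) come from the
  synthetic generator; real screens add artifacts the generator does not model.
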