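# Methods

## Model

The 2-HT eyewitness identification model is a multinomial processing tree
over the three observable outcomes of a simultaneous six-member lineup
(suspect selection, filler selection, rejection), with separate trees for
culprit-present and culprit-absent lineups. Four latent probabilities
drive both trees: detection of culprit presence `dP` (yields a culprit
identification), detection of culprit absence `dA` (yields a rejection),
biased suspect selection `b` (operates when detection fails; captures
lineup unfairness), and guessing-based selection `g`, which lands on the
suspect with the random-sampling probability `c = 1/lineup size` and on
some filler with `1 − c`. All parameters are probabilities in [0, 1].

`c` is stored as the literal decimal 0.16667 rather than 1/6. The
analyses this package reproduces used that rounded constant, and the
difference (2/3 × 10⁻⁶) propagates into third decimals of G² on real
sample sizes; bit-compatibility with the published fits takes precedence.
`c` is configurable for other lineup sizes, but degenerate values 0 and 1
are rejected — no real lineup concentrates all or none of the guessing
mass on the suspect.

A multi-condition model instantiates one tree pair per experimental
condition and expresses equality constraints (e.g. "`b` equal across all
conditions") by mapping each (parameter, condition) slot to a shared
free-parameter index; slots may instead be pinned to constants. Index
assignment is deterministic — parameters in the order dP, dA, b, g,
conditions in declaration order — so fits are bitwise reproducible.

Both experiments' base models equate `b` and `dA` across conditions.
The four-condition experiment states it uses the same constraints as the
two-condition one; we take that to include the same constant c = 0.16667
(both experiments used six-member lineups, so no other value is
plausible).

## Estimation

Counts are pooled per condition × tree and treated as independent
multinomials; the log-likelihood kernel omits the count-only multinomial
coefficient. Maximization runs L-BFGS-B on the box [1e-9, 1−1e-9]^k from
10 starting points (0.5 everywhere, plus 9 seeded uniform draws on
[0.05, 0.95]), keeping the best converged solution; objective tolerance
1e-14, gradient tolerance 1e-12. These problems are small (≤ 10 free
parameters) and, on all data sets examined, unimodal — the multi-start
grid guards against ridges introduced by equality constraints, and a
dedicated test checks that 10 different seeds agree in log-likelihood to
1e-8.

Goodness of fit is `G² = 2·Σ n·ln(n/(N·p̂))` over cells with n > 0
(zero cells contribute 0, the n·ln n → 0 limit), with
df = #cells − #trees − #free parameters and an upper-tail χ² p-value;
df = 0 is reported as p = 1. Standard errors are square roots of the
diagonal of the inverse observed information, where the Hessian of the
negative log-likelihood is computed by central differences with step
1e-5 (estimates nudged inside the box first). If the smallest Hessian
eigenvalue falls below 1e-6 of the largest — a threshold above the
finite-difference noise floor (~1e-7 relative) but below any genuinely
informative direction — the information matrix is treated as singular:
SEs come back NaN with a warning, point estimates stand. Estimates
within 1e-6 of a bound are flagged as boundary solutions; their Wald SEs
are only approximate. In the two-format experiment `dA` ≈ 0.03 with
SE 0.04 sits near (not on) the boundary; it is flagged-adjacent but
interior, and we report it as published rather than censoring.

Whether the original analyses' SEs used observed or expected
information is not documented; observed information reproduces every
published SE at two decimals, which is as far as the comparison can go.

## Nested tests

Hypotheses on the latent processes are ΔG² likelihood-ratio tests: add
an equality constraint, refit, compare. The restricted model is fitted
fresh but additionally seeded with the general solution collapsed onto
the constraint (group means), which prevents spurious positive ΔG² from
an unlucky restricted start. ΔG² in (−1e-6, 0) is clipped to zero;
anything more negative raises an error rather than being silently
clipped, since a nested model genuinely fitting better can only mean the
general fit failed. The four-condition analysis follows the published
two-step sequence exactly: first equate `dP` across the three conditions
where contextual cueing is theoretically impossible (Δdf = 2), adopt
that as the augmented base model, then test the focal combined/
three-culprits condition against the pooled rest (Δdf = 1). The g
homogeneity statistic is computed from the fully-dP-pooled model; this
reproduces the published ΔG²(3) = 6.70 (running it from the base model
instead gives 6.44 — the sequence matters and ours matches the source).

## A range caveat on "saturated" models

Freeing all four parameters of one condition gives as many parameters as
identifiable cells (df = 0), but the 2-HT map is not onto the proportion
simplex: some observed tables — including the combined-format condition
of the two-format experiment — would require dA < 0 to be matched
exactly. There the constrained MLE sits on the dA = 0 boundary with
G² > 0, and the usual saturated-model identity (fitted probabilities =
observed proportions, G² = 0) holds only for data inside the model's
range. Tests of that identity accordingly use in-range data.

## Power and sensitivity

G² tests are asymptotically χ², so sensitivity analyses use the
noncentral χ² distribution with noncentrality λ = N·w² (Cohen's w). The
noncentral CDF comes from scipy's `ncx2` (a Poisson-mixture series
implemented independently in the test suite serves as the cross-check);
`sensitivity_w` inverts the power function by bracketed Brent
root-finding on w ∈ [1e-6, 1] (xtol 1e-10). N counts total responses
entering the test — participants × responses per participant (four
lineups each here), i.e. N = 3064 for 766 participants. This convention
reproduces both published sensitivity values (w = 0.07 and 0.06 at
df = 1, α = β = .05) and is stated explicitly because power-software
input conventions are a recurring source of confusion; the original
write-up does not document which N it used, so the convention is
inferred from reproducing both values.

## Synthetic data and validation

The simulator draws pooled multinomial counts per condition × tree from
the model's category probabilities with N_tree = participants × lineups
of that type, emulating the study designs (2 present + 2 absent lineups
per participant, or 3 + 1 / 1 + 3). This reflects exactly the
independence assumption of the pooled analysis; per-participant
clustering and parameter heterogeneity are not modelled, so recovery
results validate the estimator under the model's own assumptions, not
robustness to within-witness dependence. A master seed spawns one
substream per replicate (numpy `SeedSequence.spawn`), making studies
reproducible and order-independent.

Validation harness sizes (package defaults, chosen to make the checks
statistically meaningful at interactive runtimes): parameter recovery
uses 200 replicates at the two-format design sizes (382/384
participants) with true values near the fitted ones (dP = .30/.28,
dA = .05, b = .06, g = .44/.42), asserting absolute bias < 0.02;
type-I-error calibration simulates 1000 null data sets (equal dP) and
checks the dP-equality test rejects at a rate of 5% ± 1.5%
(binomial SD at 1000 replicates is 0.69%, so the band is a real
constraint); SE calibration compares mean model-based SE with the
empirical SD of estimates across 100 replicates within 15%. Simulation
fits use 2–3 optimizer starts — sufficient for these unimodal problems —
while data analysis keeps the full 10-start grid.

## Known limitations

- Only the 2-HT lineup trees, replicated over conditions, are supported;
  this is not a general MPT engine (the EQN export exists precisely so
  instantiated models can be cross-checked in one).
- No hierarchical/latent-class extensions, Bayesian estimation, or
  bootstrap intervals; SEs and Wald intervals are asymptotic.
- Pooling assumes independent responses; each witness contributes four.
  The simulator could be extended with participant-level heterogeneity
  to probe this, but no published value constrains such an extension.
- Wald SEs for boundary-adjacent parameters (small dA) should be read
  with care; the package flags, not censors.
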