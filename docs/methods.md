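# Methods

## Model

The package implements a discrete Bayesian network over 42 variables: 31
root factors (terrorist-organisation profile, weapon characteristics,
target demographics, weather, four police prevention measures, three
emergency-response timeliness indicators) and 11 aggregate child nodes
(organisation influence A, activity B, weapon-access difficulty C, weapon
danger D, target attraction E, weather condition F, police prevention
ability G, emergency-response ability H, organisation threat I, attack
success J, casualties K). The joint distribution factorizes into one CPT
per node; roots carry priors.

The default structure fixes the families that are certain from the model's
documentation ({14,15,16}→D, {17..21}→E, {22,23,24}→F, {25..28}→G,
{29,30,31}→H, {A,B,C}→I, {E,F,G,I}→J, {D,H,J}→K) and tags the remaining
assignments ({1,2,3,6}→A, {7,8,9}→B, {4,5,10..13}→C, and E→K as the 42nd
edge) as overridable default assumptions. E→K encodes that crowd exposure
scales casualties independently of whether the attack nominally succeeds.
Node I is deliberately *not* a parent of K: organisational threat acts on
casualties only through attack success. State labels are stored
ASCII-normalized (e.g. `>1000/km^2`, `50-500 people`); identity is exact
string match, case-sensitive.

## Inference

Exact posteriors are computed by variable elimination with a min-fill
ordering (deterministic tie-break by variable id). Factors are kept in
linear space — the networks are small and well-conditioned, so log-space
bookkeeping would buy nothing. A brute-force enumeration oracle (capped at
10^7 joint states) recomputes every posterior independently in the test
suite; agreement is required to 1e-9. Evidence with zero probability
raises a typed error rather than propagating NaNs.

## Dempster–Shafer fusion

Mass functions support arbitrary focal subsets; the combination rule is
implemented simultaneously over all N inputs (product over focal
combinations, intersection bucketing, renormalization by 1−K). For the
singleton-supported masses used in elicitation the rule reduces to a
normalized elementwise product; that closed form is the fast path and the
general implementation is its oracle in a property test. Total conflict
(K=1) is an error, never silently renormalized. The edge-existence
threshold comparison is strict (weight > 0.85). All eight published fused
rows of node H's CPT reproduce from the printed expert vectors at
three-decimal precision, so node H's CPT is *computed* from the panels
rather than transcribed (several printed rows sum to 1.001; exact fusion is
normalized by construction).

## EM learning

Parameters are fit by EM on a fixed structure. The E-step computes, per
record, the exact joint posterior over all unobserved variables (one
variable-elimination call per distinct record pattern; records are grouped
by pattern first, so cost scales with distinct patterns rather than sample
size; a per-family fallback covers patterns whose hidden-state space
exceeds 2×10^5). The M-step renormalizes expected counts with a
pseudocount α per cell. Defaults: α=1, convergence on absolute observed
log-likelihood change < 1e-6, cap 500 iterations, initialization from
uniform rows jittered by a seeded Dirichlet(5) draw to break symmetry
reproducibly. With α>0 the iteration ascends a penalized likelihood; the
raw observed log-likelihood trace is recorded and is monotone in all
packaged experiments (tolerance 1e-8). Missingness is treated as ignorable
(MAR); the synthetic module can generate outcome-dependent missingness to
exhibit the resulting bias, but recovery guarantees apply to MCAR only.

Recovery is audited by per-row total variation (0.5·Σ|p−q|) between
generating and fitted CPTs. Rows whose parent combination is observed
fewer than a support threshold of times (20 in the packaged experiments)
are reported but excluded from summaries — with few observations the
estimate is prior-dominated and TV against the truth is uninformative.
The packaged recovery experiment uses a seeded 6-node random ground truth,
n=5000 records and 10% MCAR missingness; mean row TV comes out near 0.024.

## Illustrative CPTs

The study-scale model's learned and elicited CPTs are not published, so the
packaged model carries an explicit stand-in, constructed as follows. Every
state of every variable gets a severity score in [0,1] (1 = most favourable
to the attacker), anchored by the documented extreme-condition states
(worst = 1, best = 0) and interpolated for intermediate states. A child's
CPT row for a parent configuration with weighted mean severity s is

    P(child = c | s)  ∝  exp(−λ (sev(c) − s)^2),   λ = 8.

Because the per-state weights are likelihood-ratio ordered in s, the
probability of the more severe child state is non-decreasing in every
parent's severity — the qualitative monotonicity the analyses rely on.
Family weights encode the documented orderings: among prevention measures
security check (0.4) > police investigation (0.3) > patrol (0.2) >
surveillance (0.1); attack success weights prevention ability 0.45,
attraction 0.25, threat 0.2, weather 0.1; casualties weight success 0.4,
emergency response 0.3, weapon danger 0.2, exposure 0.1. Root priors are
uniform except the two documented anchors used by the validation battery:
P(security check = Yes) = 0.40 and P(wind = Upwind) = 0.15.

These tables support direction-level conclusions only (which lever is
strongest, which scenario fails most); numeric posteriors from the original
study-scale model are not reproducible from published material and are not
claimed.

## Scenario and sensitivity analysis

Scenarios are named partial evidence assignments; the nine packaged
case-study scenarios cross three organisation profiles with three target
profiles and additionally clamp the weather-condition node to Favorable
(attackers choose their moment). Two published-table state labels were
normalized to the registry ("Many" precipitation → "Heavy"; "Middle"
education → "Medium"). The extreme-condition test clamps all 31 roots to
worst then best states and asserts P(J=Yes) and P(K=Major) are higher under
worst.

Two sensitivity semantics are deliberately distinct operations:
evidence-flip sensitivity (condition the input node on each state, compare
target posteriors) and bounded prior perturbation (multiply one prior state
by 1+δ, renormalize the rest by proportional co-variation, recompute the
target). Effect size is the L∞ distance between target distributions;
total variation is reported alongside. Perturbations that would leave the
simplex are clipped and flagged. Ranking over all roots uses the max
effect over each root's states, sorted descending with an id tie-break.

## Axiom-based partial validation

Three checks screen an expert-built model: (1) a prior nudge must move a
downstream posterior in the direction implied by conditioning on the nudged
state (the mixture identity P'(T) = P(T) + ε·[P(T|root=s) − P(T|root≠s)]
makes the conditioning probe the exact expected direction); no movement is
acceptable only under d-separation. (2) Growing nudges must act with
consistent sign and non-decreasing magnitude. (3) Jointly applied
same-direction nudges must have at least the effect of every proper subset
(slack 1e-9; "no change" threshold 1e-12). Under multiplicative prior
perturbation with proportional co-variation every posterior is a Möbius
function of δ, hence monotone in it — a genuinely sign-flipping
single-root pathway cannot exist under this semantics, so the axiom-2
failure path is exercised with mixed-sign delta sequences, which violate
the same-sign requirement legitimately. Checks operate on copies; a
battery run verifies CPT equality before/after.

## Synthetic data

The generator stands in for a study-scale table of 287 discretized
incident records (defaults: n=287, 10% missingness, MCAR). Records are
forward-sampled from a ground-truth network — either the illustrative
model or a seeded Dirichlet(1) redraw of its CPTs — and masked cell-wise.
The `mnar-severity` mechanism doubles the masking probability for records
with Major casualties, emulating outcome-dependent reporting. No record is
ever fully masked (re-draw rule), keeping every record's likelihood finite.
The generator emulates the shape of real case data (categorical records,
partial observation), not its dependence structure or its historical
frequencies: passing recovery tests demonstrates the estimator, not
real-world calibration.

## Problem sizes and numerical choices

Packaged experiments use sizes that keep the full suite fast while leaving
the statistics well-resolved: 50 random ≤6-node networks × 3 evidence
settings for the inference/oracle comparison (tolerance 1e-9), n=5000 with
10% MCAR for EM recovery, n=10^4–10^5 for sampling-frequency bounds (3–4
binomial SDs). CPT normalization tolerance is 1e-9 throughout; case CSVs
write missing values as empty fields and accept `NA` on read.

## Known limitations

* The illustrative CPTs are a documented construction, not elicited or
  learned values; only node H's family is faithful to published numbers.
* Exact inference only; no approximate engines, continuous nodes or
  dynamic networks.
* EM assumes MAR; MNAR data produce biased fits by design.
* The default structure's A/B/C parent assignments and the E→K edge are
  declared assumptions, overridable via model files.
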