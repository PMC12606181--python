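# Methods

This note documents the models and procedures dyadseq implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generator does and does not emulate.

## Data model

The unit of analysis is the **dyad**, an unordered pair of birds.  Dyads are
*familiar* when both members come from the same capture site and *stranger*
otherwise; capture site is a proxy for prior acquaintance.  Raw observation
records carry a session, observer, timestamp, behaviour and the two birds
involved.  Two sampling schemes coexist: nearest-neighbour **scan sampling**
(a `proximity` record at fixed 5-minute marks, symmetric by nature) and
**all-occurrence sampling** of five contact behaviours.  All records are
symmetrized to the canonical unordered dyad, because every downstream
quantity is dyad-level.

Binarization collapses records into occurrence indicators per (dyad,
behaviour, 5-minute bin).  Bins are half-open intervals `[k·w, (k+1)·w)`
**anchored at each session's start** — sessions are split morning/evening,
so anchoring at clock midnight would put bin boundaries at arbitrary offsets
inside sessions — and concatenated chronologically into one global index.
Consequently `b` bins always represent `b·w/3600` *observed* hours, which is
what the rate computations rely on.  Any number of raw records of the same
behaviour for a dyad in one bin (multi-observer duplication, continuous
behaviours) collapse to a single 1; this also makes binarization idempotent
and order-invariant, which the test suite asserts as properties.

Risk tiers: `proximity` → LOW; `shoulder_contact`, `allopreen`,
`beak_touch` → MODERATE; `allofeed`, `copulation` → HIGH.  The 1 m proximity
criterion is a field-protocol matter; the package trusts the label.  Records
naming unknown birds or behaviours are rejected with a named-row report
rather than guessed at; the reader assumes uncertain identifications were
filtered upstream.

## Sequence verdicts

First occurrences are computed per **tier** (minimum bin over the tier's
behaviours); within-tier behaviour order is ignored, matching the
three-level escalation scheme.  With first bins `t_L, t_M, t_H` (absent =
infinity):

- **generalized** supported iff `t_L < min(t_M, t_H)`;
- **precise** supported iff generalized supported and (`t_H` absent or
  `t_M <= t_H`).

Ties: a LOW/contact tie in the same bin counts as violated — only the
MODERATE/HIGH pair is granted simultaneity, because at 5-minute resolution a
contact record in the same bin as the first proximity record gives no
evidence that proximity came first.  A HIGH observation with no MODERATE
ever breaks the precise ladder (violated) while still satisfying the
generalized prediction if LOW preceded it.

Dyads never observed in contact have nothing to order and are **not
evaluable**; they are excluded from all supported/evaluable denominators.
This is the strict choice — such dyads are arguably consistent with the
prediction (they never escalated) — so `classify_all(...,
noncontact_as_supported=True)` (CLI: `--include-noncontact-as-supported`)
exposes the lenient alternative for sensitivity analysis.  Under the strict
default, the large number of proximity-only stranger dyads does not dilute
either stratum.

## Permutation null for sequences

Null hypothesis: the *ordering* of a dyad's occurrences carries no
information; only frequencies matter.  Each iteration permutes the bin
column of the deduplicated long-format records **jointly across all dyads
and behaviours**, preserving exactly the multiset of bins and the per-(dyad,
behaviour) record counts, then recomputes first occurrences and the
stratum's supported proportion.  Permuting without replacement (exact
marginal conservation) was chosen over resampling with replacement; a
per-dyad-only shuffle is available as `mode="within_dyad"`.  Post-shuffle
collisions (two records of one dyad+behaviour landing in one bin) are
harmless for first-occurrence minima and are collapsed wherever the binary
representation is materialized.

P-values are one-sided (the hypothesis is directional — observed support
*exceeds* random ordering) with the add-one rule
`p = (1 + #{null >= observed}) / (1 + n_iter)`, never exactly zero; at the
default 1000 iterations the resolution is about 0.001.  One top-level seed
spawns independent per-iteration substreams, so results do not depend on
execution order.

## Multi-membership Bernoulli model

For evaluable dyad (i, j):

    logit P(y_ij = 1) = alpha + beta * stranger_ij (+ sex terms) + u_i + u_j
    u_k ~ Normal(0, sigma_u), shared across all birds

Each bird's effect loads every dyad it belongs to with weight 1 (classic
equal-weight multi-membership; no weighting scheme is implied by the data).
Priors are weakly informative and exposed in `PriorConfig`: Normal(0, 10) on
fixed effects and half-Student-t(3, 0, 2.5) on `sigma_u`.  Sex composition
(MF reference, MM and FF indicators) is an additive option, off by default.

`summarize` reports posterior means and equal-tailed 95% credible intervals
on the log-odds scale, plus an **odds factor** computed samplewise —
`mean(exp(draws))`, with interval endpoints `exp` of the quantiles — never
`exp` of the summarised mean, which understates a skewed posterior.  (The
two coincide only for a degenerate posterior.)

### Sampler

The posterior is sampled with **component-wise slice sampling within Gibbs**
(stepping-out and shrinkage), the scheme BUGS-family samplers use for
logistic mixed models, with two exact auxiliary moves:

- a **translation move**: shift all bird effects by `c` and absorb `-2c`
  into the intercept (likelihood-invariant because every dyad loads two bird
  effects); `c` has a closed-form Gaussian conditional.  This removes the
  strong intercept/bird-effect posterior correlation.
- an **interweaving (ancillarity–sufficiency) update** of `log sigma_u`:
  after the centered conditional update, `sigma_u` is re-drawn in the
  non-centered parameterisation `u = sigma_u * z` with `z` held fixed, where
  the likelihood informs it directly.  Without this the variance component
  mixes very slowly whenever its posterior concentrates near zero.

Defaults are 4 chains × 8000 sweeps with 4000 warmup (thinned by 4), started
over-dispersed around the penalised fixed-effects-only estimate.  With the
auxiliary moves, split-Rhat is ≈ 1.00 and bulk ESS is in the thousands for
every parameter on cohort-sized designs.  The one failure mode — a slice
shrinkage loop not finding the slice — is counted and reported
(`stuck_fraction`); any appreciable value marks the fit as a diagnostic
failure in the pipeline report.

During development the sampler was validated on a fixture dataset against an
independent slice sampler and an external MCMC implementation, which agreed
with each other to Monte-Carlo error.  (An ensemble-MCMC backend tried first
produced a silently biased posterior on this geometry and was discarded;
parameter-recovery coverage is the regression test that guards against this
class of defect.)

## Paired proximity-rate test

For each bird, stranger partners are split by whether the dyad was *ever*
observed in contact.  A dyad's hourly proximity rate counts LOW-occurrence
bins in `[0, t)` divided by the observed hours those bins represent, where
`t` is the dyad's first contact bin (contacted partners) or the whole study
(never-contacted partners).  Truncation matters: proximity *after* first
contact reflects an established relationship, not vetting.  Partner means
are unweighted across partners (not pooled over bins), so a heavily observed
partner does not dominate.  Birds lacking either partner class, and dyads
whose first contact falls in bin 0 (empty window), are excluded and logged.
Because group means are reported, both SD and SE accompany them in the
pipeline report (the ± convention is otherwise ambiguous).

The test statistic is the paired t on per-bird differences; the null
distribution flips each difference's sign independently (5000 iterations,
one-sided in the direction contact > non-contact, add-one rule).  For small
n an `exact=True` mode enumerates all 2^n patterns.  Degenerate all-zero
differences report p = 1 with a flag.

## Synthetic cohort generator

`SimulationConfig` defaults encode the observational design: sites of
(5, 6, 7, 4) birds (n = 22, 8 female), 22 days × 6 h in two equal sessions
(132 observed hours), 300 s bins.  The latent relationship process is a
discrete-time per-bin hazard chain at the same 5-minute granularity as the
analysis:

- A stranger dyad is *progressing* with probability `preference_fraction`
  (0.31, matching roughly a third of strangers ever reaching contact);
  familiar dyads progress with that probability times `familiar_boost`
  (2.2 → ~68%, pre-existing bonds being far more likely to show contact).
- A progressing dyad draws its escalation order: the predicted
  LOW→MODERATE→HIGH order with probability `adherence` (0.92 strangers,
  0.75 familiars — familiar relationships predate the study, so their
  first-occurrence order in the observation window is much closer to
  arbitrary), otherwise a uniformly random tier order.  These two adherence
  values imply a positive familiarity log-odds contrast
  (`SimulationConfig.implied_beta_stranger()`).
- Tier onsets are separated by geometric waits with per-bin hazards
  `EscalationHazards` (init 1/150 bins ≈ 2 observation days;
  low→moderate 1/250; moderate→high 1/1200, so only a minority of
  progressing dyads reach HIGH within the study, as observed cohorts show).
  Onsets beyond the study end are censored; a dyad censored before any onset
  is recorded as non-progressing in the ground truth.
- After its onset a tier emits events at hourly rates (`proximity` 0.06/h
  for progressing dyads vs 0.012/h background; contact 0.05 and 0.02/h),
  proximity only at scan marks, contact at arbitrary within-bin times.
  Contact events are duplicated by a second observer with probability 0.15.
  The progressing-vs-background proximity gap is what the paired rate test
  is meant to detect.

`null_mode=True` replaces the hazard chain with fully exchangeable timing:
per-dyad event counts are drawn as before but every event's bin is iid
uniform over the study and proximity rates are identical for all dyads.
This regime satisfies *exactly* the exchangeability assumptions of the
time-bin shuffle and the sign-flip test, and is what the type-I-error
calibration tests run against.

What the generator does **not** emulate: spatial structure (positions are
abstracted into proximity events), diurnal activity variation, observer
visibility bias, behaviour durations, directed interactions, and any
within-tier behavioural structure.  Passing tests therefore demonstrate that
the pipeline recovers known truth under the stated stochastic design, not
that field data meet those assumptions.

`model_cohort` bypasses the observation stream entirely and simulates
dyadic outcomes straight from the multi-membership likelihood; it is used
for parameter-recovery and simulation-based-calibration checks where the
sampler, not the ethogram plumbing, is under test.

## Numerical and testing choices

- Problem sizes in the test suite: permutation oracles are checked by
  exhaustive enumeration at ≤ 5 records (120 assignments) and 3 pairs
  (8 sign patterns); calibration runs 200 null-mode replicates of a
  12-bird/8-day cohort at 199 permutation iterations; recovery fits 50
  cohorts of 231 dyads with 2 chains × 1200 sweeps; simulation-based
  calibration uses 64 prior draws on 9-bird cohorts with a tightened prior
  (Normal(0, 1.5), half-t(3, 0, 1)) so prior-predictive datasets remain
  informative.
- Comparisons of a statistic with its null use a `>=` with a 1e-12 slack so
  ties count against the hypothesis (conservative).
- `first_occurrence` minima use an inf sentinel; all verdict logic is
  vectorized over dyads, which is what makes 1000-iteration reclassification
  loops cheap.
- Empty strata, empty partner classes, all-zero differences and degenerate
  windows are reported (flags/warnings), never silently dropped into
  p-values.

## Known limitations

- The sequence verdicts use first occurrences only; repeated cycling
  through tiers, durations and rates within the window are invisible to the
  verdict (by design — rate effects are the permutation null's job).
- The multi-membership model assumes one shared `sigma_u` and no
  dyad-level random effect; with one observation per dyad a dyad effect is
  unidentifiable anyway.
- The permutation null conditions on per-(dyad, behaviour) record counts; it
  does not model observer error or missed identifications.
- Bayesian credible intervals are not exact frequentist confidence
  intervals; the recovery tests show ~90–95% coverage at cohort sizes, which
  is the relevant operating characteristic here.
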