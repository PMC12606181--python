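# dyadseq

Dyadic behavioural sequence analysis for studying how animals form new social
relationships.

## The problem

When unfamiliar animals meet, forming an affiliative relationship is risky:
physical contact can provoke aggression, and high-investment behaviours
(food sharing, mating) are costly if the partner is unreliable.  One proposed
strategy — *testing the waters* — is to escalate gradually: maintain
no-contact proximity first, move to moderate-risk contact (shoulder contact,
allopreening, beak touching), and only later to high-investment contact
(allofeeding, copulation).  Detecting this pattern in observational data
raises four statistical problems that this package solves as a pipeline:

1. **Ethogram binarization** (`dyadseq.ethogram`).  Multi-observer streams of
   nearest-neighbour scans (every 5 min) and all-occurrence contact records
   are deduplicated into a binary dyad × behaviour × 5-minute-bin tensor:
   each behaviour either occurred (1) or not (0) for each unordered pair in
   each time bin.
2. **Sequence classification** (`dyadseq.sequences`).  For each dyad the
   first occurrence of each risk tier is ordered and compared with the
   predicted sequences.  With first bins $t_L, t_M, t_H$ (absent = ∞):
   - *generalized*: $t_L < \min(t_M, t_H)$ — proximity strictly before any
     contact;
   - *precise*: generalized **and** $t_M \le t_H$ — moderate before high,
     simultaneity (same bin) tolerated only for the moderate/high pair.
   Dyads never seen in contact are *not evaluable* and excluded from
   denominators.
3. **Null models** (`dyadseq.permutation`, `dyadseq.rates`).  Frequent
   behaviours are seen early by chance alone, so observed proportions are
   compared against a null that shuffles the time-bin labels of all
   occurrence records (preserving every behaviour's frequency), with
   one-sided add-one p-values $p = (1 + \#\{T^{null} \ge T^{obs}\})/(1 + B)$.
   A companion sign-flip paired permutation test asks whether birds kept
   higher pre-contact proximity rates with the strangers they later
   contacted than with those they never contacted.
4. **Familiarity effects** (`dyadseq.mmodel`).  Whether stranger dyads follow
   the predicted sequence more often than familiar dyads is estimated with a
   Bayesian multi-membership Bernoulli model,
   $\mathrm{logit}\,P(y_{ij}=1) = \alpha + \beta\,\mathrm{stranger}_{ij} + u_i + u_j$,
   $u_k \sim \mathcal N(0, \sigma_u)$, where both members' random effects
   load every dyadic outcome.  $e^{\beta}$ is the odds factor for being a
   stranger dyad.  Sampling is slice-within-Gibbs with interweaving;
   convergence is summarised with split-Rhat and effective sample size.

A synthetic cohort generator (`dyadseq.simulate`) emulates the observational
design — 22 birds pooled from four capture sites (5/6/7/4), 22 days of split
morning/evening sessions (~132 h), 5-minute scans, five contact behaviours,
multi-observer duplication — with a latent per-dyad escalation process and
known ground truth, so every stage is testable without field data.

## Worked example

```python
import dyadseq as dq

cohort = dq.simulate(dq.SimulationConfig(), seed=1)   # 22 birds, 22 days
matrix = dq.binarize(cohort.observations, cohort.roster, cohort.schedule)
classifications, summary = dq.classify_all(matrix)
print(summary[summary.stratum != "all"].to_string(index=False))
```

```
 stratum    sequence  n_supported  n_evaluable  proportion
stranger generalized           53           56    0.946429
stranger     precise           51           56    0.910714
familiar generalized           22           32    0.687500
familiar     precise           22           32    0.687500
```

94.6% of the 56 evaluable stranger dyads progressed through proximity before
any contact, against 68.8% of familiar dyads.  Is that more than frequency
alone explains?

```python
res = dq.null_distribution(matrix, "generalized", stratum="stranger",
                           n_iter=1000, seed=42)
# observed = 0.946, random expectation = 0.527 (upper 95% 0.625), p = 0.0010
```

The familiarity contrast, with bird-level dependence controlled:

```python
data = dq.build_model_data(classifications, "generalized")
fit = dq.fit(data, chains=4, total_iter=8000, warmup=4000, seed=7)
print(dq.summarize(fit).head(3).round(3).to_string(index=False))
```

```
    parameter  mean  ci_low  ci_high  odds_factor  odds_ci_low  odds_ci_high  rhat      ess
    intercept 0.911   0.021    2.018        2.896        1.021         7.522   1.0 3831.961
beta_stranger 2.314   0.938    3.933       14.104        2.554        51.067   1.0 3730.940
      sigma_u 0.425   0.017    1.268          NaN          NaN           NaN   1.0 3317.658
```

Being a stranger dyad multiplies the odds of following the generalized
sequence (posterior log-odds 2.31, 95% CI [0.94, 3.93]); the odds-factor
column is the samplewise-exponentiated posterior.  Finally, the pre-contact
proximity rates:

```python
pairs = dq.paired_rates(matrix)
test = dq.permuted_paired_test(pairs, n_iter=5000, seed=9)
# contacted partners: 0.0903 /h, never-contacted: 0.0111 /h,
# paired t = 7.40, one-sided p = 0.0002
```

Birds maintained ~8× more proximity with the strangers they later contacted,
before any contact happened.

Each script in `examples/` demonstrates one capability end to end;
`dyadseq all` (or `dyadseq.run(RunConfig(...))`) chains every stage and
writes a consolidated `report.json`.  See `docs/methods.md` for the models,
parameter meanings and limitations.

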