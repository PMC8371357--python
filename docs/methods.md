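# Methods

This note documents the models implemented in `searchprime`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Study design being modelled

Participants complete a pre-test anagram phase (up to 14 six-letter sets,
stopping once 30 correct words have been submitted), then a spatial grid
search task (5 rounds of 80 clicks on 20×20 grids whose 0/100-point tiles
are clustered or dispersed, by random assignment), then a post-test anagram
phase with 14 fresh letter-sets. The primary outcome is
Δt = t_A2 − t_A1, the change in mean seconds per letter-set from pre- to
post-test, each phase mean excluding the letter-set in which the 30th word
was found (that set is cut short by task completion). The hypothesis under
test is one-sided — clustered-arm Δt > dispersed-arm Δt — paired with a
TOST equivalence test at d = ±0.36, the smallest effect size of interest.

## Landscape generators

**Clustered.** The number of patches is drawn uniformly from {3,…,5} and
each patch's size independently from {10,…,20}. A patch seeds at a uniform
reward-free cell and accretes one cell at a time, uniformly from the Moore
(8-neighbour) frontier of the patch, until it reaches its size or has no
frontier. The accretion neighbourhood and frontier weighting were design
choices (the patchy-landscape convention leaves them open); Moore
connectivity was chosen to match the dispersed generator's neighbourhood
definition. Patches may overlap — each patch's frontier excludes only its
own cells — so the landscape is regenerated until the total reward count
lies in [77, 83]. This retention band is why clustered reward mass varies
between landscapes while dispersed reward mass does not.

**Dispersed.** Rewards are placed sequentially: a uniform draw among empty
cells is accepted outright if no Moore neighbour holds a reward, and with
probability 0.001 otherwise, until 80 rewards are placed. A livelock guard
(10,000 draws per pass, then a full restart) protects against stranding
near saturation; at 80/400 occupancy restarts are essentially never needed.
Mean payoff is exactly 80·100/400 = 20 points per tile.

Landscape CSVs are 20 integer rows with 0-based row-major (row, col)
coordinates and a JSON sidecar carrying condition, reward count and RNG
provenance.

## Spatial metrics

The dispersion measure averages, over the 80 selected tiles, each tile's
mean Manhattan distance to the other 79, then averages the five per-grid
values per participant. This equals the mean over all unordered pairs,
which is how it is computed (and asserted in tests). The sequential-step
measure is the Manhattan distance between consecutive selections; the
contingent split classifies the step ending at selection *t* by the payoff
at *t−1*. The first click of each grid contributes no step. A grid in
which a class never occurs (e.g. zero hits) is dropped from that
participant's contingent mean rather than imputed; participants with the
class undefined in every grid get a missing value that propagates to the
paired analysis. Contingent means are averaged within grid first and then
across grids, consistent with the two-stage averaging of the dispersion
measure.

## Anagram metrics

Letter-sets draw 4 of the 15 allowed consonants and 2 of the 5 vowels
without replacement within class (K, V, X, Z, J, Q excluded). No
dictionary validation is performed; word validity is an input flag, and
study letter-sets can be supplied verbatim from a plain-text list.

Bigram similarity decomposes a word of length L into L+1 tokens — a start
marker + first letter, each adjacent pair, last letter + end marker — and
counts the multiset intersection (minimum of per-token counts) between two
words. The worked pair `tale`/`gale` shares 3 tokens either way, but the
multiset reading is retained as the stricter, information-preserving one.
Consecutive-word chains are confined within a letter-set visit (an
`across_sets` flag enables the cross-set sensitivity analysis), and only
correct submissions enter chains; incorrect submissions stay in the logs.
Pairs sharing zero bigrams count as zeros in the session mean.

## Synthetic participants

**Grid agent.** A win-stay/lose-shift policy: after a hit (miss), with
probability `p_local_after_hit` (`p_local_after_miss`) the next tile is
uniform among unrevealed tiles within Chebyshev radius 1 of the last
selection, falling back to a global uniform draw when the neighbourhood is
exhausted. Defaults were calibrated once against the qualitative pattern
the pipeline must detect: the clustered arm uses (0.95, 0.90) — an
area-restricted searcher that probes around a patch before leaving — and
the dispersed arm (0.20, 0.60) — a win-shift agent that leaves a found
reward. These give a clustered-arm mean step near 2.6 tiles, a
between-arm dispersion gap with |d| ≈ 2–3, and the contingency reversal
(after-hit < after-miss in the clustered arm only).

**Dwell model.** Letter-set dwells are log-normal — dwell times are
positive and right-skewed, and a location shift on the log scale gives a
clean standardized-effect calibration. The post-test mean is multiplied by
a practice factor (default 0.7), which reproduces strongly negative Δt in
both arms (about −31 s at the default median dwell of 90 s), and the
clustered×post cell additionally by exp(δ). δ = 0 is the null; δ ≈ 0.145
corresponds to a true standardized effect near d = 0.5 on Δt under the
defaults. Correct words per set are 1 + Poisson(1.8), so the 30-word
criterion is typically reached around the 11th set. A vectorized Δt
sampler (`simulate_delta_t`) reproduces the session-level generative
process as whole matrices for calibration studies with thousands of
replicates; a test verifies its agreement with the session path.

**Word stream.** Correct words are 4-letter draws from the set's 6
letters; with probability `chain_prob` a word is instead derived from an
earlier word by substituting one unused letter (the `tale` → `gale`
move). The edit source is the immediately preceding word, or with
probability `anchor_persistence` the set's first solution. High anchor
persistence (clustered arm default 0.7 vs 0.1) models persevering on one
early solution, which lowers similarity between *consecutive* words — the
direction of the observed within-set effect.

**Nuisance behaviours.** Comprehension failure, inactivity and low word
production are sampled independently per participant at configurable rates
(all 0 by default) and surface through the participant table exactly where
the exclusion criteria look for them. The participant table also carries a
simulated total grid-task duration (log-normal minutes, clustered arm
faster), because the click-event schema has no timestamps but the
exploratory battery includes grid-time analyses; in real-data mode the
column is optional and its analyses are skipped when absent.

**What the generator does not emulate.** Stable individual differences
(dwell means are exchangeable across participants, so the synthetic Δt
spread, sd ≈ 21 s, is narrower than human data), learning within the grid
task, fatigue trends across letter-sets, real lexical constraints, and
exact human means (the agents reproduce signs and magnitudes of the
qualitative pattern, not point values). Passing tests therefore show the
pipeline recovers effects it is fed and stays calibrated under the null —
not that the generative model is a faithful cognitive model.

## Inference conventions

- Welch's t throughout for two-sample comparisons; zero variance in both
  samples is a degenerate-input error.
- Cohen's d uses the pooled n−2 sd even alongside Welch tests (the
  conventional pairing); sign convention d = (group1 − group2)/s_pooled
  with clustered as group 1. CIs invert the noncentral-t CDF in the
  noncentrality parameter (Brent's method to 1e−10, with the analytic tail
  limits where scipy's nct underflows); the normal approximation was
  rejected because it visibly misses published CI widths at n ≈ 170.
- TOST converts the d bounds to raw bounds via the pooled sd and runs two
  one-sided Welch tests; p_tost is the larger of the two one-sided p's.
  Analytic TOST power at true d uses the noncentral t with df = 2n−2;
  at n = 168 and bounds ±0.36 it is 90.01% under the null.
- Required sample size inverts noncentral-t power (df = 2n−2,
  ncp = d·√(n/2)) by bisection to the smallest integer n meeting the
  target; d = 0.36 at α = 0.05 and 95% one-sided power gives n = 168.
- Pearson CIs use Fisher's z; OLS uses classical standard errors
  (statsmodels); fixed-effects meta-analysis weights each study by the
  inverse of var(dᵢ) = (n₁+n₂)/(n₁n₂) + dᵢ²/(2(n₁+n₂)).
- The exploratory battery reports raw p-values (its type-I error is
  inflated by multiplicity, as the design acknowledges); a Holm-adjustment
  helper is provided for sensitivity analyses.
- The primary test is one-sided (clustered > dispersed). Reports carry the
  one-sided p; two-sided values are recoverable from the same statistics.

## Exclusion pipeline

The seven criteria (comprehension failures > 2 in either task; < 20 words
in either anagram phase; two 50-s inactivity warnings in the post-test
anagram or the grid task; ≥ 100 s of inactivity during a warning; > 150 s
on the post-test instructions) plus completion are evaluated independently
for every participant, so the retained set is order-invariant and the
report lists every trigger per participant. The 100-s rule is
operationalized on the maximum inactivity observed during any warning,
which is what the schema carries. Retained counts per condition are
reported and are, by construction, the counts the analyses consume.

## Problem sizes

Test-suite simulations use pools of 10–12 landscapes and cohorts of 20–40
participants per arm, with calibration suites at the study's 168/arm via
the vectorized Δt sampler (1000 null replicates; 100 recovery replicates;
10,000 Monte-Carlo TOST studies). These sizes make every Monte-Carlo
tolerance explicit in the tests (±2 binomial standard errors for rejection
rates, ±0.15 for effect recovery) while keeping the default suite fast.

## Known limitations

- The grid count per participant is fixed at 5 rounds (the task
  instructions' value); it is exposed as `StudyConfig.n_grids` because the
  procedure description elsewhere mentions eight rounds.
- The clustered patch tool's exact growth rule is a documented assumption
  (Moore accretion, uniform frontier); other accretion rules would change
  patch shapes but not the retention-band contract.
- Bigram similarity between words straddling letter-set boundaries, and
  set- (rather than multiset-) intersection, are available as flags; the
  defaults are the stricter readings.
- Synthetic cohorts cannot reproduce human point estimates (e.g. the
  exact dispersion means or the points-earned gap); acceptance of the
  pipeline rests on analytic quantities and on sign/magnitude patterns.
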