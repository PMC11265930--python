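# Methods

`latchseq` analyses categorical behavioural sequences recorded at
multi-compartment, multi-latch puzzle boxes visited by free-ranging
animals identified by RFID. This note documents the models and
procedures the package implements, the conventions it adopts where the
field leaves choices open, what the synthetic generator does and does
not emulate, and the package's known limitations.

## The analysis units

**Events.** The raw substrate is a timestamped log per site and testing
night: individual detections, door openings (door id, latch type
∈ {H, R, V, S}, work time in seconds, an exploratory-diversity count
scored from video) and re-baiting events. Timestamps are site-local and
timezone-naive; nights are explicit labels, not inferred from clock
time.

**Trials.** A trial is one individual's contiguous visit: maximal runs
of the individual's events whose inter-event gaps are strictly below
the absence threshold (default 60 s). A gap of *exactly* the threshold
starts a new trial ("absent for at least one minute" read as ≥).
Trial indices are chronological per individual over the whole study;
`doors_opened_to_date` counts openings in strictly earlier trials, so
the "has opened at least six doors" gate reflects experience at trial
start.

**Solvers.** An individual is a solver once it has opened ≥ 3 doors of
the same latch type over all its trials; solving ≥ 2 latch types makes
it a flexible solver.

**Social condition.** Box state is tracked per (site, box, night):
every re-bait closes all doors; a box with no prior re-bait record is
all-closed by convention; reopening an open door is logged and ignored.
A trial is *unrestricted* iff the box was unopened at trial start, the
focal animal was the first solver to arrive since the last re-bait, and
no other solver's events fall inside the trial window; otherwise it is
*competitive*. Presence is inferred from temporal overlap of logged
events at the same box only. Unidentified individuals are excluded from
trials and solver counts; they count as competitors only if
`unknown_counts_as_competitor` is set (off by default, since the
competitive definition names solvers).

**Work-time bins.** Work time is ordinal: 1 (< 5 s), 2 (5–15 s),
3 (16–30 s), 4 (≥ 31 s). The written bin edges leave fractional values
in (15, 16) and (30, 31) unassigned; the package closes the gaps with
half-open intervals [5, 16), [16, 31), [31, ∞).

## Sequence metrics

For a trial's latch sequence *x* of length *n* over the alphabet
*A* = {H, R, V, S}:

* longitudinal entropy `h(x) = −Σ π_i ln π_i` over within-sequence
  state proportions π (natural log; the complexity index is base-
  invariant because it uses h/h_max);
* transition count `q(x)` = number of adjacent positions whose states
  differ, q_max = n − 1;
* complexity index `C(x) = sqrt((q/q_max) · (h/h_max))` with
  h_max = ln |A| over the **full** four-latch alphabet regardless of how
  many latches the sequence uses (the fixed-alphabet convention of the
  standard sequence-analysis toolkits). C = 0 iff one latch type was
  used; C = 1 iff all latches occur equally often and every opening
  switches latch. A length-1 sequence cannot switch and is defined to
  score 0 (such sequences are excluded by the ≥ 6-length filter in any
  case).

**Dissimilarity.** Pairwise optimal matching (OM): the minimum total
cost of insertions/deletions (cost 1) and substitutions transforming
one sequence into the other, by the standard dynamic programme.
Substitution costs come from pooled observed transition rates:
`SC(i, j) = 2 − p(i→j) − p(j→i)`, zero diagonal, clipped below at zero.
Rows of the transition matrix with no observed outgoing transition are
set uniform so the matrix stays stochastic. Distances are normalised by
the length of the longer sequence (the classic length normalisation for
this distance; `sum` and `none` are selectable). Costs are pooled over
all sequences entering the analysis by default; per-condition
estimation is selectable.

A caveat worth stating: OM with transition-rate costs is guaranteed
non-negative, symmetric and zero on identical sequences, but it is a
true metric only when the indel-capped substitution costs themselves
satisfy the triangle inequality — transition-rate costs need not. The
test suite checks the triangle inequality exactly on instances meeting
that precondition and the remaining axioms unconditionally.

**Partitions.** Off-diagonal distances split exactly once into
intra-individual (same individual, different trials) and
inter-individual pairs, per social condition. Individuals with a single
qualifying trial contribute nothing to the intra set.

**Analysis subset.** Sequence analyses keep solver trials with ≥ 6
openings, ≥ 6 doors opened to date, restricted to each individual's
first test year (earliest year observed in the log). Latch-preference
tests use the final five first-arrival trials per solver; solitude can
additionally be required via a flag.

## Inference

* χ² goodness of fit against uniform latch use, df = categories − 1.
* Mann–Whitney U reported in the W convention (rank sum of the first
  sample minus n₁(n₁+1)/2, the value R's `wilcox.test` prints; the U
  statistic of the first sample is the same number). Exact p by
  enumeration when n₁ + n₂ ≤ 12 and tie-free; otherwise normal
  approximation with tie and continuity corrections. Two-sided
  throughout (configurable).
* Binomial (logistic) GLM fitted by IRLS; Wald 95% CIs (β ± 1.96 SE);
  AIC = 2k − 2ℓ; AICc = AIC + 2k(k+1)/(n−k−1), requiring n > k + 1.
  Perfect separation raises an error naming the diverging
  coefficients. Profile-likelihood CIs are out of scope.
* Forward stepwise competition from the intercept-only model: each step
  adds the candidate with the largest deviance reduction (ties broken
  by input order) and retains it iff AICc drops, else stops. The
  comparison table carries every model on the visited path — including
  the final rejected candidate — with ΔAICc, Akaike weights
  `w_m = exp(−Δ_m/2)/Σ exp(−Δ_j/2)`, and the per-step likelihood-ratio
  test (LRT = deviance reduction, χ² tail on the parameter difference).

## The synthetic generator

The generator emulates the data-generating structure the analyses
assume, with every latent written to `truth.json`:

* **Population.** n individuals (default 31, the multi-solution cohort
  size); solver status Bernoulli(0.23); latch preferences
  θᵢ ~ Dirichlet(α·w) around shared difficulty weights
  w = (S .295, H .269, V .262, R .174) — the difficulty ordering the
  preference analyses probe, swivel easiest through rod hardest — with
  concentration α (default 2 — strongly individual profiles). Half the solvers are "knowledgeable" (full latch
  repertoire from the start); the rest are naive, start with their
  single favourite latch and add one latch every two trials, producing
  the rising complexity trajectory.
* **Nights.** Each night (default 31) holds four bait cycles. A cycle
  opens with a re-bait; one eligible solver visits alone (unrestricted)
  or, with probability 0.5, two solvers overlap (competitive for both:
  the second arrives 15–25 s into the first's trial). The box has two
  working sides with three doors per latch each; every visitor works
  one side and joint visitors take opposite sides, so the door
  constraint — and hence the opening law at τ = 1 — is identical across
  conditions. Non-solvers appear as detection-only scrounging visits
  after the solver trials. At least two minutes of silence separate
  cycles so trials segment cleanly.
* **Openings.** A sticky Markov chain: repeat the previous latch with
  probability κ (default 0.4) while its doors last, otherwise sample
  θᵢ restricted to latches with closed doors. During competitive
  trials preferences are sharpened to θᵢ^(1/τ), renormalised
  (τ = 0.5 default; τ = 1 is the identity).
* **Work times.** Log-normal with log-mean μ₀ − λ·(cumulative doors)
  (μ₀ = ln 18 s, σ = 0.8, learning slope λ = 0.05 per door), clipped to
  [0.5, 300] s — a declining learning curve on the bin scale.
* **Diversity.** First-trial exploratory diversity
  ~ 1 + Poisson(3 + 4·solver + 2·juvenile), making diversity the
  informative success predictor; per-door diversity declines with
  experience.
* **Determinism.** One RNG substream per night derived from
  (seed, night index), so adding nights never perturbs earlier ones;
  outputs are byte-identical given seed and config.

What the generator does **not** emulate: spatial movement and home
ranges, multi-site structure (one site/box by default), observational
social learning, weather-driven scheduling, unidentified individuals,
inter-observer scoring error, and any dependence of visitation on past
success. Tests passing on synthetic data therefore show the pipeline
recovers structure *of the kinds encoded here* — preference
individuality, sharpening under competition, learning curves — not that
real field data contain them.

Two regime notes: with full stickiness (κ = 1) a trial is a single
repeated latch only while the favourite latch has closed doors left
(three per side), so that invariant is exercised with ≤ 3 openings per
trial; and pooled intra-distance comparisons across conditions weight
individuals by their squared trial counts, so condition contrasts at
τ = 1 are judged against the τ = 0.5 effect size rather than by a
pooled two-sample test.

## Numerical and edge-case conventions

* Segmentation boundary: gap == threshold splits.
* Empty logs, filters that eliminate everything, and solvers with fewer
  than five qualifying trials degrade to empty/partial outputs with
  logged warnings, never errors.
* The OM dynamic programme's value is unique; cost ties need no
  tie-break. χ² with all-zero counts, Mann–Whitney with an empty
  sample, non-nested LRT, c_val ≤ 0 and negative work times are errors.
* Stepwise treats a candidate whose fit separates as unavailable at
  that step.
* Report medians always carry their group sizes; trial blocks default
  to 3 (blocks 1–3, 4–6, …) and are configurable.

## Test problem sizes

Recovery tests regenerate synthetic seasons at 12 nights
(individuality, learning-curve and complexity-trajectory checks) and 30
nights with up to three trials per solver-night (the competition
contrast, which needs many intra-individual pairs per condition). These
sizes give stable medians while keeping the whole suite fast; they are
deliberate package defaults for its own regression testing, not
statements about the field design.
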