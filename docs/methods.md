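# Methods

This note documents the models implemented in `rehabmcdm`, their
assumptions, the tunable parameters, and the numerical choices made where
the design was genuinely open. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## The criteria system

The decision problem is hierarchical: three criterion groups (physical and
functional state 50%, psychoemotional status 30%, healthcare organization
and routine 20%), ten criteria `c1..c10`, and ordinal sub-criteria with
point scales of 2–5 consecutive levels starting at 1. Each sub-criterion
is a *benefit* (Max: higher points healthier) or a *cost* (Min: lower
points healthier) indicator; where a main criterion's nominal direction
differs from a sub-criterion's (e.g. pain syndrome is Min overall while
the "nature of the pain" descriptor is typed Max), the **sub-criterion
direction governs normalization** — normalization operates row-wise on
sub-criterion scores, and the criterion-level direction is kept as
metadata only.

Criteria without sub-criteria are represented internally as one implicit
sub-criterion holding 100% of the parent share, so scoring is uniform.
The four healthcare-organization criteria (`c7..c10`) describe the
delivered program rather than the patient; no point scales are published
for them, and in a single-program cohort they are constant. The package
models them with two-level scales (program/measure absent vs applied);
under empirical pooling their constant rows trigger the zero-spread rule
and drop out of differentiation exactly as they are absent from the
cohort's aggregate-score table.

Percent shares are stored as fractions of the printed percentages
(35% → 0.35); group shares, within-criterion shares and the ten
direct-importance priors each sum to 1 and are validated on load.

## SWARA weighting

Experts rank the criteria by a direct-importance prior and then state, for
each adjacent rank pair, a comparative importance `s ∈ [0, 1]`. The panel
is averaged with the plain arithmetic mean per rank position (no trimming:
the elicitation already bounds the values). The recursion is

    k_1 = 1,  k_j = s_j + 1
    q_1 = 1,  q_j = q_{j-1} / k_j
    w_j = q_j / Σ q

Two points deserve emphasis because both are easy to get wrong:

* **The ranking follows the direct-importance priors, not label order.**
  In the default configuration c7 (0.08) outranks c6 (0.06), so the
  rank-6 pair value lands on c7 and the rank-7 value on c6. Ties break by
  ascending criterion id for determinism.
* **The recursion divides by `k`.** An equivalent closed form,
  `w_j ∝ (Π_{m≤j} k_m)^{-1}`, is used as an independent oracle in the
  tests.

Sub-criterion weights are `w(criterion) × percent_share`; internal
computation is at full precision and rounding happens only for display.

## Normalization pool

The compromise min–max equations need a per-row min and max. The package
defaults to the **theoretical scale bounds** of each sub-criterion, for
two reasons: it is the only pool under which scores from assessments I and
II are directly comparable on one scale, and it pins the healthy-reference
alternative (best level on every row) at exactly 1. An `empirical` pool
(min/max over observed alternatives, with the other assessment poolable)
is provided for sensitivity analysis. A row with zero spread normalizes to
1 for every alternative — a constant criterion should not penalize anyone
— and is logged as a warning.

The aggregate score used downstream is the weighted sum (`wam_score`).
The cohort's published score table is headed as an arithmetic mean over
criterion groups, while the stated aggregation formula is the weighted
sum; both readings are therefore emitted (`wam_score` and `table7_view`,
the unweighted mean of the per-group means), with `wam_score` primary.
Alternatives with missing sub-criterion scores are rejected by validation
rather than imputed.

## Class-boundary calibration

Five ordered classes follow the ICF impairment qualifiers (I complete …
V no impairment). Two calibrations produce a `ClassModel`:

* **K-Means.** The *corrected value set* concatenates all aggregate scores
  of both assessments (each including the healthy reference) and appends a
  minimum of 0.01 — the scale has an attainable maximum of 1, so a
  near-zero minimum anchors the other end. 1-D K-Means uses k-means++
  seeding with the best SSE over 50 restarts and a fixed seed; restarts
  are not part of the original procedure description but 1-D K-Means is
  initialization-sensitive and best-of-restarts makes the optimum stable
  (the tests verify it against exhaustive contiguous-partition search).
  Cluster contiguity on sorted values is asserted on every run.
* **Expert labels.** Each class is spanned by the scores the panel
  labelled into it, with the added 0.01 as the sole class-I member and the
  healthy scores as class V.

Raw spans leave gaps. Internal gaps are split at the midpoint, the lower
class's new upper bound rounded down and the upper class's new lower bound
rounded up at 3 decimals (4 is configurable); when both round onto the
same tick the upper class keeps it and the lower backs off one tick.
Degenerate extreme clusters ({0.01} and the healthy {1, 1}) are treated as
anchors: their neighbour's raw bound is kept and the anchor-side boundary
closes one tick (10⁻⁴) away. The top class always ends at 1. Interval
membership is closed on both endpoints and rounding-gap values belong to
the upper class. With noisy synthetic labels, expert class spans can
overlap; the same midpoint rule is then applied with a negative gap.

**Outlier rule.** The expert calibration drops a labelled score when the
recomputed majority vote disagrees with the recorded class *and* the score
lies strictly outside the span of the other members of its recorded class
— i.e. the disputed label would move a class boundary. On the packaged
cohort exactly one score (0.2935) is rejected. Label monotonicity alone
cannot reproduce this: the recorded labels are perfectly monotone in score
(rejecting nothing), while monotonicity of the recomputed majority votes
flags three scores; the adopted rule rejects only the boundary-distorting
one. Consensus is the majority of individual votes with ties broken toward
the worse (lower) class; disagreements with the recorded reference are
reported, never overridden.

## Synthetic data

The generator emulates the study conditions: 20 patients, intake classes
II/III in 65/35 proportion, an improvement of one class width (0.2)
between assessments, latent noise sd 0.05, 10% expert vote confusion
(symmetric ±1 class), and a 12-expert panel whose pair values scatter
(sd 0.15, recorded at 2 decimals as elicited) around the packaged panel's
averages.

Each patient has a latent recovery state in [0, 1] (class c occupies the
band [(c−1)/5, c/5], draws centre on (2c−1)/10). Ordinal scores are a
deterministic equal-width quantization of the latent state per scale —
the simplest monotone link, since no generative model for the instruments
is available — so a strictly worse latent state never receives a strictly
better ordinal level. The truth tables record the band actually occupied
by the latent state.

What passing tests on this generator do show: the pipeline recovers known
weights, classes and boundaries from data with the assumed structure, and
degrades only through two understood channels — panel noise (weight
error) and latent noise near class boundaries interacting with the coarse
2–5-level scales (class confusion; the class-III centre 0.5 sits exactly
on the threshold of every two-level scale). What they do not show:
anything about the psychometrics of the real instruments, rater
dependence between criteria, or cohort demographics.

## Sizes and tolerances

Printed-value comparisons in the tests use the published precision
(4 d.p. for weights, 5 d.p. for the largest sub-weight); class boundaries
are compared at 3 decimals within one tick, since the published rounding
at two internal boundaries (0.6692 where halving gives 0.6690) is not
reproducible from the stated rule. The recovery experiments in the test
suite use 3–20 replicates of 20-patient cohorts, and the acceptance script
200 noiseless replicates — sizes at which the Monte-Carlo properties under
test are already exact or tightly concentrated.

## Known limitations

* The expert boundary derivation assumes each class has at least one
  labelled member (anchors cover I and V); a cohort with an unrepresented
  middle class needs the `classes` argument to restrict the model.
* The outlier rule is the package's own reconstruction of a procedure the
  source material applies but does not specify; it is deliberately
  conservative (both conditions must hold).
* Scores are accepted as already mapped to ordinal points; the clinical
  instruments behind the scales are out of scope.
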