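# Methods

## Psychometric model and the hypothesis grid

The response model is the guess-rate-corrected logistic
p(x) = γ + (1 − γ)/(1 + exp(−β(x − α))) on the 0–100% coherence axis.
γ is fixed at 1/8 (chance in an 8AFC direction task) and β at 1/2 per
percentage point of coherence; only the midpoint α varies across the 150
grid candidates. The grid is linear in α and anchored so that the
70%-correct levels of the extreme candidates are exactly 0 and 100%
coherence: the constant offset between a candidate's midpoint and its 70%
level is (1/β)·ln((1 − γ − (1 − p))/(1 − p)) evaluated at p = 0.70, i.e.
2·ln(0.575/0.3) ≈ 1.3012% coherence, so midpoints run from −1.3012 to
98.6988. No lapse or false-alarm parameters are modeled: model selection
is a full scan over the 150 candidates (unimodality of the likelihood
along the grid is not assumed), with exact ties broken toward the lowest
midpoint — a deterministic, most-sensitive-hypothesis rule. Candidate
probabilities are clamped below 1 − 1e−12 in the likelihood so that an
incorrect response on an easy trial leaves every candidate's
log-likelihood finite.

## Adaptive sessions

A session runs two independent tracks (left and right hemifield), 160
trials each across five blocks (32 per hemifield per block), with the
left/right presentation order shuffled within each block under the session
seed. The first trial of a track is presented at 100% coherence — the
maximally visible stimulus, a standard opening for likelihood-based
adaptive procedures — and every later trial at the current best
candidate's 70% level, clipped to [0, 100]. The final threshold is the 70%
level of the candidate selected after all 160 trials ("all-blocks" mode);
a "per-block-average" mode resets the track each block and averages the
five block thresholds (the older per-block variant). Both the final
presented level and the final selected-candidate level are recorded. A
single session seed deterministically derives three independent
sub-streams (interleaving order, left responses, right responses), so
replaying a seed reproduces the session bit for bit, and the interleaving
order cannot leak into either track's response stream.

Track updates keep a running per-candidate log-likelihood vector, so one
update costs O(grid) rather than O(grid × history); the incremental state
is asserted against full recomputation in the tests.

## RDK stimulus

The generator reproduces the display statistics of the task stimulus: 150
dots in an 8°-diameter circular aperture (≈3 dots/deg²), drifting at
13.3°/s, stimulus duration 106 ms at 60 Hz (6 frames), dot lifetime 47 ms
(2 displacement steps). Each frame, every dot is independently relabeled
signal (probability = coherence/100) or noise: signal dots translate one
frame step along one of the eight 45°-spaced trajectories, noise dots
relocate uniformly in the aperture. Dots exceeding their lifetime or
exiting the aperture are replaced at a uniform random position, keeping
the dot count exact; initial dot ages are staggered so replacements spread
across frames. The per-frame relabeling is the standard anti-streak rule —
a fixed-identity variant is available behind `reassign_each_frame=False`
but is not the default, because fixed identities produce trackable motion
streaks the task is designed to avoid. Frame-count rounding (round for
duration, floor for lifetime) is fixed and documented here rather than
configurable per call.

## Synthetic cohorts

Cohort thresholds follow an additive model: grand mean + subject random
effect + linear session-order learning drift + condition×hemifield shift +
residual noise, truncated to [0, 100]. Condition order is counterbalanced
over the six permutations of the three conditions (42 participants → 7
per permutation). Defaults encode the study conditions: n = 42, grand
mean 70% coherence, and residual SD 7.4% so that the per-participant
difference-of-differences score (active ipsi−contra minus sham
ipsi−contra) has SD 2·7.4 = 14.8% — the SD the sampling plan pairs with
the 10.51 − 2.59 = 7.92% mean difference to give d ≈ 0.54. The
subject-level SD is also 7.4% (an even split of the non-difference
variance; it cancels from every paired score, so only the residual SD is
identified by the difference-score calibration). Learning drift defaults
to zero; a nonzero slope cancels from ipsi−contra scores within a session
and is absorbed by counterbalancing in cross-condition contrasts. The
generator emulates the *statistical* structure of a cohort, not the
trial-level process — it draws thresholds directly rather than simulating
each participant's 160-trial session, so passing calibration tests speaks
to the group-level plan, not to adaptive-procedure convergence (which is
tested separately via simulated observers).

## Group statistics and power

Difference scores are ipsilateral − contralateral, so contralateral
facilitation (a *lower* contralateral threshold) is a *positive* score and
every directional hypothesis is an upper-tail test; the direction is an
explicit argument, never an implicit sign convention. The paired test is
the one-sample t on the scores (SEM with n−1 SD); each of the three
registered tests runs at α = 0.02 with no further multiplicity
correction. The exploratory condition test averages the two hemifields
per condition first, then computes the classical one-way within-subject
decomposition with (k−1, (k−1)(n−1)) degrees of freedom and no sphericity
correction. If the between-condition sum of squares is numerically zero
the F statistic is reported as 0 (the 0/0 case arises only in noise-free
synthetic tables).

Sample size uses the exact noncentral-t power of the one-tailed paired
test: power(n) = P(T′ > t₁₋α,ₙ₋₁) with T′ noncentral t(df = n−1,
nc = d·√n), scanned upward from n = 2. With the unrounded
d = 7.92/14.8 the power is 0.89996 at n = 41 and 0.9072 at n = 42, so the
returned n is 42; the 41/42 boundary is why the exact distribution, not a
normal approximation, is required. Tests cross-check the power values
against statsmodels' TTestPower and against direct simulation of the test
statistic.

## Rank-based volume overlap

Both volumes are restricted to the shared mask intersected with both
finite-value supports (no statistical threshold is applied to the t-map),
rank-transformed descending with average ranks at ties, and discretized
into equal-count bins (default 10; with no ties each bin holds n/10
voxels). Mutual information of the joint bin histogram is computed in
nats and normalized by min(H(A), H(B)) of the binned marginals, reported
×100. With equal-count bins the ceiling is log(bins) absent ties; tie
structure and in-mask voxel count make the attainable maximum
dataset-specific, which is why the score is expressed as a percentage of
each pair's own ceiling. The estimator is clamped to [0, H_min] to absorb
float round-off at the two exact boundary cases (identical and
independent maps). Bin-count sensitivity: re-running with bins ∈ {5, 10,
20} is a one-argument change; the synthetic-overlap monotonicity property
holds across that range. The supplementary checks are the Pearson
correlation of the two in-mask rank fields (a Spearman rho of the raw
maps) and the Euclidean MNI distance between two coordinate triplets.

The synthetic volume pairs place Gaussian activation blobs inside an
ellipsoidal mask and an exponentially decaying field from a source on the
mask surface; `overlap_strength` rotates the source direction from
uniformly random (0) to the direction of the strongest blob (1). At
strength 0 the two maps are co-localized only by chance, so the expected
MI rises monotonically with the dial — a random rather than antipodal
baseline is deliberate, because rank MI also detects *anti*-alignment and
an antipodal source would score spuriously high. These synthetic fields
are far smoother and more isotropic than real t-maps and e-fields
(single-compartment decay, no sulcal geometry, no dropout), so overlap
results on them validate the estimator's behavior, not neuroanatomical
realism.

## Problem sizes and numerical choices

Simulation-based tests use 500 replicates for adaptive-threshold recovery
(trial counts 20–160), 2,000 cohorts for type-I calibration and power
recovery, 10,000 replicates for the power simulation cross-check, 50
seeds for the overlap-dial property, and 200 stimuli for the realized
coherence check — sizes at which every Monte-Carlo tolerance (3–3.3
binomial SEs) is meaningful while the whole suite runs in about a minute.
All randomness flows through numpy `SeedSequence` derivation from
user-supplied integer seeds; reruns are bit-identical.

## Known limitations

- The engine models no lapse rate; a real observer's lapses bias
  recovered thresholds upward (the simulated-observer class exposes a
  lapse parameter so this can be quantified, and the session tests do so
  implicitly at lapse 0).
- Timeout trials are ingested as incorrect in simulation; real-data
  ingestion should mark them explicitly before analysis.
- The RM-ANOVA applies no sphericity correction by design (matching the
  registered plan); with three conditions and moderate n this is mild but
  not innocuous.
- The overlap normalization (min marginal entropy) is one of several
  defensible choices; scores are comparable across bin counts only within
  a fixed convention.
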