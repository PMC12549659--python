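# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and event detection

A walk record is the vertical ground-reaction force (VGRF) of each foot,
sampled at 100 Hz by 16 in-shoe force-sensitive resistors (8 per sole),
plus the per-foot totals. All analysis uses the totals; the per-sensor
channels are carried for format fidelity only.

Conditioning follows a fixed order: per-channel min–max normalization to
[0, 1], removal of the first 20 s and last 10 s of the walk (gait
initiation and termination are not steady-state), and a 9-sample median
filter with reflect padding. The order barely matters in practice — the
event threshold is *relative* (20% of the channel's peak), so detection is
scale-invariant, and the test suite verifies that event times are identical
with normalization on or off. Walks shorter than 40 s fail the fixed trim
by default; an opt-in flag trims proportionally (⅓ head, ⅙ tail) instead.

Heel strike (HS) is the upward crossing of 20% of peak force, toe off (TO)
the subsequent downward crossing. Implementation details that the bare
definition leaves open:

- **Sub-sample timing.** Crossing times are linearly interpolated between
  the bracketing samples, so events are not quantized to the 10 ms grid.
- **Debounce.** Above-threshold runs separated by gaps shorter than 100 ms
  are merged, and runs shorter than 100 ms discarded — no physiological
  stance or swing is that short, so these are threshold chatter.
- **Partial stances.** A run that starts at the first sample or ends at the
  last has an unobservable crossing and is dropped.
- **Peak definition.** The peak is the maximum of the median-filtered,
  trimmed channel; filtering already suppresses the spikes that would
  otherwise make a raw maximum fragile.

A cycle spans two successive same-foot heel strikes and must contain
exactly one toe off. Cycles with stride time outside [0.4, 2.5] s or stance
fraction outside [0.40, 0.90] (adult walking bounds) are retained but
flagged invalid with reason codes; only valid cycles enter the feature
matrix, and the counts of excluded rows are reported.

## Feature panel

Each matrix row is one valid cycle of one foot. The 27-column default panel
comprises: stride/stance/swing times and percentages, cadence
(120/stride), stance-to-swing ratio, step time, walking speed, stride and
step length, trailing-window (10-cycle) standard deviations of stride,
stance, swing and cadence, the corresponding coefficients of variation,
left/right asymmetry indices (|L−R|/mean) for stride and stance time, the
contralateral foot's timing at the paired cycle, bilateral means, and a
foot indicator. Several columns are exact or near-exact functions of
others (swing% = 100 − stance%, step time = stride/2, stride length =
speed × stride) — the panel is deliberately redundant so that correlation
pruning has real work to do, mirroring feature inventories built by
accreting variants of the same timing quantities.

Two modeling choices deserve emphasis:

- **Stride length is modeled, not measured.** Vertical force alone cannot
  give displacement, so stride_length = reference_speed × stride_time, with
  the reference speed read per subject from the demographics table
  (`speed_mps`) when present and from the feature config (default 1.2 m/s)
  otherwise. When the speed column is informative (as when it comes from a
  clinical walking-speed measurement), the derived distance features are
  informative; when it is a constant, they are redundant with stride time
  and get pruned.
- **Variability is a trailing window.** Each cycle's variability features
  use only that cycle and its 9 predecessors, so a row never sees future
  cycles; the first 9 cycles of each foot have undefined variability and
  are dropped (counted as warm-up). A subject-level sd would be constant
  across the subject's rows and leak identity into cycle-level folds.

## Curation (CRISP stages 1–2)

Correlation pruning flags pairs with |Pearson r| ≥ 0.80 after rounding to
two decimals (the rounding is part of the flagging rule, not cosmetic), and
resolves them greedily by descending rounded |r|: the member with lower
mutual information (MI) against the class label is dropped, ties dropping
the lexicographically later name. Because a pair is only resolved when both
members are still retained, chains of collinear features collapse onto
their most label-informative member, and the post-condition — no retained
pair at or above the threshold — is testable and tested.

MI is estimated by 10-bin quantile discretization of the feature followed
by the plug-in contingency formula (nats). Quantile binning makes the
estimate invariant to strictly monotone transforms and exactly zero for
constant features; it is biased upward for small n like every plug-in
estimator, but only the *ranking* within a flagged pair matters here.

RFE wraps a 100-tree random forest, eliminating one feature per iteration
until 10 remain; one-at-a-time elimination gives a complete ranking at
negligible cost for ≤ 30 columns. Both stages fit on training rows only.
When pruning leaves fewer than 10 columns (possible on heavily redundant
panels), RFE keeps all of them — the selected count is
min(10, retained).

## SMOTE (CRISP stage 3)

Class counts are equalized to the majority by synthetic interpolation:
x_new = x_i + δ·(x_zi − x_i), δ ~ U[0, 1], with x_zi drawn uniformly from
the k = 5 same-class nearest neighbours of x_i. Neighbourhoods use
Euclidean distance after standardizing the (training) columns — without
standardization the nearest-neighbour graph is dominated by whichever
column has the largest scale. Interpolation itself happens in the original
feature space. Base rows are visited round-robin rather than sampled, a
deliberate deviation from classical SMOTE that lowers coverage variance
and makes the provenance audit exhaustive; the neighbour choice and δ
remain random. Every synthetic row records (base, neighbour, δ), and
`verify_synthetic_geometry` re-derives it to < 1e-9 per coordinate. k is
truncated with a warning when a minority class has fewer than k + 1
members; a singleton minority is an error.

## Classifiers and tuning

KNN, decision tree, random forest, gradient boosting and XGBoost run
behind a single adapter that enforces the shared contract: posterior rows
sum to one, the predicted label is the posterior argmax, prediction-time
columns must match fit-time columns, and everything is deterministic under
a fixed seed. KNN operates on standardized features (a scaler is part of
its estimator); tree ensembles are scale-invariant and use raw features.
Gradient-boosted backends come from scikit-learn and xgboost — the additive
ensemble update and the second-order regularized objective are the
backends' contracts, not re-implemented here.

Grid search (exhaustive, stratified 5-fold inner CV on accuracy, ties to
the first candidate in documented grid order) is available and tested, but
`run_experiment` defaults to untuned models: the package's experiments are
about the curation pipeline, not hyperparameter optimization, and nested
search multiplies runtime by the grid size without changing the
CRISP-vs-baseline comparison that the experiments measure.

## Evaluation protocol

Folds are subject-grouped and label-stratified by default: no subject's
cycles ever straddle train and test, which is the only clinically
defensible split (cycle-level stratified splitting is available to emulate
the alternative, identity-leaking reading). The same five folds serve every
model and configuration, so paired comparisons are paired by fold.

The *overall* protocol scores pooled cycle predictions; the *subject-wise*
protocol first collapses each test subject's cycles into one decision —
majority vote (binary) or modal class (severity), exact ties broken by the
highest mean posterior among the tied classes — and scores subjects.
Metrics: accuracy, precision, recall, specificity, F1 (percent) and
ROC-AUC, PD-positive for the binary task, macro one-vs-rest for severity.
Zero-denominator ratios report 0 with a flag; AUC is NaN when a fold's
truth contains a single class. CRISP vs baseline is compared per metric by
two-sided paired t-tests over folds (df = folds − 1) at α = 0.05 without
multiplicity correction; all-zero difference vectors report p = 1, flagged
degenerate.

A `LeakageGuard` snapshots each fold's held-out rows at construction,
exposes features only, and raises an audit error on any label access before
predictions exist; the test suite additionally verifies that arbitrary
perturbation of held-out rows leaves every fitted artifact (pruning result,
RFE ranking, SMOTE provenance, tuned spec) bit-identical.

## Synthetic cohorts

The simulator generates per-foot VGRF as a sum of stance templates
f(s) = sin(πs)^0.4 · (1 + 0.3·cos(2πs)·sin(πs)) on normalized stance time
s ∈ [0, 1]: a double bump (loading response near 25%, push-off near 75%,
midstance valley at 0.70 of peak ≈ 610 N for a 700 N body force) whose
steep edges put the 20%-of-peak crossing within ~3 ms of the true support
boundary — so the generator's event times serve as an oracle for the
detector at the 10 ms level. Feet are offset by half a stride; the 16
sensor channels split each foot's total by fixed nonnegative weights
summing to one; Gaussian sensor noise (default sd 10 N) is added and
clipped at zero.

Cohorts are hierarchical: subject-level timing parameters are drawn from
class distributions (between-subject sd), then each cycle perturbs them
(within-subject sd), so subject identity genuinely correlates cycles and
subject-wise evaluation differs from cycle-level. Default contrasts follow
the parkinsonian pattern — PD: longer stride time (1.13 vs 1.04 s), higher
stance fraction (0.625 vs 0.615), lower speed (1.08 vs 1.25 m/s), and
elevated within-subject variability (stride sd 0.035 vs 0.020 s); each
Hoehn–Yahr stage step adds a configurable gradient (default 0.04 s stride,
with proportional stance/speed/variability shifts). Stage- and class-count
knobs (`stage_weights`, `n_hc`) inject imbalance. Two presets matter:

- defaults: stage-1 PD overlaps slow controls by design (~1.5 between-subject
  sd on speed), so subject classification has an irreducible error floor —
  realistic, and the reason end-to-end accuracy checks do not use it;
- `high_separation_config`: class gaps of ~3–4 between-subject sd with low
  noise, a cohort whose Bayes error is negligible, used where a check must
  attribute any error to the pipeline rather than to class overlap.

What the simulator does **not** emulate: waveform-shape pathology (it
varies timing, not morphology), dual-task or treadmill conditions, sensor
drift and saturation, real demographic structure, and longitudinal change.
Passing tests therefore certify the pipeline's mechanics — event recovery,
feature fidelity, leakage-free curation, voting and statistics — not
clinical performance on real cohorts.

## Scale of the shipped experiments

The test suite and acceptance script use cohorts of 20 subjects/class
(binary) or 12 subjects/stage-weight-unit (severity), one 60 s walk per
subject, averaged over 5 simulation seeds (12 for the severity F1
comparison, whose effect is small — see below). These sizes give stable
estimates of every directional property while keeping a full run in
minutes on one CPU; larger cohorts change nothing qualitatively.

## Honest characterization of the CRISP effect in simulation

On these synthetic cohorts the CRISP-vs-baseline difference is small.
Gradient-boosted baselines handle the injected stage imbalance well (the
minority stage still contributes hundreds of cycles), so SMOTE's headroom
is limited; correlation pruning and RFE mostly remove redundancy that tree
ensembles tolerate anyway. The measured benefit is a directional
improvement in macro F1 on the skewed severity task (about +1 to +3 points,
seed-dependent) and in specificity under binary imbalance, not the large
gains achievable on richer real data. The acceptance checks therefore
assert direction (CRISP ≥ baseline at fixed conditions), never magnitude.

## Known limitations

- Stride/step length and speed features depend on the reference-speed
  model; with constant reference speed they carry no information beyond
  stride time.
- The MI estimator's absolute values are bin-count dependent; only
  within-pair comparisons are used.
- Severity stages are configurable but default to {1, 2, 3}; cohorts using
  a different staging convention must set the stage set explicitly.
- Paired t-tests over 5 folds have low power and are reported without
  multiplicity correction.
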