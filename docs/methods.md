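# Methods

## The assay and what the pipeline computes

The pipeline analyses a FACS-based reporter assay for Smoothened (Smo)
activation in a clonal insect cell line. Cells express a Smo–circularly
permutated GFP fusion that fluoresces only in the active conformation, so a
single fluorescence channel (FL1) reports per-cell pathway state; forward
and side scatter (FSC/SSC) identify intact cells. Stimulation is Hh
conditioned medium mixed with fresh medium; the *dose* throughout is the
conditioned-medium volume fraction in [0, 1] (a mixing ratio written
`c:f` parses to `c/(c+f)`, so "1:5" is 1/6).

The analysis chain is: scatter gating → per-well QC → gated-population
median fluorescence → dual-control normalization → target-class clustering
and hit calling, plus a single-cell dose-response branch (mixture modelling
→ responder fractions → threshold-distribution fit).

## Population model behind the simulator

Every stage is testable without instrument data because the
`simulate` module generates event-level wells with known ground truth:

- **Threshold heterogeneity.** Each viable cell carries an activation
  threshold drawn from a log-normal distribution on dose
  (`mu_theta`, `sigma_theta`). A cell at dose `d` is "on" with probability
  `F_theta(d)`, the log-normal CDF; dose 0 activates with probability
  exactly 0 so unstimulated controls are clean negatives. This is the
  simplest positive-support model that produces bimodal histograms at
  intermediate doses: increasing dose recruits more responders rather than
  shifting the whole population.
- **Fluorescence.** Off- and on-state fluorescence are log-normal
  (`mu_off = log 150`, `mu_on = log 2500`, scales 0.35). The on-state
  location is dose-independent, matching the observation that saturating
  stimulation does not brighten individual responders. The separation
  (≈2.8 log units ≥ 3× the mode scale) makes intermediate doses
  unambiguously bimodal.
- **Scatter and debris.** Viable-cell FSC/SSC are bivariate log-normal
  (correlation 0.5); a configurable `debris_fraction` (default 0.05) of
  events comes from a separate, smaller-scatter debris population used to
  exercise the gate and the QC rule.
- **Defaults as study conditions.** `mu_theta = log 0.05`,
  `sigma_theta = 0.8` put the median activation threshold at a 5%
  conditioned-medium fraction and the 95%-responder dose near 0.19 ≈ a 1:5
  mixing ratio; wells acquire 4000 events; stimulated screen wells receive
  dose 0.5 (the conventional 1:1 mixture).
- **Compound action.** Compounds act multiplicatively on the natural-scale
  medians of the off state, on state and threshold, and additively on the
  debris fraction (toxicity), clamped to [0, 0.95]. These four numbers are
  the ground-truth manifest a simulated screen emits.
- **Kinetics.** When a stimulation time is given, the on/off separation is
  scaled by the saturating factor `t/(t + tau)` with `tau = 6 h`, making
  the signal weak at 4 h and near-maximal at 24 h; the core screen path
  assumes the 24 h steady state.
- **Reproducibility.** Per-well random streams derive from a master seed by
  SHA-256 of `"<seed>|<tag>"` (first 4 bytes, mod 2^31) — never Python's
  randomized `hash`. Fixed seeds give bit-identical wells.

What the simulator does *not* emulate: cell growth or division, autocrine
ligand production, spectral compensation, instrument saturation or
acquisition-time drift, and any within-cell threshold variability over time
(thresholds are fixed per event draw; whether real cells re-draw their
threshold over time is an open biological question). Passing tests
therefore demonstrate the correctness of the analysis machinery under this
generative model, not the behaviour of any real cell line.

## Gating

Real screens gate by hand; the pipeline replaces this with a deterministic,
auditable construction: a Mahalanobis ellipse in log FSC/SSC. Location and
covariance come from the minimum-covariance-determinant estimator (fixed
random state; fitted on a deterministic subsample of at most 2000 pooled
control events when the pool is larger), and the radius is the order
statistic of rank `ceil(q·n)` of all control Mahalanobis distances, so the
realized control coverage is within `1/n` of the target quantile
(default `q = 0.90`). The gate is fitted once per plate on the unstimulated
control wells (configurable) and applied to every well. Boundary events —
distance exactly equal to the radius — count as inside. A well passes QC
only when *strictly more than half* of its events are in-gate.

## Normalization and per-well statistics

The per-well statistic is the exact median (midpoint convention for even
counts) of in-gate fluorescence, optionally on a seed-deterministic
without-replacement subsample emulating a fixed acquisition count. Plate
control medians are the medians *of the per-well medians* of the respective
control wells, robust to one bad control well. The normalized response is

    100 · (med_treat − med_neg) / (med_pos − med_neg)

so the stimulated control is 100% and the mock control 0% by construction;
values are not clamped (negative responses mean below the unstimulated
baseline). A plate whose control span falls below 1e-6 of the negative
control is reported as a failed assay. Both stimulated and mock-stimulated
sample wells are normalized against the same control pair. Replicate
comparisons use the two-sided Mann–Whitney U test: the exact permutation
null (full label-assignment enumeration, tie-safe) for total n ≤ 10,
otherwise the normal approximation with tie correction.

## Clustering and hit calling

Compounds are grouped by annotated primary target class; the annotation
file is the contract (pathway-level regrouping is a second annotation
column supplied by the user). QC-failing compounds are excluded before
counting; classes with fewer than 3 remaining members are suppressed but
reported. Clusters are ranked by median normalized response. Hit thresholds
default to 150% (up) and 80% (down) — the down rule reads "at least a 20%
reduction of the stimulated response" on the normalized scale — and the hit
table also reports the fraction of member compounds individually beyond
each threshold. The two screen concentrations are analysed separately; no
cross-concentration pooling. Cluster ranking carries no p-values by
default; when cluster-vs-control tests are requested, Benjamini–Hochberg
FDR is applied and both raw and adjusted values reported. Cross-condition
reproducibility is a Spearman rank correlation over the key intersection,
with an audit of dropped entries.

## Mixture model and threshold recovery

Bimodality is assessed on log fluorescence with one- and two-component
Gaussian mixtures. EM initializes deterministically from the median split
(optional seeded random restarts), floors component scales at 1e-3 log
units, and stops when the relative log-likelihood improvement falls below
1e-8 or after 500 iterations (the relative form keeps the criterion
independent of event count). A well is *bimodal* when
`BIC(k=1) − BIC(k=2) > 10`, the minority weight is ≥ 0.05 and the locations
are ≥ 2 pooled scales apart; a two-component fit violating the weight or
separation guard is flagged degenerate (the separation guard is
scale-aware — `max(0.1, 2·pooled scale)` — because EM on a single mode
happily converges to two overlapping half-weight components).

The responder fraction of a bimodal well is the upper component's weight.
Unimodal wells are assigned 0 or 1 against the unstimulated-control
location: within 2 control scales → 0; clearly above → 1; clearly *below* →
0 (a mode far under the off control cannot be a responding population —
e.g. a strongly quenching compound); with no reference the result is
explicitly indeterminate rather than guessed.

The threshold distribution is recovered by weighted least squares of the
log-normal CDF to (dose, fraction) pairs, weights proportional to event
counts, initialized by probit regression and solved with bounded
trust-region least squares (`sigma` constrained to [1e-3, 10]). The fit
requires ≥ 4 distinct non-zero doses and a mix of fractions (all-0/all-1
series are unidentifiable). Confidence intervals are percentile bootstrap
over wells (200 replicates by default; resamples that become degenerate are
dropped and counted). The fit operates on per-well fractions rather than a
joint likelihood over all events — more robust to mixture misfit at extreme
doses and fully auditable from the per-dose table. `saturation_dose` is the
closed-form log-normal quantile.

## Problem sizes and numerical checks

The repeated simulation studies use 8 doses × 10,000 events for threshold
recovery (50 seeded runs; success = both parameters within 10% relative
error, required in ≥ 90% of runs), 100 seeds × 4000 events for the
bimodality operating characteristics, and 50 full 384-well × 4000-event
screens for spiked-class ranking. FCS round trips are exact to float32
precision (~7 significant digits). All tolerances asserted in tests were
computed from the oracles described there (binomial tails, enumeration,
grid search), not tuned.

## Known limitations

- The mixture/CDF machinery formalizes what the underlying experiments
  report qualitatively from histograms; fitted threshold parameters
  describe the generative model, not a measured biological quantity.
- The gate is elliptical and scatter-only; no doublet discrimination or
  fluorescence gating.
- One plate per analysis run; no cross-plate batch correction beyond the
  per-plate control pair.
- The FCS writer/reader covers exactly the subset of FCS 3.0 the pipeline
  produces (float32 list mode, three channels); it is not a general parser.
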