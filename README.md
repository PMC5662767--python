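# smoscreen

Analysis pipeline for FACS-based small-molecule screens of Smoothened (Smo)
activation, built around a fluorescent conformation sensor read out one
cell at a time on a flow cytometer. It is aimed at people running (or
re-analysing) plate-format flow screens: it turns per-well event data into
gated, QC'd, control-normalized responses, aggregates compounds into
target-class clusters with hit calls, and models the single-cell
dose-response — the bimodal fluorescence histograms that arise when each
cell carries its own activation threshold.

Because such screens rarely ship raw event data, the package includes a
synthetic flow-data generator with full ground truth (cell-specific
log-normal activation thresholds, log-normal on/off fluorescence states, a
debris scatter population, multiplicative compound effects), so every stage
of the pipeline is testable end to end.

## The statistics at the core

**Normalized response.** For a well with gated-population median
fluorescence `m`, against the plate's stimulated (`m⁺`) and mock (`m⁻`)
control medians:

    R = 100 · (m − m⁻) / (m⁺ − m⁻)   [%]

so the Hh-stimulated control is 100%, the unstimulated control 0%.

**Gating and QC.** A Mahalanobis ellipse on log FSC/SSC fitted to control
wells (robust covariance, radius = empirical coverage quantile, default
90%); wells with ≤ 50% of events in-gate are excluded (strict rule).

**Responder fraction and threshold distribution.** Log-fluorescence is fit
with 1- and 2-component Gaussian mixtures (EM); a BIC rule with weight and
separation guards decides bimodality; the upper component's weight
estimates the fraction of responding cells. Across a dilution series the
expected responder fraction at dose `d` is the log-normal threshold CDF
`F(d; μ_θ, σ_θ)`, recovered by weighted least squares with bootstrap
confidence intervals.

**Hit calling.** Compounds cluster by annotated primary target; classes
with ≥ 3 QC-passing members are ranked by median response; defaults call
up-hits at ≥ 150% and down-hits at ≤ 80% (a ≥ 20% reduction of the
stimulated response).

## Worked example: recovering the activation-threshold distribution

```python
import numpy as np
from smoscreen import (PopulationConfig, apply_gate, fit_gate, fit_mixture,
                       fit_threshold_distribution, responder_fraction,
                       saturation_dose, simulate_dilution_series, simulate_well)

cfg = PopulationConfig(n_events=10_000, seed=0)   # median threshold at dose 0.05
control = simulate_well(cfg, dose=0.0, seed=1)
gate = fit_gate(control, coverage_quantile=0.99)
off_reference = fit_mixture(apply_gate(control, gate).gated_events.fl, k=1)

doses = [0.005, 0.01, 0.02, 0.05, 0.1, 0.15, 0.25, 0.5]
series = []
for table, dose in zip(simulate_dilution_series(cfg, doses, seed=2), doses):
    gated = apply_gate(table, gate)
    frac = responder_fraction(gated.gated_events.fl, reference_off=off_reference, seed=0)
    series.append((dose, frac, gated.n_gated))
    print(f"dose {dose:5.3f}  responder fraction {frac:.3f}")

model = fit_threshold_distribution(series, seed=3)
print(f"mu_theta_hat    = {model.mu_theta_hat:.3f}   (truth {cfg.mu_theta:.3f})")
print(f"sigma_theta_hat = {model.sigma_theta_hat:.3f}   (truth {cfg.sigma_theta:.3f})")
print(f"median threshold dose = {np.exp(model.mu_theta_hat):.4f}")
print(f"95% saturation dose   = {saturation_dose(model, 0.95):.3f}")
```

Output:

```
dose 0.005  responder fraction 0.000
dose 0.010  responder fraction 0.000
dose 0.020  responder fraction 0.118
dose 0.050  responder fraction 0.471
dose 0.100  responder fraction 0.767
dose 0.150  responder fraction 0.880
dose 0.250  responder fraction 0.933
dose 0.500  responder fraction 1.000
mu_theta_hat    = -2.914   (truth -2.996)
sigma_theta_hat = 0.858   (truth 0.800)
median threshold dose = 0.0542
95% saturation dose   = 0.223
```

The per-dose fractions trace the threshold CDF: almost no cells respond at
a 0.5–1% conditioned-medium fraction, about half respond at the median
threshold (5%), and the population saturates above ~20% — i.e. near a 1:5
conditioned:fresh mixing ratio. The weighted CDF fit recovers both
log-normal parameters within the bootstrap confidence intervals
(μ_θ 95% CI [−2.99, −2.81], σ_θ [0.70, 0.97] on this seed).

## Command line

```sh
smoscreen simulate --outdir sim --n-compounds 368 --n-classes 30 --seed 1
smoscreen screen --config config.yaml      # gate → QC → summaries → clusters → hits
smoscreen dose series.csv --out model.json # threshold-distribution fit
```

`simulate` writes per-well FCS 3.0 files (or a long-format CSV), the plate
map, a compound annotation and the ground-truth manifest; `screen` writes
`well_summary.csv`, `qc_report.csv`, `clusters.csv`, `hits.csv`,
`gate.json` and a provenance log.

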