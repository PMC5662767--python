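"""Single-cell threshold model: bimodality, responder fractions, CDF fit.

At intermediate ligand doses a well's fluorescence histogram is a mixture of
an off and an on population; the fraction of cells in the on state (the
*responder fraction*) rises with dose. If each cell carries a log-normally
distributed activation threshold, the expected responder fraction at dose
``d`` equals the threshold CDF ``F(d; mu_theta, sigma_theta)``. This module

1. fits one- and two-component Gaussian mixtures to log fluorescence (EM,
   deterministic quantile-split initialization),
2. decides bimodality by a BIC comparison with effect-size guards,
3. turns mixtures into per-well responder fractions, and
4. recovers ``(mu_theta, sigma_theta)`` by weighted least squares of the
   log-normal CDF over a dilution series, with bootstrap confidence
   intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: EM stopping rule: relative log-likelihood improvement below this value.
EM_TOL = 1e-8
EM_MAX_ITER = 500
#: Component scales never shrink below this many log units (anti-collapse).
SCALE_FLOOR = 1e-3

#: Bimodality guards: BIC(1) - BIC(2) must exceed this, minority weight at
#: least 0.05, and locations separated by >= 2 pooled scales.
DELTA_BIC_THRESHOLD = 10.0
MIN_COMPONENT_WEIGHT = 0.05
MIN_SEPARATION_SCALES = 2.0


class IndeterminateResponseError(ValueError):
    """Unimodal well with no off-state reference: cannot assign 0 or 1."""


@dataclass
class MixtureFit:
    """Gaussian mixture on log fluorescence (locations ascending for k=2)."""

    k: int
    weights: np.ndarray
    locations: np.ndarray
    scales: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    n_obs: int
    degenerate_bimodal: bool = False

    def responsibilities(self, log_values: np.ndarray) -> np.ndarray:
        """Posterior component membership probabilities, shape (n, k)."""
        dens = np.stack(
            [
                w * stats.norm.pdf(log_values, m, s)
                for w, m, s in zip(self.weights, self.locations, self.scales)
            ],
            axis=1,
        )
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


@dataclass
class ThresholdModel:
    """Fitted log-normal activation-threshold distribution."""

    mu_theta_hat: float
    sigma_theta_hat: float
    per_dose: list[tuple[float, float, int]]  # (dose, fraction_hat, n_events)
    fit_rss: float
    ci: dict = field(default_factory=dict)

    def cdf(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        out = np.zeros_like(dose)
        pos = dose > 0
        out[pos] = stats.norm.cdf(
            (np.log(dose[pos]) - self.mu_theta_hat) / self.sigma_theta_hat
        )
        return out


def _loglik(x: np.ndarray, w, mu, sd) -> float:
    dens = np.zeros_like(x)
    for wi, mi, si in zip(w, mu, sd):
        dens += wi * stats.norm.pdf(x, mi, si)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_mixture(
    fl_values: np.ndarray,
    k: int,
    seed: int | None = None,
    n_random_restarts: int = 0,
) -> MixtureFit:
    """EM fit of a k-component Gaussian mixture to log fluorescence.

    k=1 is closed form. k=2 initializes deterministically from the
    median split of the log values; optional random restarts (seeded)
    keep the better likelihood. Scales are floored at 1e-3 log units;
    convergence is declared when the relative log-likelihood improvement
    drops below 1e-8, capped at 500 iterations.
    """
    fl = np.asarray(fl_values, dtype=float)
    if fl.size < 50:
        raise ValueError(f"need >= 50 fluorescence values, got {fl.size}")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if np.any(fl <= 0) or not np.all(np.isfinite(fl)):
        raise ValueError("fluorescence values must be positive and finite")
    x = np.log(fl)
    n = x.size

    if np.ptp(x) == 0:  # all identical: degenerate single-point fit
        import warnings

        warnings.warn("all fluorescence values identical; degenerate k=1 fit",
                      stacklevel=2)
        return MixtureFit(
            k=1, weights=np.array([1.0]), locations=np.array([x[0]]),
            scales=np.array([SCALE_FLOOR]), loglik=float("nan"),
            bic=float("inf"), converged=True, n_iter=0, n_obs=n,
            degenerate_bimodal=(k == 2),
        )

    if k == 1:
        mu, sd = float(x.mean()), max(float(x.std()), SCALE_FLOOR)
        ll = _loglik(x, [1.0], [mu], [sd])
        return MixtureFit(
            k=1, weights=np.array([1.0]), locations=np.array([mu]),
            scales=np.array([sd]), loglik=ll,
            bic=-2 * ll + 2 * np.log(n), converged=True, n_iter=0, n_obs=n,
        )

    def em(w0, mu0, sd0):
        w, mu, sd = np.array(w0, float), np.array(mu0, float), np.array(sd0, float)
        ll_old = -np.inf
        converged = False
        for it in range(1, EM_MAX_ITER + 1):
            dens = np.stack(
                [wi * stats.norm.pdf(x, mi, si) for wi, mi, si in zip(w, mu, sd)],
                axis=1,
            )
            total = dens.sum(axis=1)
            total = np.maximum(total, 1e-300)
            ll = float(np.sum(np.log(total)))
            resp = dens / total[:, None]
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
            sd = np.maximum(np.sqrt(var), SCALE_FLOOR)
            if abs(ll - ll_old) < EM_TOL * (1.0 + abs(ll)):
                converged = True
                break
            ll_old = ll
        ll = _loglik(x, w, mu, sd)
        return w, mu, sd, ll, converged, it

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # guard: heavy ties at the median
        lo, hi = x[:-1], x[-1:]
    inits = [
        (
            [lo.size / n, hi.size / n],
            [lo.mean(), hi.mean()],
            [max(lo.std(), 10 * SCALE_FLOOR), max(hi.std(), 10 * SCALE_FLOOR)],
        )
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_restarts):
        pick = rng.choice(n, size=2, replace=False)
        inits.append(([0.5, 0.5], x[pick].tolist(), [x.std(), x.std()]))

    best = None
    for w0, mu0, sd0 in inits:
        fit = em(w0, mu0, sd0)
        if best is None or fit[3] > best[3]:
            best = fit
    w, mu, sd, ll, converged, n_iter = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    # degenerate-bimodal: vanishing component, or locations closer than
    # 0.1 log units or two pooled scales (overlapping halves of one mode)
    pooled = float(np.sqrt(np.sum(w * sd**2)))
    degenerate = bool(
        w.min() < MIN_COMPONENT_WEIGHT
        or abs(mu[1] - mu[0]) < max(0.1, MIN_SEPARATION_SCALES * pooled)
    )
    return MixtureFit(
        k=2, weights=w, locations=mu, scales=sd, loglik=ll,
        bic=-2 * ll + 5 * np.log(n), converged=converged, n_iter=n_iter,
        n_obs=n, degenerate_bimodal=degenerate,
    )


def _bimodal_verdict(
    fit1: MixtureFit,
    fit2: MixtureFit,
    delta_bic_threshold: float = DELTA_BIC_THRESHOLD,
    min_weight: float = MIN_COMPONENT_WEIGHT,
    min_separation: float = MIN_SEPARATION_SCALES,
) -> tuple[str, float]:
    if not np.isfinite(fit2.bic):  # constant data: degenerate rule
        return "unimodal", 0.0
    delta = fit1.bic - fit2.bic
    pooled_scale = float(np.sqrt(np.sum(fit2.weights * fit2.scales**2)))
    separation = abs(fit2.locations[1] - fit2.locations[0])
    is_bimodal = (
        delta > delta_bic_threshold
        and fit2.weights.min() >= min_weight
        and separation >= min_separation * pooled_scale
    )
    return ("bimodal" if is_bimodal else "unimodal"), float(delta)


def bimodality_decision(
    fl_values: np.ndarray,
    seed: int | None = None,
    delta_bic_threshold: float = DELTA_BIC_THRESHOLD,
    min_weight: float = MIN_COMPONENT_WEIGHT,
    min_separation: float = MIN_SEPARATION_SCALES,
) -> tuple[str, float]:
    """Classify a well as "unimodal" or "bimodal"; returns (verdict, ΔBIC).

    Bimodal requires BIC(k=1) - BIC(k=2) > threshold AND a minority weight
    of at least ``min_weight`` AND component locations separated by at least
    ``min_separation`` pooled scales.
    """
    fit1 = fit_mixture(fl_values, k=1, seed=seed)
    fit2 = fit_mixture(fl_values, k=2, seed=seed)
    return _bimodal_verdict(
        fit1, fit2, delta_bic_threshold, min_weight, min_separation
    )


def responder_fraction(
    fl_values: np.ndarray,
    reference_off: MixtureFit | None = None,
    seed: int | None = None,
) -> float:
    """Estimated fraction of cells in the high-fluorescence (on) state.

    Bimodal wells return the weight of the upper mixture component. Unimodal
    wells are assigned 0 or 1 by comparing the single location to the
    unstimulated-control (off) location: within 2 control scales -> 0,
    clearly above -> 1, clearly below -> 0. Without a reference a unimodal
    well is indeterminate.
    """
    fit1 = fit_mixture(fl_values, k=1, seed=seed)
    fit2 = fit_mixture(fl_values, k=2, seed=seed)
    verdict, _ = _bimodal_verdict(fit1, fit2)
    if verdict == "bimodal":
        return float(fit2.weights[1])
    if reference_off is None:
        raise IndeterminateResponseError(
            "unimodal well with no off-state reference; supply reference_off"
        )
    ref_loc = float(reference_off.locations[0])
    ref_scale = float(reference_off.scales[0])
    loc = float(fit1.locations[0])
    if abs(loc - ref_loc) <= 2 * ref_scale:
        return 0.0
    return 1.0 if loc > ref_loc else 0.0


def fit_threshold_distribution(
    series: list[tuple[float, float, int]],
    n_boot: int = 200,
    seed: int | None = None,
) -> ThresholdModel:
    """Weighted least-squares fit of the log-normal threshold CDF.

    ``series`` holds (dose, responder_fraction, n_events) per well; weights
    are the event counts. Requires >= 4 distinct non-zero doses and a mix of
    fractions (all-0 or all-1 series are unidentifiable). Confidence
    intervals come from ``n_boot`` bootstrap resamples of the wells.
    """
    data = [(d, f, n) for d, f, n in series if d > 0 and np.isfinite(f)]
    doses = np.array([d for d, _, _ in data])
    fracs = np.array([f for _, f, _ in data])
    ns = np.array([n for _, _, n in data], dtype=float)
    if len(set(doses.tolist())) < 4:
        raise ValueError(
            f"need >= 4 distinct non-zero doses, got {len(set(doses.tolist()))}"
        )
    if np.all(fracs <= 0) or np.all(fracs >= 1):
        raise ValueError("all responder fractions at 0 (or all at 1): "
                         "threshold distribution unidentifiable")

    log_d = np.log(doses)

    def fit_once(log_d, fracs, w):
        # probit-regression start: z = (log d - mu) / sigma
        z = stats.norm.ppf(np.clip(fracs, 1e-4, 1 - 1e-4))
        slope, intercept = np.polyfit(log_d, z, 1)
        if slope <= 0:
            slope, intercept = 1.0, -np.median(log_d)
        mu0, sig0 = -intercept / slope, 1.0 / slope

        def resid(p):
            mu, log_sig = p
            sig = np.exp(log_sig)
            return np.sqrt(w) * (stats.norm.cdf((log_d - mu) / sig) - fracs)

        res = optimize.least_squares(
            resid,
            x0=[mu0, np.log(np.clip(sig0, 1e-3, 10.0))],
            bounds=([log_d.min() - 10, np.log(1e-3)], [log_d.max() + 10, np.log(10.0)]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        mu_hat, sig_hat = res.x[0], float(np.exp(res.x[1]))
        rss = float(np.sum((stats.norm.cdf((log_d - mu_hat) / sig_hat) - fracs) ** 2 * w))
        return float(mu_hat), sig_hat, rss

    w = ns / ns.sum()
    mu_hat, sig_hat, rss = fit_once(log_d, fracs, w)

    ci: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots_mu, boots_sig = [], []
        m = len(doses)
        for _ in range(n_boot):
            idx = rng.integers(0, m, size=m)
            bd, bf, bw = log_d[idx], fracs[idx], w[idx]
            if len(set(bd.tolist())) < 4 or np.all(bf <= 0) or np.all(bf >= 1):
                continue
            try:
                bm, bs, _ = fit_once(bd, bf, bw / bw.sum())
            except Exception:
                continue
            boots_mu.append(bm)
            boots_sig.append(bs)
        if len(boots_mu) >= 20:
            ci = {
                "mu_theta": tuple(np.percentile(boots_mu, [2.5, 97.5])),
                "sigma_theta": tuple(np.percentile(boots_sig, [2.5, 97.5])),
                "n_boot_used": len(boots_mu),
            }
    return ThresholdModel(
        mu_theta_hat=mu_hat,
        sigma_theta_hat=sig_hat,
        per_dose=[(float(d), float(f), int(n)) for d, f, n in data],
        fit_rss=rss,
        ci=ci,
    )


def saturation_dose(model: ThresholdModel, level: float = 0.95) -> float:
    """Dose at which the expected responder fraction reaches ``level``.

    Closed-form log-normal quantile: exp(mu + sigma * Phi^{-1}(level)).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return float(
        np.exp(model.mu_theta_hat + model.sigma_theta_hat * stats.norm.ppf(level))
    )


def summarize_time_course(wells: list[tuple[float, "object"]]) -> pd.DataFrame:
    """Sort (time, WellSummary) pairs into a descriptive time-course table."""
    if len(wells) < 2:
        raise ValueError("need >= 2 time points")
    rows = [
        {
            "time_h": float(t),
            "median_fl": s.median_fl,
            "normalized_response": s.normalized_response,
        }
        for t, s in wells
    ]
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)


def parse_medium_ratio(ratio: str) -> float:
    """Convert a conditioned:fresh mixing ratio to a dose fraction.

    ``"1:5"`` means 1 part conditioned medium to 5 parts fresh, i.e. a
    volume fraction of 1/6. A bare number is taken as the fraction itself.
    """
    text = str(ratio).strip()
    if ":" in text:
        cond, fresh = text.split(":")
        cond, fresh = float(cond), float(fresh)
        if cond < 0 or fresh < 0 or cond + fresh == 0:
            raise ValueError(f"invalid mixing ratio {ratio!r}")
        return cond / (cond + fresh)
    value = float(text)
    if not 0 <= value <= 1:
        raise ValueError(f"dose fraction {value} outside [0, 1]")
    return value


def plot_dose_histograms(
    tables,
    doses,
    bins: int = 60,
    path=None,
):
    """Panel of log-fluorescence histograms across a dilution series."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(tables)
    fig, axes = plt.subplots(n, 1, figsize=(4, 1.4 * n), sharex=True)
    if n == 1:
        axes = [axes]
    for ax, table, dose in zip(axes, tables, doses):
        ax.hist(np.log10(table.fl), bins=bins, color="#3b7", density=True)
        ax.set_ylabel(f"{dose:g}", rotation=0, labelpad=18, fontsize=8)
        ax.set_yticks([])
    axes[-1].set_xlabel("log10 fluorescence")
    fig.suptitle("dose (fraction conditioned medium)", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
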