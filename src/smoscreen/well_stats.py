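"""Per-well summary statistics and the dual-control plate normalization.

The screen's per-well statistic is the *normalized response*::

    100 * (median_treat - median_neg) / (median_pos - median_neg)

where ``median_pos`` is the Hh-stimulated untreated control and
``median_neg`` the mock-stimulated control of the same plate. By
construction the stimulated control maps to 100% and the unstimulated
control to 0%; values above 100% are super-activation, negative values lie
below the unstimulated baseline and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gating import GatedWell


class DegenerateControlsError(ValueError):
    """Stimulated and unstimulated control medians coincide: assay failed."""


@dataclass
class ControlPair:
    """Plate control medians (linear fluorescence units)."""

    med_pos: float
    med_neg: float

    def __post_init__(self) -> None:
        if self.med_pos <= 0 or self.med_neg <= 0:
            raise ValueError("control medians must be > 0")
        if self.med_pos == self.med_neg:
            raise DegenerateControlsError("med_pos == med_neg")


@dataclass
class WellSummary:
    well_id: str
    role: str
    compound_id: str | None
    concentration: float | None
    stimulated: bool
    qc_pass: bool
    n_gated: int
    median_fl: float | None
    normalized_response: float | None


def median_fluorescence(
    gated: GatedWell,
    subsample_n: int | None = None,
    seed: int | None = None,
) -> float:
    """Exact median of the gated fluorescence (midpoint convention).

    ``subsample_n`` draws a without-replacement subsample first (emulating a
    fixed per-well acquisition count); the draw is seed-deterministic.
    """
    fl = gated.gated_events.fl
    if fl.size == 0:
        raise ValueError(f"well {gated.well_id!r} has no gated events")
    if subsample_n is not None and subsample_n < fl.size:
        rng = np.random.default_rng(seed)
        fl = fl[rng.choice(fl.size, size=subsample_n, replace=False)]
    return float(np.median(fl))


def normalized_response(
    med_treat: float,
    controls: ControlPair,
    rel_tol: float = 1e-6,
) -> float:
    """Percent response relative to the plate's stimulated/unstimulated pair."""
    span = controls.med_pos - controls.med_neg
    if abs(span) <= rel_tol * abs(controls.med_neg):
        raise DegenerateControlsError(
            f"control span {span:.3g} below tolerance "
            f"({rel_tol:g} of med_neg {controls.med_neg:.3g}); plate assay failed"
        )
    return 100.0 * (med_treat - controls.med_neg) / span


def compare_to_control(
    treated_replicates: list[float],
    control_replicates: list[float],
) -> float:
    """Two-sided Mann-Whitney U p-value between replicate groups.

    Small samples (total n <= 10) use the exact permutation null over all
    label assignments (tie-safe); larger samples use the normal
    approximation with tie correction.
    """
    x = np.asarray(treated_replicates, dtype=float)
    y = np.asarray(control_replicates, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 replicate values")
    if x.size + y.size <= 10:
        res = stats.permutation_test(
            (x, y),
            lambda a, b, axis=-1: stats.mannwhitneyu(a, b, axis=axis).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return float(res.pvalue)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )
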