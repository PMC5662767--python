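"""Scatter gating: learn a viable-cell gate from control wells, apply it.

The gate is a Mahalanobis ellipse in log FSC/SSC space: robust location and
covariance are estimated on the pooled control events (minimum covariance
determinant), and the gate radius is the empirical ``coverage_quantile`` of
the control events' Mahalanobis distances. Wells with an in-gate fraction
of at most 50% fail QC (strict "more than 50%" rule); boundary events, at
distance exactly equal to the radius, count as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import MinCovDet

from .events import EventTable

#: QC rule: a well is kept only when strictly more than this fraction of its
#: events falls inside the scatter gate.
QC_GATED_FRACTION = 0.5

#: Robust covariance is fitted on at most this many (deterministically
#: subsampled) control events; the radius quantile always uses all of them.
MAX_FIT_EVENTS = 2000


class DegenerateScatterError(ValueError):
    """Control scatter is rank-deficient (e.g. all events identical)."""


@dataclass
class ScatterGate:
    """Elliptical gate in log-scatter space.

    ``center`` and ``shape`` are the robust location and covariance of the
    control events' (log FSC, log SSC); ``radius`` is the Mahalanobis
    distance that encloses ``coverage_quantile`` of the control events.
    """

    center: np.ndarray
    shape: np.ndarray
    radius: float
    coverage_quantile: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.shape = np.asarray(self.shape, dtype=float).reshape(2, 2)
        if not np.allclose(self.shape, self.shape.T):
            raise ValueError("gate shape matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.shape) <= 0):
            raise ValueError("gate shape matrix must be positive definite")
        if not 0 < self.coverage_quantile < 1:
            raise ValueError("coverage_quantile must be in (0, 1)")
        if self.radius <= 0:
            raise ValueError("gate radius must be > 0")

    def mahalanobis(self, events: EventTable) -> np.ndarray:
        """Mahalanobis distance of each event's (log fsc, log ssc)."""
        x = np.column_stack([np.log(events.fsc), np.log(events.ssc)])
        d = x - self.center
        prec = np.linalg.inv(self.shape)
        return np.sqrt(np.einsum("ij,jk,ik->i", d, prec, d))

    def contains(self, events: EventTable) -> np.ndarray:
        """Boolean in-gate mask; boundary (distance == radius) is inside."""
        return self.mahalanobis(events) <= self.radius

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "center": self.center.tolist(),
                "shape": self.shape.tolist(),
                "radius": self.radius,
                "coverage_quantile": self.coverage_quantile,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, text_or_path) -> "ScatterGate":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        return cls(
            center=np.array(obj["center"]),
            shape=np.array(obj["shape"]),
            radius=obj["radius"],
            coverage_quantile=obj["coverage_quantile"],
        )


@dataclass
class GatedWell:
    """One well after gating, with the strict >50% in-gate QC verdict."""

    well_id: str
    n_total: int
    n_gated: int
    gated_events: EventTable

    @property
    def gated_fraction(self) -> float:
        return self.n_gated / self.n_total

    @property
    def qc_pass(self) -> bool:
        return self.gated_fraction > QC_GATED_FRACTION


def fit_gate(
    control_events: EventTable | list[EventTable],
    coverage_quantile: float = 0.90,
) -> ScatterGate:
    """Fit the viable-cell ellipse to (pooled) control-well events.

    Location/covariance come from the minimum-covariance-determinant
    estimator on log FSC/SSC (fitted on a deterministic subsample when the
    pool is large); the radius is the order statistic of rank
    ``ceil(q * n)`` of all control Mahalanobis distances, so the realized
    in-gate fraction of the controls is within 1/n of ``q``.
    """
    if isinstance(control_events, EventTable):
        pools = [control_events]
    else:
        pools = list(control_events)
    if not pools:
        raise ValueError("no control events supplied")
    x = np.concatenate(
        [np.column_stack([np.log(t.fsc), np.log(t.ssc)]) for t in pools]
    )
    n = len(x)
    if n < 50:
        raise ValueError(f"need >= 50 control events to fit a gate, got {n}")
    if not 0 < coverage_quantile < 1:
        raise ValueError("coverage_quantile must be in (0, 1)")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < 2:
        raise DegenerateScatterError("control scatter is rank-deficient")

    x_fit = x
    if n > MAX_FIT_EVENTS:
        idx = np.linspace(0, n - 1, MAX_FIT_EVENTS).astype(int)  # deterministic
        x_fit = x[idx]
    mcd = MinCovDet(random_state=0).fit(x_fit)
    center, shape = mcd.location_, mcd.covariance_
    if np.any(np.linalg.eigvalsh(shape) <= 1e-12):
        raise DegenerateScatterError("robust covariance is singular")

    d = x - center
    prec = np.linalg.inv(shape)
    dist = np.sort(np.sqrt(np.einsum("ij,jk,ik->i", d, prec, d)))
    k = int(np.ceil(coverage_quantile * n)) - 1  # rank ceil(q*n), 0-based
    radius = float(dist[k])
    return ScatterGate(center, shape, radius, coverage_quantile)


def apply_gate(events: EventTable, gate: ScatterGate) -> GatedWell:
    """Gate one well; fluorescence values pass through untouched."""
    if len(events) == 0:
        raise ValueError(f"empty EventTable for well {events.well_id!r}")
    inside = gate.contains(events)
    return GatedWell(
        well_id=events.well_id,
        n_total=len(events),
        n_gated=int(inside.sum()),
        gated_events=events.subset(inside),
    )


def qc_report(gated_wells: list[GatedWell]) -> pd.DataFrame:
    """Per-well QC table; failing wells carry an exclusion reason."""
    rows = [
        {
            "well_id": w.well_id,
            "n_total": w.n_total,
            "n_gated": w.n_gated,
            "gated_fraction": w.gated_fraction,
            "qc_pass": w.qc_pass,
            "exclusion_reason": (
                "" if w.qc_pass
                else f"gated_fraction {w.gated_fraction:.3f} <= {QC_GATED_FRACTION}"
            ),
        }
        for w in gated_wells
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "well_id", "n_total", "n_gated", "gated_fraction",
            "qc_pass", "exclusion_reason",
        ],
    )
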