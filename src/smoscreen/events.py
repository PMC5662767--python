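"""Per-well flow-cytometry event container.

An :class:`EventTable` holds the raw per-cell measurements of one well:
forward scatter (FSC), side scatter (SSC) and a single fluorescence channel
(FL), all on the linear instrument scale, plus optional per-event ground
truth labels when the well was produced by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed ground-truth labels for simulated events.
TRUTH_LABELS = ("off", "on", "debris")

#: Channel values are clipped to this floor so log transforms stay defined.
CHANNEL_FLOOR = 1e-6


@dataclass
class EventTable:
    """Events of one well: columns ``fsc``, ``ssc``, ``fl`` (linear units).

    Parameters
    ----------
    well_id
        Well identifier, e.g. ``"A1"`` or ``"plate1_B12"``.
    events
        DataFrame with strictly positive, finite columns ``fsc``, ``ssc``,
        ``fl``.
    labels
        Optional array of per-event ground-truth labels drawn from
        ``{"off", "on", "debris"}``; same length as ``events``.
    """

    well_id: str
    events: pd.DataFrame
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in ("fsc", "ssc", "fl") if c not in self.events.columns]
        if missing:
            raise ValueError(f"EventTable missing channel column(s): {missing}")
        vals = self.events[["fsc", "ssc", "fl"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.flatnonzero(~np.isfinite(vals).all(axis=1))
            raise ValueError(
                f"non-finite channel values in well {self.well_id!r} at rows "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
        if np.any(vals <= 0):
            bad = np.flatnonzero((vals <= 0).any(axis=1))
            raise ValueError(
                f"non-positive channel values in well {self.well_id!r} at rows "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.events):
                raise ValueError(
                    f"labels length {len(self.labels)} != events length "
                    f"{len(self.events)} in well {self.well_id!r}"
                )
            unknown = set(self.labels) - set(TRUTH_LABELS)
            if unknown:
                raise ValueError(f"unknown truth labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def fsc(self) -> np.ndarray:
        return self.events["fsc"].to_numpy(dtype=float)

    @property
    def ssc(self) -> np.ndarray:
        return self.events["ssc"].to_numpy(dtype=float)

    @property
    def fl(self) -> np.ndarray:
        return self.events["fl"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Return a new table restricted to ``mask`` (boolean or index array)."""
        ev = self.events.loc[np.asarray(mask)].reset_index(drop=True) \
            if np.asarray(mask).dtype != bool else self.events[mask].reset_index(drop=True)
        labels = None
        if self.labels is not None:
            labels = self.labels[np.asarray(mask)]
        return EventTable(self.well_id, ev, labels)

    @classmethod
    def from_arrays(
        cls,
        well_id: str,
        fsc: np.ndarray,
        ssc: np.ndarray,
        fl: np.ndarray,
        labels: np.ndarray | None = None,
    ) -> "EventTable":
        ev = pd.DataFrame(
            {
                "fsc": np.maximum(np.asarray(fsc, dtype=float), CHANNEL_FLOOR),
                "ssc": np.maximum(np.asarray(ssc, dtype=float), CHANNEL_FLOOR),
                "fl": np.maximum(np.asarray(fl, dtype=float), CHANNEL_FLOOR),
            }
        )
        return cls(well_id, ev, labels)
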