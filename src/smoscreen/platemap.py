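"""Plate-map and compound-annotation domain types.

A 384-well plate uses the standard grid A1..P24. Each well carries a role
(sample / positive control / negative control / empty), an optional compound
and concentration, and a stimulation flag. The positive control is a
Hh-stimulated untreated well; the negative control is mock-stimulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ROLES = ("sample", "pos_ctrl", "neg_ctrl", "empty")

ROWS_384 = [chr(ord("A") + i) for i in range(16)]
COLS_384 = list(range(1, 25))
WELLS_384 = [f"{r}{c}" for r in ROWS_384 for c in COLS_384]
_WELLS_384_SET = frozenset(WELLS_384)


@dataclass
class WellEntry:
    role: str
    compound_id: str | None = None
    concentration: float | None = None  # µM
    stimulated: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role token {self.role!r}; expected one of {ROLES}")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(f"negative concentration {self.concentration}")


@dataclass
class PlateMap:
    """Mapping well_id -> :class:`WellEntry` for one plate."""

    plate_id: str
    entries: dict[str, WellEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [w for w in self.entries if w not in _WELLS_384_SET]
        if bad:
            raise ValueError(
                f"well id(s) outside the 384-well grid A1-P24: {bad[:5]}"
            )

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, e in self.entries.items() if e.role == role]

    def validate_for_analysis(self) -> None:
        """Require at least one stimulated and one unstimulated control."""
        if not self.wells_with_role("pos_ctrl"):
            raise ValueError(f"plate {self.plate_id!r} has no pos_ctrl well")
        if not self.wells_with_role("neg_ctrl"):
            raise ValueError(f"plate {self.plate_id!r} has no neg_ctrl well")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well_id": w,
                "role": e.role,
                "compound_id": e.compound_id,
                "concentration_um": e.concentration,
                "stimulated": e.stimulated,
            }
            for w, e in self.entries.items()
        ]
        return pd.DataFrame(rows)


def default_screen_map(
    plate_id: str = "plate1",
    compounds: list[str] | None = None,
    concentration: float = 15.0,
    stimulated: bool = True,
    n_pos_ctrl: int = 8,
    n_neg_ctrl: int = 8,
) -> PlateMap:
    """Lay out a 384-well screen plate: controls in column 1/24, samples inside.

    Controls occupy the outer columns (8 stimulated in column 1, 8 mock in
    column 24 by default); compounds fill the remaining wells row-major.
    """
    entries: dict[str, WellEntry] = {}
    pos_wells = [f"{ROWS_384[i]}1" for i in range(n_pos_ctrl)]
    neg_wells = [f"{ROWS_384[i]}24" for i in range(n_neg_ctrl)]
    for w in pos_wells:
        entries[w] = WellEntry(role="pos_ctrl", stimulated=True)
    for w in neg_wells:
        entries[w] = WellEntry(role="neg_ctrl", stimulated=False)
    free = [w for w in WELLS_384 if w not in entries]
    compounds = compounds or []
    if len(compounds) > len(free):
        raise ValueError(f"{len(compounds)} compounds do not fit in {len(free)} free wells")
    for w, c in zip(free, compounds):
        entries[w] = WellEntry(
            role="sample", compound_id=c, concentration=concentration,
            stimulated=stimulated,
        )
    return PlateMap(plate_id, entries)
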