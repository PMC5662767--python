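"""Readers and writers: events (FCS/CSV), plate maps, annotations, tables.

All tables are UTF-8 CSV with a mandatory header row and '.' decimal
separator. The long-format event CSV dialect has columns
``well_id, fsc, ssc, fl`` and an optional ``truth_label`` column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .events import EventTable
from .fcs import DEFAULT_CHANNELS, read_fcs, write_fcs
from .platemap import ROLES, PlateMap, WellEntry
from .simulate import ScreenDataset

EVENT_CSV_COLUMNS = ("well_id", "fsc", "ssc", "fl")


def read_events(
    path,
    well_id: str | None = None,
    channel_patterns: tuple[str, str, str] = DEFAULT_CHANNELS,
) -> EventTable:
    """Read one well's events from an FCS 3.0 file or the CSV dialect.

    Format is sniffed from the leading bytes. A CSV holding several wells
    must be narrowed with ``well_id``; channel values are validated
    positive and finite with a row-level report.
    """
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty input file: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic.startswith(b"FCS3"):
        return read_fcs(path, well_id=well_id, channel_patterns=channel_patterns)
    df = pd.read_csv(path)
    missing = [c for c in ("fsc", "ssc", "fl") if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV {path} is missing channel column(s): {missing}")
    if "well_id" in df.columns:
        wells = df["well_id"].unique().tolist()
        if well_id is not None:
            df = df[df["well_id"] == well_id]
            if df.empty:
                raise ValueError(f"well {well_id!r} not present in {path}")
        elif len(wells) > 1:
            raise ValueError(
                f"{path} holds {len(wells)} wells; pass well_id to select one"
            )
        else:
            well_id = str(wells[0])
    labels = None
    if "truth_label" in df.columns:
        labels = df["truth_label"].to_numpy(dtype=object)
    return EventTable(
        well_id or "well",
        df[["fsc", "ssc", "fl"]].reset_index(drop=True).astype(float),
        labels,
    )


def write_events_csv(path, tables: list[EventTable], include_labels: bool = True) -> None:
    """Write wells to the long-format CSV dialect (one row per event)."""
    frames = []
    for t in tables:
        df = t.events.copy()
        df.insert(0, "well_id", t.well_id)
        if include_labels and t.labels is not None:
            df["truth_label"] = t.labels
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events_csv_multi(path) -> dict[str, EventTable]:
    """Read every well from a multi-well long-format CSV."""
    df = pd.read_csv(path)
    if "well_id" not in df.columns:
        raise ValueError(f"{path} lacks a well_id column")
    out = {}
    for wid, grp in df.groupby("well_id", sort=False):
        labels = grp["truth_label"].to_numpy(dtype=object) if "truth_label" in grp else None
        out[str(wid)] = EventTable(
            str(wid), grp[["fsc", "ssc", "fl"]].reset_index(drop=True).astype(float),
            labels,
        )
    return out


def write_screen_fcs(dataset: ScreenDataset, outdir) -> list[str]:
    """One FCS file per well, named ``<plate>_<well>.fcs``."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for well_id, table in dataset.wells.items():
        p = os.path.join(outdir, f"{dataset.plate_map.plate_id}_{well_id}.fcs")
        write_fcs(p, table)
        paths.append(p)
    return paths


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_plate_map(path) -> PlateMap:
    """Read a plate map CSV: well_id, role, compound_id, concentration_um, stimulated.

    Duplicate wells are rejected with the offending line numbers (header is
    line 1). An optional ``plate_id`` column must be single-valued.
    """
    df = pd.read_csv(path, dtype={"well_id": str, "compound_id": str})
    required = {"well_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map {path} missing column(s): {sorted(missing)}")
    dup = df[df["well_id"].duplicated(keep=False)]
    if not dup.empty:
        first = dup["well_id"].iloc[0]
        lines = (dup.index[dup["well_id"] == first] + 2).tolist()
        raise ValueError(f"duplicate well {first!r} at lines {lines} in {path}")
    plate_id = "plate1"
    if "plate_id" in df.columns:
        ids = df["plate_id"].dropna().unique()
        if len(ids) > 1:
            raise ValueError(f"{path} mixes plates {ids.tolist()}; one plate per map")
        if len(ids) == 1:
            plate_id = str(ids[0])
    entries = {}
    for idx, row in df.iterrows():
        role = str(row["role"]).strip()
        if role not in ROLES:
            raise ValueError(
                f"unknown role token {role!r} at line {idx + 2} in {path}"
            )
        conc = row.get("concentration_um")
        if conc is not None and not pd.isna(conc):
            try:
                conc = float(conc)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed concentration {conc!r} at line {idx + 2} in {path}"
                ) from None
        else:
            conc = None
        compound = row.get("compound_id")
        compound = None if (compound is None or pd.isna(compound)) else str(compound)
        stim = _parse_bool(row.get("stimulated", False)) if "stimulated" in df.columns else False
        entries[str(row["well_id"])] = WellEntry(
            role=role, compound_id=compound, concentration=conc, stimulated=stim
        )
    return PlateMap(plate_id, entries)


def read_annotation(path) -> dict[str, str]:
    """Read a compound annotation CSV: compound_id, target_class[, pathway]."""
    df = pd.read_csv(path, dtype=str)
    missing = {"compound_id", "target_class"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing column(s): {sorted(missing)}")
    dup = df[df["compound_id"].duplicated(keep=False)]
    if not dup.empty:
        first = dup["compound_id"].iloc[0]
        lines = (dup.index[dup["compound_id"] == first] + 2).tolist()
        raise ValueError(f"duplicate compound {first!r} at lines {lines} in {path}")
    return dict(zip(df["compound_id"], df["target_class"]))


def write_manifest(dataset: ScreenDataset, path) -> None:
    dataset.manifest.to_csv(path, index=False)
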