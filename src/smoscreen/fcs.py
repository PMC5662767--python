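"""Minimal FCS 3.0 list-mode reader/writer for three linear channels.

Writes one file per well with channels FSC-A, SSC-A, FL1-A stored as
little-endian 32-bit floats ($DATATYPE/F/, $MODE/L/, $BYTEORD/1,2,3,4/) and
reads the same subset of the standard back. This is deliberately a narrow
implementation: single data segment, float data, no analysis segment, no
compensation — exactly what the pipeline produces and consumes.
"""

from __future__ import annotations

import numpy as np

from .events import EventTable

DEFAULT_CHANNELS = ("FSC-A", "SSC-A", "FL1-A")
_DELIM = "/"


def write_fcs(path, table: EventTable, channels: tuple[str, str, str] = DEFAULT_CHANNELS) -> None:
    """Write one well's events as an FCS 3.0 file (float32, list mode)."""
    data = np.column_stack([table.fsc, table.ssc, table.fl]).astype("<f4")
    n_events, n_par = data.shape
    databytes = data.tobytes()

    def text_segment(begin_data: int, end_data: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data),
            "$ENDDATA": str(end_data),
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$NEXTDATA": "0",
            "$TOT": str(n_events),
            "$PAR": str(n_par),
            "$FIL": f"{table.well_id}.fcs",
        }
        for i, name in enumerate(channels, start=1):
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = "262144"
        parts = [_DELIM]
        for k, v in kv.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    # two-pass offset resolution: segment lengths depend on the printed
    # offsets, which stabilize after one re-evaluation
    text_start = 58
    begin_data = end_data = 0
    for _ in range(3):
        text = text_segment(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + len(databytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = text_segment(begin_data, end_data)
    text_end = text_start + len(text) - 1

    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(databytes)


def read_fcs(
    path,
    well_id: str | None = None,
    channel_patterns: tuple[str, str, str] = DEFAULT_CHANNELS,
) -> EventTable:
    """Read an FCS 3.0 file with float32 list-mode data into an EventTable.

    ``channel_patterns`` are matched case-insensitively against the $PnN
    names to locate the FSC, SSC and fluorescence channels.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) == 0:
        raise ValueError(f"empty FCS file: {path}")
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"not an FCS 3.x file: {path}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    kv = {
        tokens[i].strip().upper(): tokens[i + 1]
        for i in range(0, len(tokens) - 1, 2)
        if tokens[i].strip()
    }
    if kv.get("$DATATYPE") != "F" or kv.get("$MODE") != "L":
        raise ValueError("only float list-mode FCS data is supported")
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"
    n_events, n_par = int(kv["$TOT"]), int(kv["$PAR"])
    begin_data = int(kv.get("$BEGINDATA") or raw[26:34])
    data = np.frombuffer(
        raw, dtype=dtype, count=n_events * n_par, offset=begin_data
    ).reshape(n_events, n_par)

    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    cols = {}
    for key, pattern in zip(("fsc", "ssc", "fl"), channel_patterns):
        matches = [i for i, nm in enumerate(names) if pattern.lower() in nm.lower()]
        if not matches:
            raise ValueError(
                f"channel matching {pattern!r} not found among {names} in {path}"
            )
        cols[key] = data[:, matches[0]].astype(float)
    wid = well_id or kv.get("$FIL", "well").removesuffix(".fcs")
    return EventTable.from_arrays(wid, cols["fsc"], cols["ssc"], cols["fl"])
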