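"""End-to-end screen analysis: gate -> QC -> summaries -> clusters -> hits.

:func:`analyze_screen` is the in-memory core used by tests and simulations;
:func:`run_pipeline` wraps it with file IO, provenance logging and output
serialization for the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import EventTable
from .gating import ScatterGate, apply_gate, fit_gate, qc_report
from .io import read_annotation, read_events_csv_multi, read_fcs, read_plate_map
from .platemap import PlateMap
from .screen_analysis import (
    DEFAULT_DOWN_THRESHOLD,
    DEFAULT_MIN_CLUSTER_SIZE,
    DEFAULT_UP_THRESHOLD,
    ClusterSummary,
    aggregate_by_target,
    call_hits,
)
from .well_stats import ControlPair, WellSummary, median_fluorescence, normalized_response


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration."""

    events_path: str | None = None  # directory of .fcs files or multi-well CSV
    plate_map_path: str | None = None
    annotation_path: str | None = None
    outdir: str = "smoscreen_out"
    coverage_quantile: float = 0.90
    gate_on_role: str = "neg_ctrl"  # controls the gate is drawn on
    subsample_n: int | None = 4000
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    up_threshold: float = DEFAULT_UP_THRESHOLD
    down_threshold: float = DEFAULT_DOWN_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_quantile < 1:
            raise ValueError("coverage_quantile must be in (0, 1)")
        if not self.down_threshold < 100 < self.up_threshold:
            raise ValueError("need down_threshold < 100 < up_threshold")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ScreenResult:
    gate: ScatterGate
    qc: pd.DataFrame
    controls: ControlPair
    well_summaries: pd.DataFrame
    clusters: list[ClusterSummary]
    cluster_table: pd.DataFrame
    hits: pd.DataFrame
    suppressed: pd.DataFrame = field(default_factory=pd.DataFrame)


def _clusters_to_frame(clusters: list[ClusterSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_class": c.target_class,
                "n_compounds": c.n_compounds,
                "median_response": c.median_response,
                "responses": ";".join(f"{v:.6g}" for v in c.responses),
            }
            for c in clusters
        ],
        columns=["target_class", "n_compounds", "median_response", "responses"],
    )


def analyze_screen(
    wells: dict[str, EventTable],
    plate_map: PlateMap,
    annotation: dict[str, str] | None = None,
    config: RunConfig | None = None,
) -> ScreenResult:
    """Run the full analysis on in-memory event tables of one plate.

    The scatter gate is fitted on the plate's own control wells and applied
    to every well; QC-failing wells are excluded; control medians are the
    per-role medians over QC-passing control wells; every sample well gets
    a normalized response; responses are clustered by target class and hits
    called.
    """
    cfg = config or RunConfig()
    plate_map.validate_for_analysis()

    gate_wells = plate_map.wells_with_role(cfg.gate_on_role)
    gate_tables = [wells[w] for w in gate_wells if w in wells]
    if not gate_tables:
        raise ValueError(f"no {cfg.gate_on_role!r} wells with events to fit the gate")
    gate = fit_gate(gate_tables, coverage_quantile=cfg.coverage_quantile)

    gated = {w: apply_gate(t, gate) for w, t in wells.items()}
    qc = qc_report(list(gated.values()))

    def control_median(role: str) -> float:
        meds = [
            median_fluorescence(gated[w], cfg.subsample_n, seed=cfg.seed)
            for w in plate_map.wells_with_role(role)
            if w in gated and gated[w].qc_pass
        ]
        if not meds:
            raise ValueError(f"no QC-passing {role!r} wells on plate {plate_map.plate_id}")
        return float(np.median(meds))

    controls = ControlPair(
        med_pos=control_median("pos_ctrl"), med_neg=control_median("neg_ctrl")
    )

    summaries: list[WellSummary] = []
    for well_id, entry in plate_map.entries.items():
        if entry.role == "empty" or well_id not in gated:
            continue
        g = gated[well_id]
        med = median_fluorescence(g, cfg.subsample_n, seed=cfg.seed) if g.n_gated else None
        resp = (
            normalized_response(med, controls)
            if (g.qc_pass and med is not None)
            else None
        )
        summaries.append(
            WellSummary(
                well_id=well_id,
                role=entry.role,
                compound_id=entry.compound_id,
                concentration=entry.concentration,
                stimulated=entry.stimulated or entry.role == "pos_ctrl",
                qc_pass=g.qc_pass,
                n_gated=g.n_gated,
                median_fl=med,
                normalized_response=resp,
            )
        )
    well_df = pd.DataFrame([vars(s) for s in summaries])[
        [
            "well_id", "role", "compound_id", "concentration", "stimulated",
            "qc_pass", "n_gated", "median_fl", "normalized_response",
        ]
    ]

    sample_df = well_df[(well_df["role"] == "sample") & well_df["compound_id"].notna()]
    clusters: list[ClusterSummary] = []
    suppressed = pd.DataFrame()
    hits = pd.DataFrame()
    if not sample_df.empty and annotation is not None:
        resp_df = sample_df[
            ["compound_id", "qc_pass", "normalized_response"]
        ].copy()
        resp_df["target_class"] = None
        resp_df = resp_df[resp_df["normalized_response"].notna() | ~resp_df["qc_pass"]]
        resp_df.loc[~resp_df["qc_pass"], "normalized_response"] = np.nan
        clusters, suppressed = aggregate_by_target(
            resp_df, annotation=annotation, min_cluster_size=cfg.min_cluster_size
        )
        hits = call_hits(clusters, cfg.up_threshold, cfg.down_threshold)

    return ScreenResult(
        gate=gate,
        qc=qc,
        controls=controls,
        well_summaries=well_df,
        clusters=clusters,
        cluster_table=_clusters_to_frame(clusters),
        hits=hits,
        suppressed=suppressed,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_wells(events_path) -> dict[str, EventTable]:
    if os.path.isdir(events_path):
        wells = {}
        for name in sorted(os.listdir(events_path)):
            if name.endswith(".fcs"):
                table = read_fcs(os.path.join(events_path, name))
                # file stem is <plate>_<well>; the well id is the last token
                wid = os.path.splitext(name)[0].rsplit("_", 1)[-1]
                table.well_id = wid
                wells[wid] = table
        if not wells:
            raise ValueError(f"no .fcs files found in {events_path}")
        return wells
    return read_events_csv_multi(events_path)


def run_pipeline(config: RunConfig) -> str:
    """File-level pipeline entry point; returns the output directory.

    Writes well_summary.csv, qc_report.csv, clusters.csv, hits.csv,
    suppressed.csv, gate.json, the effective config and a provenance log
    (package version, seeds, input checksums).
    """
    if config.events_path is None or config.plate_map_path is None:
        raise ValueError("config must set events_path and plate_map_path")
    plate_map = read_plate_map(config.plate_map_path)
    plate_map.validate_for_analysis()
    annotation = (
        read_annotation(config.annotation_path) if config.annotation_path else None
    )
    wells = _load_wells(config.events_path)

    result = analyze_screen(wells, plate_map, annotation, config)

    os.makedirs(config.outdir, exist_ok=True)
    out = config.outdir
    result.well_summaries.to_csv(os.path.join(out, "well_summary.csv"), index=False)
    result.qc.to_csv(os.path.join(out, "qc_report.csv"), index=False)
    result.cluster_table.to_csv(os.path.join(out, "clusters.csv"), index=False)
    result.hits.to_csv(os.path.join(out, "hits.csv"), index=False)
    result.suppressed.to_csv(os.path.join(out, "suppressed.csv"), index=False)
    result.gate.to_json(os.path.join(out, "gate.json"))
    config.to_yaml(os.path.join(out, "config.yaml"))

    checksums = {
        p: _sha256(p)
        for p in (config.plate_map_path, config.annotation_path)
        if p and os.path.isfile(p)
    }
    if os.path.isfile(config.events_path):
        checksums[config.events_path] = _sha256(config.events_path)
    log = {
        "smoscreen_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_checksums": checksums,
        "n_wells": len(wells),
        "controls": {"med_pos": result.controls.med_pos, "med_neg": result.controls.med_neg},
    }
    with open(os.path.join(out, "log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
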