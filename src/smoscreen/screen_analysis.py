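"""Target-class aggregation, concordance and hit calling for the screen.

Compounds are grouped by their annotated primary molecular target; each
class with at least ``min_cluster_size`` QC-passing members is summarized by
its median normalized response and clusters are ranked by that median.
Hits are classes whose median response clears an up- or down-threshold; the
per-compound supporting fraction (e.g. members at <= 80% of the stimulated
control, i.e. at least a 20% reduction) is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Fig.-style reporting cutoff: classes with fewer members are suppressed.
DEFAULT_MIN_CLUSTER_SIZE = 3
#: Default hit thresholds on the normalized-response percent scale.
DEFAULT_UP_THRESHOLD = 150.0
DEFAULT_DOWN_THRESHOLD = 80.0


class UnannotatedCompoundError(KeyError):
    """A screened compound is missing from the target annotation."""


@dataclass
class CompoundResponse:
    compound_id: str
    target_class: str
    concentration: float | None
    stimulated: bool
    normalized_response: float
    qc_pass: bool


@dataclass
class ClusterSummary:
    target_class: str
    n_compounds: int
    median_response: float
    responses: list[float]


def aggregate_by_target(
    responses: list[CompoundResponse] | pd.DataFrame,
    annotation: dict[str, str] | None = None,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> tuple[list[ClusterSummary], pd.DataFrame]:
    """Group QC-passing compound responses into target-class clusters.

    ``annotation`` (compound -> target class), when given, overrides/fills
    the per-record target class; every compound must then be annotated.
    Returns the reported clusters (sorted by median response, descending)
    and a suppressed-cluster report for classes below ``min_cluster_size``.
    """
    if isinstance(responses, pd.DataFrame):
        records = responses.to_dict("records")
    else:
        records = [vars(r) for r in responses]
    if not records:
        raise ValueError("no compound responses supplied")
    rows = []
    for r in records:
        target = r.get("target_class")
        if annotation is not None:
            if r["compound_id"] not in annotation:
                raise UnannotatedCompoundError(
                    f"compound {r['compound_id']!r} missing from annotation"
                )
            target = annotation[r["compound_id"]]
        if target is None:
            raise UnannotatedCompoundError(
                f"compound {r['compound_id']!r} has no target class"
            )
        rows.append(
            {
                "compound_id": r["compound_id"],
                "target_class": target,
                "normalized_response": r["normalized_response"],
                "qc_pass": bool(r["qc_pass"]),
            }
        )
    df = pd.DataFrame(rows)
    kept = df[df["qc_pass"]]
    if kept.empty:
        warnings.warn("all compounds failed QC; no clusters to report", stacklevel=2)
        return [], df.assign(suppressed_reason="qc_failed")

    clusters: list[ClusterSummary] = []
    suppressed_rows = []
    for target, grp in kept.groupby("target_class", sort=True):
        vals = grp["normalized_response"].to_numpy(dtype=float)
        if len(vals) >= min_cluster_size:
            clusters.append(
                ClusterSummary(
                    target_class=str(target),
                    n_compounds=len(vals),
                    median_response=float(np.median(vals)),
                    responses=vals.tolist(),
                )
            )
        else:
            for _, row in grp.iterrows():
                suppressed_rows.append(
                    {
                        **row.to_dict(),
                        "suppressed_reason": f"cluster size {len(vals)} < {min_cluster_size}",
                    }
                )
    for _, row in df[~df["qc_pass"]].iterrows():
        suppressed_rows.append({**row.to_dict(), "suppressed_reason": "qc_failed"})
    clusters.sort(key=lambda c: (-c.median_response, c.target_class))
    return clusters, pd.DataFrame(suppressed_rows)


def concordance(
    responses_a: pd.Series | dict[str, float],
    responses_b: pd.Series | dict[str, float],
) -> tuple[float, dict]:
    """Spearman rank correlation over paired compounds/clusters.

    Pairing is by index/key intersection; the audit dict records how many
    entries were used and how many were dropped from each side.
    """
    a = pd.Series(responses_a, dtype=float)
    b = pd.Series(responses_b, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired values, got {len(common)}")
    rho = stats.spearmanr(a.loc[common], b.loc[common]).statistic
    audit = {
        "n_used": int(len(common)),
        "n_dropped_a": int(len(a) - len(common)),
        "n_dropped_b": int(len(b) - len(common)),
    }
    return float(rho), audit


def call_hits(
    clusters: list[ClusterSummary],
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> pd.DataFrame:
    """Label clusters up-hit / down-hit / none and count supporting members.

    A cluster is an up-hit when its median response is >= ``up_threshold``
    and a down-hit when <= ``down_threshold`` (percent of the stimulated
    control). ``frac_members_up`` / ``frac_members_down`` give the fraction
    of member compounds individually beyond the same thresholds, supporting
    statements like "15 of 23 compounds reduced the response by >= 20%".
    """
    if not down_threshold < 100 < up_threshold:
        raise ValueError(
            f"need down_threshold < 100 < up_threshold, got "
            f"({down_threshold}, {up_threshold})"
        )
    rows = []
    for c in clusters:
        vals = np.asarray(c.responses, dtype=float)
        if c.median_response >= up_threshold:
            label = "up"
        elif c.median_response <= down_threshold:
            label = "down"
        else:
            label = "none"
        rows.append(
            {
                "target_class": c.target_class,
                "n_compounds": c.n_compounds,
                "median_response": c.median_response,
                "hit": label,
                "n_members_up": int((vals >= up_threshold).sum()),
                "n_members_down": int((vals <= down_threshold).sum()),
                "frac_members_up": float((vals >= up_threshold).mean()),
                "frac_members_down": float((vals <= down_threshold).mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target_class", "n_compounds", "median_response", "hit",
            "n_members_up", "n_members_down",
            "frac_members_up", "frac_members_down",
        ],
    )


def cluster_pvalues(
    clusters: list[ClusterSummary],
    control_responses: list[float],
) -> pd.DataFrame:
    """Mann-Whitney p-value per cluster vs control, with BH-FDR adjustment."""
    from statsmodels.stats.multitest import multipletests

    from .well_stats import compare_to_control

    rows = []
    for c in clusters:
        rows.append(
            {
                "target_class": c.target_class,
                "p_value": compare_to_control(c.responses, control_responses),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
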