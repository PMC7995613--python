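"""Cluster segmentation and maximum open-probability estimation.

At saturating agonist, a single channel's activity arrives in clusters: a
run of openings from one channel, terminated when it desensitizes.  Shut
periods of at least ``t_crit`` (default 100 ms) split the record, clusters
are trimmed to run from their first opening to their last closing, and only
clusters longer than ``min_duration`` (default 100 ms) are accepted — a gap
of exactly 100 ms splits, a cluster of exactly 100 ms is rejected.  Long
shut/desensitized intervals never enter the time accounting.

Each cluster's P_open is its open time divided by its duration; the mean
over clusters at saturating agonist estimates the maximum P_open, the
efficacy measure of the flip mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dwells import DwellSequence

__all__ = [
    "Cluster",
    "ClusterSummary",
    "segment_clusters",
    "cluster_popen",
    "clusters_to_frame",
    "select_group",
    "summarize_group",
]

T_CRIT_DEFAULT = 0.1  # s of shut time that separates clusters
MIN_DURATION_DEFAULT = 0.1  # s below/at which a candidate cluster is rejected


@dataclass
class Cluster:
    """A run of openings bounded by long shut periods.

    ``dwells`` holds the trimmed slice (first and last dwells are open);
    ``popen`` is total open time / (end - start).
    """

    start: float
    end: float
    dwells: DwellSequence
    popen: float
    n_openings: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def open_time(self) -> float:
        return self.popen * self.duration


def segment_clusters(
    dwells: DwellSequence,
    t_crit: float = T_CRIT_DEFAULT,
    min_duration: float = MIN_DURATION_DEFAULT,
) -> list[Cluster]:
    """Split a dwell sequence into accepted clusters.

    Any non-open dwell of duration ≥ ``t_crit`` is a separator.  Each
    candidate between separators is trimmed to first-opening → last-closing
    and accepted when its trimmed duration exceeds ``min_duration``.
    """
    if t_crit <= 0 or min_duration < 0:
        raise ValueError("t_crit must be positive and min_duration non-negative")
    is_open = np.asarray(dwells.state_class == "open")
    durations = dwells.durations
    separator = (~is_open) & (durations >= t_crit)

    clusters: list[Cluster] = []
    sep_idx = np.flatnonzero(separator)
    bounds = np.concatenate(([-1], sep_idx, [len(dwells)]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = slice(lo + 1, hi)
        open_in_seg = np.flatnonzero(is_open[seg])
        if open_in_seg.size == 0:
            continue
        first = seg.start + open_in_seg[0]
        last = seg.start + open_in_seg[-1]
        trimmed = dwells.slice(first, last + 1)
        duration = trimmed.total_duration
        if duration <= min_duration:
            continue
        open_mask = np.asarray(trimmed.state_class == "open")
        open_time = float(trimmed.durations[open_mask].sum())
        clusters.append(
            Cluster(
                start=trimmed.start_time,
                end=trimmed.start_time + duration,
                dwells=trimmed,
                popen=open_time / duration,
                n_openings=int(open_mask.sum()),
            )
        )
    return clusters


def cluster_popen(cluster: Cluster) -> float:
    """Open probability of one cluster: open time / cluster duration."""
    if cluster.duration <= 0:
        raise ValueError("cluster has zero duration")
    open_mask = np.asarray(cluster.dwells.state_class == "open")
    return float(cluster.dwells.durations[open_mask].sum()) / cluster.duration


def clusters_to_frame(
    clusters: list[Cluster],
    patch_id: str = "patch0",
    agonist: str = "glycine",
    concentration_uM: float = np.nan,
    construct: str | None = None,
) -> pd.DataFrame:
    """Tabulate clusters with their experimental labels (one row each)."""
    rows = []
    for c in clusters:
        row = {
            "patch_id": patch_id,
            "agonist": agonist,
            "concentration_uM": concentration_uM,
            "start_s": c.start,
            "end_s": c.end,
            "duration_s": c.duration,
            "open_time_s": c.open_time,
            "popen": c.popen,
            "n_openings": c.n_openings,
        }
        if construct is not None:
            row["construct"] = construct
        rows.append(row)
    columns = [
        "patch_id", "agonist", "concentration_uM", "start_s", "end_s",
        "duration_s", "open_time_s", "popen", "n_openings",
    ] + (["construct"] if construct is not None else [])
    return pd.DataFrame(rows, columns=columns)


def select_group(table: pd.DataFrame, group: Mapping[str, object] | str) -> pd.DataFrame:
    """Rows of a cluster table belonging to one experimental group.

    ``group`` is either a column→value mapping or a ``"construct:agonist"``
    label (just ``"agonist"`` when the table has no construct column).
    """
    if isinstance(group, str):
        if ":" in group:
            construct, agonist = group.split(":", 1)
            group = {"construct": construct.strip(), "agonist": agonist.strip()}
        else:
            group = {"agonist": group.strip()}
    mask = pd.Series(True, index=table.index)
    for col, val in group.items():
        if col not in table.columns:
            raise KeyError(f"cluster table has no column {col!r}")
        mask &= table[col] == val
    out = table[mask]
    if out.empty:
        raise ValueError(f"no clusters match group {group!r}")
    return out


@dataclass
class ClusterSummary:
    """Mean ± SD over clusters plus 1.5·IQR box statistics."""

    mean: float
    sd: float
    n_clusters: int
    n_patches: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    single_cluster: bool = False


def summarize_group(
    table: pd.DataFrame, group: Mapping[str, object] | str | None = None
) -> ClusterSummary:
    """Summary statistics of cluster P_open for one group.

    Mean and SD are computed over clusters (patch count carried as
    metadata).  Quartiles use linear interpolation between order statistics;
    whiskers extend to the most extreme points within 1.5·IQR of the
    quartiles, the convention of standard box plots.
    """
    rows = table if group is None else select_group(table, group)
    if rows.empty:
        raise ValueError("empty group")
    values = rows["popen"].to_numpy(float)
    n = values.size
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    in_low = values[values >= q25 - 1.5 * iqr]
    in_high = values[values <= q75 + 1.5 * iqr]
    return ClusterSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        n_clusters=n,
        n_patches=int(rows["patch_id"].nunique()) if "patch_id" in rows else 1,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        single_cluster=n == 1,
    )
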