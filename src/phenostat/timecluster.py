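"""Grouping near-coincident timestamps into time clusters.

A scanner passes over every plant in sequence, so one experimental time
point yields a spread of timestamps a few minutes wide (e.g. a 2 PM scan
produces times between 2:00:00 and 2:05:30).  DBSCAN on the one-dimensional
time axis, with epsilon expressed in hours (default 1), groups these into
clusters; each cluster's timestamps are then replaced by the cluster median
so downstream grouping and faceting see one time value per scan.
Measurements of the same plant falling inside one cluster are technical
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .errors import ValidationError


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the 1-D timestamp clustering.

    eps_hours
        DBSCAN epsilon, in hours.  Two measurements closer than this are
        density-reachable.  The default of 1 handles any protocol whose
        consecutive scans are at least an hour apart; anything narrower is
        treated as technical replication.
    min_pts
        DBSCAN ``minPts``.  With the default 1 every point is a core point,
        so clusters are exactly the connected components under
        "gap <= eps" and no point is ever labelled noise.
    """

    eps_hours: float = 1.0
    min_pts: int = 1

    def __post_init__(self) -> None:
        if self.eps_hours <= 0:
            raise ValidationError("eps_hours must be positive")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")


def dbscan_1d(timestamps, config: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """Cluster timestamps with DBSCAN on the time axis.

    Distance is the absolute time difference; epsilon is
    ``config.eps_hours`` hours.  Returns one integer label per input, with
    cluster ids dense and ordered by each cluster's earliest timestamp.
    Noise points (possible only when ``min_pts > 1``) get label ``-1``.
    """
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    if ts.empty:
        raise ValidationError("at least one timestamp is required")
    seconds = ts.astype("int64").to_numpy(dtype=np.float64) / 1e9
    raw = DBSCAN(
        eps=config.eps_hours * 3600.0, min_samples=config.min_pts
    ).fit_predict(seconds.reshape(-1, 1))

    # relabel in chronological order of cluster start
    labels = np.full(len(raw), -1, dtype=np.int64)
    starts = {}
    for lab in np.unique(raw):
        if lab == -1:
            continue
        starts[lab] = seconds[raw == lab].min()
    for new, (old, _) in enumerate(sorted(starts.items(), key=lambda kv: kv[1])):
        labels[raw == old] = new
    return labels


def assign_cluster_times(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Substitute each cluster's median time for its members' timestamps.

    Adds ``cluster_id`` and ``dbscan_cluster`` (the median timestamp of the
    cluster, interpolated to the midpoint for even-sized clusters) and
    preserves the raw timestamp in ``timestamp_raw``.  Noise rows (label
    ``-1``) keep their own timestamp.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValidationError(
            f"label vector length {len(labels)} != table length {len(table)}"
        )
    out = table.copy()
    out["cluster_id"] = labels
    out["timestamp_raw"] = out["timestamp"]
    medians = (
        out.loc[out["cluster_id"] >= 0]
        .groupby("cluster_id")["timestamp"]
        .median()
    )
    out["dbscan_cluster"] = out["cluster_id"].map(medians)
    noise = out["cluster_id"] < 0
    out.loc[noise, "dbscan_cluster"] = out.loc[noise, "timestamp"]
    out["timestamp"] = out["dbscan_cluster"]
    return out


def detect_technical_replicates(
    table: pd.DataFrame, plant_col: str = "unit"
) -> pd.DataFrame:
    """Flag repeated measurements of one plant within one time cluster.

    Rows sharing ``(plant, cluster_id)`` form a replicate group; the group
    size is recorded in ``n_technical_reps``.
    """
    if "cluster_id" not in table.columns:
        raise ValidationError("run assign_cluster_times before replicate detection")
    out = table.copy()
    out["n_technical_reps"] = (
        out.groupby([plant_col, "cluster_id"])[plant_col].transform("size")
    )
    return out


def cluster_summary(table: pd.DataFrame) -> pd.DataFrame:
    """One row per time cluster: id, median time, member count."""
    return (
        table.loc[table["cluster_id"] >= 0]
        .groupby("cluster_id")
        .agg(
            dbscan_cluster=("dbscan_cluster", "first"),
            n_measurements=("dbscan_cluster", "size"),
        )
        .reset_index()
    )
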