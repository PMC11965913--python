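"""Outlier filtering, logit transformation of proportion traits, and
replicate aggregation.

Within every time cluster, each trait is screened for outliers — by default
values more than three sample standard deviations from the cluster mean
(the classic 3-sigma rule), optionally by Tukey fences on the interquartile
range.  Removed values are blanked, not the whole row, so co-measured
traits survive.  Traits expressed as percentages (spectral-index bins) are
mapped to the logit scale, after replacing exact 0%/100% with the nearest
interior observed value so no infinities enter the analysis.  Finally,
technical replicates of one plant within one cluster collapse to their
median, leaving one row per plant per time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ingest import trait_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierConfig:
    """How to screen trait values within a (trait, time-cluster) group.

    method
        ``"zscore"`` drops x with ``|x - mean| > z_threshold * sd`` (sample
        sd); ``"iqr"`` drops x outside ``[Q1 - m*IQR, Q3 + m*IQR]`` with
        type-7 quantiles; ``"none"`` disables filtering.
    """

    method: str = "zscore"
    z_threshold: float = 3.0
    iqr_multiplier: float = 1.5
    #: extra grouping columns (e.g. cultivar, treatment) added to the
    #: (trait, cluster) key
    group_by: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.method not in ("zscore", "iqr", "none"):
            raise ValidationError(f"unknown outlier method {self.method!r}")
        if self.z_threshold <= 0 or self.iqr_multiplier <= 0:
            raise ValidationError("outlier thresholds must be positive")


@dataclass(frozen=True)
class ProportionSpec:
    """Which trait columns hold proportions, and on which scale.

    ``percent_0_100`` columns are divided by 100 before the logit.
    """

    columns: tuple[str, ...] = ()
    scale: str = "percent_0_100"

    def __post_init__(self) -> None:
        if self.scale not in ("percent_0_100", "unit_0_1"):
            raise ValidationError(f"unknown proportion scale {self.scale!r}")


def filter_outliers(values, config: OutlierConfig = OutlierConfig()) -> np.ndarray:
    """Keep-mask over *values*; missing values are ignored in the statistics
    and always kept.

    Degenerate groups (fewer than 3 observed values, or zero spread) pass
    through untouched — there is no basis to call anything an outlier.
    """
    x = np.asarray(values, dtype=float)
    keep = np.ones(x.shape, dtype=bool)
    if config.method == "none":
        return keep
    obs = x[~np.isnan(x)]
    if obs.size < 3:
        return keep
    if config.method == "zscore":
        sd = obs.std(ddof=1)
        if sd == 0:
            return keep
        mean = obs.mean()
        with np.errstate(invalid="ignore"):
            keep &= ~(np.abs(x - mean) > config.z_threshold * sd)
    else:  # iqr
        q1, q3 = np.quantile(obs, [0.25, 0.75])  # linear = type-7
        iqr = q3 - q1
        lo = q1 - config.iqr_multiplier * iqr
        hi = q3 + config.iqr_multiplier * iqr
        with np.errstate(invalid="ignore"):
            keep &= ~((x < lo) | (x > hi))
    keep |= np.isnan(x)
    return keep


def apply_outlier_filter(
    table: pd.DataFrame,
    config: OutlierConfig = OutlierConfig(),
    traits: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Blank outlying cells per (trait, time cluster) group.

    The mask for each trait is computed over all measurements sharing a
    ``cluster_id`` (optionally refined by ``config.group_by`` factors); a
    removed value is blanked for that trait only, the row survives for the
    others.  Returns the filtered table and per-trait removal counts.
    """
    if config.method == "none":
        return table.copy(), {}
    if "cluster_id" not in table.columns:
        raise ValidationError("outlier filtering requires assigned time clusters")
    traits = traits if traits is not None else trait_columns(table)
    out = table.copy()
    removed: dict[str, int] = {}
    group_cols = ["cluster_id", *config.group_by]
    for trait in traits:
        keep = np.ones(len(out), dtype=bool)
        for _, idx in out.groupby(group_cols, dropna=False).indices.items():
            keep[idx] = filter_outliers(out[trait].to_numpy()[idx], config)
        n = int((~keep).sum())
        if n:
            out.loc[~keep, trait] = np.nan
            removed[trait] = n
            logger.info("trait %s: removed %d outlying values", trait, n)
    return out, removed


def replace_boundary_proportions(
    column, spec: ProportionSpec = ProportionSpec()
) -> np.ndarray:
    """Rescale to (0,1) and replace exact 0/1 with the nearest interior
    observed value of the same column.

    The replacement is computed over the whole experiment for the column, so
    a 0% cell becomes the smallest strictly positive share ever observed for
    that trait (and symmetrically for 100%).
    """
    x = np.asarray(column, dtype=float)
    if spec.scale == "percent_0_100":
        x = x / 100.0
    obs = x[~np.isnan(x)]
    if obs.size and ((obs < 0).any() or (obs > 1).any()):
        raise ValidationError("proportion values outside [0, 1] after rescaling")
    interior = obs[(obs > 0) & (obs < 1)]
    has_zero = (obs == 0).any()
    has_one = (obs == 1).any()
    if (has_zero or has_one) and interior.size == 0:
        raise ValidationError(
            "column contains only boundary proportions (0/1); no interior "
            "value exists to substitute"
        )
    if has_zero:
        x = np.where(x == 0, interior.min(), x)
    if has_one:
        x = np.where(x == 1, interior.max(), x)
    return x


def logit_transform(p):
    """``ln(p / (1 - p))`` for proportions strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    flat = np.atleast_1d(p)
    obs = flat[~np.isnan(flat)]
    if np.any((obs <= 0) | (obs >= 1)):
        raise ValidationError("logit requires 0 < p < 1 (replace boundaries first)")
    return np.log(p / (1.0 - p))


def inv_logit(x):
    """Inverse of :func:`logit_transform`: ``1 / (1 + exp(-x))``."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def transform_proportions(
    table: pd.DataFrame, spec: ProportionSpec
) -> pd.DataFrame:
    """Apply boundary replacement + logit to every declared proportion column.

    Transformed columns are renamed ``<trait>_logit`` so the scale is
    self-describing in every downstream table and export.
    """
    missing = [c for c in spec.columns if c not in table.columns]
    if missing:
        raise ValidationError(f"proportion columns not in table: {missing}")
    out = table.copy()
    for col in spec.columns:
        out[col] = logit_transform(replace_boundary_proportions(out[col], spec))
        out = out.rename(columns={col: f"{col}_logit"})
    return out


def detect_proportion_columns(table: pd.DataFrame) -> list[str]:
    """Opt-in heuristic: trait name contains ``"bin"`` and >=99% of observed
    values lie in [0, 100]."""
    found = []
    for col in trait_columns(table):
        if "bin" not in col:
            continue
        obs = table[col].dropna()
        if len(obs) and (obs.between(0, 100).mean() >= 0.99):
            found.append(col)
    return found


def aggregate_replicates(
    table: pd.DataFrame,
    plant_col: str = "vtr",
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse technical replicates to one row per (plant, time cluster).

    Each trait becomes the median of its surviving replicate values
    (interpolated for even counts); a group whose values were all removed
    yields a missing cell.  Non-trait columns take their first value within
    the group (they are constant per plant).
    """
    if "cluster_id" not in table.columns:
        raise ValidationError("aggregation requires assigned time clusters")
    traits = traits if traits is not None else trait_columns(table)
    keys = [plant_col, "cluster_id"]
    agg = {c: "median" for c in traits}
    for c in table.columns:
        if c not in traits and c not in keys and c != "timestamp_raw":
            agg[c] = "first"
    out = table.groupby(keys, dropna=False, sort=True).agg(agg).reset_index()
    return out[[c for c in table.columns if c in out.columns]]


def drop_single_level_factors(
    table: pd.DataFrame, factor_cols: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Remove factor columns with exactly one distinct non-missing level.

    A one-level factor cannot contribute a contrast and would break model
    fitting downstream.
    """
    dropped = [
        c for c in factor_cols
        if c in table.columns and table[c].dropna().nunique() == 1
    ]
    if dropped:
        logger.info("dropping single-level factor columns: %s", dropped)
    return table.drop(columns=dropped), dropped
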