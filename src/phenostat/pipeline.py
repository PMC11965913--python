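"""End-to-end orchestration: prepare (ingest -> cluster -> preprocess) and
analyze (subset -> descriptives -> ANOVA -> Tukey -> letters -> export)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import export, ingest, preprocess, stats, timecluster
from .config import RunConfig
from .errors import PhenostatError, ValidationError

logger = logging.getLogger(__name__)

CACHE_NAME = "processed.parquet"


def _find_one(project: Path, pattern: str, required: bool = True) -> Path | None:
    hits = sorted(project.glob(pattern))
    if not hits:
        if required:
            raise FileNotFoundError(
                f"no file matching {pattern!r} in project directory {project}"
            )
        return None
    if len(hits) > 1:
        raise ValidationError(f"multiple files match {pattern!r} in {project}: {hits}")
    return hits[0]


def locate_project_files(project: str | Path) -> dict[str, Path | None]:
    """Resolve the archive, annotation, translation and groups files."""
    project = Path(project)
    if not project.is_dir():
        raise FileNotFoundError(f"project directory not found: {project}")
    groups = sorted(project.glob("groups.xlsx")) + sorted(project.glob("groups.csv"))
    return {
        "archive": _find_one(project, "*.zip"),
        "handmade": _find_one(project, "*_handmade.csv"),
        "translation": _find_one(project, "*_translation.csv"),
        "groups": groups[0] if groups else None,
    }


def prepare_project(
    project: str | Path,
    config: RunConfig = RunConfig(),
    output_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run ingestion, time clustering and preprocessing for one project.

    Writes the processed table as a parquet cache plus a CSV copy and a
    JSON preparation report (rows read/dropped, clusters found, outliers
    removed per trait, transformed columns, dropped factors).  On failure
    any partial outputs are removed.
    """
    project = Path(project)
    outdir = Path(output_dir) if output_dir else project / "output"
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [outdir / CACHE_NAME, outdir / "processed.csv",
               outdir / "prepare_report.json"]
    try:
        table, report = _prepare(project, config)
        export.write_cache(table, outputs[0])
        table.to_csv(outputs[1], index=False)
        outputs[2].write_text(json.dumps(report, indent=2, default=str))
    except Exception:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise
    return table, report


def _prepare(project: Path, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    files = locate_project_files(project)
    raw = ingest.read_experiment_archive(files["archive"])
    ann, tr, groups = ingest.read_annotations(
        files["handmade"], files["translation"], files["groups"]
    )
    joined = ingest.join_annotations(raw, ann, tr, groups)
    n_dropped = len(raw) - len(joined)

    labels = timecluster.dbscan_1d(joined["timestamp"], config.cluster)
    clustered = timecluster.assign_cluster_times(joined, labels)
    clustered = timecluster.detect_technical_replicates(clustered, plant_col="vtr")
    n_clusters = int((pd.Series(labels).max() + 1) if len(labels) else 0)

    prop_cols = tuple(config.proportions.columns)
    if not prop_cols and config.auto_detect_proportions:
        prop_cols = tuple(preprocess.detect_proportion_columns(clustered))
    spec = preprocess.ProportionSpec(
        columns=prop_cols, scale=config.proportions.scale
    )
    transformed = preprocess.transform_proportions(clustered, spec)

    filtered, removed = preprocess.apply_outlier_filter(transformed, config.outlier)
    aggregated = preprocess.aggregate_replicates(filtered, plant_col="vtr")
    factor_cols = ingest.factor_columns(aggregated)
    tidy, dropped_factors = preprocess.drop_single_level_factors(
        aggregated, factor_cols
    )

    report = {
        "rows_read": int(len(raw)),
        "rows_dropped_untranslated": int(n_dropped),
        "clusters_found": n_clusters,
        "replicate_group_sizes": sorted(
            clustered["n_technical_reps"].unique().tolist()
        ),
        "outliers_removed": removed,
        "logit_columns": [f"{c}_logit" for c in prop_cols],
        "dropped_single_level_factors": dropped_factors,
        "rows_out": int(len(tidy)),
    }
    return tidy, report


def load_cache(project: str | Path, output_dir: str | Path | None = None) -> pd.DataFrame:
    outdir = Path(output_dir) if output_dir else Path(project) / "output"
    cache = outdir / CACHE_NAME
    if not cache.exists():
        raise FileNotFoundError(
            f"no prepared cache at {cache}; run prepare first"
        )
    return export.read_cache(cache)


def apply_subset(table: pd.DataFrame, subset: dict) -> pd.DataFrame:
    """Whitelist filter: keep rows whose factor value is in the allowed list."""
    out = table
    for factor, levels in subset.items():
        if factor not in out.columns:
            raise ValidationError(f"subset factor {factor!r} not in table")
        out = out[out[factor].astype(str).isin([str(lv) for lv in levels])]
    return out.reset_index(drop=True)


def analyze_project(
    project: str | Path,
    response: str,
    factors: list[str],
    alpha: float = 0.05,
    subset: dict | None = None,
    terms: list[str] | None = None,
    output_dir: str | Path | None = None,
    table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the statistics stage and export the results workbook.

    Returns the sheet dictionary (raw_data, descriptive, anova, tukey,
    letters, model) that is also written to ``results.xlsx`` and mirrored
    as CSVs.  ``terms`` defaults to every model term.
    """
    project = Path(project)
    outdir = Path(output_dir) if output_dir else project / "output"
    if table is None:
        table = load_cache(project, output_dir)
    table = apply_subset(table, subset or {})

    work = table.copy()
    # the cluster time is an ordinary factor for modeling; render it as text
    if "dbscan_cluster" in work.columns and pd.api.types.is_datetime64_any_dtype(
        work["dbscan_cluster"]
    ):
        work["dbscan_cluster"] = work["dbscan_cluster"].dt.strftime(
            "%Y-%m-%d %H:%M:%S"
        )
    for f in factors:
        if f not in work.columns:
            raise ValidationError(f"factor {f!r} not in processed table")
        if work[f].dropna().nunique() < 2:
            raise ValidationError(
                f"factor {f!r} has fewer than 2 levels in the analyzed subset"
            )
    spec = stats.ModelSpec(response=response, factors=tuple(factors), alpha=alpha)
    model_terms, formula = stats.build_model_terms(spec)
    terms = terms if terms is not None else model_terms

    anova = stats.fit_anova(work, spec)
    resid = stats.model_residuals(work, spec)
    try:
        sw_w, sw_p = stats.shapiro_wilk(resid)
    except PhenostatError as exc:
        logger.warning("Shapiro-Wilk not computable: %s", exc)
        sw_w = sw_p = float("nan")
    logger.info("Shapiro-Wilk on residuals: W=%.4f p=%.4g", sw_w, sw_p)

    tukey_frames, letter_frames = [], []
    for term in terms:
        tk = stats.tukey_hsd(work, spec, term)
        tukey_frames.append(tk)
        cld = stats.compact_letter_display(stats.tukey_p_matrix(tk), alpha)
        cld.insert(0, "term", term)
        letter_frames.append(cld)

    sheets = {
        "raw_data": table,
        "descriptive": stats.describe_groups(work, list(factors), response),
        "anova": anova,
        "tukey": pd.concat(tukey_frames, ignore_index=True),
        "letters": pd.concat(letter_frames, ignore_index=True),
        "model": pd.DataFrame({
            "formula": [formula],
            "alpha": [alpha],
            "shapiro_w": [sw_w],
            "shapiro_p": [sw_p],
        }),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    export.write_workbook(sheets, outdir / "results.xlsx")
    export.write_csv_mirror(sheets, outdir / "results_csv")
    return sheets
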