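"""Reading and joining phenotyping experiment archives and annotation tables.

A phenotyping platform exports an experiment as a ZIP of CSV files.  Every
CSV carries a ``unit`` column with the pot coordinate (``"T:X:Y"`` — table
number and spatial position), an ISO 8601 ``timestamp`` column, and one
numeric column per measured trait (height, leaf area, digital biomass,
spectral-index bins, ...).  Two annotation tables accompany the archive: a
hand-made CSV mapping each plant ID ("V.T.R" — variety, treatment,
repetition) to its treatment and cultivar labels, and a translation CSV
establishing the one-to-one correspondence between plant IDs and unit
coordinates.  An optional groups table adds extra factors (e.g. the allelic
state of a gene) per cultivar.
"""

from __future__ import annotations

import logging
import re
import zipfile
from pathlib import Path

import pandas as pd

from ._util import LEVEL_CHARSET, clean_columns, sanitize_level
from .errors import BijectionError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

UNIT_PATTERN = re.compile(r"^\d+:\d+:\d+$")

#: columns that are never treated as traits
_RESERVED = {"unit", "timestamp", "timestamp_raw", "dbscan_cluster", "cluster_id"}

_FACTOR_BASE = {"vtr", "treatment", "cultivar"}


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Numeric columns of *table* other than coordinates/timestamps/factors."""
    out = []
    for c in table.columns:
        if c in _RESERVED or c in _FACTOR_BASE:
            continue
        if pd.api.types.is_numeric_dtype(table[c]):
            out.append(c)
    return out


def _parse_timestamps(series: pd.Series, source: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(
            f"{source}: unparseable ISO 8601 timestamp {series[idx]!r} at row {idx}"
        )
    return parsed


def _validate_units(series: pd.Series, source: str) -> None:
    bad = ~series.astype(str).str.match(UNIT_PATTERN)
    if bad.any():
        idx = int(bad.idxmax())
        raise ValidationError(
            f"{source}: unit {series[idx]!r} at row {idx} does not match 'T:X:Y'"
        )


def read_measurement_csv(handle, source: str) -> pd.DataFrame:
    """Read one measurement CSV, validating schema, units and timestamps."""
    df = clean_columns(pd.read_csv(handle))
    for col in ("unit", "timestamp"):
        if col not in df.columns:
            raise SchemaError(f"{source}: required column {col!r} missing")
    df["timestamp"] = _parse_timestamps(df["timestamp"], source)
    _validate_units(df["unit"], source)
    return df


def read_experiment_archive(path: str | Path) -> pd.DataFrame:
    """Read a ZIP of measurement CSVs into one concatenated table.

    Files are read in sorted name order; row order is preserved within each
    file.  Trait columns are the union over files — a trait absent from one
    file yields missing values for that file's rows.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    SchemaError
        If a member CSV lacks ``unit`` or ``timestamp`` (message names the file).
    ValidationError
        If a timestamp does not parse as ISO 8601 (message gives the row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"experiment archive not found: {path}")
    frames = []
    with zipfile.ZipFile(path) as zf:
        names = sorted(n for n in zf.namelist() if n.lower().endswith(".csv"))
        if not names:
            raise SchemaError(f"{path}: archive contains no CSV files")
        for name in names:
            with zf.open(name) as fh:
                frames.append(read_measurement_csv(fh, f"{path.name}:{name}"))
    table = pd.concat(frames, ignore_index=True, sort=False)
    logger.info("read %d rows from %d CSVs in %s", len(table), len(names), path)
    return table


def write_experiment_archive(table: pd.DataFrame, path: str | Path,
                             name: str = "measurements.csv") -> Path:
    """Write *table* back out as a single-CSV ZIP (round-trip counterpart)."""
    path = Path(path)
    out = table.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(name, out.to_csv(index=False))
    return path


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return clean_columns(pd.read_excel(path))
    return clean_columns(pd.read_csv(path))


def read_annotations(
    handmade_path: str | Path,
    translation_path: str | Path,
    groups_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and validate the annotation, translation and optional groups tables.

    Returns ``(annotations, translation, groups)`` with cleaned column names
    ``vtr``/``treatment``/``cultivar`` (annotations), ``vtr``/``unit``
    (translation) and ``cultivar`` + factor columns (groups, or ``None``).

    The translation must be a bijection: duplicate plant IDs or duplicate
    unit coordinates raise :class:`BijectionError`.  Factor levels in the
    groups table outside ``[A-Za-z0-9_]`` are sanitized (offending characters
    mapped to ``_``) with the mapping logged.
    """
    ann = _read_table(handmade_path).rename(columns={"v_t_r": "vtr"})
    for col in ("vtr", "treatment", "cultivar"):
        if col not in ann.columns:
            raise SchemaError(f"{handmade_path}: required column {col!r} missing")
    if ann["vtr"].duplicated().any():
        dup = ann.loc[ann["vtr"].duplicated(), "vtr"].iloc[0]
        raise ValidationError(f"{handmade_path}: duplicate plant ID {dup!r}")

    tr = _read_table(translation_path).rename(
        columns={"v_t_r": "vtr", "t_x_y": "unit"}
    )
    for col in ("vtr", "unit"):
        if col not in tr.columns:
            raise SchemaError(f"{translation_path}: required column {col!r} missing")
    _validate_units(tr["unit"], str(translation_path))
    for col in ("vtr", "unit"):
        if tr[col].duplicated().any():
            dup = tr.loc[tr[col].duplicated(), col].iloc[0]
            raise BijectionError(
                f"{translation_path}: {col} {dup!r} appears more than once; "
                "plant IDs and unit coordinates must correspond one-to-one"
            )

    groups = None
    if groups_path is not None:
        groups = _read_table(groups_path)
        if "cultivar" not in groups.columns:
            raise SchemaError(f"{groups_path}: required column 'cultivar' missing")
        for col in groups.columns:
            if col == "cultivar":
                continue
            levels = groups[col].dropna().astype(str)
            bad = levels[~levels.str.match(LEVEL_CHARSET)]
            if not bad.empty:
                mapping = {lv: sanitize_level(lv) for lv in bad.unique()}
                logger.warning(
                    "groups factor %r: sanitized levels %s (allowed charset "
                    "is letters, digits, underscore)", col, mapping
                )
                groups[col] = groups[col].map(
                    lambda v: sanitize_level(v) if isinstance(v, str) else v
                )
    return ann, tr, groups


def join_annotations(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame,
    translation: pd.DataFrame,
    groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate each measurement row with plant ID, treatment, cultivar and
    any extra group factors.

    Rows whose unit coordinate has no translation entry are dropped (the
    translation table selects the plants that belong to the experiment); the
    dropped count is logged.  Annotation values overwrite same-named columns
    coming from the archive.  Group factors join via cultivar; cultivars
    absent from the groups table get missing factor values with a warning.
    """
    table = measurements.copy()
    keep = table["unit"].isin(translation["unit"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d rows with untranslated unit coordinates", n_dropped)
    table = table.loc[keep].reset_index(drop=True)

    overlap = [c for c in ("vtr", "treatment", "cultivar") if c in table.columns]
    if overlap:
        logger.info("annotation overwrites archive columns: %s", overlap)
        table = table.drop(columns=overlap)

    table = table.merge(translation[["vtr", "unit"]], on="unit", how="left")
    table = table.merge(
        annotations[["vtr", "treatment", "cultivar"]], on="vtr", how="left"
    )

    if groups is not None:
        extra = [c for c in groups.columns if c != "cultivar"]
        dropped = [c for c in extra if c in table.columns]
        if dropped:
            table = table.drop(columns=dropped)
        table = table.merge(groups, on="cultivar", how="left")
        missing = set(table["cultivar"].dropna()) - set(groups["cultivar"].dropna())
        if missing:
            logger.warning(
                "cultivars absent from groups table, factors left missing: %s",
                sorted(missing),
            )
    return table


def factor_columns(table: pd.DataFrame) -> list[str]:
    """Candidate factor columns: the annotation factors plus any group extras."""
    known = [c for c in ("treatment", "cultivar") if c in table.columns]
    extras = [
        c for c in table.columns
        if c not in known and c not in _RESERVED and c != "vtr"
        and not pd.api.types.is_numeric_dtype(table[c])
        and not pd.api.types.is_datetime64_any_dtype(table[c])
    ]
    return known + extras
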