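"""Result export: deterministic XLSX workbooks, CSV mirrors, parquet cache.

The processed-table cache is parquet (self-describing columnar, with a
schema-version marker in the file metadata) and must round-trip exactly.
Workbook bytes are made reproducible by pinning the document properties and
repacking the container with fixed entry dates, so identical inputs always
yield identical files.
"""

from __future__ import annotations

import datetime
import io
import re
import zipfile
from pathlib import Path

import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

SCHEMA_VERSION = "phenostat-cache-1"
_EPOCH = datetime.datetime(2000, 1, 1)


def write_cache(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    arrow = pa.Table.from_pandas(table, preserve_index=False)
    meta = dict(arrow.schema.metadata or {})
    meta[b"phenostat_schema"] = SCHEMA_VERSION.encode()
    pq.write_table(arrow.replace_schema_metadata(meta), path)
    return path


def read_cache(path: str | Path) -> pd.DataFrame:
    arrow = pq.read_table(path)
    meta = arrow.schema.metadata or {}
    if meta.get(b"phenostat_schema") != SCHEMA_VERSION.encode():
        raise ValueError(
            f"{path} is not a {SCHEMA_VERSION} cache; re-run prepare"
        )
    return arrow.to_pandas()


_STAMP_RE = re.compile(
    rb"(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:)"
)


def _repack_deterministic(data: bytes) -> bytes:
    """Rewrite an XLSX/zip container with fixed entry dates and name order.

    openpyxl re-stamps ``dcterms:modified`` at save time, so the document
    timestamps are pinned here as well.
    """
    stamp = _EPOCH.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    src = zipfile.ZipFile(io.BytesIO(data))
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as dst:
        for name in sorted(src.namelist()):
            payload = src.read(name)
            if name == "docProps/core.xml":
                payload = _STAMP_RE.sub(rb"\g<1>" + stamp + rb"\g<2>", payload)
            info = zipfile.ZipInfo(name, date_time=(2000, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, payload)
    return buf.getvalue()


def write_workbook(sheets: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Write one sheet per table, in dict order, with reproducible bytes."""
    path = Path(path)
    buf = io.BytesIO()
    with pd.ExcelWriter(buf, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name[:31], index=False)
        props = writer.book.properties
        props.created = _EPOCH
        props.modified = _EPOCH
        props.creator = "phenostat"
        props.lastModifiedBy = "phenostat"
    path.write_bytes(_repack_deterministic(buf.getvalue()))
    return path


def write_csv_mirror(sheets: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sheets.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
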