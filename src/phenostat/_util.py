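"""Shared helpers: janitor-style name cleaning, level sanitization, significance codes."""

from __future__ import annotations

import re

import pandas as pd

#: characters permitted in factor levels (letter-display compatibility)
LEVEL_CHARSET = re.compile(r"^[A-Za-z0-9_]+$")

_NON_ALNUM = re.compile(r"[^0-9a-zA-Z]+")


def clean_name(name: str) -> str:
    """Clean a column name the way janitor's ``clean_names`` does.

    Lowercase, every run of non-alphanumeric characters becomes a single
    underscore, leading/trailing underscores stripped: ``"V.T.R"`` ->
    ``"v_t_r"``, ``"Leaf Area [mm2]"`` -> ``"leaf_area_mm2"``.
    """
    return _NON_ALNUM.sub("_", str(name)).strip("_").lower()


def clean_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *df* with janitor-cleaned column names."""
    out = df.copy()
    out.columns = [clean_name(c) for c in out.columns]
    return out


def sanitize_level(level: str) -> str:
    """Map every character outside ``[A-Za-z0-9_]`` to ``_``.

    Factor levels feed the compact letter display and model formulas, so
    e.g. the allele name ``"Ppd-D1a"`` becomes ``"Ppd_D1a"``.
    """
    return re.sub(r"[^A-Za-z0-9_]", "_", str(level))


def sig_code(p: float) -> str:
    """R-style significance code for a p-value.

    ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, ``.`` p<0.1, else empty.
    """
    if not (p == p):  # NaN
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""
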