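"""Group statistics: descriptives, normality, ANOVA, Tukey HSD, letter display.

The model is a fixed-effects linear model over user-chosen factors.  Main
effects enter in the user's order, followed by all two-way interactions —
higher-order interactions are deliberately excluded to keep models
estimable on typical phenotyping designs.  Sums of squares are sequential
(Type I), so term order matters and is preserved throughout.  Pairwise
contrasts use Tukey's honestly-significant-difference procedure on the full
model's residual mean square, with the Kramer adjustment for unbalanced
group sizes, and feed an insert-and-absorb compact letter display: groups
that share a letter are not significantly different at the chosen alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.formula.api import ols

from ._util import sig_code
from .errors import ValidationError

GROUP_SEP = ":"


@dataclass(frozen=True)
class ModelSpec:
    """Response trait, ordered factor list and significance level."""

    response: str
    factors: tuple[str, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValidationError("at least one factor is required")
        if len(set(self.factors)) != len(self.factors):
            raise ValidationError("duplicate factor names in model spec")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


def describe_groups(
    table: pd.DataFrame, factors: list[str], trait: str
) -> pd.DataFrame:
    """Descriptive statistics per observed factor-level combination.

    Group labels are the colon-joined levels (``"1:lettuce"``).  Skewness is
    the moment ratio m3/m2^(3/2) and kurtosis the Pearson (non-excess)
    m4/m2^2; both are reported missing for degenerate groups (n < 3 or zero
    spread).  ``cv_perc`` is 100*sd/mean with the sample standard deviation.
    """
    rows = []
    if table.empty:
        return pd.DataFrame(
            columns=["group", "n", "median", "mean", "cv_perc", "min", "max",
                     "skewness", "kurtosis"]
        )
    for key, sub in table.groupby(factors, dropna=True, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        x = sub[trait].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        mean = x.mean()
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        m2 = ((x - mean) ** 2).mean()
        degenerate = x.size < 3 or m2 == 0
        rows.append({
            "group": GROUP_SEP.join(str(k) for k in key),
            "n": int(x.size),
            "median": float(np.median(x)),
            "mean": float(mean),
            "cv_perc": float(100.0 * sd / mean) if mean != 0 else np.nan,
            "min": float(x.min()),
            "max": float(x.max()),
            "skewness": np.nan if degenerate
            else float(((x - mean) ** 3).mean() / m2 ** 1.5),
            "kurtosis": np.nan if degenerate
            else float(((x - mean) ** 4).mean() / m2 ** 2),
        })
    return pd.DataFrame(rows)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's AS R94 approximation).

    Valid for 3 <= n <= 5000 after dropping missing values; a zero-variance
    sample is reported as not computable.
    """
    x = pd.Series(values).dropna().to_numpy(dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValidationError(
            f"Shapiro-Wilk requires 3 <= n <= 5000 observations, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def build_model_terms(spec: ModelSpec) -> tuple[list[str], str]:
    """Expand the factor list into model terms and a display formula.

    Main effects keep the user's order; every unordered pair contributes one
    two-way interaction (no three-way or higher terms).
    """
    terms = list(spec.factors)
    terms += [f"{a}{GROUP_SEP}{b}"
              for a, b in itertools.combinations(spec.factors, 2)]
    formula = f"{spec.response} ~ " + " + ".join(terms)
    return terms, formula


def _patsy_term(term: str) -> str:
    return ":".join(f'C(Q("{f}"))' for f in term.split(GROUP_SEP))


def _prepare_model_frame(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.response, *spec.factors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"columns not in table: {missing}")
    df = table[cols].dropna().copy()
    for f in spec.factors:
        df[f] = df[f].astype(str)
    if len(df) < 2:
        raise ValidationError("need at least 2 non-missing observations")
    for f in spec.factors:
        if df[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    return df


def fit_anova(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Sequential (Type I) ANOVA over the expanded term list.

    Each term's sum of squares is the drop in residual SS when the term
    joins the model, and its df the gain in model rank, so the partition is
    exact even on unbalanced or partially aliased designs; a term adding no
    estimable contrast (zero rank gain) is dropped with a warning.  Returns
    one row per term plus a ``Residuals`` row, with columns
    ``term, df, sumsq, meansq, statistic, p.value, sig``.  P-values are kept
    at full precision; display rounding is left to the export layer.
    """
    df = _prepare_model_frame(table, spec)
    terms, _ = build_model_terms(spec)
    rhs = "1"
    fit = ols(f'Q("{spec.response}") ~ {rhs}', data=df).fit()
    rows = []
    for term in terms:
        rhs = f"{rhs} + {_patsy_term(term)}"
        new = ols(f'Q("{spec.response}") ~ {rhs}', data=df).fit()
        df_term = int(round(new.df_model - fit.df_model))
        if df_term == 0:
            warnings.warn(
                f"term {term!r} is not estimable on this design and was "
                "dropped", stacklevel=2,
            )
        else:
            rows.append({"term": term, "df": df_term,
                         "sumsq": float(fit.ssr - new.ssr)})
        fit = new
    df_resid = int(round(fit.df_resid))
    if df_resid < 1:
        raise ValidationError(
            "zero residual degrees of freedom; drop factors or interactions"
        )
    rows.append({"term": "Residuals", "df": df_resid, "sumsq": float(fit.ssr)})
    out = pd.DataFrame(rows)
    out["meansq"] = out["sumsq"] / out["df"]
    mse = out.loc[out["term"] == "Residuals", "meansq"].iloc[0]
    is_term = out["term"] != "Residuals"
    out["statistic"] = np.where(is_term, out["meansq"] / mse, np.nan)
    out["p.value"] = np.where(
        is_term,
        scipy.stats.f.sf(out["statistic"], out["df"], df_resid),
        np.nan,
    )
    out["sig"] = [sig_code(p) if t != "Residuals" else ""
                  for t, p in zip(out["term"], out["p.value"])]
    return out[["term", "df", "sumsq", "meansq", "statistic", "p.value", "sig"]]


def model_residuals(table: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Residuals of the fitted model, for normality diagnostics.

    Normality is judged on residuals rather than raw groups: ANOVA's
    assumption is normal errors around the cell means.
    """
    df = _prepare_model_frame(table, spec)
    terms, _ = build_model_terms(spec)
    formula = f'Q("{spec.response}") ~ ' + " + ".join(_patsy_term(t) for t in terms)
    return ols(formula, data=df).fit().resid.to_numpy()


def _term_groups(df: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(GROUP_SEP)
    return df[parts].astype(str).agg(GROUP_SEP.join, axis=1)


def tukey_hsd(table: pd.DataFrame, spec: ModelSpec, term: str) -> pd.DataFrame:
    """All-pairs Tukey HSD contrasts for one model term.

    The standard error of each contrast uses the residual mean square of
    the full fitted model with the Tukey-Kramer correction
    ``sqrt(MSE/2 * (1/n_i + 1/n_j))``; adjusted p-values and the 1-alpha
    simultaneous intervals come from the studentized range distribution
    with (k levels, residual df).  Interaction terms compare the
    colon-joined level combinations.
    """
    terms, _ = build_model_terms(spec)
    if term not in terms:
        raise ValidationError(f"term {term!r} not in model terms {terms}")
    df = _prepare_model_frame(table, spec)
    aov = fit_anova(table, spec)
    resid = aov.loc[aov["term"] == "Residuals"].iloc[0]
    mse, df_resid = float(resid["meansq"]), int(resid["df"])

    groups = _term_groups(df, term)
    means = df[spec.response].groupby(groups).mean()
    sizes = df[spec.response].groupby(groups).size()
    levels = list(means.index)
    k = len(levels)
    if k < 2:
        raise ValidationError(f"term {term!r} has fewer than 2 observed levels")
    q_crit = scipy.stats.studentized_range.ppf(1 - spec.alpha, k, df_resid)

    rows = []
    for a, b in itertools.combinations(levels, 2):
        est = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            q, p = np.inf, 0.0
        else:
            q = abs(est) / se
            p = float(scipy.stats.studentized_range.sf(q, k, df_resid))
        rows.append({
            "term": term,
            "contrast": f"{a}-{b}",
            "estimate": float(est),
            "conf.low": float(est - q_crit * se),
            "conf.high": float(est + q_crit * se),
            "adj.p.value": min(p, 1.0),
            "sig": sig_code(p),
        })
    return pd.DataFrame(rows)


def tukey_p_matrix(tukey: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric adjusted-p matrix from a Tukey contrast table."""
    levels: list[str] = []
    for contrast in tukey["contrast"]:
        for lv in contrast.split("-", 1):
            if lv not in levels:
                levels.append(lv)
    mat = pd.DataFrame(1.0, index=levels, columns=levels)
    for _, row in tukey.iterrows():
        a, b = row["contrast"].split("-", 1)
        mat.loc[a, b] = mat.loc[b, a] = row["adj.p.value"]
    return mat


def compact_letter_display(
    pairwise: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Assign letters so that two levels share one iff not significantly
    different.

    *pairwise* is a square symmetric matrix of adjusted p-values indexed by
    level.  Uses the insert-and-absorb construction: start with all levels
    in one letter column; for each significant pair occupying a common
    column, split that column into two copies, removing one member from
    each; finally absorb columns whose membership is a subset of another's.
    Letters are emitted 'a', 'b', ... in first-use order.
    """
    if list(pairwise.index) != list(pairwise.columns):
        raise ValidationError("pairwise matrix must share index and columns")
    arr = pairwise.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValidationError("pairwise p-value matrix must be symmetric")
    levels = list(pairwise.index)
    columns: list[set[str]] = [set(levels)]
    for a, b in itertools.combinations(levels, 2):
        if not pairwise.loc[a, b] < alpha:
            continue
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            c for i, c in enumerate(new_columns)
            if not any(
                c < d or (c == d and i > j)
                for j, d in enumerate(new_columns)
            )
        ]
    # letters in first-use order: order columns by earliest member level
    order = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(order[lv] for lv in c))
    letters = {lv: "" for lv in levels}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i) if i < 26 else f"<{i}>"
        for lv in levels:
            if lv in col:
                letters[lv] += ch
    return pd.DataFrame({"level": levels, "letters": [letters[lv] for lv in levels]})
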