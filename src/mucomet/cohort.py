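"""Cohort characteristics table: group summaries with descriptive tests.

Categorical variables are summarised as N (%) per group and compared
with a two-sided Fisher exact test (probability-mass criterion);
continuous variables as mean (SD) with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test.  The output mirrors the conventional
"Table 1" of a case-control study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import GROUP, SUBTYPE, validate_metadata


class CohortError(ValueError):
    pass


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  A table with a zero margin carries no information and
    returns p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise CohortError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise CohortError("contingency cells must be non-negative")
    if t.sum() == 0:
        raise CohortError("contingency table is all zeros")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the combined sample is small (<= 20)
    and tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    if series.dtype == bool:
        return True
    return series.nunique(dropna=True) <= 2 and series.dropna().isin([0, 1]).all()


def build_cohort_table(
    metadata: pd.DataFrame,
    group_col: str = GROUP,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """One summary row per variable level, with a per-variable p-value.

    Variable types are inferred from dtype: object/bool/categorical
    columns get count (%) summaries and a Fisher exact test (2x2 only;
    wider categorical variables fall back to a chi-square-free flag),
    numeric columns get mean (SD) and the rank-sum test.  A variable
    with a single level across both groups is flagged and gets no p.
    """
    metadata = validate_metadata(metadata, group_col=group_col)
    groups = metadata[group_col]
    levels = [g for g in groups.dropna().unique()]
    if len(levels) != 2:
        raise CohortError(f"cohort table needs exactly 2 groups, got {levels}")
    g1, g2 = levels
    if variables is None:
        variables = [
            c for c in metadata.columns if c not in (group_col, SUBTYPE)
        ]
    if not variables:
        raise CohortError("no variables to summarise")

    rows = []
    for var in variables:
        series = metadata[var]
        x = series[groups == g1]
        y = series[groups == g2]
        if _is_categorical(series):
            cats = [c for c in series.dropna().unique()]
            counts1 = x.value_counts()
            counts2 = y.value_counts()
            if len(cats) < 2:
                p, flag = np.nan, "single level"
            elif len(cats) == 2:
                t = [
                    [int(counts1.get(cats[0], 0)), int(counts2.get(cats[0], 0))],
                    [int(counts1.get(cats[1], 0)), int(counts2.get(cats[1], 0))],
                ]
                p, flag = fisher_exact(t), ""
            else:
                p, flag = np.nan, "more than 2 levels"
            for cat in cats:
                n1, n2 = int(counts1.get(cat, 0)), int(counts2.get(cat, 0))
                rows.append(
                    {
                        "variable": var,
                        "level": str(cat),
                        "kind": "categorical",
                        f"summary_{g1}": _n_pct(n1, len(x)),
                        f"summary_{g2}": _n_pct(n2, len(y)),
                        "p": p,
                        "flag": flag,
                    }
                )
        else:
            xv, yv = x.dropna().to_numpy(float), y.dropna().to_numpy(float)
            if np.unique(np.concatenate([xv, yv])).size < 2:
                p, flag = np.nan, "single level"
            else:
                p, flag = wilcoxon_rank_sum(xv, yv), ""
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "kind": "continuous",
                    f"summary_{g1}": _mean_sd(xv),
                    f"summary_{g2}": _mean_sd(yv),
                    "p": p,
                    "flag": flag,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["groups"] = (str(g1), str(g2))
    out.attrs["group_sizes"] = (int((groups == g1).sum()), int((groups == g2).sum()))
    return out


def _n_pct(n: int, total: int) -> str:
    pct = 0.0 if total == 0 else 100.0 * n / total
    return f"{n} ({pct:.0f}%)"


def _mean_sd(values: np.ndarray) -> str:
    if values.size == 0:
        return "-"
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return f"{values.mean():.1f} ({sd:.1f})"


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering with p to 3 decimal places."""
    g1, g2 = table.attrs.get("groups", ("group 1", "group 2"))
    n1, n2 = table.attrs.get("group_sizes", ("", ""))
    lines = [
        f"| Characteristic | {g1} N = {n1} | {g2} N = {n2} | p |",
        "|---|---|---|---|",
    ]
    for (var, _), sub in table.groupby(["variable", "kind"], sort=False):
        first = sub.iloc[0]
        p = "" if pd.isna(first["p"]) else f"{first['p']:.3f}"
        if first["flag"]:
            p = f"({first['flag']})"
        if first["kind"] == "continuous":
            lines.append(
                f"| {var} | {first[f'summary_{g1}']} | {first[f'summary_{g2}']} | {p} |"
            )
        else:
            lines.append(f"| {var} |  |  | {p} |")
            for _, row in sub.iterrows():
                lines.append(
                    f"| &nbsp;&nbsp;{row['level']} | {row[f'summary_{g1}']} "
                    f"| {row[f'summary_{g2}']} |  |"
                )
    return "\n".join(lines) + "\n"
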