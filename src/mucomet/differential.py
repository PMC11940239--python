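"""Two-group fold-change + t-test + FDR screen with volcano annotation.

Fold changes are ratios of arithmetic group means computed on the
normalized (pre-log) table; p-values come from a two-sided Welch t-test
on the log-transformed table; Q-values are Benjamini-Hochberg adjusted
over all metabolites of the contrast.  The same screen serves the
case-vs-control contrast and the diarrhea- vs constipation-predominant
subtype contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, GROUP, validate_metadata

logger = logging.getLogger(__name__)

#: volcano gates: |log2FC| >= 1 (fold change 2) and p < 0.05
DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.05


class ContrastError(ValueError):
    pass


def _group_masks(
    groups: pd.Series, group1: str, group2: str, index: pd.Index
) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.reindex(index)
    mask1 = (groups == group1).to_numpy()
    mask2 = (groups == group2).to_numpy()
    if mask1.sum() < 1 or mask2.sum() < 1:
        raise ContrastError(
            f"contrast {group1!r} vs {group2!r}: both groups need >= 1 sample "
            f"(got {int(mask1.sum())} and {int(mask2.sum())})"
        )
    return mask1, mask2


def fold_change(
    table: FeatureTable, groups: pd.Series, group1: str, group2: str
) -> pd.DataFrame:
    """Per-metabolite fold change group1/group2 on pre-log abundances.

    Returns a frame with columns ``fc`` and ``log2fc``.  Features whose
    group-2 mean is zero get ``fc = NaN`` and are flagged for exclusion
    from the volcano.
    """
    if table.state not in ("raw", "normalized"):
        raise ContrastError(
            f"fold_change expects pre-log abundances, got state {table.state!r}"
        )
    mask1, mask2 = _group_masks(groups, group1, group2, table.sample_ids)
    values = table.values()
    mean1 = values[mask1].mean(axis=0)
    mean2 = values[mask2].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean2 > 0, mean1 / mean2, np.nan)
        log2fc = np.where(np.isfinite(fc) & (fc > 0), np.log2(fc), np.nan)
    undefined = int(np.isnan(fc).sum())
    if undefined:
        logger.warning(
            "%d feature(s) have zero %s-group mean; fold change undefined",
            undefined,
            group2,
        )
    return pd.DataFrame({"fc": fc, "log2fc": log2fc}, index=table.metabolite_names)


def group_t_test(
    table: FeatureTable, groups: pd.Series, group1: str, group2: str
) -> pd.Series:
    """Two-sided Welch t-test per metabolite on logged values.

    Degenerate features (zero variance in both groups and identical
    means) get p = 1 by convention.
    """
    if table.state != "logged":
        raise ContrastError(
            f"group_t_test expects log-transformed values, got state {table.state!r}"
        )
    mask1, mask2 = _group_masks(groups, group1, group2, table.sample_ids)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ContrastError("t-test needs >= 2 samples per group")
    values = table.values()
    x, y = values[mask1], values[mask2]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(x, y, axis=0, equal_var=False).pvalue
    degenerate = (x.std(axis=0) == 0) & (y.std(axis=0) == 0)
    identical = degenerate & (x.mean(axis=0) == y.mean(axis=0))
    p = np.where(identical, 1.0, p)
    return pd.Series(p, index=table.metabolite_names, name="p")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_analysis(
    normalized: FeatureTable,
    logged: FeatureTable,
    metadata: pd.DataFrame,
    group1: str,
    group2: str,
    group_col: str = GROUP,
) -> pd.DataFrame:
    """Full screen for one contrast: FC, Welch p, BH Q, volcano gates."""
    metadata = validate_metadata(metadata, normalized, group_col=group_col)
    groups = metadata[group_col]
    fc = fold_change(normalized, groups, group1, group2)
    p = group_t_test(logged, groups, group1, group2)
    result = fc.join(p)
    result["q"] = bh_fdr(result["p"].to_numpy())
    result["neglog10p"] = -np.log10(result["p"])
    result.index.name = "metabolite"
    return result


def volcano_table(
    diff: pd.DataFrame,
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Annotate a differential result with threshold flags.

    ``passes_fc``: |log2FC| at or beyond the gate; ``passes_p``:
    p < threshold; ``highlight``: both.  Rows are sorted by p ascending;
    features with undefined fold change are dropped (with a warning from
    :func:`fold_change`).  The -log10 of the p gate is stored in
    ``table.attrs["neglog10_p_threshold"]`` (1.30 for p = 0.05).
    """
    if diff.empty:
        raise ContrastError("differential result is empty")
    out = diff.loc[np.isfinite(diff["log2fc"])].copy()
    out["passes_fc"] = (out["log2fc"] >= log2fc_threshold) | (
        out["log2fc"] <= -log2fc_threshold
    )
    out["passes_p"] = out["p"] < p_threshold
    out["highlight"] = out["passes_fc"] & out["passes_p"]
    out = out.sort_values("p", kind="mergesort")
    out.attrs["log2fc_threshold"] = float(log2fc_threshold)
    out.attrs["p_threshold"] = float(p_threshold)
    out.attrs["neglog10_p_threshold"] = round(-float(np.log10(p_threshold)), 2)
    return out


def plot_volcano(volcano: pd.DataFrame, path=None, ax=None):
    """Volcano rendering: log2FC vs -log10 p, point size by significance,
    colour by fold change, dashed gate lines."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    x = volcano["log2fc"]
    y = volcano["neglog10p"]
    sizes = 8 + 18 * y / max(float(y.max()), 1.0)
    sc = ax.scatter(
        x, y, s=sizes, c=x, cmap="coolwarm", alpha=0.8, edgecolors="none"
    )
    thr = volcano.attrs.get("log2fc_threshold", DEFAULT_LOG2FC_THRESHOLD)
    p_line = volcano.attrs.get("neglog10_p_threshold", 1.30)
    ax.axvline(thr, ls="--", c="grey", lw=0.8)
    ax.axvline(-thr, ls="--", c="grey", lw=0.8)
    ax.axhline(p_line, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    plt.colorbar(sc, ax=ax, label="log2 fold change")
    for name, row in volcano[volcano["highlight"]].head(8).iterrows():
        ax.annotate(str(name), (row["log2fc"], row["neglog10p"]), fontsize=6)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
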