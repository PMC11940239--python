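"""End-to-end orchestration: preprocess -> differential -> RF -> cohort.

A :class:`PipelineConfig` names the inputs, contrast, thresholds and the
RF configuration; :func:`run_pipeline` executes the stages in order and
writes all artifacts plus a run manifest (config, package versions, seed
and input hashes) so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import build_cohort_table, render_markdown
from .differential import differential_analysis, plot_volcano, volcano_table
from .io import (
    read_feature_table,
    read_metadata,
    sha256_of,
    write_yaml,
)
from .preprocess import PreprocessConfig, preprocess
from .rf import RFConfig, run_validation
from .synthetic import CASE, CONTROL, SUBTYPE_C, SUBTYPE_D
from .tables import GROUP, SUBTYPE, validate_metadata

logger = logging.getLogger(__name__)

CONTRAST_CASE_CONTROL = "case-vs-control"
CONTRAST_SUBTYPE = "IBS-D-vs-IBS-C"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    feature_table: str
    metadata: str
    output_dir: str
    contrast: str = CONTRAST_CASE_CONTROL
    case_label: str = CASE
    control_label: str = CONTROL
    log2fc_threshold: float = 1.0
    p_threshold: float = 0.05
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    seed: int = 0
    make_figures: bool = True

    def validate(self) -> None:
        if self.log2fc_threshold <= 0 or not 0 < self.p_threshold < 1:
            raise PipelineError("config", "thresholds must be positive (p in (0,1))")
        if self.contrast not in (CONTRAST_CASE_CONTROL, CONTRAST_SUBTYPE):
            raise PipelineError("config", f"unknown contrast {self.contrast!r}")
        for path in (self.feature_table, self.metadata):
            if not Path(path).exists():
                raise PipelineError("config", f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .io import read_yaml
        from .rf import RFGrid

        raw = read_yaml(path) or {}
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "rf" in raw:
            rf = dict(raw["rf"])
            if rf.get("grid"):
                rf["grid"] = RFGrid(
                    **{k: tuple(v) for k, v in rf["grid"].items()}
                )
            raw["rf"] = RFConfig(**rf)
        return cls(**raw)


def _contrast_labels(config: PipelineConfig, metadata: pd.DataFrame):
    """(group column, group1, group2) for the configured contrast.

    Validated before any computation so a missing subtype column fails
    fast."""
    if config.contrast == CONTRAST_CASE_CONTROL:
        return GROUP, config.case_label, config.control_label
    if SUBTYPE not in metadata.columns:
        raise PipelineError(
            "config", f"contrast {config.contrast!r} needs a {SUBTYPE!r} column"
        )
    return SUBTYPE, SUBTYPE_D, SUBTYPE_C


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and return the artifact paths."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    t_start = time.perf_counter()

    def stage(name):
        logger.info("stage %s ...", name)

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    # mark partial output so consumers never trust it
                    (out / "FAILED").write_text(f"{name}: {exc}\n")
                    if not isinstance(exc, PipelineError):
                        raise PipelineError(name, str(exc)) from exc
                    return False
                logger.info(
                    "stage %s done in %.1fs", name, time.perf_counter() - self.t0
                )
                return False

        return _Ctx()

    with stage("load"):
        table = read_feature_table(config.feature_table)
        metadata = read_metadata(config.metadata)
        metadata = validate_metadata(metadata, table)
        group_col, group1, group2 = _contrast_labels(config, metadata)
        mask = metadata[group_col].isin([group1, group2]).to_numpy()
        if mask.sum() < 4:
            raise PipelineError(
                "load", f"contrast {config.contrast!r} selects fewer than 4 samples"
            )
        table = table.with_data(table.data.loc[mask], state="raw")
        metadata = metadata.loc[mask]

    with stage("preprocess"):
        states = preprocess(table, config.preprocess)

    with stage("differential"):
        diff = differential_analysis(
            states["normalized"], states["logged"], metadata, group1, group2,
            group_col=group_col,
        )
        volcano = volcano_table(
            diff, config.log2fc_threshold, config.p_threshold
        )
        path = out / "differential.tsv"
        volcano.to_csv(path, sep="\t")
        artifacts["differential"] = path
        if config.make_figures:
            fig = out / "volcano.png"
            plot_volcano(volcano, fig)
            artifacts["volcano_figure"] = fig

    with stage("rf_validation"):
        rf_config = dataclasses.replace(config.rf, seed=config.seed)
        result = run_validation(
            states["scaled"], metadata[group_col], positive_label=group1,
            config=rf_config,
        )
        path = out / "rf_iterations.tsv"
        result.iterations.to_csv(path, sep="\t", index=False)
        artifacts["rf_iterations"] = path
        path = out / "rf_importance.tsv"
        result.importance.to_csv(path, sep="\t", index=False)
        artifacts["rf_importance"] = path
        summary = {
            "auc_summary": result.auc_summary.to_dict(orient="records"),
            "baseline": result.baseline.to_dict(orient="records"),
            "top_features": result.ranking[:10],
        }
        artifacts["rf_summary"] = write_yaml(summary, out / "rf_summary.yaml")
        if config.make_figures:
            artifacts["rf_figure"] = _plot_rf(result, out / "rf_validation.png")

    with stage("cohort"):
        cohort_cols = [
            c
            for c in metadata.columns
            if c not in (group_col, SUBTYPE)
            and metadata[c].notna().any()
        ]
        if cohort_cols:
            cohort = build_cohort_table(metadata, group_col=group_col)
            path = out / "cohort_table.tsv"
            cohort.to_csv(path, sep="\t", index=False)
            artifacts["cohort_table"] = path
            (out / "cohort_table.md").write_text(render_markdown(cohort))
            artifacts["cohort_markdown"] = out / "cohort_table.md"

    with stage("manifest"):
        import numpy, scipy, sklearn  # noqa: PLC0415

        manifest = {
            "package": {"name": "mucomet", "version": __version__},
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "config": config,
            "inputs": {
                "feature_table": {
                    "path": str(config.feature_table),
                    "sha256": sha256_of(config.feature_table),
                },
                "metadata": {
                    "path": str(config.metadata),
                    "sha256": sha256_of(config.metadata),
                },
            },
            "seed": config.seed,
            "artifacts": {k: str(v) for k, v in artifacts.items()},
            "runtime_seconds": round(time.perf_counter() - t_start, 2),
        }
        artifacts["manifest"] = write_yaml(manifest, out / "manifest.yaml")

    return artifacts


def _plot_rf(result, path) -> Path:
    """Two-panel rendering: per-arm AUC distributions; top-10 features
    with 1-AUC error bars against the baseline band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    for arm, color in (("real", "#c0392b"), ("scrambled", "#2980b9")):
        aucs = result.iterations.loc[
            result.iterations["arm"] == arm, "test_auc"
        ]
        ax1.hist(aucs, bins=15, alpha=0.6, label=f"Y-{arm}", color=color)
    ax1.axvline(0.5, ls="--", c="grey", lw=0.8)
    ax1.set_xlabel("test AUC")
    ax1.set_ylabel("iterations")
    ax1.legend()

    top = result.ranking[:10]
    imp = result.importance.set_index(["feature", "arm"])
    ys = range(len(top), 0, -1)
    for arm, color, off in (("real", "#c0392b", 0.15), ("scrambled", "#2980b9", -0.15)):
        med = [imp.loc[(f, arm), "median_one_minus_auc"] for f in top]
        lo = [imp.loc[(f, arm), "ci_low"] for f in top]
        hi = [imp.loc[(f, arm), "ci_high"] for f in top]
        ax2.errorbar(
            med,
            [y + off for y in ys],
            xerr=[
                [m - l for m, l in zip(med, lo)],
                [h - m for m, h in zip(med, hi)],
            ],
            fmt="o",
            ms=3,
            color=color,
            label=f"Y-{arm}",
        )
    base = result.baseline.set_index("arm")
    ax2.axvspan(
        base.loc["real", "ci_low"], base.loc["real", "ci_high"],
        color="grey", alpha=0.3, label="baseline CI (real)",
    )
    ax2.set_yticks(list(ys), top)
    ax2.set_xlabel("1 - AUC after permutation")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
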