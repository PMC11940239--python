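"""Feature-table preprocessing: sample normalization, log transform, scaling.

The pipeline contract is raw -> normalized -> logged -> scaled.  Each
step validates the state of its input and returns a new table.  The
default choices (median-based sample normalization, log10, unit-variance
autoscaling) are the common defaults of metabolomics preprocessing
toolkits; each step also offers the usual alternatives so the choice is
explicit configuration rather than a buried assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Switches for the three preprocessing steps.

    normalization: ``median`` (per-sample median scaling), ``sum``
    (per-sample total scaling), or ``none``.
    log_base: 10 or 2.
    scaling: ``auto`` (mean 0 / SD 1), ``pareto`` (mean 0, divide by
    sqrt(SD)), ``center`` (mean 0 only), or ``none``.
    pseudo: pseudo-count added before the log; ``None`` means half the
    smallest positive value in the table.
    """

    normalization: str = "median"
    log_base: int = 10
    scaling: str = "auto"
    pseudo: float | None = None


def _require_state(table: FeatureTable, state: str, op: str) -> None:
    if table.state != state:
        raise PreprocessError(
            f"{op} expects a table in state {state!r}, got {table.state!r}"
        )


def normalize_samples(table: FeatureTable, method: str = "median") -> FeatureTable:
    """Remove per-sample intensity differences by row scaling.

    Each sample's values are divided by the sample's median positive
    value (or its total, for ``method='sum'``) and re-multiplied by the
    grand median of those per-sample factors, so the output stays on an
    intensity-like scale.  A sample with no positive value is an error.
    """
    _require_state(table, "raw", "normalize_samples")
    values = table.values()
    if method == "none":
        return table.with_data(table.data.copy(), state="normalized")
    dead = (values > 0).sum(axis=1) == 0
    if dead.any():
        bad = table.sample_ids[dead].tolist()
        raise PreprocessError(f"sample(s) with no positive values: {bad}")
    if method == "median":
        masked = np.where(values > 0, values, np.nan)
        factors = np.nanmedian(masked, axis=1)
    elif method == "sum":
        factors = values.sum(axis=1)
    else:
        raise PreprocessError(f"unknown normalization method {method!r}")
    grand = float(np.median(factors))
    normalized = values * (grand / factors)[:, None]
    frame = pd.DataFrame(normalized, index=table.sample_ids, columns=table.metabolite_names)
    return table.with_data(frame, state="normalized")


def default_pseudo(table: FeatureTable) -> float:
    """Half the smallest positive value in the table; 0 if all positive entries exist."""
    values = table.values()
    positive = values[values > 0]
    if positive.size == 0:
        raise PreprocessError("table has no positive values; cannot pick a pseudo-count")
    return float(positive.min()) / 2.0 if (values <= 0).any() else 0.0


def log_transform(
    table: FeatureTable, pseudo: float | None = None, base: int = 10
) -> FeatureTable:
    """log(value + pseudo); the default pseudo-count is half the smallest
    positive value when zeros are present, 0 otherwise."""
    _require_state(table, "normalized", "log_transform")
    if pseudo is None:
        pseudo = default_pseudo(table)
    if pseudo < 0:
        raise PreprocessError("pseudo-count must be >= 0")
    values = table.values() + pseudo
    if (values <= 0).any():
        raise PreprocessError(
            "log transform undefined: some value + pseudo <= 0 "
            f"(pseudo={pseudo!r}); increase the pseudo-count"
        )
    if base == 10:
        logged = np.log10(values)
    elif base == 2:
        logged = np.log2(values)
    else:
        raise PreprocessError(f"unsupported log base {base!r}")
    frame = pd.DataFrame(logged, index=table.sample_ids, columns=table.metabolite_names)
    return table.with_data(frame, state="logged")


def autoscale(table: FeatureTable, method: str = "auto") -> FeatureTable:
    """Column-wise scaling of a logged table.

    ``auto``: mean-centre and divide by the sample SD (n-1 denominator);
    ``pareto``: divide by sqrt(SD); ``center``: centre only.  Zero-SD
    columns are centred and flagged in ``zero_variance``.
    """
    _require_state(table, "logged", "autoscale")
    values = table.values()
    means = values.mean(axis=0)
    if values.shape[0] > 1:
        sds = values.std(axis=0, ddof=1)
    else:
        sds = np.zeros(values.shape[1])
    # a column whose spread is at rounding level of its magnitude carries
    # no information; dividing by its SD would only amplify float noise
    zero_sd = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
    centred = values - means
    if method == "auto":
        divisor = np.where(zero_sd, 1.0, sds)
    elif method == "pareto":
        divisor = np.where(zero_sd, 1.0, np.sqrt(sds))
    elif method in ("center", "none"):
        divisor = np.ones_like(sds)
    else:
        raise PreprocessError(f"unknown scaling method {method!r}")
    scaled = centred / divisor
    scaled -= scaled.mean(axis=0)  # exact re-centre after division
    frame = pd.DataFrame(scaled, index=table.sample_ids, columns=table.metabolite_names)
    flagged = tuple(table.metabolite_names[zero_sd])
    return table.with_data(frame, state="scaled", zero_variance=flagged)


def preprocess(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> dict[str, FeatureTable]:
    """Run the full chain and return every intermediate state.

    The differential screen needs the ``normalized`` table (fold changes
    are ratios of arithmetic means) and the ``logged`` one (t-tests on
    the variance-stabilised scale); the classifier uses ``scaled``.
    """
    config = config or PreprocessConfig()
    normalized = normalize_samples(table, method=config.normalization)
    logged = log_transform(normalized, pseudo=config.pseudo, base=config.log_base)
    scaled = autoscale(logged, method=config.scaling)
    return {"raw": table, "normalized": normalized, "logged": logged, "scaled": scaled}
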