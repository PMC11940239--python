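"""Synthetic mucosal-metabolomics data with planted group effects.

The generator emulates the statistical structure a case-control
metabolomics screen assumes: per-feature log-normal abundances, a small
set of metabolites whose case-group mean is shifted by a known log2 fold
change, and per-sample demographic covariates drawn from stated
marginals.  It exists so that every downstream stage — preprocessing,
volcano screening, Random Forest validation, cohort tables — is testable
without access to any clinical dataset.

Model
-----
For feature *j* the control-group abundance is log-normal,

    X_ij = exp(mu_j + sigma_j * Z_ij),   Z_ij ~ N(0, 1),

with location ``mu_j`` drawn once per feature from
``baseline_log_mean_range`` and scale ``sigma_j = sqrt(ln(1 + cv^2))``
set by the within-group coefficient of variation.  A planted effect with
log2 fold change *f* shifts the case-group location by ``f * ln 2`` at
unchanged scale, so the ratio of case to control means is exactly
``2**f`` — the fold-change statistic recovers the planted value in
expectation.  A planted ``log2fc = 0`` therefore leaves the two groups
identically distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import FeatureTable, GROUP, SAMPLE_ID, SUBTYPE

CASE = "IBS"
CONTROL = "control"
SUBTYPE_C = "IBS-C"
SUBTYPE_D = "IBS-D"

#: Cohort covariate marginals of the 44-case / 69-control study design:
#: categorical variables as per-group level proportions, continuous
#: variables as per-group mean/SD.
TABLE1_MARGINALS: dict = {
    "n_case": 44,
    "n_control": 69,
    "sex": {
        "kind": "categorical",
        "levels": ("F", "M"),
        "proportions": {"case": (30 / 44, 14 / 44), "control": (38 / 69, 31 / 69)},
    },
    "age": {
        "kind": "continuous",
        "mean": {"case": 52.0, "control": 59.0},
        "sd": {"case": 16.0, "control": 13.0},
    },
    "body_mass": {
        "kind": "continuous",
        "mean": {"case": 77.0, "control": 77.0},
        "sd": {"case": 18.0, "control": 15.0},
    },
    "height": {
        "kind": "continuous",
        "mean": {"case": 168.0, "control": 168.0},
        "sd": {"case": 10.0, "control": 13.0},
    },
    "bmi": {
        "kind": "continuous",
        "mean": {"case": 27.0, "control": 27.7},
        "sd": {"case": 5.4, "control": 8.5},
    },
    "dm": {
        "kind": "categorical",
        "levels": ("Yes", "No"),
        "proportions": {"case": (7 / 44, 37 / 44), "control": (9 / 69, 60 / 69)},
    },
    "hypertension": {
        "kind": "categorical",
        "levels": ("Yes", "No"),
        "proportions": {"case": (14 / 44, 30 / 44), "control": (32 / 69, 37 / 69)},
    },
}

REQUIRED_VARIABLES = ("sex", "age", "body_mass", "height", "bmi", "dm", "hypertension")


class SyntheticSpecError(ValueError):
    """A generator specification violates one of its invariants."""


@dataclass(frozen=True)
class PlantedEffect:
    """A metabolite with a known case-vs-control log2 fold change.

    ``cv`` is the within-group coefficient of variation on the natural
    scale; it governs detectability at a given sample size.
    """

    metabolite_name: str
    log2fc: float
    cv: float = 0.6

    def validate(self) -> None:
        if not math.isfinite(self.log2fc):
            raise SyntheticSpecError(
                f"effect {self.metabolite_name!r}: log2fc must be finite"
            )
        if not self.cv > 0:
            raise SyntheticSpecError(f"effect {self.metabolite_name!r}: cv must be > 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic dataset.

    Defaults reproduce the study design the package targets: 44 cases vs
    69 controls, ~300 log-normal features, and covariate marginals from
    the cohort table.  ``correlation`` switches on a block-equicorrelation
    structure (off by default; features are independent).  ``missing_rate``
    zeroes entries at random to mimic below-detection dropouts (off by
    default).
    """

    n_case: int = 44
    n_control: int = 69
    n_features: int = 300
    baseline_log_mean_range: tuple[float, float] = (math.log(1e4), math.log(1e6))
    baseline_cv: float = 0.6
    effects: tuple[PlantedEffect, ...] = ()
    covariate_marginals: Mapping = field(
        default_factory=lambda: dict(TABLE1_MARGINALS)
    )
    case_label: str = CASE
    control_label: str = CONTROL
    subtype_d_fraction: float = 0.5
    correlation: float = 0.0
    correlation_block_size: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case + self.n_control < 4:
            raise SyntheticSpecError("n_case + n_control must be >= 4")
        if self.n_case < 1 or self.n_control < 1:
            raise SyntheticSpecError("each group needs at least one sample")
        if self.n_features < max(1, len(self.effects)):
            raise SyntheticSpecError(
                "n_features must be >= max(1, number of planted effects)"
            )
        lo, hi = self.baseline_log_mean_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise SyntheticSpecError("baseline_log_mean_range must be a finite interval")
        if not self.baseline_cv > 0:
            raise SyntheticSpecError("baseline_cv must be > 0")
        names = [e.metabolite_name for e in self.effects]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("effect metabolite names must be unique")
        for effect in self.effects:
            effect.validate()
        if not 0.0 <= self.correlation < 1.0:
            raise SyntheticSpecError("correlation must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SyntheticSpecError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.subtype_d_fraction <= 1.0:
            raise SyntheticSpecError("subtype_d_fraction must be in [0, 1]")

    def feature_names(self) -> list[str]:
        """Planted effects occupy the first columns under their own names."""
        names = [e.metabolite_name for e in self.effects]
        width = len(str(self.n_features))
        names += [
            f"M{i:0{width}d}" for i in range(len(names) + 1, self.n_features + 1)
        ]
        return names


def study_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default study-like spec: 44/69 samples, 300 features, planted
    effects at the magnitudes the screen is meant to detect (log2FC 1.63,
    1.08, -1.52) plus one small-effect metabolite below the fold-change
    gate but well-powered for the t-test."""
    effects = (
        PlantedEffect("Neu5Ac", 1.63),
        PlantedEffect("1-palmitoylglycerol", 1.08),
        PlantedEffect("cis-4-hydroxycyclohexanecarboxylic acid", -1.52),
        PlantedEffect("glycine", 0.60),
    )
    return SyntheticSpec(effects=effects, seed=seed, **overrides)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def generate_feature_table(spec: SyntheticSpec) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw one (feature table, metadata) pair from a spec.

    The returned table is in the ``raw`` state with strictly positive
    entries (zeros only if ``missing_rate > 0``).  Identical spec and
    seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    m = spec.n_features
    names = spec.feature_names()

    mu = rng.uniform(*spec.baseline_log_mean_range, size=m)
    sigma = np.full(m, _lognormal_sigma(spec.baseline_cv))
    shift = np.zeros(m)
    for j, effect in enumerate(spec.effects):
        sigma[j] = _lognormal_sigma(effect.cv)
        shift[j] = effect.log2fc * math.log(2.0)

    z = rng.standard_normal((n, m))
    if spec.correlation > 0:
        # block equicorrelation: shared latent draw per sample per block
        rho = spec.correlation
        bs = max(1, spec.correlation_block_size)
        n_blocks = -(-m // bs)
        latent = rng.standard_normal((n, n_blocks))
        block_of = np.arange(m) // bs
        z = math.sqrt(1 - rho) * z + math.sqrt(rho) * latent[:, block_of]

    is_case = np.zeros(n, dtype=bool)
    is_case[: spec.n_case] = True
    log_values = mu + sigma * z + np.where(is_case[:, None], shift[None, :], 0.0)
    values = np.exp(log_values)

    if spec.missing_rate > 0:
        # below-detection dropout: missing entries are recorded as 0
        values[rng.random(values.shape) < spec.missing_rate] = 0.0

    width = len(str(n))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    table = FeatureTable(
        pd.DataFrame(values, index=pd.Index(sample_ids, name=SAMPLE_ID), columns=names),
        state="raw",
    )

    metadata = _draw_covariates(
        spec.covariate_marginals, spec.n_case, spec.n_control, rng
    )
    metadata.index = table.sample_ids
    metadata.insert(
        0, GROUP, np.where(is_case, spec.case_label, spec.control_label)
    )
    subtype = np.full(n, "", dtype=object)
    n_d = int(round(spec.subtype_d_fraction * spec.n_case))
    case_subtypes = np.array([SUBTYPE_D] * n_d + [SUBTYPE_C] * (spec.n_case - n_d))
    subtype[: spec.n_case] = rng.permutation(case_subtypes)
    metadata.insert(1, SUBTYPE, subtype)
    return table, metadata


def generate_cohort_table_input(
    marginals: Mapping | None = None, seed: int = 0
) -> pd.DataFrame:
    """Metadata-only draw for exercising the cohort-characteristics table.

    ``marginals`` must define the group sizes (``n_case``, ``n_control``)
    and every cohort variable; defaults to :data:`TABLE1_MARGINALS`.
    """
    marginals = dict(TABLE1_MARGINALS if marginals is None else marginals)
    for key in ("n_case", "n_control"):
        if key not in marginals:
            raise SyntheticSpecError(f"marginals missing group size {key!r}")
    rng = np.random.default_rng(seed)
    n_case, n_control = int(marginals["n_case"]), int(marginals["n_control"])
    metadata = _draw_covariates(marginals, n_case, n_control, rng)
    n = n_case + n_control
    width = len(str(n))
    metadata.index = pd.Index(
        [f"S{i:0{width}d}" for i in range(1, n + 1)], name=SAMPLE_ID
    )
    metadata.insert(0, GROUP, [CASE] * n_case + [CONTROL] * n_control)
    return metadata


def _draw_covariates(
    marginals: Mapping, n_case: int, n_control: int, rng: np.random.Generator
) -> pd.DataFrame:
    missing = [v for v in REQUIRED_VARIABLES if v not in marginals]
    if missing:
        raise SyntheticSpecError(f"covariate marginals missing variable(s): {missing}")
    columns: dict[str, np.ndarray] = {}
    sizes = {"case": n_case, "control": n_control}
    for name in REQUIRED_VARIABLES:
        marginal = marginals[name]
        parts = []
        for group in ("case", "control"):
            size = sizes[group]
            if marginal["kind"] == "categorical":
                levels = list(marginal["levels"])
                p = np.asarray(marginal["proportions"][group], dtype=float)
                p = p / p.sum()
                parts.append(rng.choice(levels, size=size, p=p))
            elif marginal["kind"] == "continuous":
                mean = float(marginal["mean"][group])
                sd = float(marginal["sd"][group])
                parts.append(mean + sd * rng.standard_normal(size))
            else:  # pragma: no cover - config guard
                raise SyntheticSpecError(
                    f"variable {name!r}: unknown marginal kind {marginal['kind']!r}"
                )
        columns[name] = np.concatenate(parts)
    return pd.DataFrame(columns)
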