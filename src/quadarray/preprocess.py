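"""Normalization, replicate exclusion, collapse and flooring.

Processing of one array proceeds in four deterministic steps:

1. **Global linear scaling.**  Every processed signal on the array is
   multiplied by an array-specific factor = reference 75th-percentile value
   (1500 RU for a whole series) divided by the observed 75th percentile of
   the array's non-control signals.  After scaling, every array in a series
   has the same 75th percentile, making intensities comparable in "RNA
   units" (RU).

2. **Feature exclusion.**  Within each probe's on-chip quadruplicate,
   individual features are dropped, in order and with a single recorded
   reason each: (i) manually flagged; (ii) flagged as outlier by the
   feature-extraction software; (iii) normalized signal outside the
   quartile fences Q1 - k*IQR .. Q3 + k*IQR of the quadruplicate's
   normalized-signal distribution (k = 1.42 by default); (iv) pixel-level
   coefficient of variation above 0.5.

3. **Collapse.**  Surviving replicate signals are averaged with the
   geometric mean, yielding one value per probe and sample.  A probe whose
   members are all excluded is reported missing, not imputed.

4. **Flooring.**  Collapsed values below the surrogate floor (20 RU,
   derived from negative-control intensity distributions) are substituted
   by the floor.

The percentile convention is linear interpolation between order statistics
(numpy's default, "type 7") everywhere; the fence rule and the floor stage
are configurable for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateArrayError
from .io import ArrayTable, validate_features

__all__ = [
    "PipelineConfig",
    "NormalizationResult",
    "CollapseRecord",
    "compute_scaling_factor",
    "apply_normalization",
    "exclude_replicates",
    "collapse_replicates",
    "apply_floor",
    "preprocess_sample",
    "ArrayPreprocessor",
]

EXCLUSION_REASONS = ("manual_flag", "software_outlier", "iqr_fence", "pixel_cv")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the preprocessing pipeline.

    Defaults are the series-wide constants of the assay this pipeline
    models: reference 75th percentile 1500 RU, surrogate floor 20 RU,
    replicate fence multiplier 1.42, pixel-CV cutoff 0.5.
    """

    reference_percentile_value: float = 1500.0
    percentile: float = 75.0
    surrogate_floor: float = 20.0
    iqr_multiplier: float = 1.42
    pixel_cv_max: float = 0.5
    #: numpy percentile method; "linear" is interpolation between order
    #: statistics (type 7)
    quantile_convention: str = "linear"
    #: "quartile_fences": [Q1 - k*IQR, Q3 + k*IQR]; "median_centered":
    #: [median - k*IQR, median + k*IQR]
    fence_convention: str = "quartile_fences"
    #: "post_collapse" floors the per-probe collapsed value,
    #: "pre_collapse" floors surviving replicate values before averaging
    floor_stage: str = "post_collapse"

    def __post_init__(self) -> None:
        for name in (
            "reference_percentile_value",
            "surrogate_floor",
            "iqr_multiplier",
            "pixel_cv_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.fence_convention not in ("quartile_fences", "median_centered"):
            raise ValueError(f"unknown fence_convention {self.fence_convention!r}")
        if self.floor_stage not in ("post_collapse", "pre_collapse"):
            raise ValueError(f"unknown floor_stage {self.floor_stage!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NormalizationResult:
    """Scaling audit for one array."""

    sample_id: str
    observed_p75: float
    scaling_factor: float


@dataclass
class CollapseRecord:
    """Audit of one probe's quadruplicate collapse."""

    probe_id: str
    surviving_values: list[float]
    excluded: list[tuple[int, str]] = field(default_factory=list)
    collapsed_value: float | None = None


def _percentile(values: np.ndarray, q: float, convention: str) -> float:
    return float(np.percentile(values, q, method=convention))


def compute_scaling_factor(
    raw_gps_values: Iterable[float], config: PipelineConfig = PipelineConfig()
) -> float:
    """Array-specific global scaling factor.

    factor = reference_percentile_value / P75(raw non-control signals),
    with P75 under the configured quantile convention.

    Raises :class:`DegenerateArrayError` when the observed percentile is not
    strictly positive (e.g. an all-zero array).
    """
    values = np.asarray(list(raw_gps_values), dtype=float)
    if values.size == 0:
        raise DegenerateArrayError("no signal values to normalize")
    if not (values > 0).any():
        raise DegenerateArrayError("all signal values are zero")
    p = _percentile(values, config.percentile, config.quantile_convention)
    if p <= 0:
        raise DegenerateArrayError(
            f"observed {config.percentile}th percentile is {p}; "
            "cannot form a positive scaling factor"
        )
    return config.reference_percentile_value / p


def apply_normalization(table: ArrayTable, factor: float) -> ArrayTable:
    """Multiply every signal on the array by ``factor``; everything else
    (flags, CVs, ordering) is untouched."""
    if factor <= 0:
        raise ValueError("scaling factor must be strictly positive")
    feats = table.features.copy()
    feats["gps"] = feats["gps"].to_numpy(dtype=float) * factor
    return ArrayTable(
        sample_id=table.sample_id,
        strain=table.strain,
        subset=table.subset,
        experiment_id=table.experiment_id,
        features=feats,
    )


def _fence_interval(
    values: np.ndarray, config: PipelineConfig
) -> tuple[float, float]:
    q1 = _percentile(values, 25.0, config.quantile_convention)
    q3 = _percentile(values, 75.0, config.quantile_convention)
    iqr = q3 - q1
    if config.fence_convention == "quartile_fences":
        return q1 - config.iqr_multiplier * iqr, q3 + config.iqr_multiplier * iqr
    med = _percentile(values, 50.0, config.quantile_convention)
    return med - config.iqr_multiplier * iqr, med + config.iqr_multiplier * iqr


def exclude_replicates(
    quadruplicate: Sequence[tuple[float, bool, bool, float]],
    config: PipelineConfig = PipelineConfig(),
    *,
    probe_id: str = "",
) -> CollapseRecord:
    """Apply the four exclusion rules to one quadruplicate.

    ``quadruplicate`` holds 1–4 tuples
    ``(normalized_gps, manual_flag, outlier_flag, pixel_cv)`` in replicate
    order (replicate indices 1..len).  Rules are applied in order (i) manual
    flag, (ii) software outlier flag, (iii) quartile fence on the normalized
    values of the members surviving (i)–(ii), (iv) pixel CV; each member is
    excluded at most once, with the first applicable reason.

    The returned record has no collapsed value; combine with
    :func:`collapse_replicates`.
    """
    n = len(quadruplicate)
    if n == 0:
        raise ValueError("quadruplicate must contain at least one member")
    if n > 4:
        raise ValueError("a quadruplicate holds at most four members")

    values = np.array([m[0] for m in quadruplicate], dtype=float)
    manual = np.array([bool(m[1]) for m in quadruplicate])
    soft = np.array([bool(m[2]) for m in quadruplicate])
    cv = np.array([m[3] for m in quadruplicate], dtype=float)

    reason = np.array([""] * n, dtype=object)
    reason[manual] = "manual_flag"
    reason[soft & (reason == "")] = "software_outlier"

    pool = reason == ""  # members entering the fence computation
    if pool.any():
        lo, hi = _fence_interval(values[pool], config)
        out = pool & ((values < lo) | (values > hi))
        reason[out] = "iqr_fence"
    reason[(reason == "") & (cv > config.pixel_cv_max)] = "pixel_cv"

    surviving = [float(v) for v, r in zip(values, reason) if r == ""]
    excluded = [(i + 1, str(r)) for i, r in enumerate(reason) if r != ""]
    return CollapseRecord(probe_id=probe_id, surviving_values=surviving, excluded=excluded)


def collapse_replicates(surviving_values: Iterable[float]) -> float | None:
    """Geometric mean of the surviving replicate signals; ``None`` when no
    member survived.  Non-positive values are rejected (the geometric mean
    is undefined there)."""
    values = np.asarray(list(surviving_values), dtype=float)
    if values.size == 0:
        return None
    if (values <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def apply_floor(
    value: float | None, config: PipelineConfig = PipelineConfig()
) -> float | None:
    """Substitute the surrogate floor for sub-floor values; missing stays
    missing."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return value
    return max(float(value), config.surrogate_floor)


def _exclusion_reasons_frame(
    nc: pd.DataFrame, config: PipelineConfig
) -> pd.Series:
    """Vectorised exclusion rules over one array's non-control features.

    Returns a Series of reason strings aligned with ``nc`` ("" = surviving).
    ``nc['gps']`` must already be normalized.
    """
    reason = pd.Series("", index=nc.index, dtype=object)
    reason[nc["manual_flag"].to_numpy(dtype=bool)] = "manual_flag"
    soft = nc["outlier_flag"].to_numpy(dtype=bool) & (reason == "").to_numpy()
    reason[soft] = "software_outlier"

    pool = nc[(reason == "").to_numpy()]
    grp = pool.groupby("probe_id", sort=False)["gps"]
    q1 = grp.quantile(0.25, interpolation=config.quantile_convention)
    q3 = grp.quantile(0.75, interpolation=config.quantile_convention)
    iqr = q3 - q1
    if config.fence_convention == "quartile_fences":
        lo, hi = q1 - config.iqr_multiplier * iqr, q3 + config.iqr_multiplier * iqr
    else:
        med = grp.quantile(0.50, interpolation=config.quantile_convention)
        lo, hi = med - config.iqr_multiplier * iqr, med + config.iqr_multiplier * iqr
    lo_row = pool["probe_id"].map(lo).to_numpy(dtype=float)
    hi_row = pool["probe_id"].map(hi).to_numpy(dtype=float)
    v = pool["gps"].to_numpy(dtype=float)
    fenced = pool.index[(v < lo_row) | (v > hi_row)]
    reason[fenced] = "iqr_fence"

    high_cv = (reason == "").to_numpy() & (
        nc["pixel_cv"].to_numpy(dtype=float) > config.pixel_cv_max
    )
    reason[high_cv] = "pixel_cv"
    return reason


def preprocess_sample(
    table: ArrayTable, config: PipelineConfig = PipelineConfig()
) -> tuple[pd.Series, NormalizationResult, pd.DataFrame]:
    """Run scale → exclude → collapse → floor on one array.

    Returns
    -------
    values : pd.Series
        One floored value per non-control probe (NaN = all members
        excluded), indexed by probe_id in first-appearance order.
    norm : NormalizationResult
        Observed percentile and scaling factor.
    audit : pd.DataFrame
        One row per *excluded* feature: probe_id, replicate_index, reason,
        normalized value.
    """
    validate_features(table.features)
    nc = table.features[~table.features["is_control"].astype(bool)].copy()
    factor = compute_scaling_factor(nc["gps"].to_numpy(dtype=float), config)
    observed = config.reference_percentile_value / factor
    nc["gps"] = nc["gps"].to_numpy(dtype=float) * factor

    reason = _exclusion_reasons_frame(nc, config)
    audit = nc.loc[reason != "", ["probe_id", "replicate_index", "gps"]].copy()
    audit.insert(2, "reason", reason[reason != ""])
    audit = audit.rename(columns={"gps": "normalized_gps"}).reset_index(drop=True)

    surv = nc[(reason == "").to_numpy()].copy()
    if (surv["gps"].to_numpy(dtype=float) <= 0).any():
        raise ValueError(
            "non-positive normalized signal among surviving replicates; "
            "geometric-mean collapse is undefined (use floor_stage="
            "'pre_collapse' to floor replicate values first)"
        )
    if config.floor_stage == "pre_collapse":
        surv["gps"] = np.maximum(
            surv["gps"].to_numpy(dtype=float), config.surrogate_floor
        )
    collapsed = np.exp(
        np.log(surv["gps"]).groupby(surv["probe_id"], sort=False).mean()
    )

    probe_order = nc["probe_id"].drop_duplicates()
    values = collapsed.reindex(probe_order)
    # in pre_collapse mode the collapse of floored values is >= floor up to
    # rounding; the clip also irons out that float noise
    values = values.clip(lower=config.surrogate_floor)
    values.name = table.sample_id
    values.index.name = "ProbeName"
    norm = NormalizationResult(
        sample_id=table.sample_id, observed_p75=observed, scaling_factor=factor
    )
    return values, norm, audit


class ArrayPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer from feature tables to an expression matrix.

    Parameters mirror :class:`PipelineConfig`.  ``transform`` accepts a
    sequence of :class:`~quadarray.io.ArrayTable` and returns a probes x
    samples DataFrame of normalized, collapsed, floored values (NaN where a
    probe lost all replicates).  Per-array scaling audits and the exclusion
    audit of the last transform are exposed as ``normalization_`` and
    ``audit_``.
    """

    def __init__(
        self,
        reference_percentile_value: float = 1500.0,
        percentile: float = 75.0,
        surrogate_floor: float = 20.0,
        iqr_multiplier: float = 1.42,
        pixel_cv_max: float = 0.5,
        quantile_convention: str = "linear",
        fence_convention: str = "quartile_fences",
        floor_stage: str = "post_collapse",
    ) -> None:
        self.reference_percentile_value = reference_percentile_value
        self.percentile = percentile
        self.surrogate_floor = surrogate_floor
        self.iqr_multiplier = iqr_multiplier
        self.pixel_cv_max = pixel_cv_max
        self.quantile_convention = quantile_convention
        self.fence_convention = fence_convention
        self.floor_stage = floor_stage

    def _config(self) -> PipelineConfig:
        return PipelineConfig(**self.get_params())

    def fit(self, X: Sequence[ArrayTable] | None = None, y=None):
        """Validate parameters; the transform itself is per-array and keeps
        no cross-array state."""
        self._config()
        self.n_features_in_ = 0 if X is None else len(X)
        return self

    def transform(self, X: Sequence[ArrayTable]) -> pd.DataFrame:
        config = self._config()
        cols: list[pd.Series] = []
        norms: list[NormalizationResult] = []
        audits: list[pd.DataFrame] = []
        for table in X:
            vals, norm, audit = preprocess_sample(table, config)
            cols.append(vals)
            norms.append(norm)
            audit = audit.copy()
            audit.insert(0, "sample_id", table.sample_id)
            audits.append(audit)
        matrix = pd.concat(cols, axis=1)
        self.normalization_ = norms
        self.audit_ = (
            pd.concat(audits, ignore_index=True)
            if audits
            else pd.DataFrame(
                columns=["sample_id", "probe_id", "replicate_index", "reason", "normalized_gps"]
            )
        )
        return matrix

    def fit_transform(self, X: Sequence[ArrayTable], y=None, **fit_params):
        return self.fit(X, y).transform(X)
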