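"""Pairwise subtype-specificity ("Venn") classification.

For a pair of cell subsets (A, B) every probe falls into exactly one of
four categories, judged on its collapsed expression values in RNA units:

* ``negligible`` — below the expression floor (500 RU) in both subsets;
* ``shared`` — expressed (>= 500 RU) in at least one subset, but with less
  than a twofold difference between the subsets;
* ``unique_A`` / ``unique_B`` — expressed in at least one subset with a
  greater-than-twofold difference, the named subset being the higher one.

A value of exactly 500 RU counts as expressed, and a fold of exactly 2 is
still ``shared``; both follow from the strict inequalities of the scheme.
Classification is performed per experiment and then summarised across
experiments as mean ± sample s.d. per category, matching how the
independent biological replicates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import AggregationError, MissingSampleError
from .io import sample_id_for

__all__ = [
    "ClassifyConfig",
    "SubtypeCall",
    "VennSummary",
    "CATEGORIES",
    "SubtypeClassifier",
    "classify_gene_pair",
    "classify_matrix_pair",
    "venn_summary",
    "summarize_across_experiments",
    "export_heatmap_matrix",
]

CATEGORIES = ("negligible", "shared", "unique_A", "unique_B")


@dataclass(frozen=True)
class ClassifyConfig:
    """Expression floor (RU) and fold threshold of the pairwise scheme."""

    expression_floor: float = 500.0
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.expression_floor <= 0:
            raise ValueError("expression_floor must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SubtypeCall:
    probe_id: str
    pair: tuple[str, str]
    value_a: float
    value_b: float
    fold: float
    category: str


@dataclass(frozen=True)
class VennSummary:
    """Per-pair category counts for one experiment.

    ``n_unclassifiable`` counts probes missing in either sample; they are
    not part of ``total``.
    """

    pair: tuple[str, str]
    experiment: str
    n_negligible: int
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    n_unclassifiable: int = 0

    @property
    def total(self) -> int:
        return self.n_negligible + self.n_shared + self.n_unique_a + self.n_unique_b

    def count(self, category: str) -> int:
        return {
            "negligible": self.n_negligible,
            "shared": self.n_shared,
            "unique_A": self.n_unique_a,
            "unique_B": self.n_unique_b,
        }[category]


class SubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier over (value_A, value_B) expression pairs.

    A deterministic, parameter-free-to-fit classifier: ``fit`` only
    validates the thresholds (there is nothing to estimate), ``predict``
    maps an (n, 2) array of positive expression values in RU onto the four
    categories.  Shaped as an sklearn estimator so it composes with
    pipelines and parameter search.
    """

    def __init__(self, expression_floor: float = 500.0, fold_threshold: float = 2.0):
        self.expression_floor = expression_floor
        self.fold_threshold = fold_threshold

    def _config(self) -> ClassifyConfig:
        return ClassifyConfig(self.expression_floor, self.fold_threshold)

    def fit(self, X=None, y=None):
        self._config()
        self.classes_ = np.asarray(CATEGORIES, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        """Categories for an (n, 2) array of [value_A, value_B] pairs."""
        config = self._config()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_probes, 2)")
        if not np.all(X > 0):
            raise ValueError("expression values must be strictly positive")
        a, b = X[:, 0], X[:, 1]
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        fold = hi / lo
        out = np.full(len(X), "shared", dtype=object)
        negligible = (a < config.expression_floor) & (b < config.expression_floor)
        unique = ~negligible & (fold > config.fold_threshold)
        out[negligible] = "negligible"
        out[unique & (a > b)] = "unique_A"
        out[unique & (b > a)] = "unique_B"
        return out

    def fold(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.maximum(X[:, 0], X[:, 1]) / np.minimum(X[:, 0], X[:, 1])


def classify_gene_pair(
    value_a: float, value_b: float, config: ClassifyConfig = ClassifyConfig(), *,
    probe_id: str = "", pair: tuple[str, str] = ("A", "B"),
) -> SubtypeCall:
    """Classify a single probe for one subset pair."""
    if value_a <= 0 or value_b <= 0:
        raise ValueError("expression values must be strictly positive")
    clf = SubtypeClassifier(config.expression_floor, config.fold_threshold).fit()
    X = np.array([[value_a, value_b]])
    return SubtypeCall(
        probe_id=probe_id,
        pair=pair,
        value_a=float(value_a),
        value_b=float(value_b),
        fold=float(clf.fold(X)[0]),
        category=str(clf.predict(X)[0]),
    )


def classify_matrix_pair(
    matrix: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    config: ClassifyConfig = ClassifyConfig(),
) -> pd.DataFrame:
    """Per-probe calls for two sample columns of an expression matrix.

    Probes missing (NaN) in either sample get category ``unclassifiable``.
    Returns a DataFrame with columns probe_id, value_a, value_b, fold,
    category.
    """
    for s in (sample_a, sample_b):
        if s not in matrix.columns:
            raise MissingSampleError(f"sample {s!r} not in expression matrix")
    a = matrix[sample_a].to_numpy(dtype=float)
    b = matrix[sample_b].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    clf = SubtypeClassifier(config.expression_floor, config.fold_threshold).fit()
    category = np.full(len(matrix), "unclassifiable", dtype=object)
    fold = np.full(len(matrix), np.nan)
    if ok.any():
        X = np.column_stack([a[ok], b[ok]])
        category[ok] = clf.predict(X)
        fold[ok] = clf.fold(X)
    return pd.DataFrame(
        {
            "probe_id": matrix.index.astype(str),
            "value_a": a,
            "value_b": b,
            "fold": fold,
            "category": category,
        }
    )


def venn_summary(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pair: tuple[str, str],
    experiment: str,
    *,
    strain: str | None = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> VennSummary:
    """Category counts for one subset pair within one experiment.

    ``metadata`` maps SampleID to (Strain, Subset, ExperimentID); the two
    sample columns are resolved from (pair, experiment, strain).
    """
    sample_a = sample_id_for(metadata, subset=pair[0], experiment=experiment, strain=strain)
    sample_b = sample_id_for(metadata, subset=pair[1], experiment=experiment, strain=strain)
    calls = classify_matrix_pair(matrix, sample_a, sample_b, config)
    counts = calls["category"].value_counts()
    return VennSummary(
        pair=pair,
        experiment=experiment,
        n_negligible=int(counts.get("negligible", 0)),
        n_shared=int(counts.get("shared", 0)),
        n_unique_a=int(counts.get("unique_A", 0)),
        n_unique_b=int(counts.get("unique_B", 0)),
        n_unclassifiable=int(counts.get("unclassifiable", 0)),
    )


def summarize_across_experiments(
    summaries: Sequence[VennSummary],
) -> pd.DataFrame:
    """Mean and sample s.d. (ddof=1; 0 for a single experiment) of each
    category's count across independent experiments of the same pair."""
    if len(summaries) == 0:
        raise AggregationError("no summaries to aggregate")
    pairs = {s.pair for s in summaries}
    if len(pairs) != 1:
        raise AggregationError(f"summaries mix subset pairs: {sorted(pairs)}")
    rows = []
    for cat in CATEGORIES:
        counts = np.array([s.count(cat) for s in summaries], dtype=float)
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        rows.append(
            {
                "pair": "|".join(summaries[0].pair),
                "category": cat,
                "mean": float(np.mean(counts)),
                "sd": sd,
                "n_experiments": len(counts),
            }
        )
    return pd.DataFrame(rows)


def export_heatmap_matrix(
    matrix: pd.DataFrame,
    probes: Iterable[str],
    samples: Iterable[str],
    path: str | Path,
    *,
    row_scaling: str = "none",
) -> pd.DataFrame:
    """Write a probes x samples submatrix for external heat-map rendering.

    ``row_scaling='log2_zscore'`` log2-transforms and standardises each row
    to mean 0 and unit sample s.d. (ddof=1, matching how the expression
    bar values are summarised); rows with zero or undefined variance are
    emitted as all zeros.  The written TSV is also returned.
    """
    probes = list(probes)
    samples = list(samples)
    unknown_p = [p for p in probes if p not in matrix.index]
    if unknown_p:
        raise KeyError(f"unknown probe(s): {unknown_p[:5]}")
    unknown_s = [s for s in samples if s not in matrix.columns]
    if unknown_s:
        raise MissingSampleError(f"unknown sample(s): {unknown_s[:5]}")
    sub = matrix.loc[probes, samples].astype(float)
    if row_scaling == "log2_zscore":
        vals = np.log2(sub.to_numpy())
        mean = vals.mean(axis=1, keepdims=True)
        sd = (
            vals.std(axis=1, ddof=1, keepdims=True)
            if vals.shape[1] > 1
            else np.zeros((vals.shape[0], 1))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (vals - mean) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        sub = pd.DataFrame(z, index=sub.index, columns=sub.columns)
    elif row_scaling != "none":
        raise ValueError(f"unknown row_scaling {row_scaling!r}")
    out = sub.copy()
    out.index.name = "ProbeName"
    out.to_csv(path, sep="\t", na_rep="NA")
    return sub
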