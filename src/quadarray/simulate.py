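"""Synthetic feature tables with planted ground truth.

The generator emulates the structure of a one-color expression series in
which every non-control probe is printed four times per array (on-chip
quadruplicates) and samples span strains x cell subsets x independent
experiments.  It plants, per probe:

* a **subset-specific** ("unique") expression pattern — baseline times
  ``planted_fold`` in one subset, baseline elsewhere;
* a **negligible** pattern — below the 500 RU expression floor in every
  subset, a fraction of which is pushed below the 20 RU surrogate floor to
  exercise flooring;
* otherwise a **shared** log-normal baseline, truncated away from the
  classification boundaries.

The planted per-probe expression table ("truth") is stored on the scale the
pipeline reports: its feature-level 75th percentile equals the reference
value (1500 RU) in every subset, so after the pipeline's global linear
scaling the planted values are recovered directly.  Each array is then
emitted as truth x an arbitrary per-array scale factor x multiplicative
log-normal replicate noise, with planted replicate outliers (signal
multiplied or divided by ``outlier_magnitude``), planted manual/software
flags (whose signals are corrupted the same way, so exclusion is load-
bearing) and planted high pixel-CV members.

Everything is reproducible from ``seed``; per-array draws use substreams
keyed by (seed, sample id), so the generated tables do not depend on the
order in which arrays are materialised.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassifyConfig, SubtypeClassifier
from .io import ArrayTable, write_feature_table

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "generate_dataset",
    "generate_group_samples",
    "write_dataset",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Study-design and noise parameters of the simulator.

    Defaults describe a desk-scale version of the emulated design: 2,000
    probes (the real arrays carry ~32,000 transcripts; scale ``n_probes``
    up for full-size runs), quadruplicate printing, two strains x three
    subsets x two independent experiments.
    """

    n_probes: int = 2000
    n_control_probes: int = 100
    replicates_per_probe: int = 4
    #: log-scale location/spread of expressed (shared/unique-baseline)
    #: probes, in RU before per-subset renormalization
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 0.6
    #: expressed probes are kept at or above this value (four times the
    #: 500 RU classification floor) so planted categories sit away from
    #: the decision boundaries
    expressed_min: float = 2000.0
    frac_unique_per_pair: float = 0.02
    planted_fold: float = 4.0
    frac_negligible: float = 0.62
    #: fraction of probes planted below the 20 RU surrogate floor
    #: (drawn from U(1, 15) on the normalized scale); taken out of the
    #: negligible fraction
    frac_subfloor: float = 0.03
    replicate_noise_log_sd: float = 0.05
    outlier_rate: float = 0.01
    outlier_magnitude: float = 8.0
    flag_rate: float = 0.005
    high_cv_rate: float = 0.005
    strains: tuple[str, ...] = ("BALBC", "B6")
    subsets: tuple[str, ...] = ("iNKT1", "iNKT2", "iNKT17")
    experiments: tuple[str, ...] = ("Exp1", "Exp2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.replicates_per_probe not in (1, 2, 3, 4):
            raise ValueError("replicates_per_probe must be in 1..4")
        if self.planted_fold <= 1 or self.outlier_magnitude <= 1:
            raise ValueError("planted_fold and outlier_magnitude must exceed 1")
        total = len(self.subsets) * self.frac_unique_per_pair + self.frac_negligible
        if total > 1 + 1e-12:
            raise ValueError(
                "unique and negligible fractions exceed 1 "
                f"({len(self.subsets)} x {self.frac_unique_per_pair} + "
                f"{self.frac_negligible})"
            )
        if self.frac_subfloor > self.frac_negligible:
            raise ValueError("frac_subfloor cannot exceed frac_negligible")
        for name in (
            "frac_unique_per_pair",
            "frac_negligible",
            "frac_subfloor",
            "outlier_rate",
            "flag_rate",
            "high_cv_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicate_noise_log_sd < 0:
            raise ValueError("replicate_noise_log_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset.

    expression
        probes x subsets planted values on the normalized (post-scaling)
        scale; feature-level 75th percentile equals the reference value in
        every subset column.
    categories
        probes x subset-pairs planted classification ("A|B" column labels),
        derived by applying the pairwise rule to ``expression``.
    events
        one row per planted replicate-level QC event: sample_id, probe_id,
        replicate_index, kind in {outlier_high, outlier_low, manual_flag,
        software_outlier, high_pixel_cv}.
    """

    expression: pd.DataFrame
    categories: pd.DataFrame
    events: pd.DataFrame
    subfloor_probes: list[str]
    params: GeneratorParams
    seed: int
    scale_factors: dict[str, float] = field(default_factory=dict)


def _rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _feature_p75(values: np.ndarray, replicates: int) -> float:
    """75th percentile over the feature-level population (each probe value
    appearing once per on-chip replicate), linear interpolation."""
    return float(np.percentile(np.repeat(values, replicates), 75.0))


def _plant_expression(params: GeneratorParams) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    rng = _rng_for(params.seed, "plant")
    n = params.n_probes
    subsets = list(params.subsets)
    probes = [f"P{i + 1:06d}" for i in range(n)]

    n_unique = int(round(params.frac_unique_per_pair * n))
    n_neg = int(round(params.frac_negligible * n))
    n_subfloor = min(int(round(params.frac_subfloor * n)), n_neg)

    order = rng.permutation(n)
    cursor = 0
    unique_idx: dict[str, np.ndarray] = {}
    for s in subsets:
        unique_idx[s] = order[cursor : cursor + n_unique]
        cursor += n_unique
    neg_idx = order[cursor : cursor + n_neg]
    cursor += n_neg
    subfloor_idx = neg_idx[:n_subfloor]

    base = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, n))
    base = np.maximum(base, params.expressed_min)
    expr = np.tile(base[:, None], (1, len(subsets)))
    for j, s in enumerate(subsets):
        expr[unique_idx[s], j] = base[unique_idx[s]] * params.planted_fold
    neg_values = np.exp(rng.uniform(np.log(30.0), np.log(350.0), n_neg))
    expr[neg_idx, :] = neg_values[:, None]

    # renormalize each subset column so its feature-level P75 is the
    # reference value; sub-floor probes are then planted directly on the
    # normalized scale (all below the P75 order statistic, which therefore
    # stays put)
    for j in range(len(subsets)):
        p75 = _feature_p75(expr[:, j], params.replicates_per_probe)
        expr[:, j] *= 1500.0 / p75
    subfloor_values = rng.uniform(1.0, 15.0, n_subfloor)
    expr[subfloor_idx, :] = subfloor_values[:, None]

    expression = pd.DataFrame(expr, index=pd.Index(probes, name="ProbeName"), columns=subsets)

    clf = SubtypeClassifier(**ClassifyConfig().to_dict()).fit()
    cats = {}
    for i, a in enumerate(subsets):
        for b in subsets[i + 1 :]:
            X = expression[[a, b]].to_numpy()
            cats[f"{a}|{b}"] = clf.predict(X)
    categories = pd.DataFrame(cats, index=expression.index)
    subfloor_probes = [probes[i] for i in sorted(subfloor_idx)]
    return expression, categories, subfloor_probes


def _generate_array(
    params: GeneratorParams,
    expression: pd.DataFrame,
    strain: str,
    subset: str,
    experiment: str,
) -> tuple[ArrayTable, pd.DataFrame, float]:
    sample_id = f"{strain}_{subset}_{experiment}"
    rng = _rng_for(params.seed, sample_id)
    n, reps = params.n_probes, params.replicates_per_probe
    shape = (n, reps)

    scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    noise = (
        np.exp(rng.normal(0.0, params.replicate_noise_log_sd, shape))
        if params.replicate_noise_log_sd > 0
        else np.ones(shape)
    )
    truth = expression[subset].to_numpy()
    raw = truth[:, None] * scale * noise

    manual = rng.random(shape) < params.flag_rate
    software = rng.random(shape) < params.flag_rate
    cv = rng.uniform(0.02, 0.3, shape)
    high_cv = rng.random(shape) < params.high_cv_rate
    cv[high_cv] = rng.uniform(0.55, 1.0, int(high_cv.sum()))
    clean = ~(manual | software | high_cv)
    outlier = (rng.random(shape) < params.outlier_rate) & clean
    up = rng.random(shape) < 0.5

    corrupt = outlier | manual | software
    mag = np.where(up, params.outlier_magnitude, 1.0 / params.outlier_magnitude)
    raw = np.where(corrupt, raw * mag, raw)

    probes = expression.index.to_numpy()
    feats = pd.DataFrame(
        {
            "probe_id": np.repeat(probes, reps),
            "replicate_index": np.tile(np.arange(1, reps + 1), n),
            "gps": raw.ravel(),
            "manual_flag": manual.ravel(),
            "outlier_flag": software.ravel(),
            "pixel_cv": cv.ravel(),
            "is_control": False,
        }
    )
    if params.n_control_probes > 0:
        ctrl = pd.DataFrame(
            {
                "probe_id": [f"CTRL{i + 1:04d}" for i in range(params.n_control_probes)],
                "replicate_index": 1,
                "gps": np.exp(rng.normal(5.0, 1.0, params.n_control_probes)) * scale,
                "manual_flag": False,
                "outlier_flag": False,
                "pixel_cv": rng.uniform(0.02, 0.3, params.n_control_probes),
                "is_control": True,
            }
        )
        feats = pd.concat([feats, ctrl], ignore_index=True)

    kinds = {
        "manual_flag": manual,
        "software_outlier": software & ~manual,
        "high_pixel_cv": high_cv & ~(manual | software),
        "outlier_high": outlier & up,
        "outlier_low": outlier & ~up,
    }
    rows = []
    for kind, mask in kinds.items():
        pi, ri = np.nonzero(mask)
        for p, r in zip(pi, ri):
            rows.append((sample_id, probes[p], r + 1, kind))
    events = pd.DataFrame(
        rows, columns=["sample_id", "probe_id", "replicate_index", "kind"]
    )

    table = ArrayTable(
        sample_id=sample_id,
        strain=strain,
        subset=subset,
        experiment_id=experiment,
        features=feats,
    )
    return table, events, scale


def generate_dataset(
    params: GeneratorParams = GeneratorParams(),
) -> tuple[list[ArrayTable], SyntheticTruth]:
    """Generate one full synthetic series.

    Returns the arrays (one per strain x subset x experiment) and the
    planted truth.  Byte-identical for identical ``params``.
    """
    expression, categories, subfloor = _plant_expression(params)
    tables: list[ArrayTable] = []
    event_frames: list[pd.DataFrame] = []
    scales: dict[str, float] = {}
    for strain in params.strains:
        for subset in params.subsets:
            for experiment in params.experiments:
                table, events, scale = _generate_array(
                    params, expression, strain, subset, experiment
                )
                tables.append(table)
                event_frames.append(events)
                scales[table.sample_id] = scale
    all_events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["sample_id", "probe_id", "replicate_index", "kind"])
    )
    truth = SyntheticTruth(
        expression=expression,
        categories=categories,
        events=all_events,
        subfloor_probes=subfloor,
        params=params,
        seed=params.seed,
        scale_factors=scales,
    )
    return tables, truth


def generate_group_samples(
    effect_size: float,
    n_a: int,
    n_b: int,
    distribution: str = "normal",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two groups of animal-level measurements for decision-tree studies.

    ``effect_size`` shifts group B's location in units of the population
    s.d. (both supported distributions have unit s.d.); 0 yields
    exchangeable null groups.
    """
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs n >= 2")
    rng = _rng_for(seed, f"groups:{distribution}")
    if distribution == "normal":
        a = rng.normal(0.0, 1.0, n_a)
        b = rng.normal(effect_size, 1.0, n_b)
    elif distribution == "exponential":
        a = rng.exponential(1.0, n_a)
        b = rng.exponential(1.0, n_b) + effect_size
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return a, b


def write_dataset(
    tables: Sequence[ArrayTable], truth: SyntheticTruth, out_dir: str | Path
) -> Path:
    """Write feature tables, the metadata sidecar and the truth files.

    Layout: ``features/<sample>.tsv``, ``metadata.tsv``,
    ``truth_expression.tsv``, ``truth_categories.tsv``,
    ``truth_events.tsv``, ``generator_params.json``.  Returns the metadata
    path.
    """
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tables:
        fname = f"features/{t.sample_id}.tsv"
        write_feature_table(t, out / fname)
        rows.append((t.sample_id, t.strain, t.subset, t.experiment_id, fname))
    meta = pd.DataFrame(
        rows, columns=["SampleID", "Strain", "Subset", "ExperimentID", "FeatureFile"]
    )
    meta_path = out / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    truth.expression.to_csv(out / "truth_expression.tsv", sep="\t")
    truth.categories.to_csv(out / "truth_categories.tsv", sep="\t")
    truth.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
    (out / "generator_params.json").write_text(
        json.dumps(truth.params.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return meta_path
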