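"""End-to-end orchestration: feature tables -> expression matrix -> Venn
reports, with a machine-readable run manifest.

Outputs written to the output directory:

* ``expression_matrix.tsv`` — probes x samples, floored values, NA missing
* ``normalization.tsv`` — per-array observed percentile and scaling factor
* ``exclusion_audit.tsv`` — one row per excluded feature with its reason
* ``classification_report.tsv`` — per-probe calls per pair/experiment
* ``venn_report.tsv`` — per-pair category counts, mean ± s.d. across
  experiments
* ``manifest.json`` — config snapshot, input digests, stage counts

Reports and matrices are byte-identical across reruns with identical
inputs and configuration (the manifest additionally carries a timestamp).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classify import ClassifyConfig, VennSummary, classify_matrix_pair, summarize_across_experiments, venn_summary
from .errors import QuadArrayError
from .io import (
    ArrayTable,
    read_metadata,
    read_feature_table,
    sample_id_for,
    write_expression_matrix,
)
from .preprocess import ArrayPreprocessor, PipelineConfig

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    classify_config: dict
    inputs: dict[str, str]  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "timestamp": self.timestamp,
                "config": self.config,
                "classify_config": self.classify_config,
                "inputs": self.inputs,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    metadata_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    classify_config: ClassifyConfig = ClassifyConfig(),
    *,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> RunManifest:
    """Run preprocess + classification over all samples of a series.

    ``pairs`` restricts the pairwise comparisons; by default every
    unordered pair of subsets present within each strain is compared, per
    experiment, and summarised across experiments.

    All inputs are read and validated before any output is written, so a
    failing run leaves no partial outputs.
    """
    metadata_path = Path(metadata_path)
    out = Path(out_dir)
    meta = read_metadata(metadata_path)

    tables: list[ArrayTable] = []
    digests: dict[str, str] = {str(metadata_path): _sha256(metadata_path)}
    for row in meta.itertuples(index=False):
        table = read_feature_table(
            row.FeatureFile,
            sample_id=row.SampleID,
            strain=row.Strain,
            subset=row.Subset,
            experiment_id=row.ExperimentID,
        )
        tables.append(table)
        digests[str(row.FeatureFile)] = _sha256(Path(row.FeatureFile))

    pre = ArrayPreprocessor(**config.to_dict())
    matrix = pre.fit_transform(tables)

    n_features = sum(len(t.noncontrol()) for t in tables)
    counts: dict[str, int] = {
        "samples": len(tables),
        "features_read": n_features,
        "features_excluded": int(len(pre.audit_)),
        "features_surviving": n_features - int(len(pre.audit_)),
        "probes": int(matrix.shape[0]),
        "probe_values_collapsed": int(matrix.notna().sum().sum()),
        "probe_values_missing": int(matrix.isna().sum().sum()),
        "probe_values_floored": int((matrix == config.surrogate_floor).sum().sum()),
    }
    for reason, n in pre.audit_["reason"].value_counts().items():
        counts[f"excluded_{reason}"] = int(n)

    # classification per strain / pair / experiment
    call_frames: list[pd.DataFrame] = []
    venn_rows: list[pd.DataFrame] = []
    n_classified = 0
    for strain in sorted(meta["Strain"].unique()):
        sub_meta = meta[meta["Strain"] == strain]
        subsets = sorted(sub_meta["Subset"].unique())
        experiments = sorted(sub_meta["ExperimentID"].unique())
        strain_pairs = (
            [p for p in pairs if p[0] in subsets and p[1] in subsets]
            if pairs is not None
            else list(combinations(subsets, 2))
        )
        for pair in strain_pairs:
            summaries: list[VennSummary] = []
            for exp in experiments:
                try:
                    summary = venn_summary(
                        matrix, sub_meta, pair, exp, strain=strain, config=classify_config
                    )
                except QuadArrayError:
                    continue  # pair not measured in this experiment
                summaries.append(summary)
                sa = sample_id_for(sub_meta, subset=pair[0], experiment=exp, strain=strain)
                sb = sample_id_for(sub_meta, subset=pair[1], experiment=exp, strain=strain)
                calls = classify_matrix_pair(matrix, sa, sb, classify_config)
                calls.insert(1, "strain", strain)
                calls.insert(2, "pair", f"{pair[0]}|{pair[1]}")
                calls.insert(3, "experiment", exp)
                call_frames.append(calls)
                n_classified += summary.total
            if summaries:
                agg = summarize_across_experiments(summaries)
                agg.insert(0, "strain", strain)
                venn_rows.append(agg)
    counts["probe_calls"] = n_classified

    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, out / "expression_matrix.tsv")
    pd.DataFrame(
        [
            {
                "sample_id": n.sample_id,
                "observed_p75": n.observed_p75,
                "scaling_factor": n.scaling_factor,
            }
            for n in pre.normalization_
        ]
    ).to_csv(out / "normalization.tsv", sep="\t", index=False)
    pre.audit_.to_csv(out / "exclusion_audit.tsv", sep="\t", index=False)
    if call_frames:
        pd.concat(call_frames, ignore_index=True).to_csv(
            out / "classification_report.tsv", sep="\t", index=False
        )
    if venn_rows:
        pd.concat(venn_rows, ignore_index=True).to_csv(
            out / "venn_report.tsv", sep="\t", index=False
        )

    manifest = RunManifest(
        config=config.to_dict(),
        classify_config=classify_config.to_dict(),
        inputs=digests,
        counts=counts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
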