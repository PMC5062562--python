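"""Reading and writing the pipeline's tabular formats.

The raw input is the tab-delimited per-feature table produced by one-color
feature-extraction software: one row per *physical* feature (a probe printed
at one position on the glass), carrying the processed green-channel signal
(``gProcessedSignal``), QC flags and the coefficient of variation of the
pixel intensities within the feature.  Non-control probes are printed four
times per array ("on-chip quadruplicates").

A minimal canonical dialect is used (columns below); genuine vendor exports
can be adapted by passing a column-name mapping, since the vendor format
carries dozens of columns we never consume.

Required feature-table columns
    ProbeName, ReplicateIndex, gProcessedSignal, IsManualFlag (0/1),
    IsOutlier (0/1), PixelCV, IsControl (0/1)

Sample metadata sidecar columns
    SampleID, Strain, Subset, ExperimentID, FeatureFile

Expression matrices are written as TSV with probes as rows, samples as
columns and missing values encoded as ``NA``; floats are written at full
``repr`` precision so a write/read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, MissingSampleError

FEATURE_COLUMNS = (
    "ProbeName",
    "ReplicateIndex",
    "gProcessedSignal",
    "IsManualFlag",
    "IsOutlier",
    "PixelCV",
    "IsControl",
)

METADATA_COLUMNS = ("SampleID", "Strain", "Subset", "ExperimentID", "FeatureFile")

#: canonical internal column names of ``ArrayTable.features``
_INTERNAL = {
    "ProbeName": "probe_id",
    "ReplicateIndex": "replicate_index",
    "gProcessedSignal": "gps",
    "IsManualFlag": "manual_flag",
    "IsOutlier": "outlier_flag",
    "PixelCV": "pixel_cv",
    "IsControl": "is_control",
}

STRAINS = ("BALBC", "B6")
SUBSETS = ("iNKT1", "iNKT2", "iNKT17", "CD4neg_iNKT1", "CD4pos_iNKT1", "other")

MAX_REPLICATES = 4


@dataclass(frozen=True)
class FeatureRecord:
    """One physical on-chip feature."""

    probe_id: str
    replicate_index: int
    gps: float
    manual_flag: bool = False
    outlier_flag: bool = False
    pixel_cv: float = 0.0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.gps < 0:
            raise ValueError(f"gps must be >= 0, got {self.gps}")
        if self.pixel_cv < 0:
            raise ValueError(f"pixel_cv must be >= 0, got {self.pixel_cv}")
        if self.replicate_index not in (1, 2, 3, 4):
            raise ValueError(
                f"replicate_index must be in 1..4, got {self.replicate_index}"
            )


@dataclass
class ArrayTable:
    """One scanned sample: metadata plus all its features.

    ``features`` is a DataFrame with columns probe_id, replicate_index, gps,
    manual_flag, outlier_flag, pixel_cv, is_control — one row per physical
    feature, in file order.
    """

    sample_id: str
    strain: str
    subset: str
    experiment_id: str
    features: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_features(self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def noncontrol(self) -> pd.DataFrame:
        return self.features[~self.features["is_control"]]

    def records(self) -> list[FeatureRecord]:
        """Materialise features as FeatureRecord objects (file order)."""
        return [
            FeatureRecord(
                probe_id=r.probe_id,
                replicate_index=int(r.replicate_index),
                gps=float(r.gps),
                manual_flag=bool(r.manual_flag),
                outlier_flag=bool(r.outlier_flag),
                pixel_cv=float(r.pixel_cv),
                is_control=bool(r.is_control),
            )
            for r in self.features.itertuples(index=False)
        ]


def validate_features(df: pd.DataFrame) -> None:
    """Validate a canonical feature frame against the data invariants.

    Raises
    ------
    FormatError
        missing column.
    ValueError
        negative signal or pixel CV, replicate index out of 1..4 (the
        offending row number, 1-based over data rows, is named).
    IntegrityError
        duplicated (probe, replicate) or more than four printings of a
        non-control probe, or no non-control feature at all.
    """
    for col in _INTERNAL.values():
        if col not in df.columns:
            raise FormatError(f"feature table lacks required column {col!r}")

    gps = df["gps"].to_numpy(dtype=float)
    if np.isnan(gps).any():
        row = int(np.flatnonzero(np.isnan(gps))[0]) + 1
        raise ValueError(f"missing gProcessedSignal in row {row}")
    if (gps < 0).any():
        row = int(np.flatnonzero(gps < 0)[0]) + 1
        raise ValueError(f"negative gProcessedSignal in row {row}")
    cv = df["pixel_cv"].to_numpy(dtype=float)
    if (cv < 0).any():
        row = int(np.flatnonzero(cv < 0)[0]) + 1
        raise ValueError(f"negative PixelCV in row {row}")
    rep = df["replicate_index"].to_numpy()
    bad = ~np.isin(rep, (1, 2, 3, 4))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"ReplicateIndex outside 1..4 in row {row}")

    nc = df[~df["is_control"].astype(bool)]
    if nc.empty:
        raise IntegrityError("no non-control feature present")
    if nc.duplicated(subset=["probe_id", "replicate_index"]).any():
        dup = nc[nc.duplicated(subset=["probe_id", "replicate_index"])].iloc[0]
        raise IntegrityError(
            f"duplicate (probe, replicate) pair: "
            f"({dup['probe_id']}, {dup['replicate_index']})"
        )
    counts = nc["probe_id"].value_counts()
    if (counts > MAX_REPLICATES).any():
        probe = counts.index[counts.to_numpy() > MAX_REPLICATES][0]
        raise IntegrityError(
            f"non-control probe {probe!r} printed {int(counts[probe])} times "
            f"(at most {MAX_REPLICATES} on-chip replicates allowed)"
        )


def read_feature_table(
    path: str | Path,
    *,
    sample_id: str | None = None,
    strain: str = "other",
    subset: str = "other",
    experiment_id: str = "",
    column_map: Mapping[str, str] | None = None,
) -> ArrayTable:
    """Read one per-feature TSV into a validated :class:`ArrayTable`.

    ``column_map`` maps canonical column names to the names actually present
    in the file, so richer vendor exports can be consumed without rewriting.
    Rows are kept in file order; invalid rows abort the read with an error
    naming the row, they are never silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"ProbeName": str}, float_precision="round_trip"
    )
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    feats = df[list(FEATURE_COLUMNS)].rename(columns=_INTERNAL)
    feats = feats.astype(
        {
            "probe_id": str,
            "replicate_index": int,
            "gps": float,
            "manual_flag": bool,
            "outlier_flag": bool,
            "pixel_cv": float,
            "is_control": bool,
        }
    )
    return ArrayTable(
        sample_id=sample_id if sample_id is not None else path.stem,
        strain=strain,
        subset=subset,
        experiment_id=experiment_id,
        features=feats,
    )


def write_feature_table(table: ArrayTable, path: str | Path) -> None:
    """Write an ArrayTable back to the canonical TSV dialect."""
    inv = {v: k for k, v in _INTERNAL.items()}
    out = table.features.rename(columns=inv)[list(FEATURE_COLUMNS)].copy()
    for col in ("IsManualFlag", "IsOutlier", "IsControl"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata sidecar TSV.

    Returns a DataFrame with the METADATA_COLUMNS; relative FeatureFile paths
    are resolved against the metadata file's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing metadata column(s) {', '.join(missing)}"
        )
    if df.empty:
        raise FormatError(f"{path.name}: metadata file lists no samples")
    if df["SampleID"].duplicated().any():
        dup = df["SampleID"][df["SampleID"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicated SampleID {dup!r} in metadata")
    df = df.copy()
    df["FeatureFile"] = [
        str((path.parent / f) if not Path(f).is_absolute() else Path(f))
        for f in df["FeatureFile"]
    ]
    return df


def read_samples(metadata_path: str | Path) -> list[ArrayTable]:
    """Read every sample listed in a metadata sidecar."""
    meta = read_metadata(metadata_path)
    return [
        read_feature_table(
            row.FeatureFile,
            sample_id=row.SampleID,
            strain=row.Strain,
            subset=row.Subset,
            experiment_id=row.ExperimentID,
        )
        for row in meta.itertuples(index=False)
    ]


def validate_expression_matrix(matrix: pd.DataFrame, *, floor: float | None = None) -> None:
    """Check an expression matrix (probes x samples) for duplicated labels
    and, when ``floor`` is given, for values below the surrogate floor."""
    if matrix.index.duplicated().any():
        raise IntegrityError("duplicated probe_ids in expression matrix")
    if matrix.columns.duplicated().any():
        raise IntegrityError("duplicated sample_ids in expression matrix")
    if floor is not None:
        vals = matrix.to_numpy(dtype=float)
        if vals.size and np.any(vals[~np.isnan(vals)] < floor):
            raise IntegrityError(f"expression value below the floor of {floor}")


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a probes x samples matrix as TSV, missing values as ``NA``.

    Values are written with full repr precision, so
    ``read_expression_matrix(write_expression_matrix(m)) == m`` bit-exactly.
    """
    validate_expression_matrix(matrix)
    out = matrix.copy()
    out.index.name = "ProbeName"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.index.name = "ProbeName"
    validate_expression_matrix(df)
    return df.astype(float)


def sample_id_for(
    metadata: pd.DataFrame, *, subset: str, experiment: str, strain: str | None = None
) -> str:
    """Resolve the unique SampleID for a (subset, experiment[, strain]) key."""
    sel = (metadata["Subset"] == subset) & (metadata["ExperimentID"] == experiment)
    if strain is not None:
        sel &= metadata["Strain"] == strain
    hits: Sequence[str] = metadata.loc[sel, "SampleID"].tolist()
    if len(hits) == 0:
        raise MissingSampleError(
            f"no sample with subset={subset}, experiment={experiment}, strain={strain}"
        )
    if len(hits) > 1:
        raise IntegrityError(
            f"ambiguous sample for subset={subset}, experiment={experiment}, "
            f"strain={strain}: {hits}"
        )
    return hits[0]
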