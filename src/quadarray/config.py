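"""Flat key-value configuration files (YAML or JSON) for the CLI.

A config file may set any field of :class:`~quadarray.preprocess.PipelineConfig`
(top level or under ``preprocess:``), of
:class:`~quadarray.classify.ClassifyConfig` (top level or under
``classify:``) and of :class:`~quadarray.stats.StatsConfig` (under
``stats:``).  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .classify import ClassifyConfig
from .errors import FormatError
from .preprocess import PipelineConfig
from .stats import StatsConfig

__all__ = ["load_configs", "dump_configs"]

_SECTIONS = {
    "preprocess": PipelineConfig,
    "classify": ClassifyConfig,
    "stats": StatsConfig,
}


def _field_names(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def load_configs(
    path: str | Path | None,
) -> tuple[PipelineConfig, ClassifyConfig, StatsConfig]:
    """Load the three config dataclasses from one file (defaults when
    ``path`` is None)."""
    if path is None:
        return PipelineConfig(), ClassifyConfig(), StatsConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")

    kwargs = {name: dict(raw.get(name) or {}) for name in _SECTIONS}
    for key, value in raw.items():
        if key in _SECTIONS:
            continue
        placed = False
        for name, cls in _SECTIONS.items():
            if key in _field_names(cls):
                kwargs[name].setdefault(key, value)
                placed = True
                break
        if not placed:
            raise FormatError(f"{path}: unknown config key {key!r}")
    for name, cls in _SECTIONS.items():
        unknown = set(kwargs[name]) - _field_names(cls)
        if unknown:
            raise FormatError(
                f"{path}: unknown {name} config key(s) {sorted(unknown)}"
            )
    try:
        return (
            PipelineConfig(**kwargs["preprocess"]),
            ClassifyConfig(**kwargs["classify"]),
            StatsConfig(**kwargs["stats"]),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def dump_configs(
    path: str | Path,
    pipeline: PipelineConfig = PipelineConfig(),
    classify: ClassifyConfig = ClassifyConfig(),
    stats: StatsConfig = StatsConfig(),
) -> None:
    data = {
        "preprocess": pipeline.to_dict(),
        "classify": classify.to_dict(),
        "stats": stats.to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
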