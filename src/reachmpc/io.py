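"""Serialization helpers: JSON summaries, config echoes, CSV conventions.

Record and solution CSV schemas live on their classes
(:meth:`SimulationRecord.to_csv`, :meth:`OcpSolution.to_csv`); this module
adds the run-directory layout used by the command-line interface: one
directory per run containing ``record.csv``, ``config.yaml`` and
``diagnostics.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .nmpc import SimulationRecord


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_run_directory(directory, record: SimulationRecord,
                        config: dict | None = None) -> Path:
    """Write a simulation run to ``directory`` in the standard layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    record.to_csv(directory / "record.csv")
    (directory / "diagnostics.json").write_text(
        json.dumps(_jsonable({"metadata": record.metadata,
                              "iterations": record.diagnostics}), indent=2))
    if config is not None:
        (directory / "config.yaml").write_text(
            yaml.safe_dump(_jsonable(config), sort_keys=False))
    return directory


def write_summary_json(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2))


def read_record(path) -> SimulationRecord:
    return SimulationRecord.from_csv(path)
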