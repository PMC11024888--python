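"""YAML-backed workflow configuration shared by the CLI commands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .annotate import AnnotationConfig

__all__ = ["WorkflowConfig", "load_config"]


@dataclass(frozen=True)
class WorkflowConfig:
    """Every tunable of the workflow, with the printed defaults.

    precursor/fragment tolerances 25/50 ppm, acceptance score >= 10,
    RRT tolerance +/-0.015, in-source artifact ceiling 1%, heatmap floor
    0.01% and QC floor 0.1% relative abundance.
    """

    precursor_tol_ppm: float = 25.0
    fragment_tol_ppm: float = 50.0
    score_threshold: float = 10.0
    rrt_tolerance: float = 0.015
    artifact_fraction: float = 0.01
    rt_window: float = 0.2
    min_height: float = 1000.0
    heatmap_min_pct: float = 0.01
    qc_min_pct: float = 0.1
    min_fold_change: float = 2.0
    seed: int = 1

    def annotation(self) -> AnnotationConfig:
        return AnnotationConfig(
            precursor_tol_ppm=self.precursor_tol_ppm,
            fragment_tol_ppm=self.fragment_tol_ppm,
            score_threshold=self.score_threshold,
            rrt_tolerance=self.rrt_tolerance,
            artifact_fraction=self.artifact_fraction,
            rt_window=self.rt_window,
            min_height=self.min_height,
        )


def load_config(path: Optional[str | Path] = None) -> WorkflowConfig:
    """Load a YAML config; unknown keys are rejected, omitted keys default."""
    if path is None:
        return WorkflowConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(WorkflowConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return WorkflowConfig(**data)
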