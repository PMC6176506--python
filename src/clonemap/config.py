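"""Run-wide configuration with the workflow's standard thresholds."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their standard defaults.

    Every threshold defaults to the value the workflow was designed
    around: amplification-start-time gate 40 min, alignment-ratio floor
    0.2, Fisher confirmation p < 1e-4, segmentation penalty gamma = 20,
    10,000 multiscale bootstraps, feature-weight sweep 0.1-10 in steps
    of 0.25 with 10 spatial nearest neighbors, and SSCS validation at
    FDR < 0.05.
    """

    seed: int = 0
    ast_threshold_min: float = 40.0
    alignment_ratio_min: float = 0.2
    lorenz_auc_min: float | None = None
    cna_correlation_min: float | None = None
    fisher_p: float = 1e-4
    gamma: float = 20.0
    n_bootstrap: int = 10_000
    sweep_min: float = 0.1
    sweep_max: float = 10.0
    sweep_step: float = 0.25
    n_neighbors: int = 10
    fdr: float = 0.05
    min_callers: int = 2
    min_samples: int = 2
    section_spacing_um: float = 700.0
    paths: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
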