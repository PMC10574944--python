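"""Pipeline configuration: every tunable threshold in one validated object.

Defaults are the operative values of the method (see docs/methods.md for
units and rationale); any subset can be overridden from a YAML or JSON
mapping file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .technique import Thresholds

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline.

    Detection thresholds live in :class:`~climbkit.technique.Thresholds`;
    the remaining fields control motion segmentation (envelope multiplier
    ``n_sigma``, rolling ``window``, threshold fraction ``rho``, minimum
    movement ``k_mu``, speed pre-smoothing ``smooth_window``), the phase
    machine (``min_phase_frames``) and calibration (RANSAC iterations and
    inlier tolerance, seeded by ``seed``).
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    n_sigma: float = 2.0
    window: int = 3
    rho: float = 0.5
    smooth_window: int = 15
    spike_window: int = 7
    min_phase_frames: int = 5
    fps: float = 60.0
    ransac_iterations: int = 500
    ransac_inlier_tol: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sigma <= 0 or not (0 < self.rho < 1):
            raise ValueError("need n_sigma > 0 and 0 < rho < 1")
        if self.window < 3 or self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("window must be >= 3 and smooth_window odd >= 1")
        if self.spike_window < 1 or self.spike_window % 2 == 0:
            raise ValueError("spike_window must be odd and >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def k_mu(self) -> int:
        return self.thresholds.k_mu

    def to_json(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    @classmethod
    def from_mapping(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        th_doc = doc.pop("thresholds", {})
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        unknown_th = set(th_doc) - {f.name for f in dataclasses.fields(Thresholds)}
        if unknown_th:
            raise ValueError(f"unknown threshold keys: {sorted(unknown_th)}")
        return cls(thresholds=Thresholds(**th_doc), **doc)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a config from YAML/JSON, or the defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.from_mapping(doc or {})
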