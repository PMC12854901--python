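"""Run configuration: every tunable of the pipeline with its default, with
lossless YAML/JSON round-tripping."""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """All pipeline tunables.

    ``median_kernel`` is ordered (y, x, z) as in standard confocal notation;
    the z axis carries the small tap because axial sampling is coarse.
    """

    # input
    voxel_size: Optional[tuple[float, float, float]] = None  # μm (z,y,x); overrides sidecar

    # preprocessing
    median_kernel: tuple[int, int, int] = (5, 5, 3)
    n_bins: int = Field(default=128, ge=16)
    histogram_weighting: Literal["intensity", "count"] = "intensity"

    # GMM fit + model selection
    k_candidates: tuple[int, ...] = (2, 3, 4)
    n_starts: int = Field(default=5, ge=1)
    max_nfev: int = Field(default=200, ge=10)
    selection_tol: float = 6e-3
    background_ceiling_quantile: float = 0.60

    # objects
    min_size: int = Field(default=4, ge=1)

    # behaviour verdict
    p_threshold: float = 0.05
    r_flat: float = 0.2
    rel_change_threshold: float = 0.10
    profile_bins: int = Field(default=4, ge=2)

    # secondary quantification
    coloc_mask: Literal["otsu-union", "whole-image"] = "otsu-union"
    n_prebleach: int = 5
    min_bleach_fraction: float = 0.5

    # export
    bit_depth: Optional[int] = None
    write_masks: bool = False

    rng_seed: int = 0

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            return cls.from_yaml(path)
        import json

        return cls.model_validate(json.loads(path.read_text()))
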