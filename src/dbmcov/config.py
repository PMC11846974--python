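"""Run configuration: every stage parameter and seed in one serializable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    outdir: str = "dbmcov_run"
    # --- synthetic cohort ---
    simulate: bool = True
    n_per_cell: int = 15
    timepoints_dpi: tuple[int, ...] = (-7, 30, 90, 120)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (0.1, 0.1, 0.1)
    k0: int = 6
    seed: int = 0
    # --- existing data (used when simulate is false) ---
    image_dir: str | None = None
    mask_path: str | None = None
    cohort_csv: str | None = None
    behavior_csv: str | None = None
    # --- preprocessing ---
    fwhm_mm: float = 0.085
    # --- decomposition ---
    analysis_dpi: float = 90.0
    k_list: tuple[int, ...] = tuple(range(2, 21, 2))
    n_splits: int = 5
    opnmf_max_iter: int = 10_000
    opnmf_tol: float = 1e-5
    # --- statistics ---
    q_level: float = 0.01
    bonferroni_m: int = 8
    # --- stage toggles ---
    run_opnmf: bool = True
    run_voxelstats: bool = True
    run_behavior: bool = True
    write_images: bool = True

    def __post_init__(self) -> None:
        self.timepoints_dpi = tuple(int(t) for t in self.timepoints_dpi)
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.k_list = tuple(int(k) for k in self.k_list)

    def to_dict(self) -> dict:
        return asdict(self)

    #: filesystem locations, excluded from the analysis-parameter hash
    _PATH_FIELDS = ("outdir", "image_dir", "mask_path", "cohort_csv", "behavior_csv")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        blob = json.dumps(params, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)
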