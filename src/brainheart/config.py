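"""Run configuration: every tunable of the analysis graph in one object.

The defaults reproduce the study design: 155 volumes at TR 2 s with the
first 5 discarded, 0.009-0.08 Hz band, 6 mm seed spheres, 60 s / 10 s
sliding windows, 30 first-level and 20 group ICA dimensions, CDT p < 0.001
for FC contrasts and p < 0.005 for synchronization/regressions, cluster FWE
alpha 0.05, FDR q 0.05 (0.10 exploratory). Configs round-trip through YAML
unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    master_seed: int = 0

    # cohort generation
    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_networks: int = 5
    synth_overrides: dict = field(default_factory=dict)  # CouplingSpec fields

    # seed ROIs
    seed_names: tuple[str, ...] = (
        "pcc", "vmpfc", "amygdala_l", "amygdala_r", "na_l", "na_r"
    )
    roi_radius_mm: float = 6.0
    sync_seed_roi: str = "na_l"  # seed used for voxelwise FC-HR sync maps

    # preprocessing
    n_discard: int = 5
    fwhm_mm: float = 0.0
    low_hz: float = 0.009
    high_hz: float = 0.08

    # sliding windows
    window_s: float = 60.0
    step_s: float = 10.0

    # group ICA
    n_pcs: int = 30
    n_components: int = 20
    ica_max_iter: int = 10000
    ica_tol: float = 1e-5

    # inference
    cdt_fc: float = 0.001
    cdt_sync: float = 0.005
    fwe_alpha: float = 0.05
    fdr_q: float = 0.05
    fdr_q_exploratory: float = 0.10
    n_permutations: int = 199
    connectivity: int = 18

    # stage toggles (voxelwise permutation analyses dominate run time)
    voxelwise_sync: bool = True
    voxelwise_contrasts: bool = True
    behavior_regressions: bool = True

    def __post_init__(self) -> None:
        for name in ("cdt_fc", "cdt_sync", "fwe_alpha", "fdr_q", "fdr_q_exploratory"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        for name in ("n_subjects", "n_pcs", "n_components", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.low_hz >= self.high_hz:
            raise ConfigError("low_hz must be below high_hz")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.seed_names = tuple(self.seed_names)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["seed_names"] = list(self.seed_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
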