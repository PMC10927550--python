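"""Pipeline configuration: explicit parameters and seeds, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grids import GridSpec
from .synthetic import LC_CLASSES


def default_lc_transition() -> list[list[float]]:
    """Land abandonment scenario: grassland and cropland drift toward forest."""
    k = len(LC_CLASSES)
    T = [[1.0 if i == j else 0.0 for j in range(k)] for i in range(k)]
    g, f, c = (
        LC_CLASSES.index("grassland"),
        LC_CLASSES.index("forest"),
        LC_CLASSES.index("cropland"),
    )
    T[g][g], T[g][f] = 0.7, 0.3
    T[c][c], T[c][f] = 0.85, 0.15
    return T


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run; all seeds explicit."""

    out_dir: str = "scratch/run"
    seed: int = 1
    # grid
    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 100.0
    fine_to_coarse_factor: int = 10
    relief_amplitude: float = 3000.0
    pa_fraction: float = 0.18
    # species / observations
    n_species: int = 25
    expected_points: float = 2000.0
    min_pixels: int = 30
    occ_cap: int = 10000
    # scenarios
    horizons: list[int] = field(default_factory=lambda: [2050, 2080])
    ssps: list[int] = field(default_factory=lambda: [245])
    warming: dict = field(
        default_factory=lambda: {"2050-245": 1.5, "2050-585": 2.0, "2080-245": 2.5, "2080-585": 4.5}
    )
    n_gcm: int = 2
    lc_transition: list[list[float]] = field(default_factory=default_lc_transition)
    # bias correction
    k_clusters: int = 30
    ebc_max_dup: int = 10
    ebc_target: str = "areal"
    # model
    alpha: float = 0.5
    lam_grid: list[float] = field(default_factory=lambda: [1e-2, 1e-3, 1e-4])
    quad_n0: int = 1000
    quad_tol: float = 0.01
    lc_variants: list[str] = field(default_factory=lambda: ["LC", "LC10"])
    n_blocks: int = 10
    n_folds: int = 5
    retention_cutoff: float = 0.3
    # dispersal
    dispersal_mode: str = "limited"
    # prioritization
    algorithm: str = "caz"
    abf_z: float = 0.25
    top_fraction: float = 0.20

    def grid(self) -> GridSpec:
        return GridSpec(
            self.n_rows,
            self.n_cols,
            self.cell_size,
            fine_to_coarse_factor=self.fine_to_coarse_factor,
        )

    def ssp_offsets(self) -> dict[tuple[int, int], float]:
        out = {}
        for h in self.horizons:
            for s in self.ssps:
                out[(h, s)] = float(self.warming[f"{h}-{s}"])
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
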