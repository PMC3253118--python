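"""Layered run configuration with flat dotted keys.

Defaults equal the modelling settings the pipeline is built around:
k = 10 nearest neighbours for the adaptive kernel, 3-SD ellipse, focal
radius 9 cells, VIF threshold 7.5.  A YAML file with flat dotted keys
(e.g. ``gwr.k_neighbors: 10``) overrides defaults; CLI flags override the
file.  The configuration round-trips losslessly through serialization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Schema-invalid configuration; message carries the offending key."""


@dataclass
class RunConfig:
    species: list[str] | None = None          # None = all species present
    bin_width_alt: float = 100.0               # m
    bin_width_tma: float = 1.0                 # degrees C
    bin_width_pma: float = 100.0               # mm
    response_kind: str = "presence_intensity"
    response_radius_km: float = 100.0
    vif_threshold: float = 7.5
    gwr_k_neighbors: int = 10
    moran_scheme: str = "inverse_distance"
    moran_row_standardize: bool = True
    moran_permutations: int = 0
    ellipse_n_sd: float = 3.0
    focal_radius_cells: float = 9.0
    min_records: int = 30
    seed: int = 0
    write_rank_rasters: bool = False

    _KEYMAP = {
        "species": "species",
        "bins.alt_width": "bin_width_alt",
        "bins.tma_width": "bin_width_tma",
        "bins.pma_width": "bin_width_pma",
        "response.kind": "response_kind",
        "response.radius_km": "response_radius_km",
        "selection.vif_threshold": "vif_threshold",
        "gwr.k_neighbors": "gwr_k_neighbors",
        "moran.scheme": "moran_scheme",
        "moran.row_standardize": "moran_row_standardize",
        "moran.permutations": "moran_permutations",
        "ellipse.n_sd": "ellipse_n_sd",
        "focal.radius_cells": "focal_radius_cells",
        "min_records": "min_records",
        "seed": "seed",
        "output.rank_rasters": "write_rank_rasters",
    }

    @property
    def bin_widths(self) -> dict[str, float]:
        return {
            "ALT": self.bin_width_alt,
            "TMA": self.bin_width_tma,
            "PMA": self.bin_width_pma,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping of dotted keys")
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        for key, value in raw.items():
            attr = cls._KEYMAP.get(key)
            if attr is None:
                raise ConfigError(f"unknown configuration key: {key!r}")
            expected = type(getattr(cfg, attr)) if getattr(cfg, attr) is not None else None
            if expected in (int, float) and isinstance(value, (int, float)):
                value = expected(value)
            elif expected is bool and not isinstance(value, bool):
                raise ConfigError(f"{key}: expected boolean, got {value!r}")
            setattr(cfg, attr, value)
        return cfg

    def to_mapping(self) -> dict:
        inv = {v: k for k, v in self._KEYMAP.items()}
        out = {}
        for attr, value in asdict(self).items():
            if attr in inv:
                out[inv[attr]] = value
        return out

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)
        return path
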