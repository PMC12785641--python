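"""Run configuration: every sampled distribution's parameters plus seed.

The configuration serializes losslessly to YAML; the effective config is
written next to generated batches for provenance.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cells import CellBounds, VolumeSpec
from .diffraction import DiffractionConfig
from .errors import ConfigurationError
from .oblique import SkewConfig
from .placement import PlacementRules

__all__ = ["GeneratorConfig"]

PLACEMENT_MODES = ("uniform", "molecules", "equal_atoms")


@dataclass(frozen=True)
class GeneratorConfig:
    volume: VolumeSpec = field(default_factory=VolumeSpec)
    bounds: CellBounds = field(default_factory=CellBounds)
    skew: SkewConfig = field(default_factory=SkewConfig)
    rules: PlacementRules = field(default_factory=PlacementRules)
    diffraction: DiffractionConfig = field(default_factory=DiffractionConfig)
    placement_mode: str = "molecules"
    space_group: str = "P-1"
    n_special_positions: int = 4
    special_p: float = 0.05
    v_atom_range: tuple[float, float] = (7.0, 22.0)
    x_h_range: tuple[float, float] = (0.3, 0.6)
    u_range: tuple[float, float] = (0.01, 0.1)
    dev_range: tuple[float, float] = (-0.005, 0.005)
    general_table: str | None = None  # None -> packaged defaults
    special_table: str | None = None
    radii_table: str | None = None
    equal_atom_element: str = "C"
    hkl_dialect: str = "shelx"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement_mode not in PLACEMENT_MODES:
            raise ConfigurationError(
                f"placement_mode must be one of {PLACEMENT_MODES}, "
                f"got {self.placement_mode!r}"
            )
        if self.space_group not in ("P1", "P-1"):
            raise ConfigurationError(f"unsupported space group {self.space_group!r}")
        if not 0.0 <= self.special_p <= 1.0:
            raise ConfigurationError(f"special_p must be in [0, 1], got {self.special_p}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)

        def build(key, target, tuple_fields=()):
            if key in data and isinstance(data[key], dict):
                sub = dict(data[key])
                for tf in tuple_fields:
                    if tf in sub and isinstance(sub[tf], list):
                        sub[tf] = tuple(sub[tf])
                data[key] = target(**sub)

        build("volume", VolumeSpec)
        build("bounds", CellBounds)
        build("skew", SkewConfig)
        build("rules", PlacementRules, ("bond_window",))
        build("diffraction", DiffractionConfig, ("resolution_range", "completeness_range"))
        for tf in ("v_atom_range", "x_h_range", "u_range", "dev_range"):
            if tf in data and isinstance(data[tf], list):
                data[tf] = tuple(data[tf])
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
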