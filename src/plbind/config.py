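"""Nested run configuration with YAML loading and dotted overrides.

Every module's tunables live in one section; unknown keys are rejected
so a typo in a config file fails loudly instead of silently using a
default.  Command-line overrides use the flat ``section.key=value``
syntax, which makes the published hyperparameter variants (6 vs 22 atom
types; 256/512/1024 pocket points) one-flag runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SurfaceConfig", "StructureConfig", "SequenceConfig", "LigandConfig",
    "InteractionConfig", "FusionConfig", "TrainConfig", "RunConfig",
]


@dataclass
class SurfaceConfig:
    resolution: float = 1.0  # target sampling density, points per A^2
    level: float = 1.05  # level-set offset, A
    pocket_k: int = 512  # pocket size, in {256, 512, 1024} for the published variants
    atom_types: int = 22  # element vocabulary size, 22 or 6
    k_atoms: int = 16  # atom neighbors per surface point
    chem_dim: int = 16
    chem_hidden: int = 16
    embed_dim: int = 32
    n_layers: int = 3
    radius: float = 9.0  # quasi-geodesic window radius, A


@dataclass
class StructureConfig:
    pocket_radius: float = 8.0  # A from any ligand atom
    k_neighbors: int = 16
    n_layers: int = 3
    hidden_scalar: int = 32
    hidden_vector: int = 4
    dropout: float = 0.1


@dataclass
class SequenceConfig:
    backend: str = "fallback"  # "fallback" or "protbert"
    width: int = 32  # fallback embedding width
    window: int = 2  # fallback mixing half-window
    seed: int = 0


@dataclass
class LigandConfig:
    hidden_dim: int = 128
    atom_rounds: int = 3
    mol_rounds: int = 2
    strip_hydrogens: bool = True


@dataclass
class InteractionConfig:
    cutoff: float = 5.0  # contact cutoff c, A (strict <)
    pooling: str = "mean"  # "mean" or "sum"
    hidden_dim: int = 32
    out_dim: int = 32
    n_rounds: int = 2
    protein_scope: str = "pocket"  # "pocket" or "all" atoms in V_p


@dataclass
class FusionConfig:
    d_model: int = 128
    n_heads: int = 4
    encoder_layers: int = 2
    decoder_layers: int = 2
    share_decoders: bool = False


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_decay: float = 1.0  # per-epoch multiplicative decay
    batch_size: int = 8
    epochs: int = 200
    seed: int = 0
    weight_decay: float = 0.0
    patience: int = 30  # early-stopping patience, epochs
    head_hidden: int = 64

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 0 or self.patience < 0:
            raise ValueError("training hyperparameters must be non-negative (batch >= 1)")


@dataclass
class RunConfig:
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    ligand: LigandConfig = field(default_factory=LigandConfig)
    interaction: InteractionConfig = field(default_factory=InteractionConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    # ------------------------------------------------------------ plumbing
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, obj: dict[str, Any]) -> "RunConfig":
        cfg = cls()
        for section, value in obj.items():
            if section == "seed":
                cfg.seed = int(value)
                continue
            if not hasattr(cfg, section) or not dataclasses.is_dataclass(getattr(cfg, section)):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            names = {f.name for f in dataclasses.fields(sub)}
            for key, v in value.items():
                if key not in names:
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(sub, key, v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(obj)

    def apply_override(self, expr: str) -> None:
        """Apply one ``section.key=value`` override (YAML-typed value)."""
        try:
            dotted, raw = expr.split("=", 1)
            section, key = dotted.split(".", 1)
        except ValueError as err:
            raise ValueError(f"override must look like section.key=value, got {expr!r}") from err
        if not hasattr(self, section):
            raise KeyError(f"unknown config section {section!r}")
        sub = getattr(self, section)
        if not dataclasses.is_dataclass(sub) or key not in {f.name for f in dataclasses.fields(sub)}:
            raise KeyError(f"unknown config key {dotted!r}")
        value = yaml.safe_load(raw)
        current = getattr(sub, key)
        # YAML 1.1 reads "1e-3" as a string; coerce to the field's type
        if isinstance(current, bool) and not isinstance(value, bool):
            value = str(value).lower() in ("1", "true", "yes", "on")
        elif isinstance(current, int) and not isinstance(value, bool) and not isinstance(value, int):
            value = int(value)
        elif isinstance(current, float) and not isinstance(value, float):
            value = float(value)
        setattr(sub, key, value)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
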