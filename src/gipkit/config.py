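"""Study configuration: one YAML document describing a full simulated study."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .simdata import BlockSpec, TraitArchitecture

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """Parameters of a simulate -> GWAS -> GIP -> replication run.

    ``traits`` uses the exchangeable parameterization (equal h2 / r_g /
    prevalence across traits); ``causal`` optionally plants a fixed shared
    liability effect at one SNP index for positive-control runs.
    """

    seed: int = 1
    n_traits: int = 4
    h2_liab: float = 0.4
    r_g: float = 0.7
    env_corr: float = 0.3
    prevalence: float = 0.15
    binary: bool = True
    n_blocks: int = 100
    block_size: int = 10
    within_block_r: float | tuple[float, ...] = 0.9
    graded_ld: bool = True  # scalar within_block_r = max of a 0..max grading
    maf_range: tuple[float, float] = (0.05, 0.5)
    discovery_n: int = 4000
    replication_n: tuple[int, ...] = (3000, 3000)
    causal_snp: int | None = None
    causal_effect: float = 0.0
    ldsc_blocks: int = 100
    ld_window_bp: int = 1_000_000
    gip_draws: int = 500
    base_threshold: float = 5e-8
    alpha: float = 0.05
    trait_names: tuple[str, ...] = ()
    qc_maf_min: float = 0.0
    qc_info_min: float = 0.0
    qc_call_rate_min: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic step")

    @property
    def block_spec(self) -> BlockSpec:
        r = self.within_block_r
        if self.graded_ld and isinstance(r, (int, float)):
            return BlockSpec.graded(
                self.n_blocks, self.block_size, r_max=float(r),
                maf_range=tuple(self.maf_range),
            )
        if isinstance(r, (list, tuple)):
            r = tuple(r)
        return BlockSpec(
            n_blocks=self.n_blocks,
            block_size=self.block_size,
            within_block_r=r,
            maf_range=tuple(self.maf_range),
        )

    @property
    def architecture(self) -> TraitArchitecture:
        return TraitArchitecture.exchangeable(
            n_traits=self.n_traits,
            h2_liab=self.h2_liab,
            r_g=self.r_g,
            prevalence=self.prevalence,
            env_corr=self.env_corr,
            binary_mode=self.binary,
            names=tuple(self.trait_names),
        )

    @property
    def fixed_effects(self) -> dict | None:
        if self.causal_snp is None:
            return None
        import numpy as np

        return {int(self.causal_snp): np.full(self.n_traits, self.causal_effect)}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("replication_n", "maf_range", "trait_names"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("replication_n", "maf_range", "trait_names"):
            d[name] = list(d[name])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
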