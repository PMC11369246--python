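"""Run configuration: one validated object that every stage reads.

All randomness in the pipeline flows from :attr:`RunConfig.seed`; stages derive
their own streams with :func:`stage_rng`, so any stage can be re-run in
isolation and reproduce its output bit for bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import yaml


@dataclasses.dataclass(frozen=True)
class IdentityThresholds:
    """Nested similarity tiers used to group monomers.

    Monomers connected at identity >= ``variant`` are sequence variants of one
    repeat; >= ``family`` members of one family; >= ``superfamily`` members of
    one superfamily.  Lower bounds are closed.
    """

    variant: float = 0.95
    family: float = 0.80
    superfamily: float = 0.50

    def __post_init__(self) -> None:
        t = (self.variant, self.family, self.superfamily)
        if not all(0.0 < x <= 1.0 for x in t):
            raise ValueError(f"identity thresholds must lie in (0, 1]: {t}")
        if not self.variant > self.family > self.superfamily:
            raise ValueError(f"thresholds must be ordered variant > family > superfamily: {t}")


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full satellitome run.

    Defaults mirror the protocol the pipeline implements: 2 x 500,000 read
    pairs per discovery/quantification subsample, 2 x 5,000,000 pairs for
    haplotype networks, every base at Phred quality >= 20, and monomers longer
    than the read length excluded from haplotype analysis.
    """

    seed: int = 0
    read_length: int = 150
    subsample_pairs_discovery: int = 500_000
    subsample_pairs_haplonet: int = 5_000_000
    quality_threshold: int = 20
    kmer_size: int = 21
    #: minimum canonical k-mer count kept in the discovery graph; None means
    #: estimate from the data (3 x modal single-copy k-mer depth, floor 5)
    min_kmer_count: Optional[int] = None
    masking_min_identity: float = 0.80
    masking_min_read_coverage: float = 0.50
    identity_thresholds: IdentityThresholds = dataclasses.field(default_factory=IdentityThresholds)
    #: a monomer is called male-biased when abundance_male/abundance_female
    #: exceeds this ratio (female-biased below its reciprocal)
    mf_bias_ratio: float = 1.0
    mst_max_monomer_length: int = 150
    max_rounds: int = 10
    min_haplotype_count: int = 2
    min_identity_for_extraction: float = 0.80
    name_prefix: str = "Sat"

    def __post_init__(self) -> None:
        if isinstance(self.identity_thresholds, dict):
            self.identity_thresholds = IdentityThresholds(**self.identity_thresholds)
        if self.kmer_size < 3 or self.kmer_size % 2 == 0:
            raise ValueError(f"kmer_size must be odd and >= 3, got {self.kmer_size}")
        for field in ("subsample_pairs_discovery", "subsample_pairs_haplonet"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        for field in ("masking_min_identity", "masking_min_read_coverage",
                      "min_identity_for_extraction"):
            v = getattr(self, field)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{field} must lie in (0, 1], got {v}")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_kmer_count is not None and self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1 (or None for auto)")
        if self.mf_bias_ratio < 1.0:
            raise ValueError("mf_bias_ratio must be >= 1.0")

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


#: fixed stage names used for per-stage seed derivation
STAGES = ("simulate", "discover", "catalog", "quantify", "haplonet")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator.

    The global seed is expanded with the stage's index in :data:`STAGES` via
    ``numpy.random.SeedSequence([seed, index])``, so re-running a single stage
    reproduces exactly the stream it saw inside a full run.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return np.random.default_rng(np.random.SeedSequence([seed, STAGES.index(stage)]))
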