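"""Abundance, divergence and sex-bias quantification.

Abundance of a satellite is the fraction of library base pairs masked by its
monomer (the RepeatMasker convention): reads from a per-sex subsample are
aligned against each monomer's tandem reference and every best hit credits
its aligned bp to that monomer.  A read-count mode (fraction of reads hit)
is available behind a flag for comparability with read-based definitions.

Per-hit genetic distance uses the Kimura 2-parameter model: with transition
proportion P and transversion proportion Q over the compared columns,

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Hits outside the model's domain (1-2P-Q <= 0 or 1-2Q <= 0, i.e. saturated
divergence) are excluded and counted.  Divergence landscapes bin masked bp by
K2P distance in 1% bins from 0 to 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import TandemIndex, substitution_counts
from .config import RunConfig
from .discovery import subsample_pairs

LANDSCAPE_BINS = 50  # 1%-wide bins, 0..50%


class K2PDomainError(ValueError):
    """Distance undefined: substitution proportions beyond model saturation."""


def kimura_two_parameter(p: float, q: float) -> float:
    """Kimura 2-parameter distance from transition (p) and transversion (q) proportions."""
    if p < 0 or q < 0:
        raise ValueError("substitution proportions must be >= 0")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise K2PDomainError(f"K2P undefined for p={p}, q={q}")
    return -0.5 * math.log(a * math.sqrt(b))


@dataclass
class AbundanceRecord:
    """Per-monomer masked-bp abundance and the M/F bias call."""

    name: str
    masked_bp_male: int = 0
    masked_bp_female: int = 0
    reads_hit_male: int = 0
    reads_hit_female: int = 0
    library_bp_male: int = 0
    library_bp_female: int = 0
    abundance_male: float = 0.0
    abundance_female: float = 0.0
    mf_ratio: Optional[float] = None  # math.inf when female abundance is 0
    bias_call: str = "none"  # "male" | "female" | "none"


@dataclass
class DivergenceRecord:
    """Per-monomer K2P distances of every hit, with bp weights."""

    name: str
    distances: List[float] = field(default_factory=list)
    bp_weights: List[int] = field(default_factory=list)
    saturated_hits: int = 0

    @property
    def landscape(self) -> np.ndarray:
        """Masked bp per 1% K2P bin (index i covers [i%, i+1%); last bin open)."""
        hist = np.zeros(LANDSCAPE_BINS, dtype=np.int64)
        for d, bp in zip(self.distances, self.bp_weights):
            b = min(int(d * 100), LANDSCAPE_BINS - 1)
            hist[b] += bp
        return hist


def _bias_call(ratio: Optional[float], margin: float) -> str:
    if ratio is None:
        return "none"
    if ratio > margin:
        return "male"
    if ratio < 1.0 / margin:
        return "female"
    return "none"


def quantify(
    male_pairs: Sequence[Tuple[str, str]],
    female_pairs: Sequence[Tuple[str, str]],
    monomers: Sequence[str],
    names: Sequence[str],
    config: RunConfig,
    rng: np.random.Generator,
    count_mode: str = "bp",
) -> Tuple[List[AbundanceRecord], List[DivergenceRecord]]:
    """Estimate per-sex abundance and divergence of every catalog monomer.

    Each sex's QC-passed library is subsampled to
    ``config.subsample_pairs_discovery`` pairs; reads are classified with the
    same alignment criteria as masking.  ``count_mode="bp"`` divides masked bp
    by subsample bp; ``"reads"`` divides hit reads by subsample reads.
    """
    if not monomers:
        raise ValueError("quantify requires a non-empty catalog")
    if count_mode not in ("bp", "reads"):
        raise ValueError("count_mode must be 'bp' or 'reads'")
    index = TandemIndex(list(monomers), config.read_length)
    records = [AbundanceRecord(name=n) for n in names]
    div = [DivergenceRecord(name=n) for n in names]

    totals = {}
    for sex, pairs in (("male", male_pairs), ("female", female_pairs)):
        sub = subsample_pairs(pairs, config.subsample_pairs_discovery, rng)
        total_bp = sum(len(a) + len(b) for a, b in sub)
        total_reads = 2 * len(sub)
        totals[sex] = (total_bp, total_reads)
        for pair in sub:
            for seq in pair:
                hit = index.best_hit(
                    seq, config.masking_min_identity, config.masking_min_read_coverage
                )
                if hit is None:
                    continue
                rec = records[hit.monomer_index]
                if sex == "male":
                    rec.masked_bp_male += hit.masked_bp
                    rec.reads_hit_male += 1
                else:
                    rec.masked_bp_female += hit.masked_bp
                    rec.reads_hit_female += 1
                ts, tv, cols = substitution_counts(hit.query, hit.target)
                if cols == 0:
                    continue
                try:
                    k2p = kimura_two_parameter(ts / cols, tv / cols)
                except K2PDomainError:
                    div[hit.monomer_index].saturated_hits += 1
                    continue
                div[hit.monomer_index].distances.append(k2p)
                div[hit.monomer_index].bp_weights.append(hit.masked_bp)

    for rec in records:
        rec.library_bp_male, male_reads = totals["male"]
        rec.library_bp_female, female_reads = totals["female"]
        if count_mode == "bp":
            rec.abundance_male = rec.masked_bp_male / rec.library_bp_male
            rec.abundance_female = rec.masked_bp_female / rec.library_bp_female
        else:
            rec.abundance_male = rec.reads_hit_male / male_reads
            rec.abundance_female = rec.reads_hit_female / female_reads
        if rec.abundance_female > 0:
            rec.mf_ratio = rec.abundance_male / rec.abundance_female
        elif rec.abundance_male > 0:
            rec.mf_ratio = math.inf
        else:
            rec.mf_ratio = None
        rec.bias_call = _bias_call(rec.mf_ratio, config.mf_bias_ratio)
    return records, div


def abundance_table(records: Sequence[AbundanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        ratio = "NA" if r.mf_ratio is None else ("Inf" if math.isinf(r.mf_ratio) else r.mf_ratio)
        rows.append(
            {
                "name": r.name,
                "masked_bp_male": r.masked_bp_male,
                "masked_bp_female": r.masked_bp_female,
                "library_bp_male": r.library_bp_male,
                "library_bp_female": r.library_bp_female,
                "abundance_male": r.abundance_male,
                "abundance_female": r.abundance_female,
                "mf_ratio": ratio,
                "bias_call": r.bias_call,
            }
        )
    return pd.DataFrame(rows)


def landscape_table(record: DivergenceRecord) -> pd.DataFrame:
    """Divergence landscape: one row per 1% K2P bin with its masked bp."""
    hist = record.landscape
    return pd.DataFrame(
        {"bin_lower_pct": np.arange(LANDSCAPE_BINS), "masked_bp": hist}
    )
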