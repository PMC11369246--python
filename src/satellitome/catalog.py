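"""Satellite catalog construction: canonical forms, homology, naming.

A satellite monomer is a circular sequence observed at arbitrary phase and
strand, so every monomer is stored in a canonical form (lexicographic minimum
over all rotations of itself and of its reverse complement) and all identity
comparisons are rotation- and strand-aware.

Identity metric.  Two monomers of equal length are compared by exact circular
Hamming identity: the maximum match fraction over all rotations and both
strands.  This is exact for substitution-diverged repeat units, and for
unrelated sequences it concentrates near 0.25, far below the superfamily tier.
Unequal-length monomers are compared by Smith-Waterman local alignment of the
shorter against the dimerized longer sequence (match +1, mismatch -1, gap open
-2, extend -1), with matched bases normalized by the longer length, so a short
repeat embedded in a long one is not spuriously promoted to high identity.
Gapped global edit alignment was rejected because at <= 60% identity its
match fraction for random DNA saturates near 0.55, erasing the 50% tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner

from ._seq import encode, revcomp
from .config import IdentityThresholds

_VALID = set("ACGT")


@dataclass
class SatMonomer:
    """One satellite consensus with its descriptors."""

    name: str
    sequence: str  # canonical form
    rul: int
    at_fraction: float
    abundance_male: float = 0.0
    abundance_female: float = 0.0
    mf_ratio: Optional[float] = None  # math.inf when female abundance is 0
    family: Optional[str] = None
    superfamily: Optional[str] = None

    @classmethod
    def from_sequence(cls, name: str, sequence: str, **kw) -> "SatMonomer":
        seq = canonical_form(sequence)
        at = (seq.count("A") + seq.count("T")) / len(seq)
        return cls(name=name, sequence=seq, rul=len(seq), at_fraction=at, **kw)

    @property
    def mean_abundance(self) -> float:
        return (self.abundance_male + self.abundance_female) / 2.0


@dataclass
class HomologyPartition:
    """Nested grouping of monomer names: variants within families within superfamilies."""

    variant_groups: List[List[str]]
    family_groups: List[List[str]]
    superfamily_groups: List[List[str]]
    superfamily_labels: Dict[str, str] = field(default_factory=dict)  # name -> "SFn"

    def _check_cover(self, groups: List[List[str]], names: set) -> None:
        seen: List[str] = [n for g in groups for n in g]
        if len(seen) != len(set(seen)) or set(seen) != names:
            raise AssertionError("partition does not cover all monomers exactly once")

    def validate(self) -> None:
        names = {n for g in self.variant_groups for n in g}
        for groups in (self.variant_groups, self.family_groups, self.superfamily_groups):
            self._check_cover(groups, names)
        for fine, coarse in (
            (self.variant_groups, self.family_groups),
            (self.family_groups, self.superfamily_groups),
        ):
            lookup = {n: i for i, g in enumerate(coarse) for n in g}
            for group in fine:
                if len({lookup[n] for n in group}) != 1:
                    raise AssertionError("nesting violated: fine group spans coarse groups")


def canonical_form(sequence: str) -> str:
    """Lexicographic minimum over all rotations of the sequence and its revcomp."""
    seq = sequence.upper()
    if not seq or set(seq) - _VALID:
        raise ValueError(f"invalid characters in sequence: {sorted(set(seq) - _VALID)}")
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best


def _circular_identity(a: str, b: str) -> float:
    """Max Hamming match fraction over rotations/strands; equal lengths only."""
    n = len(a)
    ca = encode(a)
    best = 0
    for bb in (b, revcomp(b)):
        windows = np.lib.stride_tricks.sliding_window_view(encode(bb + bb), n)[:n]
        best = max(best, int((windows == ca).sum(axis=1).max()))
    return best / n


_sw = PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-2, extend_gap_score=-1
)


def _local_identity(short: str, long: str) -> float:
    best = 0
    dimer = long + long
    for q in (short, revcomp(short)):
        aln = _sw.align(dimer, q)
        best = max(best, aln[0].counts().identities)
    return best / len(long)


def pairwise_identity(a, b) -> float:
    """Rotation/strand-aware identity between two monomers (or raw sequences)."""
    sa = a.sequence if isinstance(a, SatMonomer) else a
    sb = b.sequence if isinstance(b, SatMonomer) else b
    if len(sa) == len(sb):
        return _circular_identity(sa, sb)
    short, long = (sa, sb) if len(sa) < len(sb) else (sb, sa)
    return _local_identity(short, long)


# -- clustering ------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(names: List[str], identity: np.ndarray, threshold: float) -> List[List[str]]:
    uf = _UnionFind(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if identity[i, j] >= threshold:
                uf.union(i, j)
    groups: Dict[int, List[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(uf.find(i), []).append(name)
    return [sorted(g) for _, g in sorted(groups.items())]


def build_partition(
    monomers: Sequence[SatMonomer],
    thresholds: IdentityThresholds = IdentityThresholds(),
) -> HomologyPartition:
    """Single-linkage variant/family/superfamily partition of the catalog.

    Two monomers share a variant group iff connected by pairwise identity
    >= the variant threshold, a family at >= the family threshold, and a
    superfamily at >= the superfamily threshold; nesting follows from the
    threshold ordering.  Superfamilies are labelled SF1, SF2, ... by
    decreasing summed mean abundance (ties broken by first member name).
    """
    ordered = sorted(monomers, key=lambda m: m.sequence)  # input-order independence
    names = [m.name for m in ordered]
    n = len(names)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(ordered[i], ordered[j])
    variant = _single_linkage(names, ident, thresholds.variant)
    family = _single_linkage(names, ident, thresholds.family)
    superfam = _single_linkage(names, ident, thresholds.superfamily)

    by_name = {m.name: m for m in ordered}
    def group_abundance(g: List[str]) -> float:
        return sum(by_name[n].mean_abundance for n in g)

    sf_sorted = sorted(superfam, key=lambda g: (-group_abundance(g), g[0]))
    labels = {name: f"SF{i + 1}" for i, g in enumerate(sf_sorted) for name in g}
    part = HomologyPartition(variant, family, sf_sorted, labels)
    part.validate()
    return part


def _family_labels(partition: HomologyPartition) -> Dict[str, str]:
    return {name: f"F{i + 1}" for i, g in enumerate(partition.family_groups) for name in g}


def dedupe_candidates(sequences: Sequence[str], supports: Sequence[float],
                      variant_threshold: float = 0.95) -> List[Tuple[str, float]]:
    """Canonicalize and merge near-duplicate candidate monomers.

    Candidates within the variant threshold of an already-kept candidate are
    merged into it, keeping the higher-support consensus.  Iteration order is
    by decreasing support then canonical sequence, so output is input-order
    independent.
    """
    canon = [canonical_form(s) for s in sequences]
    order = sorted(range(len(canon)), key=lambda i: (-supports[i], canon[i]))
    kept: List[Tuple[str, float]] = []
    for i in order:
        if any(pairwise_identity(canon[i], seq) >= variant_threshold for seq, _ in kept):
            continue
        kept.append((canon[i], supports[i]))
    return kept


def finalize_catalog(
    sequences: Sequence[str],
    abundances: Dict[str, Tuple[float, float]],
    thresholds: IdentityThresholds = IdentityThresholds(),
    name_prefix: str = "Sat",
) -> Tuple[List[SatMonomer], HomologyPartition]:
    """Rank, name and partition deduplicated canonical monomers.

    *abundances* maps canonical sequence -> (male, female) library-bp
    fractions.  Names are ``<prefix><rank>`` zero-padded, rank by decreasing
    mean abundance with lexicographic tie-break on sequence.
    """
    canon = [canonical_form(s) for s in sequences]
    if len(set(canon)) != len(canon):
        raise ValueError("duplicate canonical sequences; run dedupe_candidates first")
    ranked = sorted(canon, key=lambda s: (-(sum(abundances.get(s, (0, 0))) / 2), s))
    width = max(2, len(str(len(ranked))))
    monomers = []
    for rank, seq in enumerate(ranked, start=1):
        ab_m, ab_f = abundances.get(seq, (0.0, 0.0))
        if ab_f > 0:
            ratio: Optional[float] = ab_m / ab_f
        elif ab_m > 0:
            ratio = math.inf
        else:
            ratio = None
        monomers.append(
            SatMonomer.from_sequence(
                f"{name_prefix}{rank:0{width}d}", seq,
                abundance_male=ab_m, abundance_female=ab_f, mf_ratio=ratio,
            )
        )
    partition = build_partition(monomers, thresholds) if monomers else HomologyPartition([], [], [])
    fam = _family_labels(partition)
    for m in monomers:
        m.family = fam.get(m.name)
        m.superfamily = partition.superfamily_labels.get(m.name)
    return monomers, partition
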