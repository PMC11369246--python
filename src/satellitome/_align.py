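"""Read-vs-monomer alignment machinery.

Satellite monomers are circular in phase: a read can start anywhere in the
repeat and cross the monomer junction, so all read alignment is done against a
tandem extension of the monomer (the monomer concatenated with itself enough
times to contain a full read at any phase).

Identity here is edit-distance identity, ``1 - ed / read_len``; in the
high-identity regime used for masking (>= 0.8) this is a faithful match
fraction, while unrelated reads score ~0.5 and are rejected with a wide
margin.  A k-mer seed prefilter keeps the edlib calls restricted to reads that
can possibly hit a monomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib

from ._seq import revcomp

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def tandem_reference(monomer: str, min_length: int) -> str:
    """Monomer repeated head-to-tail until it spans *min_length* + one monomer."""
    reps = -(-min_length // len(monomer)) + 1
    return monomer * reps


@dataclass
class Hit:
    """Best alignment of one read (or read half) against the catalog."""

    monomer_index: int
    identity: float
    masked_bp: int
    query: str          # the read segment, in the orientation that aligned
    #: the tandem reference the query aligned to (forward strand of monomer)
    target: str


class TandemIndex:
    """Seed-and-extend index over a set of monomers for read classification."""

    def __init__(self, monomers: Sequence[str], read_length: int, seed_k: int = 13):
        if not monomers:
            raise ValueError("TandemIndex requires at least one monomer")
        self.monomers = list(monomers)
        self.read_length = read_length
        self.seed_k = seed_k
        self.targets = [tandem_reference(m, read_length) for m in self.monomers]
        self._seeds: Dict[str, Set[int]] = {}
        for idx, target in enumerate(self.targets):
            for strand_seq in (target, revcomp(target)):
                for i in range(len(strand_seq) - seed_k + 1):
                    self._seeds.setdefault(strand_seq[i : i + seed_k], set()).add(idx)

    def _candidates(self, read: str) -> Set[int]:
        k = self.seed_k
        found: Set[int] = set()
        for i in range(0, len(read) - k + 1, 4):  # stride 4: dense enough, 4x cheaper
            hit = self._seeds.get(read[i : i + k])
            if hit:
                found |= hit
        return found

    def _align_segment(
        self, segment: str, candidates: Set[int], min_identity: float
    ) -> Optional[Tuple[int, float, str]]:
        """Best (monomer_index, identity, oriented_query) for one read segment."""
        max_ed = int((1.0 - min_identity) * len(segment))
        best: Optional[Tuple[int, float, str]] = None
        seg_rc = revcomp(segment)
        for idx in sorted(candidates):
            for query in (segment, seg_rc):
                res = edlib.align(query, self.targets[idx], mode="HW", task="distance", k=max_ed)
                ed = res["editDistance"]
                if ed < 0:
                    continue
                ident = 1.0 - ed / len(segment)
                if best is None or ident > best[1]:  # ties: lower monomer index wins
                    best = (idx, ident, query)
        return best

    def best_hit(
        self, read: str, min_identity: float, min_read_coverage: float = 0.5
    ) -> Optional[Hit]:
        """Classify one read against the catalog.

        A full-read alignment at identity >= *min_identity* masks the whole
        read.  Otherwise, when *min_read_coverage* <= 0.5, each read half is
        tried independently so that reads straddling an array boundary still
        contribute their satellite-derived half to the bp tally.
        """
        candidates = self._candidates(read)
        if not candidates:
            return None
        full = self._align_segment(read, candidates, min_identity)
        if full is not None:
            idx, ident, query = full
            return Hit(idx, ident, len(read), query, self.targets[idx])
        if min_read_coverage > 0.5 or len(read) < 2 * self.seed_k:
            return None
        half = len(read) // 2
        hits = []
        for seg in (read[:half], read[half:]):
            seg_cands = self._candidates(seg) & candidates
            got = self._align_segment(seg, seg_cands, min_identity) if seg_cands else None
            if got is not None:
                hits.append((got, len(seg)))
        if not hits:
            return None
        (idx, ident, query), seg_len = max(hits, key=lambda h: h[0][1])
        masked = sum(seg_len for _, seg_len in hits)
        return Hit(idx, ident, masked, query, self.targets[idx])


def substitution_counts(query: str, target: str) -> Tuple[int, int, int]:
    """(transitions, transversions, compared columns) of the best infix alignment.

    Gap columns and columns containing an ambiguous base are excluded from the
    comparison; the remaining columns form the denominator for the K2P
    transition/transversion proportions.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    ts = tv = cols = 0
    for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
        if qc == "-" or tc == "-" or qc == "N" or tc == "N":
            continue
        cols += 1
        if qc != tc:
            if (qc, tc) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return ts, tv, cols


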