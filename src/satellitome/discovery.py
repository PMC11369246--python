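"""De novo satellite monomer discovery from unassembled reads.

A pure tandem repeat with monomer M induces, over error-free reads, a k-mer
de Bruijn graph that is a single simple cycle of length |M| (for any k at
which M has no internal repeated k-mer; for monomers shorter than k the cycle
has one node per monomer position).  Discovery therefore:

1. counts canonical k-mers (min of k-mer and reverse complement) in a read
   subsample and keeps those above an abundance threshold, which strips the
   single-copy background and sequencing-error k-mers;
2. builds the directed overlap graph over the retained k-mers in both
   orientations;
3. inside each connected component, hunts for the maximum-mean-weight simple
   cycle by a greedy heaviest-edge walk with backtracking bounded by the
   component size, and spells the cycle as the candidate monomer.

The full protocol is iterative: mine a subsample, mask the discovered
monomers out of the working libraries, and repeat until a round yields no
novel satellite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from ._align import TandemIndex
from ._seq import kmer_codes, rc_kmer_codes
from .config import RunConfig
from .io import ReadRecord

logger = logging.getLogger(__name__)

#: shortest admissible k-mer cycle (monomers of at least ~6 bp are expected;
#: length-1/2 cycles are homopolymer/dinucleotide artifacts)
MIN_CYCLE_LEN = 4


@dataclass
class QCParams:
    """Whole-read quality filter: every base must reach the threshold."""

    quality_threshold: int = 20
    policy: str = "drop-read"

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.policy != "drop-read":
            raise ValueError("only the drop-read policy is supported")


@dataclass
class CandidateMonomer:
    """One spelled k-mer cycle: a candidate satellite repeat unit."""

    sequence: str
    support: float  # mean edge weight along the cycle
    round_found: int = 0


@dataclass
class KmerGraph:
    """Directed overlap graph over retained oriented k-mers."""

    k: int
    min_kmer_count: int
    #: oriented k-mer code -> list of (successor code, edge weight), heaviest first
    out_edges: Dict[int, List[Tuple[int, int]]]

    @property
    def nodes(self) -> set:
        ns = set(self.out_edges)
        for succs in self.out_edges.values():
            ns.update(v for v, _ in succs)
        return ns


def _passes(rec: ReadRecord, threshold: int) -> bool:
    return "N" not in rec.sequence and all(q >= threshold for q in rec.qualities)


def qc_filter(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]], params: QCParams
) -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    """Retain a pair iff both mates have every base >= threshold and no N."""
    t = params.quality_threshold
    for r1, r2 in pairs:
        if _passes(r1, t) and _passes(r2, t):
            yield r1, r2


def subsample_pairs(pairs: Sequence, n_pairs: int, rng: np.random.Generator) -> List:
    """Uniform sample of *n_pairs* pairs without replacement (all, if fewer)."""
    if len(pairs) == 0:
        raise ValueError("library holds no pairs")
    if n_pairs >= len(pairs):
        if n_pairs > len(pairs):
            logger.info("library holds %d pairs < requested %d; using all", len(pairs), n_pairs)
        return list(pairs)
    idx = rng.choice(len(pairs), size=n_pairs, replace=False)
    return [pairs[i] for i in idx]


# -- k-mer graph -----------------------------------------------------------


def _estimate_min_count(counts: np.ndarray) -> int:
    """Auto threshold: 3 x the modal k-mer depth of multi-copy k-mers.

    The mode of the count histogram over counts >= 3 estimates the single-copy
    sequencing depth; satellite k-mers sit at copy-number multiples of it.
    """
    multi = counts[counts >= 3]
    if multi.size == 0:
        return 5
    hist = np.bincount(np.minimum(multi, 1000))
    mode = int(hist.argmax())
    return max(5, 3 * mode)


def build_kmer_graph(
    reads: Sequence[str], k: int, min_kmer_count: Optional[int] = None
) -> KmerGraph:
    """Count canonical k-mers across *reads* and link retained adjacent k-mers."""
    blob = "N".join(reads)
    fwd, valid = kmer_codes(blob, k)
    rc, _ = rc_kmer_codes(blob, k)
    canonical = np.minimum(fwd, rc)

    uniq, counts = np.unique(canonical[valid], return_counts=True)
    if min_kmer_count is None:
        min_kmer_count = _estimate_min_count(counts)
        logger.info("auto min_kmer_count = %d", min_kmer_count)
    retained = uniq[counts >= min_kmer_count]

    node_ok = valid.copy()
    node_ok[valid] = np.isin(canonical[valid], retained, assume_unique=False)
    pair_ok = node_ok[:-1] & node_ok[1:]

    # observed adjacency in read orientation, plus its reverse-complement mirror
    u = np.concatenate([fwd[:-1][pair_ok], rc[1:][pair_ok]])
    v = np.concatenate([fwd[1:][pair_ok], rc[:-1][pair_ok]])
    edges = np.stack([u, v], axis=1)
    uniq_edges, weights = np.unique(edges, axis=0, return_counts=True)

    out: Dict[int, List[Tuple[int, int]]] = {}
    for (a, b), w in zip(uniq_edges, weights):
        out.setdefault(int(a), []).append((int(b), int(w)))
    for succs in out.values():
        succs.sort(key=lambda e: (-e[1], e[0]))
    return KmerGraph(k=k, min_kmer_count=min_kmer_count, out_edges=out)


def _components(graph: KmerGraph) -> List[List[int]]:
    """Weakly connected components, each sorted; deterministic order."""
    adj: Dict[int, set] = {}
    for a, succs in graph.out_edges.items():
        for b, _ in succs:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    seen: set = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            n = stack.pop()
            comp.append(n)
            for m in adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        comps.append(sorted(comp))
    return comps


def _best_cycle(
    comp: List[int], graph: KmerGraph, max_starts: int = 20
) -> Optional[Tuple[float, List[int]]]:
    """Greedy heaviest-edge walk with backtracking; best (mean weight, cycle)."""
    out = graph.out_edges
    strength = {u: sum(w for _, w in out.get(u, ())) for u in comp}
    starts = sorted(comp, key=lambda u: (-strength[u], u))[:max_starts]
    budget = 8 * len(comp)
    best: Optional[Tuple[float, List[int]]] = None
    for start in starts:
        path = [start]
        on_path = {start}
        weights: List[int] = []
        iters = [iter(out.get(start, ()))]
        steps = 0
        found: Optional[Tuple[float, List[int]]] = None
        while iters and steps < budget:
            steps += 1
            try:
                nxt, w = next(iters[-1])
            except StopIteration:
                iters.pop()
                on_path.discard(path.pop())
                if weights:
                    weights.pop()
                continue
            if nxt == start and len(path) >= MIN_CYCLE_LEN:
                cw = weights + [w]
                found = (sum(cw) / len(cw), list(path))
                break
            if nxt in on_path:
                continue
            path.append(nxt)
            on_path.add(nxt)
            weights.append(w)
            iters.append(iter(out.get(nxt, ())))
        if found is not None and (best is None or found[0] > best[0]):
            best = found
    return best


def _spell(cycle: List[int], k: int) -> str:
    """Spell the monomer: first base of each k-mer along the cycle."""
    shift = 2 * (k - 1)
    return "".join("ACGT"[(code >> shift) & 3] for code in cycle)


def detect_monomers(
    reads: Sequence[str], k: int, min_kmer_count: Optional[int] = None
) -> List[CandidateMonomer]:
    """Candidate monomers from one read subsample (one cycle per component)."""
    from .catalog import canonical_form

    if not reads:
        raise ValueError("empty read subsample")
    graph = build_kmer_graph(reads, k, min_kmer_count)
    candidates: Dict[str, CandidateMonomer] = {}
    for comp in _components(graph):
        if len(comp) < MIN_CYCLE_LEN:
            continue
        got = _best_cycle(comp, graph)
        if got is None:
            continue  # acyclic component: dispersed, non-tandem repeat
        mean_w, cycle = got
        seq = canonical_form(_spell(cycle, k))
        prev = candidates.get(seq)
        if prev is None or mean_w > prev.support:
            candidates[seq] = CandidateMonomer(sequence=seq, support=mean_w)
    return sorted(candidates.values(), key=lambda c: (-c.support, c.sequence))


# -- masking and the mining loop -------------------------------------------


def mask_reads(
    libraries: Dict[str, List[Tuple[str, str]]],
    monomers: Sequence[str],
    min_identity: float,
    min_read_coverage: float,
    read_length: int,
) -> Tuple[Dict[str, List[Tuple[str, str]]], Dict[int, Dict[str, int]]]:
    """Remove satellite-matching pairs from per-sex libraries.

    A read is masked when it (or, for boundary reads, one of its halves)
    aligns to some monomer's tandem reference at identity >= *min_identity*;
    a pair is dropped when either mate is masked.  Returns the kept libraries
    and the masked bp tally per monomer index per sex (best hit wins; ties go
    to the higher identity, then the lower monomer index).
    """
    if not monomers:
        raise ValueError("mask_reads requires a non-empty catalog")
    index = TandemIndex(monomers, read_length)
    kept: Dict[str, List[Tuple[str, str]]] = {}
    masked_bp: Dict[int, Dict[str, int]] = {
        i: {sex: 0 for sex in libraries} for i in range(len(monomers))
    }
    for sex, pairs in libraries.items():
        kept_pairs = []
        for pair in pairs:
            hit_any = False
            for seq in pair:
                hit = index.best_hit(seq, min_identity, min_read_coverage)
                if hit is not None:
                    masked_bp[hit.monomer_index][sex] += hit.masked_bp
                    hit_any = True
            if not hit_any:
                kept_pairs.append(pair)
        kept[sex] = kept_pairs
    return kept, masked_bp


def iterate_mining(
    male_pairs: List[Tuple[str, str]],
    female_pairs: List[Tuple[str, str]],
    config: RunConfig,
    rng: np.random.Generator,
) -> Tuple[List[CandidateMonomer], List[Dict]]:
    """Mine-mask-repeat until a round yields no novel satellite.

    Male and female libraries are mined jointly (the union of their
    subsamples feeds one k-mer graph) so both sexes' satellites enter a
    single catalog.  Returns the cumulative candidates annotated with the
    round that found them, plus a per-round report.
    """
    from .catalog import pairwise_identity

    libraries = {"male": list(male_pairs), "female": list(female_pairs)}
    if not libraries["male"] or not libraries["female"]:
        raise ValueError("both libraries must be non-empty after QC")
    catalog: List[CandidateMonomer] = []
    report: List[Dict] = []
    for round_no in range(1, config.max_rounds + 1):
        subs = [
            subsample_pairs(libraries[sex], config.subsample_pairs_discovery, rng)
            for sex in ("male", "female")
        ]
        reads = [seq for sub in subs for pair in sub for seq in pair]
        found = detect_monomers(reads, config.kmer_size, config.min_kmer_count)
        novel = [
            c
            for c in found
            if all(
                pairwise_identity(c.sequence, prev.sequence)
                < config.identity_thresholds.variant
                for prev in catalog
            )
        ]
        masked_pairs = 0
        if novel:
            for c in novel:
                c.round_found = round_no
            catalog.extend(novel)
            before = {sex: len(pairs) for sex, pairs in libraries.items()}
            libraries, _ = mask_reads(
                libraries,
                [c.sequence for c in novel],
                config.masking_min_identity,
                config.masking_min_read_coverage,
                config.read_length,
            )
            masked_pairs = sum(before[sex] - len(libraries[sex]) for sex in libraries)
        report.append(
            {"round": round_no, "candidates_found": len(novel), "pairs_masked": masked_pairs}
        )
        logger.info("round %d: %d novel candidates, %d pairs masked",
                    round_no, len(novel), masked_pairs)
        if not novel:
            break
    else:
        logger.warning("max_rounds=%d reached with novelty still appearing; "
                       "returning partial catalog", config.max_rounds)
    return catalog, report
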