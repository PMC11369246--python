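"""Haplotype extraction and minimum-spanning-tree networks for short monomers.

A read that fully spans one monomer copy carries a haplotype: the read
substring over a complete monomer window, re-phased to monomer coordinates so
identical variants observed at different read offsets collapse.  Reads with
indels against the monomer are excluded, which keeps all haplotypes the same
length and Hamming-comparable.  Haplotypes seen fewer than
``min_haplotype_count`` times in total (singletons, by default) are dropped
as likely sequencing errors.  The MST over Hamming distances then displays
the variant diversification of the family, with per-sex counts exposing
sex-linked haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from ._align import tandem_reference
from ._seq import encode, hamming, revcomp
from .config import RunConfig
from .discovery import subsample_pairs


@dataclass
class Haplotype:
    sequence: str
    count_male: int = 0
    count_female: int = 0

    @property
    def total(self) -> int:
        return self.count_male + self.count_female


@dataclass
class HaploNetwork:
    """Haplotypes of one monomer with their Hamming-distance MST."""

    monomer_name: str
    haplotypes: List[Haplotype]
    edges: List[Tuple[int, int, int]] = field(default_factory=list)  # complete graph
    tree: List[Tuple[int, int, int]] = field(default_factory=list)  # MST subset

    def validate(self) -> None:
        if not self.haplotypes:
            return
        length = len(self.haplotypes[0].sequence)
        assert all(len(h.sequence) == length for h in self.haplotypes), "ragged haplotypes"
        n = len(self.haplotypes)
        assert len(self.tree) == max(0, n - 1), "tree edge count wrong"
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((i, j) for i, j, _ in self.tree)
        assert nx.is_forest(g) and nx.is_connected(g), "tree not a spanning tree"

    @property
    def tree_weight(self) -> int:
        return sum(d for _, _, d in self.tree)


def _full_window(offset: int, read_len: int, m: int) -> Optional[int]:
    """Start (in target coords) of the first complete monomer window in the read."""
    t = -(-offset // m) * m  # first multiple of m at/after offset
    return t if t + m <= offset + read_len else None


def extract_haplotypes(
    male_pairs: Sequence[Tuple[str, str]],
    female_pairs: Sequence[Tuple[str, str]],
    monomer: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> List[Haplotype]:
    """Collapse full-monomer read windows into per-sex counted haplotypes.

    Each read is aligned to the monomer's tandem reference on both strands;
    reads aligning without indels at identity >=
    ``config.min_identity_for_extraction`` and covering at least one complete
    monomer window contribute the window substring, in monomer phase.
    """
    m = len(monomer)
    if m > config.mst_max_monomer_length:
        raise ValueError(
            f"monomer length {m} exceeds mst_max_monomer_length="
            f"{config.mst_max_monomer_length}"
        )
    target = tandem_reference(monomer, config.read_length)
    enc_target = encode(target)
    # exact k-mer prefilter: only reads sharing a seed can pass the identity cut
    seed_k = min(13, m)
    seeds = {
        s[i : i + seed_k]
        for s in (target, revcomp(target))
        for i in range(len(s) - seed_k + 1)
    }
    # gapless alignment: haplotype windows must be monomer-length, so a read
    # is placed at the phase offset minimising Hamming mismatches
    window_cache: Dict[int, np.ndarray] = {}

    def windows_for(length: int) -> np.ndarray:
        if length not in window_cache:
            window_cache[length] = np.lib.stride_tricks.sliding_window_view(
                enc_target, length
            )
        return window_cache[length]

    counts: Dict[str, List[int]] = {}
    for sex_idx, pairs in ((0, male_pairs), (1, female_pairs)):
        if not pairs:
            continue
        sub = subsample_pairs(pairs, config.subsample_pairs_haplonet, rng)
        for pair in sub:
            for seq in pair:
                if len(seq) < m or len(seq) > len(target):
                    continue
                if not any(
                    seq[i : i + seed_k] in seeds
                    for i in range(0, len(seq) - seed_k + 1, 4)
                ):
                    continue
                max_mm = int((1.0 - config.min_identity_for_extraction) * len(seq))
                best = None  # (mismatches, oriented_read, start)
                for oriented in (seq, revcomp(seq)):
                    mm = (windows_for(len(seq)) != encode(oriented)).sum(axis=1)
                    start = int(mm.argmin())
                    if mm[start] <= max_mm and (best is None or mm[start] < best[0]):
                        best = (int(mm[start]), oriented, start)
                if best is None:
                    continue
                _, oriented, start = best
                t = _full_window(start, len(oriented), m)
                if t is None:
                    continue
                hap = oriented[t - start : t - start + m]
                if "N" in hap:
                    continue
                counts.setdefault(hap, [0, 0])[sex_idx] += 1
    haps = [
        Haplotype(seq, c[0], c[1])
        for seq, c in counts.items()
        if c[0] + c[1] >= config.min_haplotype_count
    ]
    haps.sort(key=lambda h: (-h.total, h.sequence))
    return haps


def build_mst(haplotypes: Sequence[Haplotype], monomer_name: str = "") -> HaploNetwork:
    """MST over the complete Hamming-distance graph of the haplotypes.

    Kruskal with edges pre-sorted by (distance, endpoint pair) makes
    tie-breaking deterministic; total weight is minimal.
    """
    if not haplotypes:
        raise ValueError("build_mst requires at least one haplotype")
    n = len(haplotypes)
    edges = [
        (i, j, hamming(haplotypes[i].sequence, haplotypes[j].sequence))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, d in sorted(edges, key=lambda e: (e[2], e[0], e[1])):
        if not g.has_edge(i, j):
            g.add_edge(i, j, weight=d)
    mst = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    tree = sorted((min(i, j), max(i, j), g.edges[i, j]["weight"]) for i, j in mst.edges)
    net = HaploNetwork(monomer_name, list(haplotypes), edges, tree)
    net.validate()
    return net


def write_network(net: HaploNetwork, path: str | Path) -> None:
    """GraphML with per-node sequence and sex counts; tree edges only."""
    g = nx.Graph()
    g.graph["monomer"] = net.monomer_name
    for i, h in enumerate(net.haplotypes):
        g.add_node(i, sequence=h.sequence, count_male=h.count_male, count_female=h.count_female)
    for i, j, d in net.tree:
        g.add_edge(i, j, distance=d)
    nx.write_graphml(g, path)


def read_network(path: str | Path) -> HaploNetwork:
    """Read back a GraphML written by :func:`write_network`."""
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes, key=int)
    haps = [
        Haplotype(
            g.nodes[n]["sequence"],
            int(g.nodes[n]["count_male"]),
            int(g.nodes[n]["count_female"]),
        )
        for n in nodes
    ]
    tree = sorted(
        (min(int(a), int(b)), max(int(a), int(b)), int(g.edges[a, b]["distance"]))
        for a, b in g.edges
    )
    return HaploNetwork(g.graph.get("monomer", ""), haps, tree=tree)
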