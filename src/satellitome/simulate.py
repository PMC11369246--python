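"""Synthetic genomes and reads with planted satellite arrays.

The generator emulates the sequencing design the pipeline targets: one male
and one female genome sharing an identical autosomal background and identical
autosomal satellite arrays, with Y-linked arrays present only in the male;
from each genome, paired-end reads of fixed length with i.i.d. substitution
errors and Phred+33 qualities.

Arrays are uninterrupted head-to-tail tandem runs of a monomer, each copy
independently mutated by i.i.d. substitutions (no indels), so the planted bp
of every satellite — and hence its true abundance and M/F ratio — is exactly
computable.  Array segments overwrite background (genome length is preserved
exactly).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import kmer_codes, random_dna, rc_kmer_codes, revcomp
from .io import PHRED_OFFSET


@dataclass
class PlantedSatellite:
    """Ground-truth description of one planted satellite."""

    name: str
    monomer: str
    copies_autosomal: int = 0
    copies_y_linked: int = 0  # male genome only
    per_copy_divergence: float = 0.0  # expected substitutions/site in each copy
    family_seed_of: Optional[str] = None  # name of the satellite this was derived from

    def __post_init__(self) -> None:
        if len(self.monomer) < 6:
            raise ValueError(f"{self.name}: monomer shorter than 6 bp")
        if not 0.0 <= self.per_copy_divergence <= 0.3:
            raise ValueError(f"{self.name}: per_copy_divergence outside [0, 0.3]")
        if self.copies_autosomal < 0 or self.copies_y_linked < 0:
            raise ValueError(f"{self.name}: negative copy number")

    @property
    def planted_bp_male(self) -> int:
        return len(self.monomer) * (self.copies_autosomal + self.copies_y_linked)

    @property
    def planted_bp_female(self) -> int:
        return len(self.monomer) * self.copies_autosomal


@dataclass
class PlantedTruth:
    """Exact per-satellite abundances implied by the planted arrays."""

    satellites: List[PlantedSatellite]
    genome_length: int
    true_abundance: Dict[str, Tuple[float, float]]  # name -> (male, female) bp fraction
    true_mf_ratio: Dict[str, float]  # math.inf when female fraction is 0

    def to_json(self, path: str | Path) -> None:
        data = {
            "genome_length": self.genome_length,
            "satellites": [dataclasses.asdict(s) for s in self.satellites],
            "true_abundance": {k: list(v) for k, v in self.true_abundance.items()},
            "true_mf_ratio": {
                k: ("Inf" if math.isinf(v) else v) for k, v in self.true_mf_ratio.items()
            },
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            satellites=[PlantedSatellite(**s) for s in data["satellites"]],
            genome_length=data["genome_length"],
            true_abundance={k: tuple(v) for k, v in data["true_abundance"].items()},
            true_mf_ratio={
                k: (math.inf if v == "Inf" else v) for k, v in data["true_mf_ratio"].items()
            },
        )


@dataclass
class ReadSimParams:
    """Illumina-style paired-end read model."""

    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.01
    quality_model: str = "constant"  # "constant" | "two-state"
    two_state_tail: int = 10
    two_state_low_q: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate <= 0.05:
            raise ValueError("base_error_rate must lie in [0, 0.05]")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if self.quality_model not in ("constant", "two-state"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")

    @property
    def body_quality(self) -> int:
        if self.base_error_rate <= 0:
            return 40
        return int(min(40, max(2, round(-10 * math.log10(self.base_error_rate)))))


def _mutate_copy(monomer: str, divergence: float, rng: np.random.Generator) -> str:
    """One array copy: i.i.d. substitutions (always to a different base)."""
    if divergence <= 0:
        return monomer
    n = rng.binomial(len(monomer), divergence)
    if n == 0:
        return monomer
    pos = rng.choice(len(monomer), size=n, replace=False)
    out = list(monomer)
    for p in pos:
        out[p] = "ACGT".replace(out[p], "")[rng.integers(3)]
    return "".join(out)


def _build_array(sat: PlantedSatellite, copies: int, rng: np.random.Generator) -> str:
    return "".join(_mutate_copy(sat.monomer, sat.per_copy_divergence, rng) for _ in range(copies))


def _kmer_set(seq: str, k: int) -> set:
    both = seq + "NN" + revcomp(seq)
    return {both[i : i + k] for i in range(len(both) - k + 1) if "N" not in both[i : i + k]}


def build_genomes(
    satellites: Sequence[PlantedSatellite],
    genome_length: int,
    gc_background: float = 0.45,
    seed: int | np.random.Generator = 0,
    screen_k: int = 21,
    max_placement_tries: int = 1000,
) -> Tuple[str, str, PlantedTruth]:
    """Male and female genome sequences plus exact planted truth.

    Both sexes share the background and autosomal arrays (identical copies at
    identical positions); Y-linked arrays overwrite background in the male
    genome only.  Background windows that share a *screen_k*-mer with any
    monomer are re-drawn so that discovery cannot be seeded by chance
    background collisions.
    """
    names = [s.name for s in satellites]
    if len(set(names)) != len(names):
        raise ValueError("duplicate satellite names")
    planted = sum(s.planted_bp_male for s in satellites)
    if planted >= genome_length / 2:
        raise ValueError(
            f"planted bp ({planted}) must stay below half the genome length ({genome_length})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bg = random_dna(genome_length, rng, gc=gc_background)
    mono_codes: List[np.ndarray] = []
    for s in satellites:
        tandem = s.monomer + s.monomer[: screen_k - 1]  # cover the junction
        for fn in (kmer_codes, rc_kmer_codes):
            mono_codes.append(fn(tandem, screen_k)[0])
    mono_sorted = np.unique(np.concatenate(mono_codes)) if mono_codes else np.empty(0, np.uint64)
    background = list(bg)
    if mono_sorted.size:
        codes, valid = kmer_codes(bg, screen_k)
        hits = np.flatnonzero(np.isin(codes, mono_sorted) & valid)
        for i in hits:  # vanishingly rare; redraw the colliding window
            for j in range(i, i + screen_k):
                background[j] = "ACGT"[rng.integers(4)]

    # place arrays without overlap; female shares autosomal placements
    occupied: List[Tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(max_placement_tries):
            start = int(rng.integers(0, genome_length - length))
            if all(start + length <= a or start >= b for a, b in occupied):
                occupied.append((start, start + length))
                return start
        raise RuntimeError(
            "could not place array after bounded retries; increase genome_length"
        )

    male = background.copy()
    female = background.copy()
    for sat in satellites:
        for copies, male_only in ((sat.copies_autosomal, False), (sat.copies_y_linked, True)):
            if copies == 0:
                continue
            array = _build_array(sat, copies, rng)
            if rng.random() < 0.5:
                array = revcomp(array)
            start = place(len(array))
            male[start : start + len(array)] = array
            if not male_only:
                female[start : start + len(array)] = array

    abundance = {
        s.name: (s.planted_bp_male / genome_length, s.planted_bp_female / genome_length)
        for s in satellites
    }
    mf = {
        name: (m / f if f > 0 else (math.inf if m > 0 else 0.0))
        for name, (m, f) in abundance.items()
    }
    truth = PlantedTruth(list(satellites), genome_length, abundance, mf)
    return "".join(male), "".join(female), truth


def simulate_read_pairs(
    genome: str,
    params: ReadSimParams,
    n_pairs: int,
    sex_label: str,
    seed: int | np.random.Generator = 0,
    with_coords: bool = False,
):
    """Yield (id, r1_seq, r1_qual, r2_seq, r2_qual) for *n_pairs* fragments.

    With ``with_coords=True`` each tuple gains a trailing ``(start, frag_len,
    flipped)`` element giving the fragment's source coordinates.

    Fragment lengths are normal(mean, sd), rounded and clamped to
    [read_length, genome length]; mate 1 is the 5' read of the fragment on a
    uniformly random strand and mate 2 the reverse complement of the other
    end.  Substitution errors are i.i.d. at ``base_error_rate``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not genome:
        raise ValueError("genome is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G, R = len(genome), params.read_length
    if G < R:
        raise ValueError("genome shorter than read length")

    frags = np.clip(
        np.rint(rng.normal(params.fragment_mean, params.fragment_sd, size=n_pairs)),
        R, G,
    ).astype(np.int64)
    starts = (rng.random(n_pairs) * (G - frags + 1)).astype(np.int64)
    flips = rng.random(n_pairs) < 0.5
    nerr = (
        rng.binomial(R, params.base_error_rate, size=(n_pairs, 2))
        if params.base_error_rate > 0
        else np.zeros((n_pairs, 2), dtype=np.int64)
    )

    quals = _qualities(params)

    def add_errors(seq: str, k: int) -> str:
        if k == 0:
            return seq
        pos = rng.choice(R, size=k, replace=False)
        out = list(seq)
        for p in pos:
            out[p] = "ACGT".replace(out[p], "")[rng.integers(3)]
        return "".join(out)

    for i in range(n_pairs):
        frag = genome[starts[i] : starts[i] + frags[i]]
        # R1 reads 5'->3' from one fragment end, R2 from the other end on the
        # opposite strand; the sequenced strand is chosen uniformly.
        if flips[i]:
            r1, r2 = revcomp(frag[-R:]), frag[:R]
        else:
            r1, r2 = frag[:R], revcomp(frag[-R:])
        out = (
            f"{sex_label}_{i}",
            add_errors(r1, int(nerr[i, 0])), quals,
            add_errors(r2, int(nerr[i, 1])), quals,
        )
        if with_coords:
            out = out + ((int(starts[i]), int(frags[i]), bool(flips[i])),)
        yield out


def _qualities(params: ReadSimParams) -> List[int]:
    q = [params.body_quality] * params.read_length
    if params.quality_model == "two-state":
        tail = min(params.two_state_tail, params.read_length)
        for i in range(params.read_length - tail, params.read_length):
            q[i] = params.two_state_low_q
    return q


def write_read_pairs(
    genome: str,
    params: ReadSimParams,
    n_pairs: int,
    sex_label: str,
    seed: int | np.random.Generator,
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Simulate reads and write them to two Phred+33 FASTQ files (R1/R2)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, s1, q1, s2, q2 in simulate_read_pairs(genome, params, n_pairs, sex_label, seed):
            qs1 = "".join(chr(q + PHRED_OFFSET) for q in q1)
            qs2 = "".join(chr(q + PHRED_OFFSET) for q in q2)
            f1.write(f"@{rid}/1\n{s1}\n+\n{qs1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{qs2}\n")


def coverage_pairs(genome_length: int, coverage: float, read_length: int) -> int:
    """Number of read pairs giving *coverage*-fold coverage of the genome."""
    return max(1, int(round(coverage * genome_length / (2 * read_length))))


def default_panel(
    rng: np.random.Generator,
    genome_length: int = 2_000_000,
    name_prefix: str = "planted",
) -> List[PlantedSatellite]:
    """The study-condition satellite panel used throughout the test suite.

    Ten satellites spanning female abundances 5% down to 0.1%, monomer lengths
    20-300 bp and per-copy divergences up to 2%; one satellite carries a
    Y-linked accumulation giving a true male/female bp ratio of 3, the rest
    are unbiased.  Monomers are random sequences kept mutually dissimilar
    (pairwise identity < 0.5 and no shared 21-mers).
    """
    from .catalog import pairwise_identity

    abundances = [0.05, 0.03, 0.02, 0.012, 0.008, 0.005, 0.003, 0.002, 0.0015, 0.001]
    lengths = [150, 300, 50, 230, 20, 110, 270, 35, 190, 80]
    divergences = [0.02, 0.015, 0.01, 0.02, 0.005, 0.015, 0.0, 0.01, 0.02, 0.005]
    y_biased_index = 3  # true M/F = 3 via copies_y = 2 x copies_autosomal

    monomers: List[str] = []
    for L in lengths:
        for _ in range(100):
            cand = random_dna(L, rng)
            if all(pairwise_identity(cand, m) < 0.5 for m in monomers) and not any(
                _kmer_set(cand, 21) & _kmer_set(m, 21) for m in monomers
            ):
                monomers.append(cand)
                break
        else:  # pragma: no cover - random 20+-mers virtually never collide 100x
            raise RuntimeError("could not draw a dissimilar monomer")

    panel = []
    for i, (ab, L, div) in enumerate(zip(abundances, lengths, divergences)):
        copies = max(1, round(ab * genome_length / L))
        y_copies = 2 * copies if i == y_biased_index else 0
        panel.append(
            PlantedSatellite(
                name=f"{name_prefix}{i + 1:02d}",
                monomer=monomers[i],
                copies_autosomal=copies,
                copies_y_linked=y_copies,
                per_copy_divergence=div,
            )
        )
    return panel
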