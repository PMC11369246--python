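"""Discovery: QC, subsampling, k-mer cycle detection, masking, mining loop."""

import numpy as np
import pytest

from satellitome import (
    PlantedSatellite,
    QCParams,
    ReadRecord,
    RunConfig,
    build_genomes,
    detect_monomers,
    iterate_mining,
    pairwise_identity,
    qc_filter,
    subsample_pairs,
)
from satellitome._seq import random_dna, revcomp
from satellitome.discovery import mask_reads
from satellitome.simulate import ReadSimParams, coverage_pairs, simulate_read_pairs


def _rec(seq, quals, rid="r", mate=1):
    return ReadRecord(rid, mate, seq, quals, "male")


def _pair(seq1, q1, seq2=None, q2=None):
    return (
        _rec(seq1, q1, "a", 1),
        _rec(seq2 or seq1, q2 or q1, "a", 2),
    )


def _tiled_reads(array, read_len=100, step=7):
    return [array[i : i + read_len] for i in range(0, len(array) - read_len, step)]


class TestQcFilter:
    def test_clean_pair_retained(self):
        pairs = [_pair("ACGT", [40] * 4)]
        assert len(list(qc_filter(pairs, QCParams(20)))) == 1

    def test_one_low_base_drops_both_mates(self):
        pairs = [_pair("ACGT", [40, 40, 10, 40], "ACGT", [40] * 4)]
        assert list(qc_filter(pairs, QCParams(20))) == []

    def test_n_base_drops_pair(self):
        pairs = [_pair("ACNT", [40] * 4)]
        assert list(qc_filter(pairs, QCParams(20))) == []

    def test_count_matches_bruteforce(self, rng):
        # plant one low-Q base in ~10% of reads; retained = pairs with both clean
        pairs, clean = [], 0
        for i in range(300):
            quals = [[40] * 20, [40] * 20]
            dirty = False
            for q in quals:
                if rng.random() < 0.1:
                    q[int(rng.integers(20))] = 10
                    dirty = True
            clean += not dirty
            pairs.append(_pair(random_dna(20, rng), quals[0], random_dna(20, rng), quals[1]))
        assert len(list(qc_filter(pairs, QCParams(20)))) == clean


class TestSubsample:
    def test_identity_when_requesting_all(self, rng):
        pairs = [("A" * 10, "C" * 10)] * 6
        assert subsample_pairs(pairs, 6, rng) == pairs
        assert subsample_pairs(pairs, 10, rng) == pairs

    def test_seeded_reproducibility(self):
        pairs = [(str(i), str(i)) for i in range(100)]
        a = subsample_pairs(pairs, 10, np.random.default_rng(3))
        b = subsample_pairs(pairs, 10, np.random.default_rng(3))
        assert a == b

    def test_inclusion_frequency_uniform(self):
        # Monte-Carlo: sampling half of 10 pairs, a fixed pair appears ~50%
        pairs = [(str(i), str(i)) for i in range(10)]
        rng = np.random.default_rng(0)
        hits = sum(
            ("0", "0") in subsample_pairs(pairs, 5, rng) for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            subsample_pairs([], 5, rng)


class TestDetectMonomers:
    def test_pure_tandem_yields_single_cycle_monomer(self, rng):
        # the k-mer graph of a pure tandem repeat is one simple cycle of
        # length |monomer|, so exactly one candidate, rotation/strand-equivalent
        monomer = random_dna(40, rng)
        reads = _tiled_reads(monomer * 30)
        cands = detect_monomers(reads, k=15, min_kmer_count=5)
        assert len(cands) == 1
        assert len(cands[0].sequence) == 40
        assert pairwise_identity(cands[0].sequence, monomer) == 1.0

    def test_monomer_shorter_than_k(self, rng):
        # a tandem of period m < k still forms a cycle with m nodes
        monomer = random_dna(12, rng)
        reads = _tiled_reads(monomer * 60)
        cands = detect_monomers(reads, k=15, min_kmer_count=5)
        assert len(cands) == 1
        assert len(cands[0].sequence) == 12
        assert pairwise_identity(cands[0].sequence, monomer) == 1.0

    def test_random_genome_low_coverage_yields_nothing(self, rng):
        genome = random_dna(20_000, rng)
        reads = [genome[i : i + 100] for i in range(0, len(genome) - 100, 100)]  # ~1x
        assert detect_monomers(reads, k=15, min_kmer_count=5) == []

    def test_two_distant_satellites_give_two_candidates(self, rng):
        a = random_dna(60, rng)
        b = list(a)
        for p in rng.choice(60, size=24, replace=False):  # 60% identity
            b[p] = "ACGT".replace(b[p], "")[rng.integers(3)]
        b = "".join(b)
        reads = _tiled_reads(a * 25) + _tiled_reads(b * 25)
        cands = detect_monomers(reads, k=15, min_kmer_count=5)
        assert len(cands) == 2
        best_a = max(pairwise_identity(c.sequence, a) for c in cands)
        best_b = max(pairwise_identity(c.sequence, b) for c in cands)
        assert best_a == 1.0 and best_b == 1.0

    def test_reverse_complement_reads_collapse(self, rng):
        monomer = random_dna(40, rng)
        reads = _tiled_reads(monomer * 30)
        reads_rc = [revcomp(r) for r in reads]
        cands = detect_monomers(reads + reads_rc, k=15, min_kmer_count=5)
        assert len(cands) == 1

    def test_empty_subsample_rejected(self):
        with pytest.raises(ValueError):
            detect_monomers([], k=15, min_kmer_count=5)


class TestMaskReads:
    def test_exact_substring_masked_fully(self, rng):
        monomer = random_dna(80, rng)
        read = (monomer * 3)[10:110]
        libs = {"male": [(read, read)], "female": []}
        kept, bp = mask_reads(libs, [monomer], 0.8, 0.5, 100)
        assert kept["male"] == []
        assert bp[0]["male"] == 200  # both mates fully credited

    def test_diverged_read_retained(self, rng):
        monomer = random_dna(100, rng)
        read = list(monomer)
        for p in rng.choice(100, size=30, replace=False):  # ~0.70 identity
            read[p] = "ACGT".replace(read[p], "")[rng.integers(3)]
        read = "".join(read)
        libs = {"male": [(read, read)], "female": []}
        kept, bp = mask_reads(libs, [monomer], 0.8, 0.5, 100)
        assert len(kept["male"]) == 1
        assert bp[0]["male"] == 0

    def test_masked_fraction_matches_planted(self, rng):
        # genome 1% satellite by bp, error-free reads
        monomer = random_dna(100, rng)
        sat = PlantedSatellite(name="s", monomer=monomer, copies_autosomal=50)
        male, _, truth = build_genomes([sat], 500_000, seed=8)
        params = ReadSimParams(read_length=150, fragment_mean=300, base_error_rate=0.0)
        n = coverage_pairs(len(male), 8.0, 150)
        pairs = [(s1, s2) for _, s1, _, s2, _ in simulate_read_pairs(male, params, n, "m", 8)]
        libs = {"male": pairs, "female": []}
        _, bp = mask_reads(libs, [monomer], 0.8, 0.5, 150)
        frac = bp[0]["male"] / (n * 300)
        assert frac == pytest.approx(truth.true_abundance["s"][0], abs=0.002)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            mask_reads({"male": []}, [], 0.8, 0.5, 150)


def _sim_libraries(satellites, genome_length, coverage, seed, error=0.0):
    male_g, female_g, truth = build_genomes(satellites, genome_length, seed=seed)
    params = ReadSimParams(read_length=150, fragment_mean=300, base_error_rate=error)
    n = coverage_pairs(genome_length, coverage, 150)
    libs = {}
    for sex, g in (("male", male_g), ("female", female_g)):
        libs[sex] = [
            (s1, s2) for _, s1, _, s2, _ in simulate_read_pairs(g, params, n, sex, seed + 1)
        ]
    return libs, truth


class TestIterateMining:
    def test_single_satellite_terminates_in_two_rounds(self, rng):
        sat = PlantedSatellite(
            name="s", monomer=random_dna(200, rng), copies_autosomal=25
        )  # 5% of 100 kb
        libs, _ = _sim_libraries([sat], 100_000, 8.0, seed=4)
        config = RunConfig(seed=4)
        cands, report = iterate_mining(libs["male"], libs["female"], config,
                                       np.random.default_rng(4))
        assert len(report) == 2
        assert report[0]["candidates_found"] >= 1
        assert report[1]["candidates_found"] == 0
        assert max(pairwise_identity(c.sequence, sat.monomer) for c in cands) >= 0.95
        # masked-library monotonicity shows up as masked pairs in round 1 only
        assert report[0]["pairs_masked"] > 0

    def test_satellite_free_genome_terminates_empty(self, rng):
        libs, _ = _sim_libraries([], 80_000, 6.0, seed=5)
        config = RunConfig(seed=5)
        cands, report = iterate_mining(libs["male"], libs["female"], config,
                                       np.random.default_rng(5))
        assert cands == []
        assert len(report) == 1

    def test_determinism(self, rng):
        sat = PlantedSatellite(name="s", monomer=random_dna(120, rng), copies_autosomal=30)
        libs, _ = _sim_libraries([sat], 100_000, 8.0, seed=6, error=0.01)
        config = RunConfig(seed=6)
        a, _ = iterate_mining(libs["male"], libs["female"], config, np.random.default_rng(6))
        b, _ = iterate_mining(libs["male"], libs["female"], config, np.random.default_rng(6))
        assert [(c.sequence, c.round_found) for c in a] == [
            (c.sequence, c.round_found) for c in b
        ]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            iterate_mining([], [("A" * 150, "C" * 150)], RunConfig(), np.random.default_rng(0))
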