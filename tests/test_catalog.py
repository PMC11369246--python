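"""Canonical forms, rotation/strand-aware identity, homology partition, naming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satellitome import (
    IdentityThresholds,
    SatMonomer,
    build_partition,
    canonical_form,
    dedupe_candidates,
    finalize_catalog,
    pairwise_identity,
)
from satellitome._seq import random_dna, revcomp, rotate

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _mutate(seq, nsub, rng):
    pos = rng.choice(len(seq), size=nsub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT".replace(out[p], "")[rng.integers(3)]
    return "".join(out)


class TestCanonicalForm:
    def test_hand_enumerable_example(self):
        # min over {GAT,ATG,TGA} u {ATC,TCA,CAT} = ATC
        assert canonical_form("GAT") == "ATC"

    def test_identity_on_homopolymer(self):
        assert canonical_form("AAAA") == "AAAA"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            canonical_form("ACGN")
        with pytest.raises(ValueError):
            canonical_form("")

    def test_rotation_strand_invariance_bruteforce(self, rng):
        s = random_dna(200, rng)
        expected = canonical_form(s)
        for r in range(0, 200, 17):
            assert canonical_form(rotate(s, r)) == expected
            assert canonical_form(revcomp(rotate(s, r))) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(dna, st.integers(0, 59))
    def test_rotation_strand_invariance_property(self, s, r):
        assert canonical_form(rotate(s, r % len(s))) == canonical_form(s)
        assert canonical_form(revcomp(s)) == canonical_form(s)

    def test_canonical_is_a_rotation_of_input_or_revcomp(self, rng):
        s = random_dna(37, rng)
        c = canonical_form(s)
        assert c in (s + s) or c in (revcomp(s) + revcomp(s))


class TestPairwiseIdentity:
    def test_identical(self, rng):
        s = random_dna(120, rng)
        assert pairwise_identity(s, s) == 1.0

    def test_rotated_copy(self, rng):
        s = random_dna(120, rng)
        assert pairwise_identity(s, rotate(s, 31)) == 1.0
        assert pairwise_identity(s, revcomp(rotate(s, 77))) == 1.0

    def test_ten_substitutions_give_090(self, rng):
        # constructed identity verified independently by direct mismatch count
        s = random_dna(100, rng)
        t = _mutate(s, 10, rng)
        direct = sum(a == b for a, b in zip(s, t)) / 100
        assert direct == 0.90
        assert pairwise_identity(s, t) == pytest.approx(0.90, abs=0.01)
        assert pairwise_identity(s, rotate(t, 40)) == pytest.approx(0.90, abs=0.01)

    def test_symmetry(self, rng):
        a, b = random_dna(90, rng), random_dna(110, rng)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_unrelated_sequences_below_superfamily_tier(self, rng):
        vals = [
            pairwise_identity(random_dna(100, rng), random_dna(100, rng))
            for _ in range(20)
        ]
        assert max(vals) < 0.5

    def test_short_inside_long_not_promoted(self, rng):
        long = random_dna(400, rng)
        short = long[50:90]  # perfect 40-mer substring
        assert pairwise_identity(short, long) <= 0.1


class TestBuildPartition:
    def _monomers(self, seqs, abundances=None):
        ab = abundances or [0.01] * len(seqs)
        return [
            SatMonomer.from_sequence(f"M{i:02d}", s, abundance_male=a, abundance_female=a)
            for i, (s, a) in enumerate(zip(seqs, ab), start=1)
        ]

    def test_single_linkage_chains_variants(self, rng):
        # AB=0.97, BC=0.97, AC=0.94: one variant group by connectivity
        a = random_dna(100, rng)
        pos = rng.choice(100, size=6, replace=False)
        b = _mutate_at(a, pos[:3], rng)
        c = _mutate_at(b, pos[3:], rng)
        ms = self._monomers([a, b, c])
        part = build_partition(ms)
        assert sorted(map(sorted, part.variant_groups)) == [sorted(m.name for m in ms)]

    def test_family_but_not_variant(self, rng):
        a = random_dna(100, rng)
        b = _mutate(a, 15, rng)  # 85% identity
        part = build_partition(self._monomers([a, b]))
        assert len(part.variant_groups) == 2
        assert len(part.family_groups) == 1
        assert len(part.superfamily_groups) == 1

    def test_unrelated_in_separate_superfamilies(self, rng):
        a = random_dna(100, rng)
        b = _mutate(a, 60, rng)  # ~40% identity
        part = build_partition(self._monomers([a, b]))
        assert len(part.superfamily_groups) == 2

    def test_superfamily_labels_by_abundance(self, rng):
        a, b = random_dna(100, rng), random_dna(100, rng)
        ms = self._monomers([a, b], abundances=[0.001, 0.05])
        part = build_partition(ms)
        assert part.superfamily_labels[ms[1].name] == "SF1"
        assert part.superfamily_labels[ms[0].name] == "SF2"

    def test_input_order_independence(self, rng):
        seqs = [random_dna(80, rng) for _ in range(4)]
        seqs.append(_mutate(seqs[0], 10, rng))
        ms = self._monomers(seqs)
        p1 = build_partition(ms)
        p2 = build_partition(ms[::-1])
        assert sorted(map(sorted, p1.family_groups)) == sorted(map(sorted, p2.family_groups))

    def test_nesting_validated(self, rng):
        seqs = [random_dna(70, rng) for _ in range(3)]
        part = build_partition(self._monomers(seqs))
        part.validate()  # raises on violation


def _mutate_at(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = "ACGT".replace(out[p], "")[rng.integers(3)]
    return "".join(out)


class TestFinalizeCatalog:
    def test_rotation_equivalent_candidates_merge(self, rng):
        s = random_dna(60, rng)
        kept = dedupe_candidates([s, rotate(s, 13), revcomp(s)], [3.0, 2.0, 1.0])
        assert len(kept) == 1
        assert kept[0][1] == 3.0  # higher-support consensus wins

    def test_naming_by_decreasing_abundance(self, rng):
        a, b = random_dna(50, rng), random_dna(70, rng)
        ca, cb = canonical_form(a), canonical_form(b)
        monomers, _ = finalize_catalog(
            [a, b], {ca: (0.01, 0.01), cb: (0.03, 0.03)}, name_prefix="Sat"
        )
        assert monomers[0].name == "Sat01" and monomers[0].sequence == cb
        assert monomers[1].name == "Sat02" and monomers[1].sequence == ca

    def test_descriptors_self_consistent(self, rng):
        s = random_dna(90, rng)
        monomers, _ = finalize_catalog([s], {canonical_form(s): (0.0, 0.002)})
        m = monomers[0]
        assert m.rul == len(m.sequence) == 90
        assert m.at_fraction == (m.sequence.count("A") + m.sequence.count("T")) / 90
        assert m.mf_ratio == 0.0 or m.mf_ratio is None or m.mf_ratio >= 0

    def test_mf_infinite_flag(self, rng):
        s = random_dna(40, rng)
        monomers, _ = finalize_catalog([s], {canonical_form(s): (0.004, 0.0)})
        assert np.isinf(monomers[0].mf_ratio)

    def test_empty_catalog(self):
        monomers, part = finalize_catalog([], {})
        assert monomers == [] and part.variant_groups == []
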