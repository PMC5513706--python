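"""Anchor matching, spacer extraction, and dereplication."""

import numpy as np
import pytest

from spacerkit import (
    ArrayDefinition,
    PLATENSIS_IIIB,
    PLATENSIS_IIID,
    dereplicate,
    extract_pool,
    extract_spacer,
    iupac_mismatches,
)
from spacerkit._seq import IUPAC_CODES, revcomp
from spacerkit.extraction import rank_key
from spacerkit.synthetic import mutate_spacer

from conftest import oracle_dereplicate, random_dna


class TestIupacMismatches:
    @pytest.mark.parametrize(
        "pattern,text,expected",
        [
            ("ACGT", "ACGT", 0),
            ("R", "A", 0),
            ("R", "G", 0),
            ("R", "C", 1),
            ("N", "T", 0),
            # SS-19F repeat region vs one concrete resolution of it
            ("TAACTTTCARAGAAGTYTAA", "TAACTTTCAGAGAAGTCTAA", 0),
            ("TAACTTTCARAGAAGTYTAA", "TAACTTTCAAAGAAGTTTAA", 0),
        ],
    )
    def test_examples(self, pattern, text, expected):
        assert iupac_mismatches(pattern, text) == expected

    def test_matches_per_position_set_membership(self, rng):
        """Agreement with a direct per-position IUPAC-table check."""
        codes = list(IUPAC_CODES)
        for _ in range(50):
            L = int(rng.integers(1, 30))
            pattern = "".join(codes[i] for i in rng.integers(0, len(codes), L))
            text = random_dna(rng, L)
            expected = sum(
                t not in IUPAC_CODES[p] for p, t in zip(pattern, text)
            )
            assert iupac_mismatches(pattern, text) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iupac_mismatches("ACGT", "ACG")


def _make_read(adef, spacer, rng, tail=5, read_len=150):
    from spacerkit.synthetic import _resolve_iupac

    body = (
        random_dna(rng, tail)
        + _resolve_iupac(adef.forward_anchor, rng)
        + spacer
        + _resolve_iupac(adef.reverse_anchor, rng)
    )
    body += random_dna(rng, max(0, read_len - len(body)))
    return body


class TestExtractSpacer:
    def test_error_free_layout(self, rng):
        spacer = random_dna(rng, 40)
        read = _make_read(PLATENSIS_IIID, spacer, rng)
        assert extract_spacer(read, PLATENSIS_IIID) == (spacer, "+")

    def test_anchor_mismatch_budget(self, rng):
        """Two substitutions in the forward anchor are tolerated, three are not."""
        spacer = random_dna(rng, 40)
        adef = PLATENSIS_IIID
        anchor = adef.forward_anchor
        for n_sub, expected in [(2, (spacer, "+")), (3, None)]:
            bad = mutate_spacer(anchor, n_sub, seed=1)
            read = random_dna(rng, 5) + bad + spacer + adef.reverse_anchor
            read += random_dna(rng, 150 - len(read))
            assert extract_spacer(read, adef) == expected

    def test_reverse_complement_read(self, rng):
        """RC of a plus read yields the same spacer in array orientation, '-'."""
        spacer = random_dna(rng, 40)
        read = _make_read(PLATENSIS_IIID, spacer, rng)
        assert extract_spacer(revcomp(read), PLATENSIS_IIID) == (spacer, "-")

    def test_strand_symmetry_oracle(self, rng):
        """Re-running on the reverse-complemented read swaps the strand and
        nothing else, for every extractable read."""
        for _ in range(25):
            spacer = random_dna(rng, int(rng.integers(25, 61)))
            adef = PLATENSIS_IIIB if rng.random() < 0.5 else PLATENSIS_IIID
            read = _make_read(adef, spacer, rng)
            fwd = extract_spacer(read, adef)
            rev = extract_spacer(revcomp(read), adef)
            assert fwd is not None and rev is not None
            assert fwd[0] == rev[0]
            assert {fwd[1], rev[1]} == {"+", "-"}

    def test_spacer_length_bounds_enforced(self, rng):
        spacer = random_dna(rng, 10)  # below the 25 nt minimum
        read = _make_read(PLATENSIS_IIID, spacer, rng)
        assert extract_spacer(read, PLATENSIS_IIID) is None

    def test_degenerate_anchor_resolutions_all_match(self, rng):
        """Any concrete resolution of a degenerate anchor is a 0-mismatch hit."""
        spacer = random_dna(rng, 36)
        for _ in range(10):
            read = _make_read(PLATENSIS_IIIB, spacer, rng)
            assert extract_spacer(read, PLATENSIS_IIIB) == (spacer, "+")


class TestDereplicate:
    def test_exact_duplicates(self):
        pool = dereplicate(["ACGT" * 10] * 3, merge_mismatches=0)
        assert pool.n_unique == 1
        assert pool.records[0].count == 3

    def test_single_mismatch_merge(self):
        """Sequences one substitution apart count as the same spacer."""
        raw = ["AAAA" * 7] * 5 + ["AAAT" + "AAAA" * 6] * 1
        pool = dereplicate(raw, merge_mismatches=1)
        assert pool.n_unique == 1
        rec = pool.records[0]
        assert rec.sequence == "AAAA" * 7 and rec.count == 6

    def test_zero_mismatch_no_merge(self):
        raw = ["AAAA" * 7] * 5 + ["AAAT" + "AAAA" * 6] * 1
        pool = dereplicate(raw, merge_mismatches=0)
        assert pool.n_unique == 2

    def test_empty_input(self):
        pool = dereplicate([], merge_mismatches=1)
        assert pool.n_unique == 0 and pool.total_reads_in == 0

    def test_length_variants_not_merged(self):
        pool = dereplicate(["A" * 40, "A" * 39], merge_mismatches=2)
        assert pool.n_unique == 2

    @pytest.mark.parametrize("m", [1, 2])
    def test_against_all_pairs_oracle(self, rng, m):
        """Pool equals the output of the brute-force all-pairs merge."""
        base = [random_dna(rng, 40) for _ in range(50)]
        raw = []
        for s in base:
            raw += [s] * int(rng.integers(1, 6))
        for _ in range(10):  # satellites one substitution away
            parent = base[int(rng.integers(len(base)))]
            raw.append(mutate_spacer(parent, 1, seed=int(rng.integers(2**31))))
        order = rng.permutation(len(raw))
        raw = [raw[i] for i in order]
        pool = dereplicate(raw, merge_mismatches=m)
        expected = oracle_dereplicate(raw, m)
        assert {r.sequence: r.count for r in pool.records} == expected

    def test_strand_majority(self):
        pool = dereplicate([("ACGT" * 8, "-"), ("ACGT" * 8, "-"), ("ACGT" * 8, "+")])
        assert pool.records[0].strand == "-"


class TestExtractPool:
    def test_read_conservation_and_rejection(self, rng):
        """extracted + rejected == total; junk reads are rejected, not dropped."""
        spacers = [random_dna(rng, 40) for _ in range(5)]
        reads = [_make_read(PLATENSIS_IIID, s, rng) for s in spacers for _ in range(3)]
        junk = [random_dna(rng, 150) for _ in range(4)]
        pool = extract_pool(reads + junk, PLATENSIS_IIID)
        assert pool.total_reads_in == len(reads) + len(junk)
        assert pool.reads_extracted == len(reads)
        assert pool.reads_rejected == len(junk)
        assert sum(r.count for r in pool.records) == pool.reads_extracted

    def test_round_trip_error_free(self, rng):
        """Extraction + dereplication reproduces the embedded spacer multiset."""
        spacers = {random_dna(rng, int(rng.integers(25, 61))): int(rng.integers(1, 8))
                   for _ in range(20)}
        reads = []
        for s, c in spacers.items():
            reads += [_make_read(PLATENSIS_IIID, s, rng) for _ in range(c)]
        pool = extract_pool(reads, PLATENSIS_IIID)
        assert {r.sequence: r.count for r in pool.records} == spacers

    def test_global_reverse_complement_swaps_strands(self, rng):
        spacers = [random_dna(rng, 40) for _ in range(10)]
        reads = [_make_read(PLATENSIS_IIID, s, rng) for s in spacers]
        fwd = extract_pool(reads, PLATENSIS_IIID)
        rev = extract_pool([revcomp(r) for r in reads], PLATENSIS_IIID)
        assert {r.sequence: r.count for r in fwd.records} == {
            r.sequence: r.count for r in rev.records
        }
        flip = {"+": "-", "-": "+"}
        fwd_strands = {r.sequence: r.strand for r in fwd.records}
        rev_strands = {r.sequence: r.strand for r in rev.records}
        assert rev_strands == {s: flip[st] for s, st in fwd_strands.items()}


def test_rank_key_total_order():
    """Ranking orders by count desc, then length desc, then sequence."""
    from spacerkit.extraction import SpacerRecord

    a = SpacerRecord("AAA", 5)
    b = SpacerRecord("CCCC", 5)
    c = SpacerRecord("AAAA", 5)
    d = SpacerRecord("TT", 9)
    assert sorted([a, b, c, d], key=rank_key) == [d, c, b, a]


def test_array_definition_validation():
    with pytest.raises(ValueError):
        ArrayDefinition("X", "ACGX", "ACGT")
    with pytest.raises(ValueError):
        ArrayDefinition("X", "ACGT", "ACGT", max_anchor_mismatches=-1)
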