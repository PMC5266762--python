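import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bf_scan
from cladeprimer.alphabet import InvalidSymbolError, revcomp
from cladeprimer.io import NucleotideSequence
from cladeprimer.primers import (
    Primer,
    base_match,
    count_mismatches,
    primer_properties,
    read_primer_table,
    scan_binding_sites,
    wallace_tm,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "p,t,expected",
    [
        ("M", "A", True),
        ("R", "C", False),
        ("N", "A", True),
        ("N", "N", True),
        ("W", "S", False),  # disjoint two-base sets
        ("B", "A", False),
        ("Y", "Y", True),
    ],
)
def test_base_match_is_set_intersection(p, t, expected):
    assert base_match(p, t) is expected


def test_base_match_rejects_invalid_symbols():
    with pytest.raises(InvalidSymbolError):
        base_match("X", "A")


def test_count_mismatches_examples():
    assert count_mismatches(Primer("p", "ACGT", "forward"), "ACGT") == (0, [])
    assert count_mismatches(Primer("p", "ACRT", "forward"), "ACTT") == (1, [3])
    with pytest.raises(ValueError):
        count_mismatches(Primer("p", "ACGT", "forward"), "ACGTA")


def test_primer_properties_expected_gc_and_degeneracy():
    # degenerate positions M, R, Y, W each double the encoded-oligo count
    props = primer_properties(Primer("ML-F", "GGTGGTGTMGGATTCACACARTAYGCWACAGC", "forward"))
    assert props.degeneracy == 16
    # S is always G/C, W never; expected GC of "SW" is 50%
    props = primer_properties(Primer("p", "SWSWSWSWSW", "forward"))
    assert props.gc_percent == pytest.approx(50.0)


def test_wallace_tm_counts_expected_bases():
    assert wallace_tm("AATT") == 8.0
    assert wallace_tm("GGCC") == 16.0
    assert wallace_tm("AG") == 6.0


@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=10, max_size=40))
def test_gc_percent_invariant_under_revcomp(seq):
    fwd = primer_properties(Primer("f", seq, "forward"))
    rc = primer_properties(Primer("r", revcomp(seq), "forward"))
    assert fwd.gc_percent == pytest.approx(rc.gc_percent)


def test_forward_scan_trivial_hit():
    hits = scan_binding_sites(
        Primer("p", "ACGT", "forward"), NucleotideSequence("t", "TTACGTTT"), 0
    )
    assert [(h.start, h.end, h.mismatches, h.strand) for h in hits] == [(3, 6, 0, "+")]


def test_reverse_scan_finds_revcomp_footprint():
    # footprint whose revcomp is the primer: AACG at 3-6 (revcomp CGTT)
    hits = scan_binding_sites(
        Primer("p", "CGTT", "reverse"), NucleotideSequence("t", "TTAACGTT"), 0
    )
    assert [(h.start, h.end, h.strand) for h in hits] == [(3, 6, "-")]


def test_scan_shorter_template_returns_empty():
    assert scan_binding_sites(
        Primer("p", "ACGTACGTAC", "forward"), NucleotideSequence("t", "ACG"), 3
    ) == []


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
@pytest.mark.parametrize("seed", range(5))
def test_scan_agrees_with_bruteforce_oracle(orientation, seed):
    rng = np.random.default_rng(seed)
    template = "".join(rng.choice(list("ACGT"), size=200))
    primer_seq = "".join(rng.choice(list("ACGTRYMKWSN"), size=20))
    primer = Primer("p", primer_seq, orientation)
    hits = scan_binding_sites(primer, NucleotideSequence("t", template), 3)
    expected = sorted(bf_scan(primer_seq, orientation, template, 3),
                      key=lambda h: (h[2], h[0]))
    assert [(h.start, h.end, h.mismatches) for h in hits] == expected


@given(dna, st.integers(0, 2**31 - 1))
def test_hit_count_monotone_in_max_mismatches(template, seed):
    rng = np.random.default_rng(seed)
    primer = Primer("p", "".join(rng.choice(list("ACGT"), size=8)), "forward")
    rec = NucleotideSequence("t", template)
    counts = [len(scan_binding_sites(primer, rec, m)) for m in range(4)]
    assert counts == sorted(counts)


def test_planted_primer_yields_single_perfect_hit(rng):
    primer_seq = "".join(rng.choice(list("ACGT"), size=25))
    left = "".join(rng.choice(list("ACGT"), size=60))
    right = "".join(rng.choice(list("ACGT"), size=60))
    template = NucleotideSequence("t", left + primer_seq + right)
    hits = scan_binding_sites(Primer("p", primer_seq, "forward"), template, 0)
    assert [(h.start, h.end) for h in hits] == [(61, 60 + len(primer_seq))]


def test_mismatch_positions_are_primer_relative():
    # reverse primer ACGT, footprint revcomp = ACGT; template carries AGGT
    # at 1-4 -> window revcomp ACCT, mismatch at primer position 3
    primer = Primer("p", "ACGT", "reverse")
    hits = scan_binding_sites(primer, NucleotideSequence("t", "AGGT"), 1)
    assert hits[0].mismatches == 1
    assert hits[0].mismatch_positions == (3,)
    mm, pos = count_mismatches(primer, revcomp("AGGT"))
    assert (mm, tuple(pos)) == (1, (3,))


def test_primer_table_round_trip_and_length_bounds(tmp_path):
    path = tmp_path / "primers.tsv"
    path.write_text("name\tsequence\torientation\nP1\tAAAGTGCGGAGCAGCAATCACC\tforward\n")
    (primer,) = read_primer_table(path)
    assert primer.name == "P1" and primer.orientation == "forward"
    path.write_text("name\tsequence\torientation\nshort\tACGT\tforward\n")
    with pytest.raises(ValueError, match="length"):
        read_primer_table(path)
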