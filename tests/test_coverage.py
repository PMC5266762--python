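import numpy as np
import pytest

from _oracles import bf_coverage, bf_min_mismatches
from cladeprimer.coverage import coverage_table, min_mismatches, mismatch_report, \
    pair_coverage
from cladeprimer.io import GroupLabeling, NucleotideSequence, ReferenceDatabase
from cladeprimer.primers import Primer
from cladeprimer.synthetic import SyntheticConfig, generate_reference_db


def test_min_mismatches_zero_on_own_expansion():
    primer = Primer("p", "ACRTTCATNGCRTARTT", "forward")
    # one concrete expansion of the primer embedded in background
    ref = NucleotideSequence("r", "TTTT" + "ACGTTCATAGCGTAGTT" + "CCCC")
    assert min_mismatches(primer, ref) == 0


def test_min_mismatches_window_restriction():
    primer = Primer("p", "ACGTACGTAC", "forward")
    seq = "ACGTACGTAC" + "G" * 50 + "ACGTACGTAC"
    ref = NucleotideSequence("r", seq)
    assert min_mismatches(primer, ref) == 0
    # restricted to the middle stretch, only poor footprints remain
    assert min_mismatches(primer, ref, window=(25, 45)) > 0


def test_mismatch_report_flags_too_short_reference():
    primer = Primer("p", "ACGTACGTACGT", "forward")
    report = mismatch_report([primer], NucleotideSequence("r", "ACGT"))
    assert bool(report.loc[0, "no_site"]) is True


def test_all_n_primer_covers_everything(small_db):
    db, _ = small_db
    table = coverage_table(Primer("n", "N" * 15, "forward"), db)
    assert table.intra_group_percent[0] == 100.0
    assert table.out_group_hits[0] == table.out_group_size


def test_planted_schedule_coverage(small_db):
    db, _truth = small_db
    fwd = _truth.fwd_primer
    table = coverage_table(fwd, db)
    assert table.intra_group_percent == (70.0, 70.0, 100.0, 100.0)
    assert table.out_group_hits == (0, 0, 0, 0)


def test_unknown_group_raises(small_db):
    db, truth = small_db
    with pytest.raises(KeyError):
        coverage_table(truth.fwd_primer, db, in_group="nope")


def test_sequences_shorter_than_primer_not_covered():
    primer = Primer("p", "ACGTACGTACGT", "forward")
    db = ReferenceDatabase(
        [NucleotideSequence("a", "ACG"), NucleotideSequence("b", "ACGTACGTACGT")],
        GroupLabeling({"a": "g", "b": "g"}, in_group="g"),
    )
    table = coverage_table(primer, db)
    assert table.intra_group_percent == (50.0, 50.0, 50.0, 50.0)


def test_pair_coverage_bounded_by_single_primer_coverage(small_db):
    db, truth = small_db
    fwd_t = coverage_table(truth.fwd_primer, db)
    rev_t = coverage_table(truth.rev_primer, db)
    pair_t = pair_coverage(truth.fwd_primer, truth.rev_primer, db)
    for m in range(4):
        assert pair_t.intra_group_percent[m] <= min(
            fwd_t.intra_group_percent[m], rev_t.intra_group_percent[m]
        ) + 1e-9


def test_pair_coverage_zero_when_reverse_site_absent():
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(5)]
    fwd = Primer("f", seqs[0][50:70], "forward")
    rev = Primer("r", "C" * 20, "reverse")  # revcomp G*20, absent from templates?
    records = [NucleotideSequence(f"s{i}", fwd.seq.join(["", s[20:]])) for i, s in enumerate(seqs)]
    db = ReferenceDatabase(
        records, GroupLabeling({r.id: "g" for r in records}, in_group="g")
    )
    table = pair_coverage(fwd, rev, db, max_mm=0)
    assert table.intra_group_percent == (0.0,)


@pytest.mark.parametrize("seed", range(8))
def test_coverage_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(
        seed=seed,
        in_group_size=int(rng.integers(5, 15)),
        out_group_size=int(rng.integers(3, 10)),
        template_length=400,
        fwd_start=100,
        rev_end=286,
        mismatch_schedule=((0.4, 0), (0.3, 1), (0.2, 2), (0.1, 3)),
        out_group_policy="degraded" if seed % 2 else "absent",
        out_group_mismatches=5,
    )
    db, truth = generate_reference_db(config)
    groups = db.labels.groups
    for primer in (truth.fwd_primer, truth.rev_primer):
        table = coverage_table(primer, db)
        intra, hits = bf_coverage(
            primer.seq, primer.orientation, db.records, groups, truth.in_group
        )
        assert table.intra_group_percent == pytest.approx(intra)
        assert table.out_group_hits == hits
        # and the per-sequence minima agree too
        for rec in db.records:
            assert (min_mismatches(primer, rec) or 0) >= 0
            bf = bf_min_mismatches(primer.seq, primer.orientation, rec.seq, 3)
            engine = min_mismatches(primer, rec)
            engine = engine if engine is not None and engine <= 3 else None
            assert engine == bf
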