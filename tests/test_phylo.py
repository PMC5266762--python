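import math
from io import StringIO

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from cladeprimer.phylo import (
    AlignedSet,
    SaturationError,
    bipartitions,
    distance_matrix,
    jc_distance,
    jc_expected_p,
    neighbor_joining,
    p_distance,
    percent_identity,
    read_alignment,
    same_topology,
    to_newick,
)
from cladeprimer.synthetic import evolve_alignment, random_tree


def test_percent_identity_examples():
    assert percent_identity("ACGT", "ACGT") == 100.0
    assert percent_identity("ACGT", "ACGA") == 75.0
    # gap column excluded: 3 matches over 3 compared positions
    assert percent_identity("AC-T", "ACGT") == 100.0
    # ambiguity codes excluded like gaps
    assert percent_identity("ACRT", "ACGT") == 100.0


def test_percent_identity_symmetric_and_errors():
    assert percent_identity("AAGT", "ACGT") == percent_identity("ACGT", "AAGT")
    with pytest.raises(ValueError):
        percent_identity("----", "ACGT")
    with pytest.raises(ValueError):
        percent_identity("ACG", "ACGT")


def test_jc_distance_closed_form_and_domain():
    assert jc_distance(0.0) == 0.0
    assert jc_distance(0.1) == pytest.approx(0.10733, abs=1e-5)
    with pytest.raises(SaturationError):
        jc_distance(0.75)
    with pytest.raises(SaturationError):
        jc_distance(-0.01)


def test_jc_distance_exceeds_p_and_is_increasing():
    ps = np.linspace(0.01, 0.7, 30)
    ds = [jc_distance(p) for p in ps]
    assert all(d >= p for d, p in zip(ds, ps))
    assert all(b > a for a, b in zip(ds, ds[1:]))
    # inverse relationship
    assert jc_expected_p(jc_distance(0.3)) == pytest.approx(0.3)


def test_three_taxon_nj_closed_form():
    dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                        ids=["a", "b", "c"])
    tree = neighbor_joining(dm)
    lengths = {tip.name: tip.length for tip in tree.tips()}
    # three-point formulas: la=(3+4-5)/2=1, lb=(3+5-4)/2=2, lc=(4+5-3)/2=3
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((a:2,b:3):1,(c:4,d:5)) -> additive distances
    D = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    dm = DistanceMatrix(D, ids=["a", "b", "c", "d"])
    tree = neighbor_joining(dm)
    truth = TreeNode.read(StringIO("((a:2,b:3):1,c:4,d:5);"))
    assert same_topology(tree, truth)
    paths = tree.tip_tip_distances()
    for i, x in enumerate("abcd"):
        for j, y in enumerate("abcd"):
            assert abs(paths[x, y] - D[i, j]) < 1e-9


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ids=["a", "b"])
    with pytest.raises(ValueError):
        neighbor_joining(np.zeros((2, 2)), ids=["a", "b"])


def test_nj_cross_checked_against_skbio(rng):
    # independent implementation: same topology on a random noisy matrix
    n = 7
    tree = random_tree(n, 123)
    aln = evolve_alignment(tree, 5000, 456)
    dm = distance_matrix(aln)
    ours = neighbor_joining(dm)
    theirs = skbio_nj(dm)
    assert same_topology(ours, theirs)


def test_negative_branch_lengths_clamped():
    # matrix engineered to produce a negative NJ edge
    D = np.array(
        [
            [0.0, 0.1, 0.4, 0.45],
            [0.1, 0.0, 0.05, 0.5],
            [0.4, 0.05, 0.0, 0.3],
            [0.45, 0.5, 0.3, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(D, ids=list("abcd")))
    for node in tree.traverse(include_self=False):
        assert node.length >= 0


def test_newick_round_trip():
    dm = DistanceMatrix(
        np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float),
        ids=["a", "b", "c", "d"],
    )
    tree = neighbor_joining(dm)
    back = TreeNode.read(StringIO(to_newick(tree)))
    assert same_topology(tree, back)
    assert {t.name for t in back.tips()} == {"a", "b", "c", "d"}


def test_distance_matrix_from_alignment_jc_vs_p():
    aln = AlignedSet(ids=["x", "y"], seqs=["ACGTACGTAC", "ACGTACGTAA"])
    p = distance_matrix(aln, correction="p")[0, 1]
    d = distance_matrix(aln, correction="jc")[0, 1]
    assert p == pytest.approx(0.1)
    assert d == pytest.approx(jc_distance(0.1))


def test_read_alignment_accepts_gaps(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">x\nAC-T\n>y\nACGT\n")
    aln = read_alignment(path)
    assert aln.seqs == ["AC-T", "ACGT"]
    assert percent_identity(*aln.seqs) == 100.0


def test_evolved_pair_p_distance_matches_jc_expectation():
    # two leaves at total distance 0.1, 10 kb: observed p within 3 binomial sd
    tree = TreeNode.read(StringIO("(x:0.05,y:0.05);"))
    aln = evolve_alignment(tree, 10_000, 99)
    p_obs = p_distance(*aln.seqs)
    p_exp = jc_expected_p(0.1)
    sd = math.sqrt(p_exp * (1 - p_exp) / 10_000)
    assert abs(p_obs - p_exp) < 3 * sd


def test_bipartitions_five_taxa():
    t = TreeNode.read(StringIO("((a,b),(c,d),e);"))
    splits = bipartitions(t)
    assert frozenset({frozenset("ab"), frozenset("cde")}) in splits
    assert frozenset({frozenset("cd"), frozenset("abe")}) in splits
    assert len(splits) == 2
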