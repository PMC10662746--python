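"""Delta-map algebra, event semantics, and table/newick I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zcnt.profiles import (
    BalancingError,
    BinError,
    ChromLayout,
    CopyNumberMatrix,
    CopyNumberProfile,
    DeltaProfile,
    EventRecord,
    GenomicBin,
    apply_cnt_event,
    apply_delta_event,
    apply_zcnt_event,
    default_bins,
    delta_map,
    delta_transform,
    inverse_delta_map,
    inverse_delta_transform,
)
from zcnt.io import read_copy_number_table, write_copy_number_table
from zcnt.simulate import enumerate_profiles
from zcnt.tree import Phylogeny, TreeError, read_newick, write_newick


@pytest.mark.parametrize(
    "values, expected",
    [
        ([2, 2, 2, 2], [0, 0, 0, 0, 0]),
        ([3, 1, 0, 2], [1, -2, -1, 2, 0]),
        ([0, 5, 1], [-2, 5, -4, 1]),
    ],
)
def test_delta_map_examples(profile_factory, values, expected):
    d = delta_map(profile_factory(values))
    seg = d.segments["chr1"]
    assert seg.tolist() == expected
    assert seg.sum() == 0


def test_inverse_delta_map_examples(profile_factory):
    assert inverse_delta_map(
        DeltaProfile({"chr1": [0, 0, 0, 0, 0]})
    ).values.tolist() == [2, 2, 2, 2]
    assert inverse_delta_map(
        DeltaProfile({"chr1": [1, -2, -1, 2, 0]})
    ).values.tolist() == [3, 1, 0, 2]
    with pytest.raises(BalancingError):
        DeltaProfile({"chr1": [1, 0, 0]})
    with pytest.raises(BalancingError):
        inverse_delta_transform(
            np.array([1, 0, 0]), ChromLayout(["chr1"], [2])
        )


def test_delta_map_bijective_exhaustively():
    """Every m=3 profile with entries 0..3 round-trips through delta space."""
    layout = ChromLayout(["chr1"], [3])
    profiles = enumerate_profiles(3, 3)
    deltas = delta_transform(profiles, layout)
    assert (deltas.sum(axis=1) == 0).all()
    back = inverse_delta_transform(deltas, layout)
    assert np.array_equal(back, profiles)
    # injectivity: distinct profiles map to distinct delta vectors
    assert len(np.unique(deltas, axis=0)) == len(profiles)


def test_multi_chromosome_delta_segments(profile_factory):
    p = profile_factory([2, 3, 0, 2], n_chrom=2)
    d = delta_map(p)
    assert d.segments["chr1"].tolist() == [0, 1, -1]
    assert d.segments["chr2"].tolist() == [-2, 2, 0]
    assert inverse_delta_map(d).values.tolist() == [2, 3, 0, 2]


@pytest.mark.parametrize(
    "values, event, expected",
    [
        ([2, 0, 1, 2], (1, 2, +1), [2, 0, 2, 2]),  # zero skipped
        ([2, 2], (0, 1, -1), [1, 1]),
        ([1, 1, 1], (0, 2, -1), [0, 0, 0]),
    ],
)
def test_cnt_event_skips_zeros(profile_factory, values, event, expected):
    ev = EventRecord("chr1", *event)
    assert apply_cnt_event(profile_factory(values), ev).values.tolist() == expected


def test_zcnt_event_touches_everything(profile_factory):
    ev = EventRecord("chr1", 1, 2, +1)
    assert apply_zcnt_event(profile_factory([2, 0, 1, 2]), ev).values.tolist() == [2, 1, 2, 2]
    down = EventRecord("chr1", 0, 3, -1)
    assert apply_zcnt_event(np.array([0, 1, 1, 0]), down).tolist() == [-1, 0, 0, -1]
    # inverse events cancel
    p = profile_factory([2, 0, 1, 2])
    undone = apply_zcnt_event(apply_zcnt_event(p, ev), EventRecord("chr1", 1, 2, -1))
    assert undone == p


def test_delta_event_moves_two_boundaries():
    d = DeltaProfile({"chr1": [0, 0, 0, 0, 0]})
    out = apply_delta_event(d, EventRecord("chr1", 1, 2, +1))
    assert out.segments["chr1"].tolist() == [0, 1, 0, -1, 0]


@settings(derandomize=True, max_examples=150)
@given(
    values=st.lists(st.integers(0, 5), min_size=2, max_size=8),
    data=st.data(),
)
def test_zcnt_and_delta_events_commute_with_delta_map(values, data):
    """Applying a ZCNT event then mapping equals mapping then the delta event."""
    m = len(values)
    s = data.draw(st.integers(0, m - 1))
    t = data.draw(st.integers(s, m - 1))
    b = data.draw(st.sampled_from([+1, -1]))
    ev = EventRecord("chr1", s, t, b)
    p = CopyNumberProfile.from_values(values)
    lhs = delta_map(apply_zcnt_event(p, ev))
    rhs = apply_delta_event(delta_map(p), ev)
    assert lhs == rhs


@settings(derandomize=True, max_examples=60)
@given(
    values=st.lists(st.integers(0, 4), min_size=3, max_size=6),
    n_events=st.integers(2, 5),
    seed=st.integers(0, 10_000),
)
def test_zcnt_event_sequences_commute(values, n_events, seed):
    """The final profile does not depend on the order of ZCNT events."""
    rng = np.random.default_rng(seed)
    m = len(values)
    events = []
    for _ in range(n_events):
        s, t = sorted(rng.integers(m, size=2))
        events.append(EventRecord("chr1", int(s), int(t), int(rng.choice([-1, 1]))))
    p = CopyNumberProfile.from_values(values)

    def run(order):
        cur = p
        for k in order:
            cur = apply_zcnt_event(cur, events[k])
        return cur

    base = run(range(n_events))
    perm = rng.permutation(n_events)
    assert run(perm) == base


def test_genomic_bin_validation():
    with pytest.raises(BinError):
        GenomicBin("chr1", 10, 10)
    with pytest.raises(BinError):
        ChromLayout.from_bins(
            default_bins(ChromLayout(["chr1"], [2])).assign(start=[0, 500_000])
        )


# ---------------------------------------------------------------------------
# File round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("layout_kind", ["long", "wide"])
def test_table_round_trip(tmp_path, matrix_factory, rng, layout_kind):
    M = matrix_factory(rng.integers(0, 6, size=(5, 10)), n_chrom=2)
    path = tmp_path / "m.tsv"
    write_copy_number_table(M, path, layout=layout_kind)
    back = read_copy_number_table(path)
    assert back == M


def test_table_rejects_bad_input(tmp_path, matrix_factory):
    M = matrix_factory([[2, 2], [2, 3]])
    path = tmp_path / "m.tsv"
    write_copy_number_table(M, path)
    text = path.read_text().replace("\t2\n", "\t-1\n", 1)
    bad = tmp_path / "bad.tsv"
    bad.write_text(text)
    with pytest.raises(ValueError, match="negative"):
        read_copy_number_table(bad)
    dup = tmp_path / "dup.tsv"
    lines = path.read_text().splitlines()
    dup.write_text("\n".join(lines + [lines[1]]) + "\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_copy_number_table(dup)


def test_newick_round_trip(tmp_path):
    tree = Phylogeny.from_newick("((a,b),(c,d));")
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert back.leaf_set() == tree.leaf_set()
    assert back.nontrivial_splits() == tree.nontrivial_splits()
    with pytest.raises(TreeError):
        Phylogeny.from_newick("((a,b,(c;")


def test_matrix_rejects_negative_and_duplicates(matrix_factory):
    with pytest.raises(ValueError):
        matrix_factory([[2, -1]])
    with pytest.raises(ValueError):
        matrix_factory([[2, 2], [2, 2]], cells=["a", "a"])
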