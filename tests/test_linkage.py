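"""Rigidity analysis: pebble game vs numeric rigidity-matrix oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linkzyme import linkage as L


# -- independent oracle ------------------------------------------------------


def matrix_rank_dof(nodes, bars, rng):
    """Internal DOF from the numeric rank of the rigidity matrix at random
    generic coordinates (independent of the pebble game)."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    coords = rng.uniform(0.0, 10.0, size=(len(nodes), 2))
    R = np.zeros((len(bars), 2 * len(nodes)))
    for r, (u, v) in enumerate(bars):
        d = coords[idx[u]] - coords[idx[v]]
        R[r, 2 * idx[u] : 2 * idx[u] + 2] = d
        R[r, 2 * idx[v] : 2 * idx[v] + 2] = -d
    rank = np.linalg.matrix_rank(R) if len(bars) else 0
    return max(0, 2 * len(nodes) - 3 - rank)


def random_connected_framework(rng, n_nodes, extra_edges):
    nodes = list(range(n_nodes))
    bars = set()
    order = list(rng.permutation(n_nodes))
    for i in range(1, n_nodes):  # random spanning tree keeps it connected
        j = order[int(rng.integers(0, i))]
        bars.add(frozenset((order[i], j)))
    pairs = [p for p in itertools.combinations(nodes, 2) if frozenset(p) not in bars]
    rng.shuffle(pairs)
    for p in pairs[:extra_edges]:
        bars.add(frozenset(p))
    return nodes, [tuple(sorted(b)) for b in sorted(bars, key=sorted)]


# -- basic counting ----------------------------------------------------------


@pytest.mark.parametrize(
    "nodes,bars,dof",
    [
        (range(3), [(0, 1), (1, 2), (0, 2)], 0),  # triangle
        (range(4), [(0, 1), (1, 2), (2, 3), (3, 0)], 1),  # four-bar linkage
        (range(4), [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)], 0),  # braced quad
        (range(2), [(0, 1)], 0),  # single bar
        (range(1), [], 0),  # lone joint
    ],
)
def test_count_internal_dof_small_graphs(nodes, bars, dof):
    fw = L.Framework.create(nodes, bars)
    assert L.count_internal_dof(fw) == dof


def test_disconnected_framework_rejected():
    fw = L.Framework.create(range(4), [(0, 1), (2, 3)])
    with pytest.raises(L.ConfigurationError):
        L.count_internal_dof(fw)


def test_merge_contraction_and_self_bar_rejection():
    # two triangles pinned at one shared joint: still one internal rotation
    fw = L.Framework.create(
        range(6), [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], merges=[(2, 3)]
    )
    assert L.count_internal_dof(fw) == 1
    with pytest.raises(L.ConfigurationError):
        L.Framework.create(range(3), [(0, 1), (1, 2), (0, 2)], merges=[(0, 1)])


# -- square chains -----------------------------------------------------------


def test_square_chain_dof_matches_free_hinge_count():
    """Bracing k of the 2 hinges of the three-square chain leaves 2-k
    internal mechanical degrees of freedom, in any direction."""
    for braces in itertools.product(("up", "down", "free"), repeat=2):
        fw = L.build_square_chain(3, braces)
        k_free = braces.count("free")
        assert L.count_internal_dof(fw) == k_free


def test_single_square_is_rigid_unit():
    assert L.count_internal_dof(L.build_square_chain(1)) == 0


def test_double_square_braced_forms_rigid_triangle():
    assert L.count_internal_dof(L.build_square_chain(2, ("up",))) == 0
    assert L.count_internal_dof(L.build_square_chain(2, ("down",))) == 0
    assert L.count_internal_dof(L.build_square_chain(2, ("free",))) == 1


def test_brace_vector_length_mismatch_rejected():
    with pytest.raises(L.ConfigurationError):
        L.build_square_chain(3, ("up",))


def test_switch_conformations():
    """The single switch unit has 3 conformations (2 rigid, 1 flexible);
    the double unit has 4 fully rigid and 4 partially rigid states among
    its 9 brace assignments."""
    single = L.enumerate_brace_states(2)
    assert len(single) == 3
    classes = [c for _, c in single]
    assert classes.count(L.RigidityClass.RIGID) == 2
    assert classes.count(L.RigidityClass.FLEXIBLE) == 1

    double = L.enumerate_brace_states(3)
    assert len(double) == 9
    classes = [c for _, c in double]
    assert classes.count(L.RigidityClass.RIGID) == 4
    assert classes.count(L.RigidityClass.PARTIALLY_RIGID) == 4
    assert classes.count(L.RigidityClass.FLEXIBLE) == 1


def test_rigid_components_of_braced_chain():
    # one braced hinge fuses two squares into a single 7-joint cluster
    fw = L.build_square_chain(3, ("up", "free"))
    report = L.analyze(fw, flexible_dof=2)
    assert report.rigidity_class == L.RigidityClass.PARTIALLY_RIGID
    sizes = sorted(len(c) for c in report.rigid_components)
    assert sizes == [4, 7]
    # clusters cover every joint (12 raw nodes, 2 pin merges -> 10 joints)
    assert len(set().union(*report.rigid_components)) == 10


# -- oracle agreement and monotonicity --------------------------------------


def test_pebble_game_matches_rigidity_matrix_rank(rng):
    for _ in range(100):
        n = int(rng.integers(3, 9))
        extra = int(rng.integers(0, 2 * n))
        nodes, bars = random_connected_framework(rng, n, extra)
        fw = L.Framework.create(nodes, bars)
        assert L.count_internal_dof(fw) == matrix_rank_dof(nodes, bars, rng)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(3, 8), st.integers(0, 10), st.integers(0, 2**31 - 1))
def test_adding_a_bar_never_increases_dof(n, extra, seed):
    rng = np.random.default_rng(seed)
    nodes, bars = random_connected_framework(rng, n, extra)
    fw = L.Framework.create(nodes, bars)
    dof = L.count_internal_dof(fw)
    candidates = [
        p
        for p in itertools.combinations(nodes, 2)
        if tuple(sorted(p)) not in bars
    ]
    if candidates:
        p = candidates[int(rng.integers(0, len(candidates)))]
        assert L.count_internal_dof(fw.with_bars([p])) <= dof


def test_isostatic_graphs_have_zero_dof(rng):
    # triangulated polygons: 2V - 3 bars, all independent
    for n in (3, 4, 5, 6, 7):
        bars = [(i, (i + 1) % n) for i in range(n)] + [(0, j) for j in range(2, n - 1)]
        fw = L.Framework.create(range(n), bars)
        assert len(bars) == 2 * n - 3  # fan triangulation is isostatic
        assert L.count_internal_dof(fw) == 0


# -- export ------------------------------------------------------------------


def test_json_round_trip_and_dot():
    fw = L.build_square_chain(2, ("up",))
    fw2 = L.Framework.from_json(fw.to_json())
    assert fw2 == fw
    dot = fw.to_dot()
    assert dot.startswith("graph framework {") and "--" in dot
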