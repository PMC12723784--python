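"""Binding rules, feasibility, transition generation and the rate table."""

import math

import pytest

from linkzyme import species as sp
from linkzyme.species import Kind, Reaction


def ms(*runs, **kw):
    return sp.microstate_from_runs(runs, **kw)


# -- bracing -----------------------------------------------------------------


@pytest.mark.parametrize(
    "nodes,kind,expected",
    [
        (("a", "b", "c"), Kind.S, {("h1", "up"), ("h2", "up")}),
        (("e",), Kind.L, set()),  # single-node attachment is flexible
        (("b", "c"), Kind.P2, {("h2", "up")}),
        (("d", "e"), Kind.L, {("h1", "down")}),
        (("d", "e", "f"), Kind.L, {("h1", "down"), ("h2", "down")}),
        (("a",), Kind.P1, set()),
    ],
)
def test_bracing_of(nodes, kind, expected):
    assert sp.bracing_of(nodes, kind) == frozenset(expected)


def test_bracing_rejects_foreign_or_gappy_runs():
    with pytest.raises(sp.RuleViolation):
        sp.bracing_of(("d",), Kind.S)
    with pytest.raises(sp.RuleViolation):
        sp.bracing_of(("a", "c"), Kind.S)


# -- feasibility -------------------------------------------------------------


@pytest.mark.parametrize(
    "runs,feasible",
    [
        ([(Kind.L, "def"), (Kind.S, "ab")], False),  # trivalent L blocks divalent S
        ([(Kind.S, "ab"), (Kind.L, "ef")], True),  # different hinges: coexists
        ([(Kind.P2, "bc"), (Kind.L, "def")], False),  # L blocks P2 on the right
        ([(Kind.S, "abc"), (Kind.L, "f")], True),  # mono L beside rigid S complex
        ([(Kind.S, "abc"), (Kind.L, "def")], False),  # both sites fully bound
        ([(Kind.P1, "a"), (Kind.P2, "bc"), (Kind.L, "de")], True),
        ([(Kind.S, "a"), (Kind.S, "c")], True),  # two monovalent substrates
    ],
)
def test_is_feasible(runs, feasible):
    state = ms(*((k, tuple(n)) for k, n in runs))
    assert sp.is_feasible(state) is feasible


def test_occupancy_conflicts_are_infeasible():
    with pytest.raises(sp.RuleViolation):
        ms((Kind.S, ("a", "b")), (Kind.P1, ("a",)))


def test_feasibility_monotone_under_node_release():
    """Removing any single node from any instance of a feasible state
    leaves a feasible state (flexibility only increases)."""
    from linkzyme.network import build_state_graph, canonical_microstate

    g = build_state_graph()
    for state in g.nodes:
        mstate = canonical_microstate(state)
        for b in mstate.bound:
            for node in (b.nodes[0], b.nodes[-1]):
                remaining = tuple(n for n in b.nodes if n != node)
                rest = [x for x in mstate.bound if x is not b]
                if remaining:
                    rest.append(sp.Bound(b.instance, remaining))
                assert sp.is_feasible(sp.Microstate.create(rest))


def test_custom_rule_table(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text("- [[h1, up], [h2, down]]\n")
    rules = sp.FeasibilityRules.from_yaml(path)
    state = ms((Kind.S, ("a", "b")), (Kind.L, ("e", "f")))
    assert sp.is_feasible(state)  # default rules allow it
    assert not sp.is_feasible(state, rules)


# -- transitions -------------------------------------------------------------


def transitions(state, rates=None, **opts):
    rates = rates or sp.RateTable()
    return sp.enumerate_transitions(state, rates, sp.ModelOptions(**opts) if opts else sp.DEFAULT_OPTIONS)


def test_empty_enzyme_bindings():
    """Intermolecular binding is node-resolved: each kind can start at any
    free node of its site (S:3 + P1:1 + P2:2 + L:3 = 9 channels)."""
    rates = sp.RateTable()
    rates.concentrations = {k: 100.0 for k in Kind}
    trs = transitions(ms(), rates)
    assert all(t.rtype is Reaction.INTER_BIND for t in trs)
    assert len(trs) == 9
    by_kind = {k: sum(1 for t in trs if t.kind is k) for k in Kind}
    assert by_kind == {Kind.S: 3, Kind.P1: 1, Kind.P2: 2, Kind.L: 3}
    assert all(t.rate == 100.0 for t in trs)


def test_zero_concentration_kinds_do_not_bind():
    trs = transitions(ms())  # defaults: [P1]=[P2]=0
    assert {t.kind for t in trs} == {Kind.S, Kind.L}


def test_trivalent_substrate_cleaves_and_frays():
    trs = transitions(ms((Kind.S, ("a", "b", "c"))))
    symbols = {(t.rtype, t.rate_symbol) for t in trs}
    assert (Reaction.CLEAVAGE, "kclv") in symbols
    assert (Reaction.INTRA_DISS, "koff-a") in symbols
    assert (Reaction.INTRA_DISS, "koff-c") in symbols
    # the middle node cannot be released while both neighbours hold on
    assert (Reaction.INTRA_DISS, "koff-b") not in symbols
    clv = next(t for t in trs if t.rtype is Reaction.CLEAVAGE)
    kinds = sorted(b.kind.value for b in clv.new_state.bound)
    assert kinds == ["P1", "P2"]
    p2 = next(b for b in clv.new_state.bound if b.kind is Kind.P2)
    assert p2.nodes == ("b", "c") and p2.instance.lineage is not None


def test_ligation_requires_unbraced_left_hinge():
    """P1 + P2 can re-ligate into substrate, but not while a divalent
    ligand holds the left hinge down (rectification geometry)."""
    free = transitions(ms((Kind.P1, ("a",)), (Kind.P2, ("b", "c"))))
    lig = [t for t in free if t.rtype is Reaction.LIGATION]
    assert len(lig) == 1 and lig[0].rate_symbol == "klig"
    assert lig[0].new_state.bound[0].nodes == ("a", "b", "c")
    assert any(
        t.rtype is Reaction.INTER_DISS and t.rate_symbol == "koff-a" for t in free
    )

    blocked = transitions(
        ms((Kind.P1, ("a",)), (Kind.P2, ("b", "c")), (Kind.L, ("d", "e")))
    )
    assert not any(t.rtype is Reaction.LIGATION for t in blocked)


def test_cleavage_trivalent_flag():
    divalent = ms((Kind.S, ("a", "b")))
    assert any(t.rtype is Reaction.CLEAVAGE for t in transitions(divalent))
    strict = sp.ModelOptions(cleave_requires_trivalent=True)
    trs = sp.enumerate_transitions(divalent, sp.RateTable(), strict)
    assert not any(t.rtype is Reaction.CLEAVAGE for t in trs)


def test_ligation_lineage_flag():
    state = sp.Microstate.create(
        [
            sp.Bound(sp.ReactantInstance(Kind.P1, 0, lineage=7), ("a",)),
            sp.Bound(sp.ReactantInstance(Kind.P2, 1, lineage=8), ("b", "c")),
        ]
    )
    strict = sp.ModelOptions(require_same_lineage=True)
    assert not any(
        t.rtype is Reaction.LIGATION
        for t in sp.enumerate_transitions(state, sp.RateTable(), strict)
    )
    same = sp.Microstate.create(
        [
            sp.Bound(sp.ReactantInstance(Kind.P1, 0, lineage=7), ("a",)),
            sp.Bound(sp.ReactantInstance(Kind.P2, 1, lineage=7), ("b", "c")),
        ]
    )
    assert any(
        t.rtype is Reaction.LIGATION
        for t in sp.enumerate_transitions(same, sp.RateTable(), strict)
    )


def test_max_per_kind_cap():
    trs = transitions(ms((Kind.S, ("a",))), max_per_kind={Kind.S: 1})
    assert not any(
        t.rtype is Reaction.INTER_BIND and t.kind is Kind.S for t in trs
    )


def test_transition_reversibility():
    """Every binding produced from a state has its dissociation produced
    from the resulting state, and vice versa (types I/IV, II/III pairs)."""
    from linkzyme.network import build_state_graph, canonical_microstate

    rates = sp.RateTable()
    rates.concentrations = {k: 1.0 for k in Kind}
    g = build_state_graph()
    pair = {
        Reaction.INTER_BIND: Reaction.INTER_DISS,
        Reaction.INTER_DISS: Reaction.INTER_BIND,
        Reaction.INTRA_BIND: Reaction.INTRA_DISS,
        Reaction.INTRA_DISS: Reaction.INTRA_BIND,
        Reaction.CLEAVAGE: Reaction.LIGATION,
        Reaction.LIGATION: Reaction.CLEAVAGE,
    }
    for state in list(g.nodes)[::7]:  # systematic subsample keeps this fast
        mstate = canonical_microstate(state)
        for tr in sp.enumerate_transitions(mstate, rates, next_uid=len(mstate.bound)):
            back = sp.enumerate_transitions(tr.new_state, rates)
            assert any(
                b.rtype is pair[tr.rtype] and b.new_state.canonical() == state
                for b in back
            ), (state, tr.rtype, tr.new_state.canonical())


def test_no_state_has_both_sites_trivalent():
    from linkzyme.network import build_state_graph

    g = build_state_graph()
    for state in g.nodes:
        runs = {kind: nodes for kind, nodes in state}
        top_tri = any(len(nodes) == 3 for kind, nodes in state if kind in ("S",))
        bottom_tri = any(len(nodes) == 3 for kind, nodes in state if kind == "L")
        assert not (top_tri and bottom_tri)


# -- rate table and energy hierarchy ----------------------------------------


def test_default_rate_table_satisfies_hierarchy(default_rates):
    """Site binding energies from ln(koff/kuni) order substrate < ligand <
    P2 < P1, and catalysis is slower than the bonds it races."""
    report = sp.validate_rate_hierarchy(default_rates)
    assert report.passed and not report.warnings
    e = report.energies
    assert e["S"] < e["L"] < e["P2"] < e["P1"]
    assert math.isclose(e["S"], -28.3043, abs_tol=5e-4)
    assert math.isclose(e["L"], -23.1040, abs_tol=5e-4)
    assert math.isclose(e["P2"], -20.0103, abs_tol=5e-4)
    assert math.isclose(e["P1"], -8.2940, abs_tol=5e-4)


def test_flat_off_rates_break_hierarchy():
    flat = sp.RateTable(koff={n: 100.0 for n in "abcdef"})
    report = sp.validate_rate_hierarchy(flat)
    assert not report.hierarchy_ok and report.warnings


def test_catalysis_speed_checks():
    fast_clv = sp.RateTable().copy(kclv=500.0)  # faster than koff-e = 200
    assert not sp.validate_rate_hierarchy(fast_clv).cleavage_ok
    fast_lig = sp.RateTable().copy(klig=300.0)  # faster than koff-a = 250
    assert not sp.validate_rate_hierarchy(fast_lig).ligation_ok


def test_rate_table_validation_and_yaml(tmp_path):
    with pytest.raises(sp.RuleViolation):
        sp.RateTable(kuni=-1.0)
    path = tmp_path / "rates.yaml"
    path.write_text(
        "rates:\n  kclv: 2.5\n  concentrations: {S: 10, L: 50}\n"
    )
    rt = sp.RateTable.from_yaml(path)
    assert rt.kclv == 2.5
    assert rt.concentrations[Kind.S] == 10.0
    assert rt.concentrations[Kind.P1] == 0.0
    assert rt.koff["b"] == 3.0  # untouched defaults
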