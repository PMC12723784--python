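"""Reaction-network enumeration and the named turnover cycles.

The reachable state space of one enzyme is finite: every microstate is a
feasible occupancy of the six binding nodes, and every reaction changes a
single node connection or performs one cleavage/ligation.  This module
builds that network as a reversible directed multigraph over *canonical*
microstates (instance identities abstracted away, states labelled by their
sorted (kind, node-run) pairs), and locates the three named cycles of the
enzymatic mechanism:

* **target** — S displaces L, S is cleaved, P1 dissociation rectifies the
  cycle, a *new* L displaces P2 (the productive pathway);
* **idling** — the same L stays bound through catalysis, so substrate is
  consumed without ligand exchange;
* **steric** — a second substrate, not ligand, displaces P2, so turnover
  bypasses the ligand entirely.

The named cycles are definitions of the mechanism, not emergent graph
features, so they are located by constructing their canonical walks and
verifying every step against the enumerated network; a missing step is a
model-rule regression, reported as an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import linkage
from .species import (
    DEFAULT_OPTIONS,
    Kind,
    Microstate,
    ModelOptions,
    RateTable,
    Reaction,
    enumerate_transitions,
    microstate_from_runs,
)

CanonicalState = tuple[tuple[str, tuple[str, ...]], ...]

EMPTY_STATE: CanonicalState = ()


class CycleNotFoundError(RuntimeError):
    """A named cycle's walk is not realized by the enumerated network."""


def state_label(state: CanonicalState) -> str:
    if not state:
        return "empty"
    return "+".join(f"{kind}:{''.join(nodes)}" for kind, nodes in state)


def state_from_label(label: str) -> CanonicalState:
    if label == "empty":
        return ()
    runs = []
    for part in label.split("+"):
        kind, nodes = part.split(":")
        runs.append((kind, tuple(nodes)))
    return tuple(sorted(runs))


def canonical_microstate(state: CanonicalState) -> Microstate:
    """Instance-level representative of a canonical state (positional uids)."""
    return microstate_from_runs(state)


@dataclass(frozen=True)
class NamedCycle:
    """A closed walk through the state graph with a mechanistic identity."""

    cycle_id: str  # 'target' | 'idling' | 'steric'
    states: tuple[CanonicalState, ...]  # closed: last edge returns to states[0]
    edge_types: tuple[Reaction, ...]
    edge_symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.edge_types)

    def macro_projection(self) -> list[str]:
        """Collapse consecutive identical macrostates around the cycle."""
        labels = [canonical_microstate(s).macrostate() for s in self.states]
        out = [labels[0]]
        for lab in labels[1:]:
            if lab != out[-1]:
                out.append(lab)
        if len(out) > 1 and out[-1] == out[0]:
            out.pop()
        return out


def build_state_graph(
    rates: RateTable | None = None,
    options: ModelOptions = DEFAULT_OPTIONS,
    max_states: int = 50_000,
) -> nx.MultiDiGraph:
    """Breadth-first closure of the reaction rules from the empty enzyme.

    Vertices are canonical states; parallel edges are keyed by
    ``(reaction type, kind, from-run, to-run)``.  With no rate table the
    full structural network is built (all four reactants present, unit
    concentrations), and the graph is reversible: every binding has its
    dissociation and cleavage/ligation are mutual reverses.  An explicit
    rate table is honoured exactly: kinds at zero concentration contribute
    no intermolecular binding edges, which shrinks the reachable space
    (e.g. the ligand-only chain) and can leave product-release edges
    without a rebinding reverse.
    """
    if rates is None:
        rates = RateTable()
        rates.concentrations = {k: 1.0 for k in Kind}
    g = nx.MultiDiGraph()
    start: CanonicalState = EMPTY_STATE
    g.add_node(start)
    frontier = [start]
    while frontier:
        state = frontier.pop()
        ms = canonical_microstate(state)
        for tr in enumerate_transitions(ms, rates, options, next_uid=len(ms.bound)):
            if tr.rate <= 0:
                continue
            tgt = tr.new_state.canonical()
            if tgt not in g:
                if g.number_of_nodes() >= max_states:
                    raise RuntimeError(
                        f"state space exceeded {max_states} states; tighten "
                        "the occupancy limits (ModelOptions.max_per_kind)"
                    )
                g.add_node(tgt)
                frontier.append(tgt)
            key = (tr.rtype.value, tr.kind.value, tr.from_nodes, tr.to_nodes)
            g.add_edge(
                state,
                tgt,
                key=key,
                rtype=tr.rtype.value,
                symbol=tr.rate_symbol,
                rate=tr.rate,
                kind=tr.kind.value,
                from_nodes=tr.from_nodes,
                to_nodes=tr.to_nodes,
            )
    for state in g.nodes:
        ms = canonical_microstate(state)
        g.nodes[state]["label"] = state_label(state)
        g.nodes[state]["macrostate"] = ms.macrostate()
        braces = ms.brace_states()
        g.nodes[state]["bracing"] = f"h1={braces['h1']},h2={braces['h2']}"
    return g


# ---------------------------------------------------------------------------
# Named cycles
# ---------------------------------------------------------------------------


def _canon(runs) -> CanonicalState:
    return tuple(sorted((k, tuple(n)) for k, n in runs))


def _walk(steps):
    states = [_canon(s) for s, _, _ in steps]
    types = tuple(t for _, t, _ in steps)
    symbols = tuple(sym for _, _, sym in steps)
    return states, types, symbols


def target_cycle_walk():
    """The 13-state productive walk: each tuple is (state, reaction leaving
    it, rate symbol).  Reactions 1-6 of the macro-cycle are the I/IV edges;
    the III/II edges between them are the hidden intramolecular steps of
    the two allosteric displacements."""
    I, II, III, IV = Reaction.INTER_BIND, Reaction.INTRA_BIND, Reaction.INTRA_DISS, Reaction.INTER_DISS
    V = Reaction.CLEAVAGE
    steps = [
        ([("L", "def")], I, "k_S_on"),                       # 1: S binds a
        ([("L", "def"), ("S", "a")], III, "koff-d"),
        ([("L", "ef"), ("S", "a")], II, "kuni"),
        ([("L", "ef"), ("S", "ab")], III, "koff-e"),
        ([("L", "f"), ("S", "ab")], II, "kuni"),
        ([("L", "f"), ("S", "abc")], IV, "koff-f"),          # 2: L dissociates
        ([("S", "abc")], V, "kclv"),                         # 3: S cleaved
        ([("P1", "a"), ("P2", "bc")], IV, "koff-a"),         # 4: P1 dissociates
        ([("P2", "bc")], I, "k_L_on"),                       # 5: L binds d
        ([("L", "d"), ("P2", "bc")], II, "kuni"),
        ([("L", "de"), ("P2", "bc")], III, "koff-b"),
        ([("L", "de"), ("P2", "c")], II, "kuni"),
        ([("L", "def"), ("P2", "c")], IV, "koff-c"),         # 6: P2 dissociates
    ]
    return _walk(steps)


def idling_cycle_walk():
    """Cycle ii: from the trivalent-S microstate the substrate is cleaved
    while the ligand is still attached; the same ligand then walks back
    across its site and displaces P2, rejoining the target path inside
    {P2/L}.  Substrate is consumed but no ligand exchange occurs."""
    I, II, III, IV = Reaction.INTER_BIND, Reaction.INTRA_BIND, Reaction.INTRA_DISS, Reaction.INTER_DISS
    V = Reaction.CLEAVAGE
    steps = [
        ([("L", "f"), ("S", "abc")], V, "kclv"),             # cleave with L on
        ([("L", "f"), ("P1", "a"), ("P2", "bc")], IV, "koff-a"),
        ([("L", "f"), ("P2", "bc")], III, "koff-b"),
        ([("L", "f"), ("P2", "c")], II, "kuni"),
        ([("L", "ef"), ("P2", "c")], II, "kuni"),
        ([("L", "def"), ("P2", "c")], IV, "koff-c"),         # rejoined target
        ([("L", "def")], I, "k_S_on"),
        ([("L", "def"), ("S", "a")], III, "koff-d"),
        ([("L", "ef"), ("S", "a")], II, "kuni"),
        ([("L", "ef"), ("S", "ab")], III, "koff-e"),
        ([("L", "f"), ("S", "ab")], II, "kuni"),
    ]
    return _walk(steps)


def steric_cycle_walk():
    """Cycle iii: after rectification a second substrate invades at node a
    and displaces P2 with no ligand involved; turnover occurs but is
    decoupled from ligand binding."""
    I, II, III, IV = Reaction.INTER_BIND, Reaction.INTRA_BIND, Reaction.INTRA_DISS, Reaction.INTER_DISS
    V = Reaction.CLEAVAGE
    steps = [
        ([("P1", "a"), ("P2", "bc")], IV, "koff-a"),
        ([("P2", "bc")], I, "k_S_on"),                       # invading S at a
        ([("P2", "bc"), ("S", "a")], III, "koff-b"),
        ([("P2", "c"), ("S", "a")], II, "kuni"),
        ([("P2", "c"), ("S", "ab")], IV, "koff-c"),          # P2 displaced
        ([("S", "ab")], II, "kuni"),
        ([("S", "abc")], V, "kclv"),
    ]
    return _walk(steps)


_WALKS = {
    "target": target_cycle_walk,
    "idling": idling_cycle_walk,
    "steric": steric_cycle_walk,
}


def find_named_cycles(g: nx.MultiDiGraph) -> dict[str, NamedCycle]:
    """Locate the target, idling and steric cycles in a state graph.

    Each canonical walk is checked edge by edge against the graph; any
    missing state or reaction step raises :class:`CycleNotFoundError`
    (a regression in the binding rules).
    """
    out = {}
    for cid, builder in _WALKS.items():
        states, types, symbols = builder()
        closed = states + [states[0]]
        for i, (u, v) in enumerate(zip(closed, closed[1:])):
            if u not in g:
                raise CycleNotFoundError(f"{cid} cycle: state {state_label(u)} missing")
            found = False
            if g.has_edge(u, v):
                for key, data in g[u][v].items():
                    if data["rtype"] == types[i].value and data["symbol"] == symbols[i]:
                        found = True
                        break
            if not found:
                raise CycleNotFoundError(
                    f"{cid} cycle: no {types[i].value} ({symbols[i]}) edge "
                    f"{state_label(u)} -> {state_label(v)}"
                )
        out[cid] = NamedCycle(cid, tuple(closed), types, symbols)
    return out


def intramolecular_steps_between(
    cycle: NamedCycle, first: str, second: str
) -> int:
    """Number of intramolecular (II/III) steps strictly between the edge
    labelled ``first`` and the edge labelled ``second`` along the cycle."""
    symbols = list(cycle.edge_symbols)
    i, j = symbols.index(first), symbols.index(second)
    assert i < j, "edges must appear in cycle order"
    intra = {Reaction.INTRA_BIND, Reaction.INTRA_DISS}
    return sum(1 for k in range(i + 1, j) if cycle.edge_types[k] in intra)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _string_graph(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Copy with string node ids and scalar attributes (for GraphML/DOT)."""
    h = nx.MultiDiGraph()
    for n, data in sorted(g.nodes(data=True), key=lambda x: state_label(x[0])):
        h.add_node(state_label(n), **{k: str(v) for k, v in data.items()})
    for u, v, key, data in sorted(
        g.edges(keys=True, data=True), key=lambda x: (state_label(x[0]), state_label(x[1]), str(x[2]))
    ):
        attrs = {
            "rtype": data["rtype"],
            "symbol": data["symbol"],
            "rate": float(data["rate"]),
            "kind": data["kind"],
        }
        h.add_edge(state_label(u), state_label(v), **attrs)
    return h


def export_graph(g: nx.MultiDiGraph, path, fmt: str = "json") -> None:
    """Write the state graph as ``json``, ``graphml``, ``dot`` or ``csv``.

    Output ordering is canonical (sorted state labels) so exports diff
    cleanly.  ``csv`` writes two files: ``<path>.vertices.csv`` and
    ``<path>.edges.csv``.
    """
    path = str(path)
    if fmt == "json":
        with open(path, "w") as fh:
            fh.write(graph_to_json(g))
    elif fmt == "graphml":
        nx.write_graphml(_string_graph(g), path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write(graph_to_dot(g))
    elif fmt == "csv":
        vdf, edf = graph_tables(g)
        vdf.to_csv(path + ".vertices.csv", index=False)
        edf.to_csv(path + ".edges.csv", index=False)
    else:
        raise ValueError(f"unsupported format: {fmt!r}")


def graph_to_json(g: nx.MultiDiGraph) -> str:
    vertices = []
    for n in sorted(g.nodes, key=state_label):
        vertices.append(
            {
                "label": state_label(n),
                "macrostate": g.nodes[n].get("macrostate", ""),
                "bracing": g.nodes[n].get("bracing", ""),
            }
        )
    edges = []
    for u, v, data in sorted(
        g.edges(data=True), key=lambda x: (state_label(x[0]), state_label(x[1]), x[2]["symbol"], x[2]["rtype"])
    ):
        edges.append(
            {
                "source": state_label(u),
                "target": state_label(v),
                "rtype": data["rtype"],
                "symbol": data["symbol"],
                "rate": data["rate"],
                "kind": data["kind"],
                "from_nodes": list(data["from_nodes"]) if data["from_nodes"] else None,
                "to_nodes": list(data["to_nodes"]) if data["to_nodes"] else None,
            }
        )
    return json.dumps({"vertices": vertices, "edges": edges}, indent=1)


def graph_from_json(text: str) -> nx.MultiDiGraph:
    payload = json.loads(text)
    g = nx.MultiDiGraph()
    for v in payload["vertices"]:
        g.add_node(
            state_from_label(v["label"]),
            label=v["label"],
            macrostate=v["macrostate"],
            bracing=v["bracing"],
        )
    for e in payload["edges"]:
        fr = tuple(e["from_nodes"]) if e["from_nodes"] else None
        to = tuple(e["to_nodes"]) if e["to_nodes"] else None
        g.add_edge(
            state_from_label(e["source"]),
            state_from_label(e["target"]),
            key=(e["rtype"], e["kind"], fr, to),
            rtype=e["rtype"],
            symbol=e["symbol"],
            rate=e["rate"],
            kind=e["kind"],
            from_nodes=fr,
            to_nodes=to,
        )
    return g


def graph_to_dot(g: nx.MultiDiGraph) -> str:
    lines = ["digraph states {"]
    for n in sorted(g.nodes, key=state_label):
        macro = g.nodes[n].get("macrostate", "")
        lines.append(f'  "{state_label(n)}" [macrostate="{macro}"];')
    for u, v, data in sorted(
        g.edges(data=True), key=lambda x: (state_label(x[0]), state_label(x[1]), x[2]["symbol"])
    ):
        lines.append(
            f'  "{state_label(u)}" -> "{state_label(v)}" '
            f'[label="{data["symbol"]}" rtype="{data["rtype"]}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def enzyme_framework(state: CanonicalState) -> linkage.Framework:
    """The enzyme-complex framework of a state: the 3-square chain with a
    brace bar wherever the occupancy braces a hinge."""
    ms = canonical_microstate(state)
    braces = ms.brace_states()
    return linkage.build_square_chain(3, (braces["h1"], braces["h2"]))


def graph_tables(g: nx.MultiDiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vertex and edge tables (CSV contract): per-vertex macrostate,
    bracing, internal mechanical DOF and rigidity class of the complex."""
    vrows = []
    for n in sorted(g.nodes, key=state_label):
        fw = enzyme_framework(n)
        report = linkage.analyze(fw, flexible_dof=2)
        vrows.append(
            {
                "state": state_label(n),
                "macrostate": g.nodes[n].get("macrostate", ""),
                "bracing": g.nodes[n].get("bracing", ""),
                "internal_dof": report.internal_dof,
                "rigidity_class": report.rigidity_class.value,
            }
        )
    erows = []
    for u, v, data in sorted(
        g.edges(data=True), key=lambda x: (state_label(x[0]), state_label(x[1]), x[2]["symbol"], x[2]["rtype"])
    ):
        erows.append(
            {
                "source": state_label(u),
                "target": state_label(v),
                "rtype": data["rtype"],
                "symbol": data["symbol"],
                "rate": data["rate"],
                "kind": data["kind"],
            }
        )
    return pd.DataFrame(vrows), pd.DataFrame(erows)


def is_reversible(g: nx.MultiDiGraph) -> bool:
    """Every directed edge has a reverse edge (I/IV, II/III, V/VI pairs)."""
    return all(g.has_edge(v, u) for u, v in g.edges())


__all__ = [
    "CanonicalState",
    "CycleNotFoundError",
    "EMPTY_STATE",
    "NamedCycle",
    "build_state_graph",
    "canonical_microstate",
    "enzyme_framework",
    "export_graph",
    "find_named_cycles",
    "graph_from_json",
    "graph_tables",
    "graph_to_dot",
    "graph_to_json",
    "intramolecular_steps_between",
    "is_reversible",
    "state_from_label",
    "state_label",
    "target_cycle_walk",
    "idling_cycle_walk",
    "steric_cycle_walk",
]
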