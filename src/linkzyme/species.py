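"""Chemical layer of the linkage machine: reactants, binding rules, rates.

The enzyme is a chain of three rigid squares with two hinges (``h1`` left,
``h2`` right).  Its six binding nodes are the three top corners ``a, b, c``
(the substrate/product site) and the three bottom corners ``d, e, f`` (the
ligand site).  Four reactants bind these nodes:

* ``S``  — the ATP analog (substrate), binds ``a, b, c``; carries the
  catalytic moiety between its ``a*`` and ``b*`` ends where it is cleaved.
* ``P1`` — the Pi analog, binds ``a`` only.
* ``P2`` — the ADP analog, binds ``b, c``.
* ``L``  — the allosteric-effector analog (ligand), binds ``d, e, f``.

A reactant bound at two adjacent nodes braces the hinge those nodes flank
— top pairs brace it "up", bottom pairs "down" — locking one mechanical
degree of freedom.  A hinge cannot be braced both ways at once, which is
the geometric origin of negative allosteric coupling between the two
sites: neither site can be fully bound while the other is multivalently
bound on the same side.

States interconvert through six reaction types:

I   intermolecular binding      (a fresh reactant binds one free node)
II  intramolecular binding      (a bound reactant grabs an adjacent node)
III intramolecular dissociation (a multivalent reactant drops a terminal node)
IV  intermolecular dissociation (a monovalent reactant leaves)
V   cleavage                    (bound S splits into P1 and P2)
VI  ligation                    (bound P1 + P2 rejoin into S)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import yaml

Node = str

TOP_NODES: tuple[Node, ...] = ("a", "b", "c")
BOTTOM_NODES: tuple[Node, ...] = ("d", "e", "f")
ALL_NODES: tuple[Node, ...] = TOP_NODES + BOTTOM_NODES

HINGES = ("h1", "h2")

#: Adjacent node pairs and the (hinge, direction) they brace when a single
#: reactant spans both.
HINGE_SPAN: dict[tuple[Node, Node], tuple[str, str]] = {
    ("a", "b"): ("h1", "up"),
    ("b", "c"): ("h2", "up"),
    ("d", "e"): ("h1", "down"),
    ("e", "f"): ("h2", "down"),
}


class Kind(str, Enum):
    """The four reactant kinds."""

    S = "S"
    P1 = "P1"
    P2 = "P2"
    L = "L"


#: Site nodes each kind may bind, in site order.
BINDING_NODES: dict[Kind, tuple[Node, ...]] = {
    Kind.S: ("a", "b", "c"),
    Kind.P1: ("a",),
    Kind.P2: ("b", "c"),
    Kind.L: ("d", "e", "f"),
}


class Reaction(str, Enum):
    """The six linkage reaction types."""

    INTER_BIND = "I"
    INTRA_BIND = "II"
    INTRA_DISS = "III"
    INTER_DISS = "IV"
    CLEAVAGE = "V"
    LIGATION = "VI"


class RuleViolation(ValueError):
    """A microstate or operation violates the binding rules."""


# ---------------------------------------------------------------------------
# Rate table (defaults are the simulation rates of the model)
# ---------------------------------------------------------------------------

_DEFAULT_KOFF = {"a": 250.0, "b": 3.0, "c": 680.0, "d": 680.0, "e": 200.0, "f": 680.0}


@dataclass
class RateTable:
    """All kinetic parameters, in s^-1 (concentrations in uM).

    ``koff`` gives the per-node off rate, used both for intramolecular
    dissociation (reactant bound at >= 2 nodes) and intermolecular
    dissociation (last node).  ``kuni`` is the intramolecular binding rate,
    the fastest timescale in the system.  ``c_on`` converts a concentration
    to a pseudo-first-order binding propensity per free compatible node.
    """

    koff: dict[Node, float] = field(default_factory=lambda: dict(_DEFAULT_KOFF))
    kuni: float = 1e6
    kclv: float = 10.0
    klig: float = 10.0
    c_on: float = 1.0  # s^-1 uM^-1
    concentrations: dict[Kind, float] = field(
        default_factory=lambda: {Kind.S: 100.0, Kind.L: 100.0, Kind.P1: 0.0, Kind.P2: 0.0}
    )

    def __post_init__(self) -> None:
        self.concentrations = {Kind(k): float(v) for k, v in self.concentrations.items()}
        for k in Kind:
            self.concentrations.setdefault(k, 0.0)
        for n in ALL_NODES:
            if self.koff.get(n, 0.0) <= 0:
                raise RuleViolation(f"koff-{n} must be positive")
        for name in ("kuni", "kclv", "klig", "c_on"):
            if getattr(self, name) <= 0:
                raise RuleViolation(f"{name} must be positive")
        if any(c < 0 for c in self.concentrations.values()):
            raise RuleViolation("concentrations must be non-negative")

    def on_rate(self, kind: Kind) -> float:
        return self.c_on * self.concentrations[kind]

    def copy(self, **updates) -> "RateTable":
        out = RateTable(
            koff=dict(self.koff),
            kuni=self.kuni,
            kclv=self.kclv,
            klig=self.klig,
            c_on=self.c_on,
            concentrations=dict(self.concentrations),
        )
        for k, v in updates.items():
            if k == "concentrations":
                out.concentrations.update({Kind(kk): float(vv) for kk, vv in v.items()})
            elif k == "koff":
                out.koff.update(v)
            else:
                setattr(out, k, v)
        return out

    # -- config I/O ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "koff": dict(self.koff),
            "kuni": self.kuni,
            "kclv": self.kclv,
            "klig": self.klig,
            "c_on": self.c_on,
            "concentrations": {k.value: v for k, v in self.concentrations.items()},
        }

    @staticmethod
    def from_dict(d: Mapping) -> "RateTable":
        kw = {}
        for key in ("koff", "kuni", "kclv", "klig", "c_on", "concentrations"):
            if key in d:
                kw[key] = d[key]
        return RateTable(**kw)

    @staticmethod
    def from_yaml(path) -> "RateTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return RateTable.from_dict(payload.get("rates", payload))


def node_energies(rates: RateTable) -> dict[Node, float]:
    """Per-node binding energy epsilon = ln(koff / kuni), in kT (negative)."""
    return {n: math.log(rates.koff[n] / rates.kuni) for n in ALL_NODES}


@dataclass(frozen=True)
class HierarchyReport:
    """Binding-energy hierarchy check for a rate table.

    The off rates must make substrate bind tightest, then ligand, then P2,
    then P1 (site-energy sums strictly increasing), so that each
    displacement competition is won by the intended reactant.  Catalysis
    must be slower than the bonds it races: cleavage slower than every
    ligand off rate, ligation slower than P1 dissociation.
    """

    energies: dict[str, float]
    hierarchy_ok: bool
    cleavage_ok: bool
    ligation_ok: bool
    warnings: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return self.hierarchy_ok and self.cleavage_ok and self.ligation_ok


def validate_rate_hierarchy(rates: RateTable) -> HierarchyReport:
    eps = node_energies(rates)
    energies = {
        "S": eps["a"] + eps["b"] + eps["c"],
        "L": eps["d"] + eps["e"] + eps["f"],
        "P2": eps["b"] + eps["c"],
        "P1": eps["a"],
    }
    hierarchy_ok = energies["S"] < energies["L"] < energies["P2"] < energies["P1"]
    cleavage_ok = rates.kclv < min(rates.koff[n] for n in BOTTOM_NODES)
    ligation_ok = rates.klig < rates.koff["a"]
    warnings = []
    if not hierarchy_ok:
        warnings.append(
            "site energies do not satisfy eS < eL < eP2 < eP1; displacement "
            "competitions may not resolve in the intended order"
        )
    if not cleavage_ok:
        warnings.append("kclv is not slower than every ligand off rate; idling favoured")
    if not ligation_ok:
        warnings.append("klig is not slower than koff-a; catalysis siloing favoured")
    return HierarchyReport(energies, hierarchy_ok, cleavage_ok, ligation_ok, tuple(warnings))


# ---------------------------------------------------------------------------
# Instances and microstates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactantInstance:
    """One copy of a reactant, tracked by identity through a trajectory.

    ``lineage`` is the uid of the parent substrate for cleavage products,
    letting the analysis distinguish "the same ligand remains bound" from
    "a different ligand binds" and tie each P2 back to its cleavage.
    """

    kind: Kind
    uid: int
    lineage: Optional[int] = None


@dataclass(frozen=True)
class Bound:
    """A reactant instance attached to a contiguous run of enzyme nodes."""

    instance: ReactantInstance
    nodes: tuple[Node, ...]

    @property
    def kind(self) -> Kind:
        return self.instance.kind

    @property
    def uid(self) -> int:
        return self.instance.uid


def run_bracing(nodes: Iterable[Node]) -> frozenset[tuple[str, str]]:
    """Hinges braced by one instance bound at ``nodes``: each adjacent bound
    pair spans one hinge and braces it up (top site) or down (bottom)."""
    ordered = tuple(sorted(nodes))
    out = set()
    for pair in zip(ordered, ordered[1:]):
        if pair in HINGE_SPAN:
            out.add(HINGE_SPAN[pair])
    return frozenset(out)


def bracing_of(instance_nodes: Iterable[Node], kind: Kind) -> frozenset[tuple[str, str]]:
    """Bracing contributed by ``kind`` bound at ``instance_nodes``.

    Monovalent attachment braces nothing (a single bond is a flexible
    connection); each adjacent pair forms a triangle across its hinge.
    """
    nodes = tuple(sorted(instance_nodes))
    site = BINDING_NODES[kind]
    if not set(nodes) <= set(site):
        raise RuleViolation(f"{kind.value} cannot bind nodes {nodes}")
    if not _contiguous(nodes, site):
        raise RuleViolation(f"{kind.value} run {nodes} is not contiguous")
    return run_bracing(nodes)


def _contiguous(nodes: tuple[Node, ...], site: tuple[Node, ...]) -> bool:
    if not nodes:
        return False
    idx = sorted(site.index(n) for n in nodes)
    return idx == list(range(idx[0], idx[0] + len(idx)))


@dataclass(frozen=True)
class FeasibilityRules:
    """Forbidden bracing combinations (the geometric restriction table).

    Default: a hinge may not be braced up and down simultaneously — the two
    sides of the enzyme compete for each mechanical degree of freedom.  A
    user-supplied table can add or replace forbidden combinations.
    """

    forbidden: frozenset[frozenset[tuple[str, str]]] = frozenset(
        {
            frozenset({("h1", "up"), ("h1", "down")}),
            frozenset({("h2", "up"), ("h2", "down")}),
        }
    )

    @staticmethod
    def from_yaml(path) -> "FeasibilityRules":
        """Load forbidden combinations from a YAML list of lists of
        ``[hinge, direction]`` pairs."""
        with open(path) as fh:
            payload = yaml.safe_load(fh) or []
        combos = frozenset(
            frozenset((str(h), str(d)) for h, d in combo) for combo in payload
        )
        return FeasibilityRules(forbidden=combos)


DEFAULT_RULES = FeasibilityRules()


@dataclass(frozen=True)
class Microstate:
    """Occupancy of the six enzyme nodes by reactant instances."""

    bound: tuple[Bound, ...] = ()

    @staticmethod
    def create(bound: Iterable[Bound]) -> "Microstate":
        ordered = tuple(sorted(bound, key=lambda b: (ALL_NODES.index(b.nodes[0]))))
        ms = Microstate(ordered)
        ms.validate()
        return ms

    def validate(self) -> None:
        seen: set[Node] = set()
        uids: set[int] = set()
        for b in self.bound:
            site = BINDING_NODES[b.kind]
            nodes = tuple(sorted(b.nodes))
            if nodes != b.nodes:
                raise RuleViolation(f"run {b.nodes} must be listed in site order")
            if not set(nodes) <= set(site):
                raise RuleViolation(f"{b.kind.value} cannot bind nodes {nodes}")
            if not _contiguous(nodes, site):
                raise RuleViolation(f"{b.kind.value} run {nodes} is not contiguous")
            if seen & set(nodes):
                raise RuleViolation(f"nodes {seen & set(nodes)} doubly occupied")
            if b.uid in uids:
                raise RuleViolation(f"uid {b.uid} bound twice")
            seen |= set(nodes)
            uids.add(b.uid)

    # -- derived views ---------------------------------------------------

    def occupancy(self) -> dict[Node, Bound]:
        return {n: b for b in self.bound for n in b.nodes}

    def bracing(self) -> frozenset[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for b in self.bound:
            out |= run_bracing(b.nodes)
        return frozenset(out)

    def brace_states(self) -> dict[str, str]:
        """Per-hinge state in {'up', 'down', 'free'} (for rigidity export).

        Only meaningful for feasible states (at most one direction/hinge).
        """
        braces = {h: "free" for h in HINGES}
        for hinge, direction in self.bracing():
            braces[hinge] = direction
        return braces

    def canonical(self) -> tuple[tuple[str, tuple[Node, ...]], ...]:
        """Identity-free label: sorted (kind, run) pairs."""
        return tuple(sorted((b.kind.value, b.nodes) for b in self.bound))

    def macrostate(self) -> str:
        top = [b.kind.value for b in self.bound if b.nodes[0] in TOP_NODES]
        bottom = [b.kind.value for b in self.bound if b.nodes[0] in BOTTOM_NODES]
        if not top and not bottom:
            return "{}"
        if top and bottom:
            return "{" + ",".join(top) + "/" + ",".join(bottom) + "}"
        return "{" + ",".join(top or bottom) + "}"

    def instances(self, kind: Kind | None = None) -> list[Bound]:
        return [b for b in self.bound if kind is None or b.kind is kind]

    def free_nodes(self) -> list[Node]:
        occ = self.occupancy()
        return [n for n in ALL_NODES if n not in occ]

    def max_uid(self) -> int:
        return max((b.uid for b in self.bound), default=-1)


def is_feasible(ms: Microstate, rules: FeasibilityRules = DEFAULT_RULES) -> bool:
    """True iff the occupancy satisfies the binding rules.

    R1: every node is compatible with its occupant's kind; R2: each
    instance's nodes form a contiguous run; R3: no forbidden bracing
    combination (by default, no hinge braced both up and down).
    """
    try:
        ms.validate()
    except RuleViolation:
        return False
    braced = ms.bracing()
    return not any(combo <= braced for combo in rules.forbidden)


def microstate_from_runs(
    runs: Iterable[tuple[Kind | str, Iterable[Node]]], start_uid: int = 0
) -> Microstate:
    """Convenience constructor: build a microstate from (kind, nodes) pairs,
    assigning sequential uids."""
    bound = []
    uid = start_uid
    for kind, nodes in runs:
        bound.append(
            Bound(ReactantInstance(Kind(kind), uid), tuple(sorted(nodes)))
        )
        uid += 1
    return Microstate.create(bound)


# ---------------------------------------------------------------------------
# Transition generation (the six reaction types)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches of the reaction network.

    ``max_per_kind`` caps how many instances of a kind may be bound at once
    (e.g. ``{Kind.S: 1}`` forbids multi-substrate complexes and with it
    inhibitory saturation).  ``cleave_requires_trivalent`` restricts
    cleavage to fully bound substrate.  ``require_same_lineage`` permits
    ligation only between products of the same parent substrate.
    """

    max_per_kind: Mapping[Kind, int] | None = None
    cleave_requires_trivalent: bool = False
    require_same_lineage: bool = False
    rules: FeasibilityRules = DEFAULT_RULES

    def kind_cap(self, kind: Kind) -> int:
        if self.max_per_kind is None:
            return 10**9
        caps = {Kind(k): v for k, v in self.max_per_kind.items()}
        return caps.get(kind, 10**9)


DEFAULT_OPTIONS = ModelOptions()


@dataclass(frozen=True)
class Transition:
    """One elementary reaction out of a microstate."""

    rtype: Reaction
    rate_symbol: str
    rate: float
    new_state: Microstate
    kind: Kind
    #: node run of the affected instance before/after (None = unbound)
    from_nodes: Optional[tuple[Node, ...]]
    to_nodes: Optional[tuple[Node, ...]]
    #: uids consumed and produced by the reaction
    uids_before: tuple[int, ...]
    uids_after: tuple[int, ...]


def _without(ms: Microstate, drop: Bound, add: Iterable[Bound] = ()) -> Microstate:
    bound = [b for b in ms.bound if b is not drop] + list(add)
    return Microstate.create(bound)


def enumerate_transitions(
    ms: Microstate,
    rates: RateTable,
    options: ModelOptions = DEFAULT_OPTIONS,
    next_uid: int | None = None,
) -> list[Transition]:
    """All elementary reactions leaving ``ms``, with their propensities.

    Binding reactions are generated only when the resulting state is
    feasible; dissociations are always geometrically allowed.  Fresh
    instances receive uids from ``next_uid`` upward (default: one past the
    largest uid bound in ``ms``).
    """
    if not is_feasible(ms, options.rules):
        raise RuleViolation("cannot enumerate transitions of an infeasible state")
    uid = ms.max_uid() + 1 if next_uid is None else next_uid
    out: list[Transition] = []
    occ = ms.occupancy()
    counts = {k: len(ms.instances(k)) for k in Kind}

    # I: intermolecular binding — fresh monovalent attachment at any free
    # compatible node, pseudo-first-order in the reactant concentration.
    for kind in Kind:
        conc = rates.concentrations[kind]
        if conc <= 0 or counts[kind] >= options.kind_cap(kind):
            continue
        for node in BINDING_NODES[kind]:
            if node in occ:
                continue
            inst = Bound(ReactantInstance(kind, uid), (node,))
            new = Microstate.create(list(ms.bound) + [inst])
            if is_feasible(new, options.rules):
                out.append(
                    Transition(
                        Reaction.INTER_BIND,
                        f"k_{kind.value}_on",
                        rates.on_rate(kind),
                        new,
                        kind,
                        None,
                        (node,),
                        (),
                        (uid,),
                    )
                )

    for b in ms.bound:
        site = BINDING_NODES[b.kind]
        lo, hi = site.index(b.nodes[0]), site.index(b.nodes[-1])
        # II: intramolecular binding — extend the run by one adjacent node.
        for j in (lo - 1, hi + 1):
            if 0 <= j < len(site) and site[j] not in occ:
                new_nodes = tuple(sorted(b.nodes + (site[j],)))
                new = _without(ms, b, [Bound(b.instance, new_nodes)])
                if is_feasible(new, options.rules):
                    out.append(
                        Transition(
                            Reaction.INTRA_BIND,
                            "kuni",
                            rates.kuni,
                            new,
                            b.kind,
                            b.nodes,
                            new_nodes,
                            (b.uid,),
                            (b.uid,),
                        )
                    )
        # III / IV: release a terminal node of the run.
        terminals = {b.nodes[0], b.nodes[-1]}
        for node in sorted(terminals):
            remaining = tuple(n for n in b.nodes if n != node)
            if remaining:
                new = _without(ms, b, [Bound(b.instance, remaining)])
                rtype = Reaction.INTRA_DISS
            else:
                new = _without(ms, b)
                rtype = Reaction.INTER_DISS
            out.append(
                Transition(
                    rtype,
                    f"koff-{node}",
                    rates.koff[node],
                    new,
                    b.kind,
                    b.nodes,
                    remaining or None,
                    (b.uid,),
                    (b.uid,) if remaining else (),
                )
            )
        # V: cleavage — S bound at a and b splits at the catalytic moiety.
        if b.kind is Kind.S and {"a", "b"} <= set(b.nodes):
            if not (options.cleave_requires_trivalent and len(b.nodes) < 3):
                p1 = Bound(ReactantInstance(Kind.P1, uid, lineage=b.uid), ("a",))
                p2_nodes = tuple(n for n in b.nodes if n != "a")
                p2 = Bound(ReactantInstance(Kind.P2, uid + 1, lineage=b.uid), p2_nodes)
                new = _without(ms, b, [p1, p2])
                if is_feasible(new, options.rules):
                    out.append(
                        Transition(
                            Reaction.CLEAVAGE,
                            "kclv",
                            rates.kclv,
                            new,
                            Kind.S,
                            b.nodes,
                            None,
                            (b.uid,),
                            (uid, uid + 1),
                        )
                    )

    # VI: ligation — P1 at a and P2 holding b rejoin into S, geometrically
    # possible only while the left hinge is not braced down by ligand.
    for p1 in ms.instances(Kind.P1):
        for p2 in ms.instances(Kind.P2):
            if p2.nodes[0] != "b":
                continue
            if options.require_same_lineage and (
                p1.instance.lineage is None
                or p1.instance.lineage != p2.instance.lineage
            ):
                continue
            s_nodes = tuple(sorted(("a",) + p2.nodes))
            s = Bound(ReactantInstance(Kind.S, uid), s_nodes)
            bound = [x for x in ms.bound if x is not p1 and x is not p2] + [s]
            new = Microstate.create(bound)
            if is_feasible(new, options.rules):
                out.append(
                    Transition(
                        Reaction.LIGATION,
                        "klig",
                        rates.klig,
                        new,
                        Kind.S,
                        None,
                        s_nodes,
                        (p1.uid, p2.uid),
                        (uid,),
                    )
                )
    return out


__all__ = [
    "ALL_NODES",
    "BINDING_NODES",
    "BOTTOM_NODES",
    "Bound",
    "DEFAULT_OPTIONS",
    "DEFAULT_RULES",
    "FeasibilityRules",
    "HINGES",
    "HINGE_SPAN",
    "HierarchyReport",
    "Kind",
    "Microstate",
    "ModelOptions",
    "RateTable",
    "Reaction",
    "ReactantInstance",
    "RuleViolation",
    "TOP_NODES",
    "Transition",
    "bracing_of",
    "enumerate_transitions",
    "is_feasible",
    "microstate_from_runs",
    "node_energies",
    "run_bracing",
    "validate_rate_hierarchy",
]
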