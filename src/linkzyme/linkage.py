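"""2D bar-joint frameworks and generic rigidity analysis.

A linkage is modelled as a *framework*: a finite set of nodes joined by
rigid bars (distance constraints).  Pin joints that identify two nodes of
different rigid units are expressed as *merges* (node contraction), not as
zero-length bars, which keeps the constraint counting non-degenerate.

Rigidity here is generic/combinatorial: a framework is analysed through the
(2,3) pebble game, which computes the number of independent constraints of a
generic realisation and hence the number of internal floppy modes
(``2V - 3 - rank``).  No coordinates are stored; conformational change in
this model comes from adding or removing bars, never from strain.

The concrete linkages of the enzyme model are chains of rigid squares
connected at corner hinge nodes.  Each square is a 4-node quadrilateral with
one diagonal bar (generically rigid); a hinge between consecutive squares
can be braced "up" (a bar across the two top corners) or "down" (across the
two bottom corners), locking the hinge into a rigid triangle.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class BraceState(str, Enum):
    """Conformational state of one hinge of a square chain."""

    UP = "up"
    DOWN = "down"
    FREE = "free"


class RigidityClass(str, Enum):
    RIGID = "rigid"
    PARTIALLY_RIGID = "partially_rigid"
    FLEXIBLE = "flexible"


class ConfigurationError(ValueError):
    """Raised for ill-formed framework or brace specifications."""


@dataclass(frozen=True)
class Framework:
    """A bar-joint framework: nodes, bars and pin-joint merges.

    Parameters
    ----------
    nodes :
        Hashable node identifiers.
    bars :
        Unordered node pairs acting as distance constraints.
    merges :
        Pairs of nodes identified as a single pin joint.  Merges are applied
        (union-find contraction) before any rigidity computation.
    """

    nodes: frozenset = field(default_factory=frozenset)
    bars: frozenset = field(default_factory=frozenset)
    merges: frozenset = field(default_factory=frozenset)

    @staticmethod
    def create(nodes: Iterable, bars: Iterable, merges: Iterable = ()) -> "Framework":
        nodes = frozenset(nodes)
        bars = frozenset(frozenset(b) for b in bars)
        merges = frozenset(frozenset(m) for m in merges)
        for b in bars:
            if len(b) != 2:
                raise ConfigurationError(f"bar {set(b)} must join two distinct nodes")
            if not b <= nodes:
                raise ConfigurationError(f"bar {set(b)} references unknown nodes")
        for m in merges:
            if len(m) != 2 or not m <= nodes:
                raise ConfigurationError(f"merge {set(m)} is not a pair of known nodes")
        fw = Framework(nodes, bars, merges)
        # self-bars after contraction violate the framework invariant
        rep = fw._representatives()
        for b in bars:
            u, v = tuple(b)
            if rep[u] == rep[v]:
                raise ConfigurationError(
                    f"bar {set(b)} joins a node to itself after merges"
                )
        return fw

    def _representatives(self) -> dict:
        parent = {v: v for v in self.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m in self.merges:
            u, v = tuple(m)
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        return {v: find(v) for v in self.nodes}

    def contracted(self) -> tuple[list, list[tuple]]:
        """Apply merges; return (nodes, bars) of the contracted simple graph."""
        rep = self._representatives()
        nodes = sorted(set(rep.values()), key=repr)
        bars = set()
        for b in self.bars:
            u, v = tuple(b)
            ru, rv = rep[u], rep[v]
            if ru != rv:
                bars.add(frozenset((ru, rv)))
        return nodes, [tuple(sorted(b, key=repr)) for b in sorted(bars, key=repr)]

    def with_bars(self, extra: Iterable) -> "Framework":
        return Framework.create(
            self.nodes, set(self.bars) | {frozenset(b) for b in extra}, self.merges
        )

    # -- export ----------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": sorted(self.nodes, key=repr),
            "bars": sorted([sorted(b, key=repr) for b in self.bars], key=repr),
            "merges": sorted([sorted(m, key=repr) for m in self.merges], key=repr),
        }
        return json.dumps(payload, indent=1, default=str)

    @staticmethod
    def from_json(text: str) -> "Framework":
        payload = json.loads(text)
        return Framework.create(
            [_maybe_tuple(n) for n in payload["nodes"]],
            [tuple(_maybe_tuple(x) for x in b) for b in payload["bars"]],
            [tuple(_maybe_tuple(x) for x in m) for m in payload["merges"]],
        )

    def to_dot(self) -> str:
        lines = ["graph framework {"]
        nodes, bars = self.contracted()
        for n in nodes:
            lines.append(f'  "{n}";')
        for u, v in bars:
            lines.append(f'  "{u}" -- "{v}";')
        lines.append("}")
        return "\n".join(lines)


def _maybe_tuple(x):
    return tuple(x) if isinstance(x, list) else x


@dataclass(frozen=True)
class RigidityReport:
    internal_dof: int
    rigid_components: tuple[frozenset, ...]
    rigidity_class: RigidityClass


# ---------------------------------------------------------------------------
# (2,3) pebble game
# ---------------------------------------------------------------------------


class _PebbleGame:
    """Lee–Streinu (2,3) pebble game on a simple graph.

    Every vertex starts with two pebbles; inserting an independent edge
    consumes one.  An edge is independent iff four pebbles can be gathered
    on its endpoints.  The number of accepted edges is the rank of the
    generic 2D rigidity matroid restricted to the given edge set.
    """

    def __init__(self, vertices: Sequence):
        self.pebbles = {v: 2 for v in vertices}
        self.out: dict = {v: set() for v in vertices}

    def _search_pebble(self, roots: tuple) -> bool:
        """DFS for a free pebble reachable from ``roots``; reverse the path."""
        seen = set(roots)
        stack = [(r, iter(self.out[r])) for r in roots]
        parent: dict = {}
        while stack:
            v, it = stack[-1]
            found = None
            for w in it:
                if w in seen:
                    continue
                seen.add(w)
                parent[w] = v
                if self.pebbles[w] > 0:
                    found = w
                    break
                stack.append((w, iter(self.out[w])))
                break
            else:
                stack.pop()
                continue
            if found is not None:
                # reverse edges along the path, moving the pebble to a root
                w = found
                self.pebbles[w] -= 1
                while w in parent:
                    v = parent[w]
                    self.out[w].add(v)
                    self.out[v].discard(w)
                    w = v
                self.pebbles[w] += 1
                return True
        return False

    def can_gather_four(self, u, v) -> bool:
        while self.pebbles[u] + self.pebbles[v] < 4:
            if not self._search_pebble((u, v)):
                return False
        return True

    def try_insert(self, u, v) -> bool:
        if self.can_gather_four(u, v):
            self.pebbles[u] -= 1
            self.out[u].add(v)
            return True
        return False

    def snapshot(self) -> tuple:
        return (
            dict(self.pebbles),
            {v: set(s) for v, s in self.out.items()},
        )

    def restore(self, snap: tuple) -> None:
        self.pebbles, self.out = {k: v for k, v in snap[0].items()}, {
            k: set(s) for k, s in snap[1].items()
        }


def _played_game(nodes: Sequence, bars: Sequence[tuple]) -> tuple[_PebbleGame, int]:
    game = _PebbleGame(nodes)
    rank = sum(1 for u, v in bars if game.try_insert(u, v))
    return game, rank


def _require_connected(nodes: Sequence, bars: Sequence[tuple]) -> None:
    if not nodes:
        raise ConfigurationError("empty framework")
    adj: dict = {v: [] for v in nodes}
    for u, v in bars:
        adj[u].append(v)
        adj[v].append(u)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(nodes):
        raise ConfigurationError(
            "framework is disconnected; analyze components separately"
        )


def count_internal_dof(fw: Framework) -> int:
    """Internal floppy modes of a connected framework.

    Excludes the three planar rigid-body motions: returns
    ``max(0, 2V - 3 - rank)`` with the rank computed by the (2,3) pebble
    game on the merge-contracted graph.  A single node has zero internal
    degrees of freedom.
    """
    nodes, bars = fw.contracted()
    _require_connected(nodes, bars)
    if len(nodes) == 1:
        return 0
    _, rank = _played_game(nodes, bars)
    return max(0, 2 * len(nodes) - 3 - rank)


def _rigidly_linked(game: _PebbleGame, u, v) -> bool:
    """True iff adding bar (u, v) would be redundant (dependent)."""
    snap = game.snapshot()
    ok = game.can_gather_four(u, v)
    game.restore(snap)
    return not ok


def rigid_components(fw: Framework) -> tuple[frozenset, ...]:
    """Maximal rigid clusters of nodes (clusters may share hinge nodes).

    Two nodes belong to a common cluster when the bar between them is
    present or would be generically redundant.  Isolated contracted nodes
    form singleton clusters so that the clusters cover every node.
    """
    nodes, bars = fw.contracted()
    game, _ = _played_game(nodes, bars)
    linked = {}

    def is_linked(x, y):
        key = (x, y) if repr(x) < repr(y) else (y, x)
        if key not in linked:
            linked[key] = frozenset((x, y)) in {frozenset(b) for b in bars} or (
                _rigidly_linked(game, x, y)
            )
        return linked[key]

    clusters: list[frozenset] = []
    for u, v in bars:
        members = {u, v}
        for w in nodes:
            if w in members:
                continue
            if is_linked(u, w) and is_linked(v, w):
                members.add(w)
        clusters.append(frozenset(members))
    # deduplicate and keep subset-maximal clusters
    uniq = sorted(set(clusters), key=len, reverse=True)
    maximal: list[frozenset] = []
    for c in uniq:
        if not any(c < m for m in maximal):
            maximal.append(c)
    covered = set().union(*maximal) if maximal else set()
    for n in nodes:
        if n not in covered:
            maximal.append(frozenset((n,)))
    return tuple(sorted(maximal, key=lambda c: (-len(c), repr(sorted(c, key=repr)))))


def analyze(fw: Framework, flexible_dof: int | None = None) -> RigidityReport:
    """Full rigidity report for a connected framework.

    ``flexible_dof`` is the mode count of the fully floppy reference
    conformation (for a square chain, its number of free hinges); when given,
    intermediate mode counts are classified as partially rigid.  Without a
    reference, any framework with internal modes is reported flexible.
    """
    dof = count_internal_dof(fw)
    if dof == 0:
        cls = RigidityClass.RIGID
    elif flexible_dof is not None and dof < flexible_dof:
        cls = RigidityClass.PARTIALLY_RIGID
    else:
        cls = RigidityClass.FLEXIBLE
    return RigidityReport(dof, rigid_components(fw), cls)


# ---------------------------------------------------------------------------
# Square chains (the three-state switch and its concatenations)
# ---------------------------------------------------------------------------

#: Corner roles of one square, drawn as a diamond: left, top, right, bottom.
_CORNERS = ("L", "T", "R", "B")


def build_square_chain(
    n_squares: int, braces: Sequence[BraceState | str] = ()
) -> Framework:
    """Chain of generically rigid squares sharing corner hinge nodes.

    Square ``i`` has corners ``(i, 'L'|'T'|'R'|'B')`` with its four edges
    plus one diagonal, making it an isostatic rigid unit.  The right corner
    of square ``i`` is pin-merged with the left corner of square ``i+1``;
    that shared node is hinge ``i``.  Brace ``up``/``down`` at hinge ``i``
    adds a bar between the two top/bottom corners flanking the hinge,
    forming a rigid triangle across it; ``free`` adds nothing.
    """
    if n_squares < 1:
        raise ConfigurationError("need at least one square")
    braces = [BraceState(b) for b in braces]
    if len(braces) != n_squares - 1:
        raise ConfigurationError(
            f"expected {n_squares - 1} brace states for {n_squares} squares, "
            f"got {len(braces)}"
        )
    nodes = [(i, c) for i in range(n_squares) for c in _CORNERS]
    bars = []
    for i in range(n_squares):
        L, T, R, B = ((i, c) for c in _CORNERS)
        bars += [(L, T), (T, R), (R, B), (B, L), (L, R)]  # edges + diagonal
    merges = [((i, "R"), (i + 1, "L")) for i in range(n_squares - 1)]
    for i, b in enumerate(braces):
        if b is BraceState.UP:
            bars.append(((i, "T"), (i + 1, "T")))
        elif b is BraceState.DOWN:
            bars.append(((i, "B"), (i + 1, "B")))
    return Framework.create(nodes, bars, merges)


def enumerate_brace_states(
    n_squares: int,
) -> list[tuple[tuple[BraceState, ...], RigidityClass]]:
    """All per-hinge brace assignments of a square chain, classified.

    A chain with every hinge braced is rigid; every hinge free, flexible;
    anything in between, partially rigid.  The classification is computed
    from the pebble-game mode count, not inferred from the brace labels.
    """
    n_hinges = n_squares - 1
    out = []
    for combo in itertools.product(
        (BraceState.UP, BraceState.DOWN, BraceState.FREE), repeat=n_hinges
    ):
        fw = build_square_chain(n_squares, combo)
        report = analyze(fw, flexible_dof=n_hinges)
        out.append((combo, report.rigidity_class))
    return out


__all__ = [
    "BraceState",
    "ConfigurationError",
    "Framework",
    "RigidityClass",
    "RigidityReport",
    "analyze",
    "build_square_chain",
    "count_internal_dof",
    "enumerate_brace_states",
    "rigid_components",
]
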