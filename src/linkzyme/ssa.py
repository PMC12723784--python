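"""Exact stochastic simulation of a single enzyme.

The enzyme's reaction rules define a finite continuous-time Markov chain
over canonical microstates.  The chain is compiled once per structural
option set — states, edges, and *reaction channels* (a channel is one
elementary reaction, keyed by its type, reactant kind and node runs; the
same channel may be enabled in many states) — and then sampled exactly.

Two samplers are provided:

* :func:`run` — the next reaction method: every channel owns a named,
  independently seeded random stream and a tentative absolute firing time;
  a channel that stays enabled with an unchanged propensity across events
  keeps its clock, a newly enabled (or refired) channel draws a fresh
  exponential.  This is the production sampler.
* :func:`run_direct` — the Gillespie direct method over the same compiled
  chain, used as an independent cross-check in the test suite.

On top of the canonical-state chain the engine tracks reactant *instance*
identities: which ligand copy is bound, and which substrate a product pair
descends from (lineage).  These identities do not affect the kinetics in
buffered mode; they exist so that turnover events can be attributed to
pathways afterwards.
"""

from __future__ import annotations

import csv
import gzip
import heapq
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import yaml

from .network import EMPTY_STATE, CanonicalState, state_from_label, state_label
from .species import (
    DEFAULT_OPTIONS,
    Kind,
    ModelOptions,
    RateTable,
    Reaction,
    ReactantInstance,
    RuleViolation,
    enumerate_transitions,
    microstate_from_runs,
)

Run = tuple[str, ...]


# ---------------------------------------------------------------------------
# Compiled network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Edge:
    channel: int
    target: int
    rtype: Reaction
    symbol: str
    kind: Kind
    from_nodes: Optional[Run]
    to_nodes: Optional[Run]


class CompiledNetwork:
    """State space and channel table for a fixed set of structural options.

    Compiled with every reactant kind present, so a single compilation
    serves any concentration vector (including zero concentrations: the
    corresponding binding channels simply have zero propensity).
    """

    def __init__(self, options: ModelOptions = DEFAULT_OPTIONS, max_states: int = 50_000):
        self.options = options
        probe = RateTable()
        probe.concentrations = {k: 1.0 for k in Kind}
        self.states: list[CanonicalState] = []
        self.state_index: dict[CanonicalState, int] = {}
        self.edges: list[list[_Edge]] = []
        self.channel_key: list[tuple] = []
        self.channel_symbol: list[str] = []
        self._chan_index: dict[tuple, int] = {}

        def intern_state(c: CanonicalState) -> int:
            if c not in self.state_index:
                if len(self.states) >= max_states:
                    raise RuntimeError(f"state space exceeded {max_states} states")
                self.state_index[c] = len(self.states)
                self.states.append(c)
                self.edges.append([])
            return self.state_index[c]

        frontier = [intern_state(EMPTY_STATE)]
        explored = set()
        while frontier:
            si = frontier.pop()
            if si in explored:
                continue
            explored.add(si)
            ms = microstate_from_runs(self.states[si])
            for tr in enumerate_transitions(ms, probe, options, next_uid=len(ms.bound)):
                tgt = tr.new_state.canonical()
                known = tgt in self.state_index
                ti = intern_state(tgt)
                if not known:
                    frontier.append(ti)
                ckey = (tr.rtype.value, tr.kind.value, tr.from_nodes, tr.to_nodes)
                if ckey not in self._chan_index:
                    self._chan_index[ckey] = len(self.channel_key)
                    self.channel_key.append(ckey)
                    self.channel_symbol.append(tr.rate_symbol)
                self.edges[si].append(
                    _Edge(
                        self._chan_index[ckey],
                        ti,
                        tr.rtype,
                        tr.rate_symbol,
                        tr.kind,
                        tr.from_nodes,
                        tr.to_nodes,
                    )
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_channels(self) -> int:
        return len(self.channel_key)

    def symbol_rates(self, rates: RateTable, copies: dict[Kind, float] | None = None) -> np.ndarray:
        """Per-channel propensities for a rate table (buffered mode), or for
        explicit free-copy counts expressed in concentration units."""
        conc = {k: rates.concentrations[k] for k in Kind} if copies is None else copies
        out = np.empty(self.n_channels)
        for i, (rtype, kind, _, _) in enumerate(self.channel_key):
            sym = self.channel_symbol[i]
            if rtype == Reaction.INTER_BIND.value:
                out[i] = rates.c_on * conc[Kind(kind)]
            elif sym == "kuni":
                out[i] = rates.kuni
            elif sym == "kclv":
                out[i] = rates.kclv
            elif sym == "klig":
                out[i] = rates.klig
            else:  # koff-<node>
                out[i] = rates.koff[sym.split("-")[1]]
        return out


_NETWORK_CACHE: dict[tuple, CompiledNetwork] = {}


def compiled_network(options: ModelOptions = DEFAULT_OPTIONS) -> CompiledNetwork:
    key = (
        None
        if options.max_per_kind is None
        else tuple(sorted((Kind(k).value, v) for k, v in options.max_per_kind.items())),
        options.cleave_requires_trivalent,
        options.require_same_lineage,
        options.rules,
    )
    if key not in _NETWORK_CACHE:
        _NETWORK_CACHE[key] = CompiledNetwork(options)
    return _NETWORK_CACHE[key]


# ---------------------------------------------------------------------------
# Configuration, events, trajectories
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Settings for one stochastic run.

    ``mode='buffered'`` holds reactant concentrations constant (one enzyme
    in a large reservoir); ``mode='finite_copies'`` converts concentrations
    to integer copy numbers via ``copies_per_uM`` and updates them as
    reactants bind, unbind, cleave and ligate.
    """

    rates: RateTable = field(default_factory=RateTable)
    options: ModelOptions = DEFAULT_OPTIONS
    t_end: float = 100.0
    max_events: Optional[int] = None
    seed: int = 0
    mode: str = "buffered"  # or 'finite_copies'
    copies_per_uM: float = 1.0
    record_events: bool = True
    initial_state: CanonicalState = EMPTY_STATE

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.mode not in ("buffered", "finite_copies"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "t_end": self.t_end,
            "max_events": self.max_events,
            "seed": self.seed,
            "mode": self.mode,
            "copies_per_uM": self.copies_per_uM,
            "initial_state": state_label(self.initial_state),
            "options": {
                "max_per_kind": None
                if self.options.max_per_kind is None
                else {Kind(k).value: v for k, v in self.options.max_per_kind.items()},
                "cleave_requires_trivalent": self.options.cleave_requires_trivalent,
                "require_same_lineage": self.options.require_same_lineage,
            },
        }

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        opts = d.get("options") or {}
        options = ModelOptions(
            max_per_kind=None
            if opts.get("max_per_kind") is None
            else {Kind(k): int(v) for k, v in opts["max_per_kind"].items()},
            cleave_requires_trivalent=bool(opts.get("cleave_requires_trivalent", False)),
            require_same_lineage=bool(opts.get("require_same_lineage", False)),
        )
        return SimulationConfig(
            rates=RateTable.from_dict(d.get("rates", {})),
            options=options,
            t_end=float(d.get("t_end", 100.0)),
            max_events=d.get("max_events"),
            seed=int(d.get("seed", 0)),
            mode=d.get("mode", "buffered"),
            copies_per_uM=float(d.get("copies_per_uM", 1.0)),
            initial_state=state_from_label(d.get("initial_state", "empty")),
        )

    @staticmethod
    def from_yaml(path) -> "SimulationConfig":
        with open(path) as fh:
            return SimulationConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True, slots=True)
class Event:
    """One elementary reaction in a trajectory."""

    time: float
    rtype: Reaction
    symbol: str
    kind: Kind
    from_nodes: Optional[Run]
    to_nodes: Optional[Run]
    uids_before: tuple[int, ...]
    uids_after: tuple[int, ...]
    lineage: Optional[int] = None  # parent-S uid, on cleavage events


@dataclass
class Trajectory:
    """Event log of one stochastic run (replayable when events recorded)."""

    config: SimulationConfig
    initial_state: CanonicalState
    events: Optional[list[Event]]
    final_state: CanonicalState
    duration: float  # simulated time actually covered
    n_events: int
    stopped_by: str  # 't_end' | 'max_events' | 'absorbing'

    def replay(self) -> CanonicalState:
        """Reapply every event from the initial state, verifying consistency;
        returns the reconstructed final canonical state."""
        if self.events is None:
            raise RuleViolation("trajectory was run without event recording")
        mirror = _Mirror(self.initial_state)
        last_t = -np.inf
        for ev in self.events:
            if ev.time < last_t:
                raise RuleViolation("event times are not non-decreasing")
            last_t = ev.time
            mirror.apply(ev)
        final = mirror.canonical()
        if final != self.final_state:
            raise RuleViolation("replay does not reproduce the final state")
        return final


class _Mirror:
    """Occupancy mirror keyed by node run; shared by replay and analysis."""

    def __init__(self, initial: CanonicalState = EMPTY_STATE):
        self.bound: dict[Run, ReactantInstance] = {}
        for i, (kind, run) in enumerate(initial):
            self.bound[tuple(run)] = ReactantInstance(Kind(kind), i)

    def apply(self, ev: Event) -> None:
        t = ev.rtype
        if t is Reaction.INTER_BIND:
            self.bound[ev.to_nodes] = ReactantInstance(ev.kind, ev.uids_after[0])
        elif t in (Reaction.INTRA_BIND, Reaction.INTRA_DISS):
            inst = self.bound.pop(ev.from_nodes)
            if inst.uid != ev.uids_before[0]:
                raise RuleViolation(f"uid mismatch at t={ev.time}")
            self.bound[ev.to_nodes] = inst
        elif t is Reaction.INTER_DISS:
            inst = self.bound.pop(ev.from_nodes)
            if inst.uid != ev.uids_before[0]:
                raise RuleViolation(f"uid mismatch at t={ev.time}")
        elif t is Reaction.CLEAVAGE:
            s = self.bound.pop(ev.from_nodes)
            if s.uid != ev.uids_before[0]:
                raise RuleViolation(f"uid mismatch at t={ev.time}")
            p2_nodes = tuple(n for n in ev.from_nodes if n != "a")
            self.bound[("a",)] = ReactantInstance(Kind.P1, ev.uids_after[0], s.uid)
            self.bound[p2_nodes] = ReactantInstance(Kind.P2, ev.uids_after[1], s.uid)
        elif t is Reaction.LIGATION:
            p2_nodes = tuple(n for n in ev.to_nodes if n != "a")
            p1 = self.bound.pop(("a",))
            p2 = self.bound.pop(p2_nodes)
            if (p1.uid, p2.uid) != ev.uids_before:
                raise RuleViolation(f"uid mismatch at t={ev.time}")
            self.bound[ev.to_nodes] = ReactantInstance(Kind.S, ev.uids_after[0])
        else:  # pragma: no cover
            raise RuleViolation(f"unknown reaction type {t}")

    def canonical(self) -> CanonicalState:
        return tuple(sorted((inst.kind.value, run) for run, inst in self.bound.items()))

    def instances_of(self, kind: Kind) -> list[tuple[Run, ReactantInstance]]:
        return [(r, i) for r, i in self.bound.items() if i.kind is kind]


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


class _ChannelStreams:
    """One named exponential stream per reaction channel (NRM requirement).

    Stream ``i`` is seeded from ``SeedSequence(seed, spawn_key=(i,))``,
    making every channel's clock sequence reproducible independently of
    the firing order of other channels.
    """

    def __init__(self, seed: int, n_channels: int):
        self.seed = seed
        self._gens: list = [None] * n_channels
        self._bufs: list = [None] * n_channels

    def exponential(self, ch: int) -> float:
        buf = self._bufs[ch]
        if not buf:
            gen = self._gens[ch]
            if gen is None:
                gen = np.random.Generator(
                    np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(ch,)))
                )
                self._gens[ch] = gen
            buf = self._bufs[ch] = gen.standard_exponential(64).tolist()
        return buf.pop()


class _RunState:
    """Bookkeeping shared by both samplers."""

    def __init__(self, config: SimulationConfig, net: CompiledNetwork):
        self.config = config
        self.net = net
        self.state = net.state_index[config.initial_state]
        self.mirror = _Mirror(config.initial_state)
        self.next_uid = len(config.initial_state)
        self.events: Optional[list[Event]] = [] if config.record_events else None
        self.n_events = 0
        self.finite = config.mode == "finite_copies"
        if self.finite:
            self.copies = {
                k: int(round(config.rates.concentrations[k] * config.copies_per_uM))
                for k in Kind
            }
        else:
            self.copies = None

    def free_conc(self) -> dict[Kind, float]:
        return {k: self.copies[k] / self.config.copies_per_uM for k in Kind}

    def apply_edge(self, t: float, edge: _Edge, observers) -> Event:
        uids_before: tuple[int, ...]
        uids_after: tuple[int, ...]
        lineage = None
        rt = edge.rtype
        if rt is Reaction.INTER_BIND:
            uids_before = ()
            uids_after = (self.next_uid,)
            self.next_uid += 1
            if self.finite:
                self.copies[edge.kind] -= 1
        elif rt in (Reaction.INTRA_BIND, Reaction.INTRA_DISS):
            inst = self.mirror.bound[edge.from_nodes]
            uids_before = uids_after = (inst.uid,)
        elif rt is Reaction.INTER_DISS:
            inst = self.mirror.bound[edge.from_nodes]
            uids_before = (inst.uid,)
            uids_after = ()
            if self.finite:
                self.copies[edge.kind] += 1
        elif rt is Reaction.CLEAVAGE:
            s = self.mirror.bound[edge.from_nodes]
            uids_before = (s.uid,)
            uids_after = (self.next_uid, self.next_uid + 1)
            self.next_uid += 2
            lineage = s.uid
        else:  # LIGATION
            p2_nodes = tuple(n for n in edge.to_nodes if n != "a")
            uids_before = (
                self.mirror.bound[("a",)].uid,
                self.mirror.bound[p2_nodes].uid,
            )
            uids_after = (self.next_uid,)
            self.next_uid += 1
        ev = Event(
            t,
            rt,
            edge.symbol,
            edge.kind,
            edge.from_nodes,
            edge.to_nodes,
            uids_before,
            uids_after,
            lineage,
        )
        self.mirror.apply(ev)
        self.state = edge.target
        self.n_events += 1
        if self.events is not None:
            self.events.append(ev)
        for obs in observers:
            obs(ev)
        return ev

    def ligation_allowed(self, edge: _Edge) -> bool:
        p2_nodes = tuple(n for n in edge.to_nodes if n != "a")
        p1 = self.mirror.bound[("a",)]
        p2 = self.mirror.bound[p2_nodes]
        return p1.lineage is not None and p1.lineage == p2.lineage

    def finish(self, duration: float, stopped_by: str) -> Trajectory:
        return Trajectory(
            self.config,
            self.config.initial_state,
            self.events,
            self.net.states[self.state],
            duration,
            self.n_events,
            stopped_by,
        )


Observer = Callable[[Event], None]


def run(
    config: SimulationConfig, observers: Iterable[Observer] = ()
) -> Trajectory:
    """Sample one exact trajectory with the next reaction method."""
    net = compiled_network(config.options)
    if config.initial_state not in net.state_index:
        raise RuleViolation("initial state is not in the reachable state space")
    rs = _RunState(config, net)
    observers = tuple(observers)
    rates = net.symbol_rates(
        config.rates, rs.free_conc() if rs.finite else None
    )
    gate_lineage = config.options.require_same_lineage
    is_bind = [
        key[0] == Reaction.INTER_BIND.value for key in net.channel_key
    ]
    bind_kind = [
        Kind(key[1]) if b else None for key, b in zip(net.channel_key, is_bind)
    ]

    streams = _ChannelStreams(config.seed, net.n_channels)
    incarnation = [0] * net.n_channels
    heap: list[tuple[float, int, int]] = []
    enabled: set[int] = set()
    edge_by_channel = [
        {e.channel: e for e in net.edges[si]} for si in range(net.n_states)
    ]
    state_channels = [frozenset(d) for d in edge_by_channel]

    t = 0.0
    max_events = config.max_events or np.inf

    def allowed(ch: int) -> bool:
        if rates[ch] <= 0.0:
            return False
        if gate_lineage:
            e = edge_by_channel[rs.state][ch]
            if e.rtype is Reaction.LIGATION and not rs.ligation_allowed(e):
                return False
        return True

    def enable(ch: int) -> None:
        enabled.add(ch)
        incarnation[ch] += 1
        dt = streams.exponential(ch) / rates[ch]
        heapq.heappush(heap, (t + dt, ch, incarnation[ch]))

    for ch in state_channels[rs.state]:
        if allowed(ch):
            enable(ch)

    stopped_by = "t_end"
    while True:
        if rs.n_events >= max_events:
            stopped_by = "max_events"
            break
        # next valid firing
        fire = None
        while heap:
            tf, ch, tok = heap[0]
            if ch in enabled and tok == incarnation[ch]:
                fire = (tf, ch)
                break
            heapq.heappop(heap)
        if fire is None:
            stopped_by = "absorbing"
            break
        tf, ch = fire
        if tf > config.t_end:
            break
        heapq.heappop(heap)
        t = tf
        old_set = state_channels[rs.state]
        edge = edge_by_channel[rs.state][ch]
        rs.apply_edge(t, edge, observers)
        new_set = state_channels[rs.state]
        if rs.finite and edge.rtype in (Reaction.INTER_BIND, Reaction.INTER_DISS):
            # copy count of edge.kind changed: rescale its binding channels
            conc = rs.free_conc()
            for i in range(net.n_channels):
                if is_bind[i] and bind_kind[i] is edge.kind:
                    rates[i] = config.rates.c_on * conc[edge.kind]
                    if i in enabled:
                        enabled.discard(i)
                        if rates[i] > 0 and i in new_set:
                            enable(i)
        # the fired channel always redraws; channels that stay enabled with an
        # unchanged propensity keep their scheduled clocks
        enabled.discard(ch)
        for c in old_set - new_set:
            enabled.discard(c)
        for c in new_set:
            if c not in enabled and allowed(c):
                enable(c)

    duration = min(t, config.t_end) if stopped_by != "t_end" else config.t_end
    return rs.finish(duration, stopped_by)


def run_direct(
    config: SimulationConfig, observers: Iterable[Observer] = ()
) -> Trajectory:
    """Sample one exact trajectory with the Gillespie direct method.

    Cross-validation oracle for :func:`run`; both sample the same chain.
    """
    net = compiled_network(config.options)
    if config.initial_state not in net.state_index:
        raise RuleViolation("initial state is not in the reachable state space")
    rs = _RunState(config, net)
    observers = tuple(observers)
    rates = net.symbol_rates(config.rates, rs.free_conc() if rs.finite else None)
    gate_lineage = config.options.require_same_lineage
    gen = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(2**20,)))
    )
    t = 0.0
    max_events = config.max_events or np.inf
    stopped_by = "t_end"
    while True:
        if rs.n_events >= max_events:
            stopped_by = "max_events"
            break
        edges = net.edges[rs.state]
        active = []
        props = []
        for e in edges:
            r = rates[e.channel]
            if r <= 0.0:
                continue
            if (
                gate_lineage
                and e.rtype is Reaction.LIGATION
                and not rs.ligation_allowed(e)
            ):
                continue
            active.append(e)
            props.append(r)
        if not active:
            stopped_by = "absorbing"
            break
        total = float(np.sum(props))
        t_next = t + gen.standard_exponential() / total
        if t_next > config.t_end:
            break
        t = t_next
        u = gen.random() * total
        acc = 0.0
        chosen = active[-1]
        for e, r in zip(active, props):
            acc += r
            if u <= acc:
                chosen = e
                break
        rs.apply_edge(t, chosen, observers)
        if rs.finite and chosen.rtype in (Reaction.INTER_BIND, Reaction.INTER_DISS):
            conc = rs.free_conc()
            for i in range(net.n_channels):
                key = net.channel_key[i]
                if key[0] == Reaction.INTER_BIND.value and Kind(key[1]) is chosen.kind:
                    rates[i] = config.rates.c_on * conc[chosen.kind]

    duration = min(t, config.t_end) if stopped_by != "t_end" else config.t_end
    return rs.finish(duration, stopped_by)


def occupancy_times(traj: Trajectory) -> dict[CanonicalState, float]:
    """Total time spent in each canonical state over ``[0, duration]``."""
    if traj.events is None:
        raise RuleViolation("trajectory was run without event recording")
    out: dict[CanonicalState, float] = {}
    mirror = _Mirror(traj.initial_state)
    t_prev = 0.0
    state = traj.initial_state
    for ev in traj.events:
        out[state] = out.get(state, 0.0) + (ev.time - t_prev)
        mirror.apply(ev)
        state = mirror.canonical()
        t_prev = ev.time
    out[state] = out.get(state, 0.0) + max(0.0, traj.duration - t_prev)
    return out


# ---------------------------------------------------------------------------
# Trajectory persistence (CSV events + JSON header)
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "time",
    "rtype",
    "symbol",
    "kind",
    "from_nodes",
    "to_nodes",
    "uids_before",
    "uids_after",
    "lineage",
]


def _opener(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def save_trajectory(traj: Trajectory, csv_path, header_path=None) -> None:
    """Write events to CSV (optionally gzipped) plus a JSON sidecar header
    with the full configuration and run summary."""
    if traj.events is None:
        raise RuleViolation("trajectory was run without event recording")
    header_path = header_path or str(csv_path) + ".json"
    header = {
        "config": traj.config.to_dict(),
        "initial_state": state_label(traj.initial_state),
        "final_state": state_label(traj.final_state),
        "duration": traj.duration,
        "n_events": traj.n_events,
        "stopped_by": traj.stopped_by,
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=1)
    with _opener(csv_path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for ev in traj.events:
            w.writerow(
                [
                    repr(float(ev.time)),
                    ev.rtype.value,
                    ev.symbol,
                    ev.kind.value,
                    "".join(ev.from_nodes or ()),
                    "".join(ev.to_nodes or ()),
                    ";".join(map(str, ev.uids_before)),
                    ";".join(map(str, ev.uids_after)),
                    "" if ev.lineage is None else ev.lineage,
                ]
            )


def load_trajectory(csv_path, header_path=None) -> Trajectory:
    header_path = header_path or str(csv_path) + ".json"
    with open(header_path) as fh:
        header = json.load(fh)
    config = SimulationConfig.from_dict(header["config"])
    events = []
    with _opener(csv_path, "r") as fh:
        for row in csv.DictReader(fh):
            events.append(
                Event(
                    float(row["time"]),
                    Reaction(row["rtype"]),
                    row["symbol"],
                    Kind(row["kind"]),
                    tuple(row["from_nodes"]) or None,
                    tuple(row["to_nodes"]) or None,
                    tuple(int(x) for x in row["uids_before"].split(";") if x),
                    tuple(int(x) for x in row["uids_after"].split(";") if x),
                    None if row["lineage"] == "" else int(row["lineage"]),
                )
            )
    return Trajectory(
        config,
        state_from_label(header["initial_state"]),
        events,
        state_from_label(header["final_state"]),
        float(header["duration"]),
        int(header["n_events"]),
        header["stopped_by"],
    )


__all__ = [
    "CompiledNetwork",
    "Event",
    "Observer",
    "SimulationConfig",
    "Trajectory",
    "compiled_network",
    "load_trajectory",
    "run",
    "run_direct",
    "save_trajectory",
]
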