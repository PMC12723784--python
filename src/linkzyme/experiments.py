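"""Config-driven computational experiments on the linkage machine.

Three preset sweeps probe the machine's operating regime:

* **substrate sweep** — turnover, ligand activation A and efficiency E
  over a logarithmic range of substrate concentration at fixed ligand
  concentration, with paired ligand/no-ligand runs sharing seeds;
* **cleavage sweep** — pathway fractions as the cleavage rate ``kclv`` is
  scanned past the ligand off rates (entry into the idling silo);
* **ligation sweep** — total turnover as the ligation rate ``klig`` is
  scanned past ``koff-a`` (entry into the catalysis silo).

Each grid point is simulated in several independent replicates; aggregate
tables carry replicate counts and standard errors.  CSV tables are the
output contract; plotting is left to downstream scripts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import network
from .species import DEFAULT_OPTIONS, Kind, ModelOptions, RateTable
from .ssa import Event, SimulationConfig, run
from .turnover import (
    MetricsReport,
    PATHWAYS,
    TurnoverClassifier,
    compute_metrics,
    efficiency,
    ligand_activation,
)

log = logging.getLogger("linkzyme")


def measure(config: SimulationConfig, n_batches: int = 10) -> MetricsReport:
    """Run one simulation and return pathway metrics (streaming; no
    trajectory is retained)."""
    clf = TurnoverClassifier()
    config = replace(config, record_events=False) if config.record_events else config
    traj = run(config, observers=[clf])
    report = compute_metrics(clf.records, traj.duration, n_batches, seed=config.seed)
    log.info(
        "sim seed=%d t=%.3gs events=%d turnovers=%d stopped_by=%s",
        config.seed,
        traj.duration,
        traj.n_events,
        report.counts["total"],
        traj.stopped_by,
    )
    return report


def paired_activation(
    rates: RateTable,
    seed: int,
    t_end: float,
    ligand_uM: float = 100.0,
    options: ModelOptions = DEFAULT_OPTIONS,
    max_events: Optional[int] = None,
    n_batches: int = 10,
) -> dict:
    """Paired yes-ligand / no-ligand runs with the same seed.

    Returns the two metric reports plus ligand activation A and target-cycle
    efficiency E computed from them.
    """
    yes = measure(
        SimulationConfig(
            rates=rates.copy(concentrations={Kind.L: ligand_uM}),
            options=options,
            t_end=t_end,
            max_events=max_events,
            seed=seed,
            record_events=False,
        ),
        n_batches,
    )
    no = measure(
        SimulationConfig(
            rates=rates.copy(concentrations={Kind.L: 0.0}),
            options=options,
            t_end=t_end,
            max_events=max_events,
            seed=seed,
            record_events=False,
        ),
        n_batches,
    )
    return {
        "yes": yes,
        "no": no,
        "v_yesL": yes.v_total,
        "v_noL": no.v_total,
        "A": ligand_activation(yes.v_total, no.v_total),
        "E": efficiency(yes.rates["target"], yes.v_total),
    }


@dataclass
class SweepSpec:
    """One parameter scan: the swept parameter, its grid, and run budgets."""

    parameter: str  # 'S' | 'kclv' | 'klig'
    grid: Sequence[float]
    rates: RateTable = field(default_factory=RateTable)
    options: ModelOptions = DEFAULT_OPTIONS
    replicates: int = 3
    t_end: float = 200.0
    max_events: Optional[int] = 2_000_000
    base_seed: int = 1
    n_batches: int = 10

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")

    def seeds(self, point_index: int) -> list[int]:
        # distinct per (grid point, replicate); small enough for SeedSequence
        return [
            (self.base_seed * 1_000_003 + point_index * 1_009 + r) % (2**31)
            for r in range(self.replicates)
        ]

    def rates_at(self, value: float) -> RateTable:
        if self.parameter == "S":
            return self.rates.copy(concentrations={Kind.S: value})
        if self.parameter == "kclv":
            return self.rates.copy(kclv=value)
        if self.parameter == "klig":
            return self.rates.copy(klig=value)
        raise ValueError(f"unknown sweep parameter {self.parameter!r}")


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame  # one row per (grid point, replicate)
    aggregate: pd.DataFrame  # one row per grid point (mean over replicates)


_RATE_COLS = ["total"] + list(PATHWAYS)


def _aggregate(table: pd.DataFrame, by: str) -> pd.DataFrame:
    value_cols = [c for c in table.columns if c.startswith("v_") or c in ("A", "E")]
    g = table.groupby(by, sort=True)
    agg = g[value_cols].mean()
    sem = g[value_cols].sem()
    out = agg.join(sem, rsuffix="_se")
    out["replicates"] = g.size()
    return out.reset_index()


def _metrics_row(point: float, rep: int, seed: int, m: MetricsReport) -> dict:
    row = {"point": point, "replicate": rep, "seed": seed, "duration": m.duration}
    for p in _RATE_COLS:
        row[f"v_{p}"] = m.rates[p]
        row[f"n_{p}"] = m.counts[p]
    return row


def preset_substrate_sweep(spec: SweepSpec | None = None) -> SweepResult:
    """Ligand activation and per-pathway turnover across substrate
    concentrations, [L] fixed; yes/no-ligand runs are seed-paired."""
    spec = spec or SweepSpec(
        parameter="S", grid=np.logspace(-1, 4, 11), t_end=200.0
    )
    rows = []
    ligand_uM = spec.rates.concentrations[Kind.L]
    for i, s_uM in enumerate(spec.grid):
        for rep, seed in enumerate(spec.seeds(i)):
            pair = paired_activation(
                spec.rates_at(s_uM),
                seed=seed,
                t_end=spec.t_end,
                ligand_uM=ligand_uM,
                options=spec.options,
                max_events=spec.max_events,
                n_batches=spec.n_batches,
            )
            row = _metrics_row(s_uM, rep, seed, pair["yes"])
            row["v_noL"] = pair["v_noL"]
            row["A"] = pair["A"]  # NaN where v_noL = 0: undefined, not dropped
            row["E"] = pair["E"]
            rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(spec, table, _aggregate(table, "point"))


def _plain_sweep(spec: SweepSpec) -> SweepResult:
    rows = []
    for i, value in enumerate(spec.grid):
        rates = spec.rates_at(value)
        for rep, seed in enumerate(spec.seeds(i)):
            m = measure(
                SimulationConfig(
                    rates=rates,
                    options=spec.options,
                    t_end=spec.t_end,
                    max_events=spec.max_events,
                    seed=seed,
                    record_events=False,
                ),
                spec.n_batches,
            )
            row = _metrics_row(value, rep, seed, m)
            total = m.counts["total"]
            for p in PATHWAYS:
                row[f"frac_{p}"] = m.counts[p] / total if total else math.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(spec, table, _aggregate(table, "point"))


def preset_cleavage_sweep(spec: SweepSpec | None = None) -> SweepResult:
    """Pathway fractions across the cleavage rate (idling silo).

    The aggregate carries the crossover location: the first grid point at
    which the idling fraction exceeds the target fraction.
    """
    spec = spec or SweepSpec(parameter="kclv", grid=np.logspace(-1, 5, 9), t_end=200.0)
    result = _plain_sweep(spec)
    agg = result.aggregate
    frac = result.table.groupby("point")[["n_idling", "n_target", "n_total"]].sum()
    idl = frac["n_idling"] / frac["n_total"].clip(lower=1)
    tgt = frac["n_target"] / frac["n_total"].clip(lower=1)
    agg["idling_fraction"] = idl.values
    agg["target_fraction"] = tgt.values
    above = [p for p, a, b in zip(frac.index, idl, tgt) if a > b]
    agg.attrs["idling_crossover_kclv"] = min(above) if above else math.nan
    return SweepResult(spec, result.table, agg)


def preset_ligation_sweep(spec: SweepSpec | None = None) -> SweepResult:
    """Total turnover across the ligation rate (catalysis silo).

    The aggregate notes where turnover first drops below half its
    slow-ligation value, reported relative to koff-a.
    """
    spec = spec or SweepSpec(parameter="klig", grid=np.logspace(-1, 6, 8), t_end=200.0)
    result = _plain_sweep(spec)
    agg = result.aggregate
    v = agg.set_index("point")["v_total"]
    v_slow = v.iloc[0]
    onset = math.nan
    if v_slow > 0:
        below = v[v < 0.5 * v_slow]
        if len(below):
            onset = float(below.index[0])
    agg.attrs["inhibition_onset_klig"] = onset
    agg.attrs["koff_a"] = spec.rates.koff["a"]
    return SweepResult(spec, result.table, agg)


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------


def _events_from_path(states, types, symbols, t_step: float = 1.0) -> list[Event]:
    """Synthetic event list realizing a canonical path (unit-spaced times,
    deterministic uids/lineages); used for classifier fixtures.

    ``states`` has one more entry than ``types``: the explicit end state.
    """
    from .ssa import _Mirror, _RunState, compiled_network

    assert len(states) == len(types) + 1
    config = SimulationConfig(record_events=True, t_end=len(types) * t_step + 1.0)
    net = compiled_network(config.options)
    rs = _RunState(config, net)
    rs.state = net.state_index[states[0]]
    rs.mirror = _Mirror(states[0])
    rs.next_uid = len(states[0])
    events: list[Event] = []
    t = 0.0
    for i in range(len(types)):
        t += t_step
        tgt = net.state_index[states[i + 1]]
        for e in net.edges[rs.state]:
            if e.target == tgt and e.rtype is types[i] and e.symbol == symbols[i]:
                events.append(rs.apply_edge(t, e, ()))
                break
        else:
            raise RuntimeError(f"walk step {i} has no matching edge")
    return events


def make_fixtures(kind: str):
    """Small deterministic test assets.

    ``l_only_network``
        The 7-state ligand-only binding chain (one ligand copy, no
        substrate or products in solution).
    ``scripted_target`` / ``scripted_idling`` / ``scripted_steric``
        Synthetic event sequences tracing one lap of the corresponding
        named cycle (prefixed with the binding steps needed to enter it).
    ``degenerate_rates``
        Rate tables violating the binding-energy hierarchy or the
        catalysis speed limits, for validator tests.
    """
    if kind == "l_only_network":
        rates = RateTable()
        rates.concentrations = {Kind.L: 100.0, Kind.S: 0.0, Kind.P1: 0.0, Kind.P2: 0.0}
        options = ModelOptions(max_per_kind={Kind.L: 1})
        return network.build_state_graph(rates, options)
    from linkzyme.species import Reaction as R

    def canon(runs):
        return tuple(sorted((k, tuple(n)) for k, n in runs))

    # entry prefixes from the empty enzyme, so every fixture trajectory is
    # complete (real bind times and lineages)
    l_entry = (
        [canon([]), canon([("L", "d")]), canon([("L", "de")])],
        [R.INTER_BIND, R.INTRA_BIND, R.INTRA_BIND],
        ["k_L_on", "kuni", "kuni"],
    )
    s_entry = (
        [
            canon([]),
            canon([("S", "a")]),
            canon([("S", "ab")]),
            canon([("S", "abc")]),
        ],
        [R.INTER_BIND, R.INTRA_BIND, R.INTRA_BIND, R.CLEAVAGE],
        ["k_S_on", "kuni", "kuni", "kclv"],
    )
    if kind == "scripted_target":
        states, types, syms = network.target_cycle_walk()
        return _events_from_path(
            l_entry[0] + states + [states[0]],
            l_entry[1] + list(types),
            l_entry[2] + list(syms),
        )
    if kind == "scripted_idling":
        # enter via the target prefix so the ligand has a bind time, then idle
        pre_states, pre_types, pre_syms = network.target_cycle_walk()
        idl_states, idl_types, idl_syms = network.idling_cycle_walk()
        # target prefix reaches the trivalent-S state (S:abc + L:f) in 5 steps
        return _events_from_path(
            l_entry[0] + pre_states[:5] + idl_states + [idl_states[0]],
            l_entry[1] + list(pre_types[:5]) + list(idl_types),
            l_entry[2] + list(pre_syms[:5]) + list(idl_syms),
        )
    if kind == "scripted_steric":
        states, types, syms = network.steric_cycle_walk()
        return _events_from_path(
            s_entry[0] + states + [states[0]],
            s_entry[1] + list(types),
            s_entry[2] + list(syms),
        )
    if kind == "degenerate_rates":
        flat = RateTable(koff={n: 100.0 for n in "abcdef"})
        fast_clv = RateTable().copy(kclv=1e4)
        fast_lig = RateTable().copy(klig=1e4)
        return {"flat_koff": flat, "fast_cleavage": fast_clv, "fast_ligation": fast_lig}
    raise ValueError(f"unknown fixture kind {kind!r}")


__all__ = [
    "SweepResult",
    "SweepSpec",
    "make_fixtures",
    "measure",
    "paired_activation",
    "preset_cleavage_sweep",
    "preset_ligation_sweep",
    "preset_substrate_sweep",
]
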