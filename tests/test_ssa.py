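"""Exactness, determinism and bookkeeping of the stochastic engine."""

import math

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from linkzyme import network as N
from linkzyme import ssa
from linkzyme.species import Kind, ModelOptions, RateTable, Reaction


def p1_only_rates(conc=50.0):
    """Two-state toy: P1 binds only node a, so the chain is empty <-> P1:a."""
    r = RateTable()
    r.concentrations = {Kind.P1: conc, Kind.S: 0.0, Kind.P2: 0.0, Kind.L: 0.0}
    return r


def test_seed_determinism():
    cfg = ssa.SimulationConfig(t_end=0.5, seed=123)
    a, b = ssa.run(cfg), ssa.run(cfg)
    assert a.n_events == b.n_events
    assert [(e.time, e.symbol, e.uids_after) for e in a.events] == [
        (e.time, e.symbol, e.uids_after) for e in b.events
    ]
    c = ssa.run(ssa.SimulationConfig(t_end=0.5, seed=124))
    assert [(e.time, e.symbol) for e in c.events] != [
        (e.time, e.symbol) for e in a.events
    ]


def test_all_concentrations_zero_is_absorbing():
    r = RateTable()
    r.concentrations = {k: 0.0 for k in Kind}
    traj = ssa.run(ssa.SimulationConfig(rates=r, t_end=1.0, seed=0))
    assert traj.n_events == 0 and traj.stopped_by == "absorbing"


def test_replay_reproduces_final_state_and_detects_tampering():
    traj = ssa.run(ssa.SimulationConfig(t_end=0.5, seed=5))
    assert traj.replay() == traj.final_state
    broken = ssa.Trajectory(
        traj.config,
        traj.initial_state,
        traj.events[:-1],
        traj.final_state,
        traj.duration,
        traj.n_events - 1,
        traj.stopped_by,
    )
    if traj.events[-1].rtype is not Reaction.INTRA_BIND:
        with pytest.raises(Exception):
            broken.replay()


def test_event_times_strictly_increase_and_states_chain():
    traj = ssa.run(ssa.SimulationConfig(t_end=0.2, seed=9))
    times = [e.time for e in traj.events]
    assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))


def test_two_state_toy_waiting_times():
    """Mean dwell in the empty state is 1/(c_on [P1]) within 3 standard
    errors (exponential-clock closed form)."""
    conc = 50.0
    cfg = ssa.SimulationConfig(
        rates=p1_only_rates(conc), t_end=600.0, seed=21
    )
    traj = ssa.run(cfg)
    binds = [e.time for e in traj.events if e.rtype is Reaction.INTER_BIND]
    unbinds = [e.time for e in traj.events if e.rtype is Reaction.INTER_DISS]
    assert len(binds) > 10_000
    waits = np.array(binds[1:]) - np.array(unbinds[: len(binds) - 1])
    expected = 1.0 / conc
    se = waits.std(ddof=1) / math.sqrt(len(waits))
    assert abs(waits.mean() - expected) < 3 * se


def test_cleavage_and_ligation_conserve_instances():
    """Every cleavage creates exactly one P1 and one P2 carrying the
    substrate's lineage; ligation consumes one of each."""
    traj = ssa.run(ssa.SimulationConfig(t_end=30.0, seed=3))
    clv = [e for e in traj.events if e.rtype is Reaction.CLEAVAGE]
    assert clv, "no cleavage sampled"
    for e in clv:
        assert len(e.uids_before) == 1 and len(e.uids_after) == 2
        assert e.lineage == e.uids_before[0]
    for e in traj.events:
        if e.rtype is Reaction.LIGATION:
            assert len(e.uids_before) == 2 and len(e.uids_after) == 1


def test_l_only_occupancy_matches_analytic_stationary_distribution(
    l_only_rates, single_ligand_options
):
    """NRM time-in-state fractions on the 7-state ligand chain agree with
    the stationary distribution of the CTMC generator within 3 batch-means
    standard errors."""
    g = N.build_state_graph(l_only_rates, single_ligand_options)
    states = sorted(g.nodes, key=N.state_label)
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((7, 7))
    for u, v, data in g.edges(data=True):
        Q[idx[u], idx[v]] += data["rate"]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = scipy.linalg.null_space(Q.T)[:, 0]
    pi = pi / pi.sum()

    n_batches, t_batch = 16, 4.0
    cfg = ssa.SimulationConfig(
        rates=l_only_rates,
        options=single_ligand_options,
        t_end=n_batches * t_batch,
        seed=40,
    )
    traj = ssa.run(cfg)
    # batch-means occupancies
    occ = np.zeros((n_batches, 7))
    mirror_state = traj.initial_state
    t_prev = 0.0
    events = list(traj.events) + [None]
    from linkzyme.ssa import _Mirror

    mirror = _Mirror(traj.initial_state)
    for ev in traj.events:
        b0, b1 = int(t_prev // t_batch), int(ev.time // t_batch)
        i = idx[mirror_state]
        if b0 == b1:
            occ[b0, i] += ev.time - t_prev
        else:
            occ[b0, i] += (b0 + 1) * t_batch - t_prev
            for b in range(b0 + 1, b1):
                occ[b, i] += t_batch
            if b1 < n_batches:
                occ[b1, i] += ev.time - b1 * t_batch
        mirror.apply(ev)
        mirror_state = mirror.canonical()
        t_prev = ev.time
    occ[-1, idx[mirror_state]] += traj.duration - t_prev
    frac = occ / t_batch
    mean = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / math.sqrt(n_batches)
    for i, s in enumerate(states):
        assert abs(mean[i] - pi[i]) < 3 * max(se[i], 1e-6), N.state_label(s)


def test_nrm_and_direct_method_agree_on_event_type_counts():
    """Both samplers draw from the same chain: per-reaction-type counts
    over a fixed window are chi-square compatible (alpha = 0.01)."""
    cfg_n = ssa.SimulationConfig(t_end=8.0, seed=33, record_events=True)
    cfg_d = ssa.SimulationConfig(t_end=8.0, seed=77, record_events=True)
    a = ssa.run(cfg_n)
    b = ssa.run_direct(cfg_d)
    kinds = [r for r in Reaction]
    ca = [sum(1 for e in a.events if e.rtype is r) for r in kinds]
    cb = [sum(1 for e in b.events if e.rtype is r) for r in kinds]
    table = np.array([ca, cb])
    table = table[:, table.sum(axis=0) > 0]
    _, p, _, _ = scipy.stats.chi2_contingency(table)
    assert p > 0.01


def test_direct_method_determinism_and_replay():
    cfg = ssa.SimulationConfig(t_end=0.5, seed=8)
    a, b = ssa.run_direct(cfg), ssa.run_direct(cfg)
    assert [(e.time, e.symbol) for e in a.events] == [
        (e.time, e.symbol) for e in b.events
    ]
    assert a.replay() == a.final_state


def test_finite_copy_mode_conserves_and_depletes():
    """In finite-copy mode a bound reactant is removed from solution: with
    a single ligand copy there is never a second ligand binding while one
    is bound."""
    r = RateTable()
    r.concentrations = {Kind.L: 1.0, Kind.S: 0.0, Kind.P1: 0.0, Kind.P2: 0.0}
    cfg = ssa.SimulationConfig(
        rates=r, t_end=20.0, seed=2, mode="finite_copies", copies_per_uM=1.0
    )
    traj = ssa.run(cfg)
    assert traj.n_events > 100
    bound = 0
    for e in traj.events:
        if e.rtype is Reaction.INTER_BIND:
            bound += 1
        elif e.rtype is Reaction.INTER_DISS:
            bound -= 1
        assert 0 <= bound <= 1


def test_occupancy_times_sums_to_duration():
    traj = ssa.run(ssa.SimulationConfig(t_end=1.0, seed=4))
    occ = ssa.occupancy_times(traj)
    assert math.isclose(sum(occ.values()), traj.duration, rel_tol=1e-9)


def test_max_events_cap_reports_effective_duration():
    cfg = ssa.SimulationConfig(t_end=50.0, seed=1, max_events=500)
    traj = ssa.run(cfg)
    assert traj.stopped_by == "max_events"
    assert traj.n_events == 500
    assert 0 < traj.duration < 50.0


def test_trajectory_csv_round_trip(tmp_path):
    traj = ssa.run(ssa.SimulationConfig(t_end=0.3, seed=6))
    path = tmp_path / "traj.csv.gz"
    ssa.save_trajectory(traj, path)
    back = ssa.load_trajectory(path)
    assert back.n_events == traj.n_events
    assert back.final_state == traj.final_state
    assert [(e.time, e.rtype, e.uids_after) for e in back.events] == [
        (e.time, e.rtype, e.uids_after) for e in traj.events
    ]
    assert back.replay() == traj.final_state


def test_config_yaml_round_trip(tmp_path):
    cfg = ssa.SimulationConfig(
        rates=RateTable().copy(kclv=2.0),
        options=ModelOptions(max_per_kind={Kind.S: 1}),
        t_end=7.0,
        seed=99,
    )
    import yaml

    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    back = ssa.SimulationConfig.from_yaml(path)
    assert back.rates.kclv == 2.0
    assert back.options.max_per_kind == {Kind.S: 1}
    assert back.t_end == 7.0 and back.seed == 99
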