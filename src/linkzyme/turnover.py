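"""Turnover-pathway classification and rate metrics.

A *turnover* is the release of one ADP-analog (P2) instance from the
enzyme — the last chemical step of Eq.-style macro-cycle bookkeeping.  Each
release is attributed to a pathway by comparing ligand identities across
the catalytic history of that P2's parent substrate:

``target``
    Productive cycle: the ligand bound at release is a *different* ligand
    from the one the parent substrate displaced (the last ligand that was
    multivalently engaged while the substrate held the enzyme), and it
    arrived after cleavage — ligand exchange took place.
``pci``
    Productive-cycle variant: the displacing ligand is a different ligand
    but bound *before* cleavage (it then idled through catalysis).  Ligand
    exchange still occurred, so it is counted as productive.
``idling``
    The same ligand instance persisted from substrate capture through
    catalysis to P2 release: substrate consumed, no ligand exchange.
``steric``
    A second substrate invaded the product's own nodes (b/c) and blocked
    its rebinding, or substrate occupies the top site with no multivalently
    engaged ligand present: substrate, not ligand, displaced P2.
``other``
    Anything else (e.g. spontaneous P2 release with nothing else bound).

Rates are reported per pathway with batch-means standard errors.  Ligand
activation ``A = v_yesL / v_noL`` compares paired simulations with and
without ligand; efficiency ``E = 100 * v_target / v_yesL`` is the percent
of ligand-present turnover carried by the target cycle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .species import Kind, Reaction, TOP_NODES
from .ssa import Event, Trajectory, _Mirror

PATHWAYS = ("target", "pci", "idling", "steric", "other")


@dataclass(frozen=True)
class TurnoverRecord:
    """One P2 release, with the evidence used to classify it."""

    time: float
    p2_uid: int
    pathway: str
    l_now: Optional[int]  # ligand bound at release
    l_capture: Optional[int]  # ligand displaced by the parent substrate
    parent_s: Optional[int]
    cleavage_time: Optional[float]


class _Entity:
    """Catalytic history of one substrate entity.

    An entity is born when a substrate binds from solution and survives
    rounds of cleavage and re-ligation (products inherit it through their
    lineage).  ``capture`` is the displaced ligand: the *first* ligand
    instance that was multivalently engaged (bound at two or more nodes)
    while this substrate occupied the enzyme and before its first cleavage
    — the ligand the substrate competed with for the hinges.  Later
    ligands are "second" ligands: if one persists through catalysis and
    displaces P2 that is the productive pci case, not idling.  Monovalent
    bystander ligands never become the capture.  ``t_clv`` is the entity's
    first cleavage time.
    """

    __slots__ = ("capture", "t_clv")

    def __init__(self) -> None:
        self.capture: Optional[int] = None
        self.t_clv: Optional[float] = None


class TurnoverClassifier:
    """Streaming classifier: feed it events (in time order), read records.

    Usable as an SSA observer (``observers=[clf]``) so that long runs never
    need to hold a full trajectory in memory.
    """

    def __init__(self) -> None:
        self._mirror = _Mirror()
        self._l_first_bind: dict[int, float] = {}
        self._entities: dict[int, _Entity] = {}  # S uid -> entity
        self._p2_entity: dict[int, _Entity] = {}
        self.records: list[TurnoverRecord] = []
        self._p2_parent: dict[int, int] = {}

    # -- helpers ---------------------------------------------------------

    def _bound_ligand(self) -> Optional[int]:
        """The ligand instance 'in possession': most nodes bound, ties to
        the earliest-bound copy."""
        ls = self._mirror.instances_of(Kind.L)
        if not ls:
            return None
        best = max(
            ls, key=lambda ri: (len(ri[0]), -self._l_first_bind.get(ri[1].uid, math.inf))
        )
        return best[1].uid

    def _substrate_on_top(self) -> bool:
        return any(
            run[0] in TOP_NODES for run, inst in self._mirror.bound.items() if inst.kind is Kind.S
        )

    def _multivalent_ligand(self) -> Optional[int]:
        for run, inst in self._mirror.instances_of(Kind.L):
            if len(run) >= 2:
                return inst.uid
        return None

    def _entity(self, s_uid: int) -> _Entity:
        if s_uid not in self._entities:
            self._entities[s_uid] = _Entity()
        return self._entities[s_uid]

    # -- observer --------------------------------------------------------

    def __call__(self, ev: Event) -> None:
        if ev.rtype is Reaction.LIGATION:
            # the rejoined substrate continues the catalytic history of the
            # products' parent entity (read lineage before the event applies)
            p2_nodes = tuple(n for n in ev.to_nodes if n != "a")
            parent = self._mirror.bound[p2_nodes].lineage
            self._mirror.apply(ev)
            ent = self._entity(parent) if parent is not None else _Entity()
            self._entities[ev.uids_after[0]] = ent
            return
        if ev.rtype is Reaction.INTER_DISS and ev.kind is Kind.P2:
            # classification inputs are the state at release (after the event)
            p2_uid = ev.uids_before[0]
            self._mirror.apply(ev)
            self._classify_release(ev.time, p2_uid)
            return
        self._mirror.apply(ev)
        if ev.rtype is Reaction.INTER_BIND:
            if ev.kind is Kind.L:
                self._l_first_bind[ev.uids_after[0]] = ev.time
            elif ev.kind is Kind.S:
                ent = self._entity(ev.uids_after[0])
                multi = self._multivalent_ligand()
                if multi is not None and ent.capture is None:
                    ent.capture = multi
        elif ev.rtype is Reaction.INTRA_BIND and ev.kind is Kind.L:
            if ev.to_nodes is not None and len(ev.to_nodes) >= 2:
                # a ligand contesting the hinges becomes the displaced-ligand
                # candidate of any substrate it has not yet contested
                uid = ev.uids_after[0]
                for run, inst in self._mirror.instances_of(Kind.S):
                    ent = self._entity(inst.uid)
                    if ent.capture is None and ent.t_clv is None:
                        ent.capture = uid
        elif ev.rtype is Reaction.CLEAVAGE:
            ent = self._entity(ev.uids_before[0])
            if ent.t_clv is None:
                ent.t_clv = ev.time
            self._p2_entity[ev.uids_after[1]] = ent
            self._p2_parent[ev.uids_after[1]] = ev.uids_before[0]

    def _classify_release(self, t: float, p2_uid: int) -> None:
        ent = self._p2_entity.pop(p2_uid, None)
        parent_s = self._p2_parent.pop(p2_uid, None)
        l_capture = ent.capture if ent is not None else None
        t_clv = ent.t_clv if ent is not None else None
        # the displacing agent at release: a ligand counts only if it is
        # multivalently engaged (a ligand can complete a displacement only
        # from a two-node foothold); a monovalent bystander does not.  A
        # substrate occupying one of P2's own nodes (b or c) has invaded
        # the product's site and blocked its rebinding: steric displacement
        l_now = self._multivalent_ligand()
        s_on_top = self._substrate_on_top()
        s_invading = any(
            ("b" in run or "c" in run)
            for run, inst in self._mirror.instances_of(Kind.S)
        )
        if s_invading or (l_now is None and s_on_top):
            pathway = "steric"
        elif l_now is not None and l_now == l_capture:
            pathway = "idling"
        elif (
            l_now is not None
            and l_capture is not None
            and l_now != l_capture
            and t_clv is not None
            and self._l_first_bind.get(l_now, -math.inf) >= t_clv
        ):
            pathway = "target"
        elif (
            l_now is not None
            and l_now != l_capture
            and t_clv is not None
            and self._l_first_bind.get(l_now, math.inf) < t_clv
        ):
            pathway = "pci"
        else:
            pathway = "other"
        self.records.append(
            TurnoverRecord(t, p2_uid, pathway, l_now, l_capture, parent_s, t_clv)
        )


def classify_turnovers(traj: Trajectory) -> list[TurnoverRecord]:
    """Classify every P2 release of a recorded trajectory."""
    if traj.events is None:
        raise ValueError("trajectory was run without event recording")
    traj.replay()  # unreplayable trajectories are rejected up front
    clf = TurnoverClassifier()
    for ev in traj.events:
        clf(ev)
    return clf.records


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-pathway turnover rates (s^-1) with batch-means standard errors."""

    duration: float
    counts: dict[str, int]
    rates: dict[str, float]
    stderr: dict[str, float]
    n_batches: int
    seed: Optional[int] = None

    @property
    def v_total(self) -> float:
        return self.rates["total"]

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "counts": dict(self.counts),
            "rates": dict(self.rates),
            "stderr": dict(self.stderr),
            "n_batches": self.n_batches,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def compute_metrics(
    records: Iterable[TurnoverRecord],
    duration: float,
    n_batches: int = 10,
    seed: Optional[int] = None,
) -> MetricsReport:
    """Pathway counts and rates over ``duration`` seconds.

    Standard errors use batch means: the run is cut into ``n_batches``
    equal time slices, whose per-slice rates estimate the sampling spread
    of the overall rate.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    records = list(records)
    counts = {p: 0 for p in PATHWAYS}
    for r in records:
        counts[r.pathway] += 1
    counts["total"] = len(records)
    rates = {k: v / duration for k, v in counts.items()}
    edges = np.linspace(0.0, duration, n_batches + 1)
    stderr = {}
    for p in list(PATHWAYS) + ["total"]:
        times = [r.time for r in records if p == "total" or r.pathway == p]
        per_batch, _ = np.histogram(times, bins=edges)
        batch_rates = per_batch / (duration / n_batches)
        stderr[p] = float(np.std(batch_rates, ddof=1) / math.sqrt(n_batches))
    return MetricsReport(duration, counts, rates, stderr, n_batches, seed)


def ligand_activation(v_yesL: float, v_noL: float) -> float:
    """A = v_yesL / v_noL; NaN (undefined) when v_noL is zero."""
    if v_noL == 0:
        return math.nan
    return v_yesL / v_noL


def efficiency(v_target: float, v_yesL: float) -> float:
    """E = 100 * v_target / v_yesL, percent; NaN when v_yesL is zero."""
    if v_yesL == 0:
        return math.nan
    return 100.0 * v_target / v_yesL


def records_to_frame(records: Iterable[TurnoverRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time": r.time,
                "p2_uid": r.p2_uid,
                "pathway": r.pathway,
                "l_now": r.l_now,
                "l_capture": r.l_capture,
                "parent_s": r.parent_s,
                "cleavage_time": r.cleavage_time,
            }
            for r in records
        ]
    )


__all__ = [
    "MetricsReport",
    "PATHWAYS",
    "TurnoverClassifier",
    "TurnoverRecord",
    "classify_turnovers",
    "compute_metrics",
    "efficiency",
    "ligand_activation",
    "records_to_frame",
]
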