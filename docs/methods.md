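# Methods

## The model

The machine is a system of five 2D linkages. The enzyme is a chain of
three generically rigid squares (each a quadrilateral with one diagonal
bar) joined at two hinge nodes, h1 (left) and h2 (right); with both hinges
free it has exactly two internal mechanical degrees of freedom. Binding is
discretized: six enzyme nodes — a, b, c across the top (substrate site)
and d, e, f across the bottom (ligand site) — each pair with a unique
complementary node on one of four reactants:

| reactant | role        | binds      | notes                                   |
|----------|-------------|------------|-----------------------------------------|
| S        | ATP analog  | a, b, c    | carries the catalytic moiety between its a\*- and b\*-ends |
| P1       | Pi analog   | a          | product of cleavage                      |
| P2       | ADP analog  | b, c       | product of cleavage                      |
| L        | effector    | d, e, f    | not consumed                             |

Mechanics enter through *bracing*: a reactant bound at two adjacent nodes
closes a triangle over the spanned hinge and locks it — "up" for top-site
pairs ({a,b}→h1, {b,c}→h2), "down" for bottom-site pairs ({d,e}→h1,
{e,f}→h2). The model is strain-free and purely connectivity-driven:
conformational state changes only by adding or removing bars, and rigidity
is evaluated combinatorially (generic rigidity), never from coordinates.

### Feasibility rules

A microstate (an assignment of reactant instances to node runs) is
feasible iff

- **R1** every occupied node belongs to its occupant kind's site;
- **R2** each instance's nodes form a contiguous run of its site;
- **R3** no hinge is braced both up and down by the union of all bracings.

R3 is the source of negative allosteric coupling: trivalent ligand braces
both hinges down, so substrate can attach only monovalently, and vice
versa; divalent P2 ({b,c}, h2 up) and divalent-or-better ligand engaging
h2 exclude each other on the right side. These three rules are the
normative model; the exact coordinate geometry behind them is not
represented. A user-supplied rule table (a YAML list of forbidden bracing
combinations) can replace R3's default.

### Reactions and rates

Six elementary reaction types connect feasible states, each state pair
differing by one node connection or one catalytic event:

| type | reaction                     | rate                      |
|------|------------------------------|---------------------------|
| I    | fresh reactant binds one free compatible node | c_on·[X] per node |
| II   | bound reactant grabs an adjacent free node    | k_uni            |
| III  | multivalent reactant drops a terminal node    | k_off-node       |
| IV   | monovalent reactant leaves                    | k_off-node       |
| V    | S bound at a and b splits into P1@a + P2@{b(,c)} | k_clv         |
| VI   | P1@a + P2 holding b rejoin into S (h1 not braced down) | k_lig   |

Default rates (s⁻¹): k_off-a 250, k_off-b 3, k_off-c 680, k_off-d 680,
k_off-e 200, k_off-f 680, k_uni 10⁶, k_clv 10, k_lig 10. Binding is
pseudo-first-order with c_on = 1 µM⁻¹s⁻¹ (the conversion factor is a
modelling choice; concentrations default to [S] = [L] = 100 µM,
[P1] = [P2] = 0). Per-node binding energies ε = ln(k_off/k_uni) give the
site hierarchy ε_S (−28.30) < ε_L (−23.10) < ε_P2 (−20.01) < ε_P1 (−8.29)
in kT, which decides every pairwise displacement competition, and the
catalysis speed limits k_clv < min ligand k_off and k_lig < k_off-a bias
the cycle forward. `validate_rate_hierarchy` checks all of this for any
rate table and is run by the CLI before simulating.

Intermolecular binding is node-resolved: a fresh reactant may start at
*any* free node of its site (one channel per kind × node). This is needed
for the high-substrate phenomenology, where substrate saturates node a and
grabs node b directly the moment P2 bares it; an empty enzyme therefore
has nine binding channels (S:3, P1:1, P2:2, L:3).

Structural switches: `max_per_kind` caps simultaneous copies of a kind
(e.g. one substrate, which removes inhibitory saturation);
`cleave_requires_trivalent` restricts cleavage to fully bound substrate
(default off — divalent S at {a,b} may cleave); `require_same_lineage`
restricts ligation to products of the same parent (default off — products
are chemically identical).

## State space and named cycles

The reachable space is enumerated breadth-first from the empty enzyme
under the rules above: 449 canonical states and 3618 directed edges with
all four reactants present; the graph is reversible edge-for-edge (I↔IV,
II↔III, V↔VI). Canonical states abstract instance identity (sorted
(kind, run) pairs); identity lives only in the simulation layer. With
zero-concentration kinds excluded the space shrinks accordingly — e.g.
ligand only, one copy: the 7-state chain used for exactness tests.

The three named cycles are *definitions*, constructed as explicit walks
and verified edge-by-edge against the enumerated graph (a missing step
fails loudly — it would mean the rules regressed):

- **target**: 13 states/13 reversible steps; the macro-projection is the
  six-reaction cycle {L}→{S/L}→{S}→{P1,P2}→{P2}→{P2/L}→; {S/L} expands to
  5 microstates (4 hidden intramolecular steps: L drops d, S grabs b,
  L drops e, S grabs c) and {P2/L} to 4 (3 hidden steps: L grabs e,
  P2 drops b, L grabs f).
- **idling**: cleavage fires from the trivalent-S microstate while the
  contested ligand still holds node f; the same ligand then walks back
  across its site and displaces P2, rejoining the target path inside
  {P2/L}.
- **steric**: after P1 dissociates, a second substrate binds node a,
  P2 frays, the invader takes b, and P2 leaves with no ligand involved.

Where the displacement of P2 can complete by either of its nodes, the
canonical target walk takes the b-release branch (P2 retains its outer
node c, mirroring the ligand retaining f on the other leg); both branches
exist in the graph and the classifier does not depend on the choice.

## Stochastic simulation

The chain over canonical states is compiled once per option set (states,
edges, and ~100 reaction *channels* — a channel is an elementary reaction
keyed by type, kind and node runs, independent of which bystanders are
bound). The production sampler is the next reaction method: each channel
owns a named random stream (`SeedSequence(seed, spawn_key=(channel,))`)
and an absolute tentative firing time; channels that remain enabled with
unchanged propensity keep their clocks, newly enabled or just-fired
channels redraw. Propensities are constant per channel in buffered mode,
which makes clock reuse exact. A Gillespie direct-method sampler over the
same compiled chain serves as an independent cross-check (chi-square
agreement of per-type event counts, and both match the analytic
stationary distribution of the ligand-only chain within Monte-Carlo
error).

Buffered mode (default) holds concentrations fixed — one enzyme in a
large reservoir. Finite-copy mode converts concentrations to integer
copies (`copies_per_uM`), decrements/increments them on binding and
release, and rescales the affected binding channels' propensities
(their clocks are redrawn at the new rate, which is exact).

Instance identities (uids) ride on top of the canonical chain: cleavage
products carry their parent substrate's uid as lineage, and re-ligated
substrate continues the same catalytic entity. Identities never affect
propensities in buffered mode; they exist for turnover attribution and
for the replay invariant (every recorded trajectory can be reapplied
event-by-event and must reproduce the final state).

## Turnover classification

A turnover is the intermolecular release of a P2 instance. Classification
compares ligand identities across the catalytic history of that P2's
substrate entity:

- *capture* = the first ligand that was **multivalently** engaged (≥2
  nodes) while the entity's substrate was bound, before its first
  cleavage — the ligand the substrate displaced. Monovalent bystanders
  never qualify: a one-node attachment is mechanically uncommitted, and
  bound substrate flickers between divalent and trivalent so fast
  (k_off-c + k_uni) that "the ligand present at a trivalent instant" is
  noise rather than mechanism.
- At release, the displacing agent is read from the state: a ligand
  counts only from a multivalent foothold; a substrate occupying one of
  P2's own nodes (b/c) has invaded the product's site.

Rules, in order: **steric** if a substrate has invaded b/c (or substrate
is on the top site with no multivalent ligand); **idling** if the engaged
ligand at release *is* the capture; **target** if it is a different
ligand that first bound after the entity's first cleavage (capture must
exist — an exchange happened); **pci** if it is a different ligand that
bound before cleavage (it idled through catalysis, but exchange still
occurred — counted productive); **other** otherwise (mostly spontaneous
release, plus exchange-free cycles on a ligand-free enzyme). Pathway
counts partition all P2 releases.

Rates are counts over simulated time with batch-means standard errors
(≥10 equal time slices). Ligand activation A = v_yesL/v_noL uses paired
runs differing only in [L], same seed (variance reduction); it is NaN
(undefined, never silently dropped) where v_noL = 0. Efficiency
E = 100·v_target/v_yesL uses the strict target rate; the pci rate is
reported separately.

## Behaviour at the defaults, and problem sizes

With Table-default rates at [S] = [L] = 100 µM the machine turns over at
~1.3–1.6 s⁻¹ with ligand and ~0.4 s⁻¹ without (A ≈ 3–4, E ≈ 35–45%);
idling stays below ~5%. Across substrate concentration the target rate is
unimodal, steric displacement dominates above ~10³ µM, and all activity
collapses near 10⁵ µM through inhibitory saturation (multi-substrate +
one-ligand complexes); capping the model at one bound substrate removes
the collapse. Raising k_clv past the ligand off rates funnels turnover
into idling (crossover between 10² and 10³ s⁻¹); at k_clv = k_lig = 10 s⁻¹
the target cycle is modal.

Fast ligation silos the enzyme in a substrate/product interconversion.
In this rule set the silo threshold sits at k_uni rather than k_off-a:
a monovalent ligand parked on d or e (allowed — single-node binding is
flexible and braces nothing) extends to a divalent h1-down foothold at
k_uni the instant cleavage fires, which geometrically blocks re-ligation
and rescues the cycle. Turnover therefore falls only ~25% at
k_lig = 10⁵ s⁻¹ and collapses (to ~7% of baseline) once k_lig exceeds
k_uni — the regime where ligation outruns the ligand's intramolecular
binding. A coordinate-level geometry in which the fully bent enzyme put
nodes d and e out of reach of a free ligand end would move the threshold
down to k_off-a; that refinement is outside the connectivity-based rule
set used here.

Simulated problem sizes: the test suite uses 40–400 s single-enzyme runs
(10⁵–10⁶ events each) with 1–2 replicates per condition and grids of 4–6
points per sweep; the acceptance script uses 2×300 s for the paired
activation measurement, 2×40 s for the fast-cleavage silo, 2×2×120 s for
the ligation comparison and 60 s for the saturation point. Default sweep
presets (8–12 log-spaced points, 3 replicates, 200 s each) are sized for
desk-scale runs; all are reproducible from config plus seed.

## Numerical and design notes

- Rigidity is generic: squares are quadrilaterals with one diagonal; pin
  joints are node contractions, not zero-length bars (degenerate
  constraints would break the count). The (2,3) pebble game gives the
  rank; internal DOF = 2V − 3 − rank for a connected framework.
  Disconnected frameworks are rejected rather than silently summed.
- Rigid clusters are maximal sets of pairwise "rigidly linked" joints
  (bar present or generically redundant); clusters may share hinge
  joints and cover all joints.
- `partially_rigid` needs a floppy reference: a framework with some but
  not all of its reference modes locked. `analyze(fw, flexible_dof=k)`
  supplies it (the hinge count for square chains); without it any
  positive mode count reports `flexible`.
- Tie-breaks: when several ligands are bound, "the" engaged ligand is
  the one with the most nodes, then the earliest-bound. Runs are kept in
  site order; terminal-node release only (a middle node cannot let go
  while both neighbours hold).
- Event times use per-channel exponential streams; identical seeds give
  identical event lists on any platform (no global RNG state).
- Trajectories persist as one-event-per-row CSV (optionally gzipped)
  plus a JSON header carrying the full configuration; graphs export to
  JSON (round-trip exact), GraphML, DOT and CSV tables with canonical
  ordering for diffability.

## Limitations

- Feasibility is topological (R1–R3); metric effects of the coordinate
  geometry — which single nodes are physically reachable in each bent
  conformation — are not modelled, with the ligation-silo threshold
  consequence described above.
- 2D only; no strain, elastic energies, dwell-time or cycle-time
  analysis; one enzyme per simulation; ligand self-binding (neck-linker
  style) is out of scope.
- The synthetic study conditions (c_on, concentrations, run lengths,
  replicate counts) are package choices; conclusions from the test suite
  are statements about this model under those conditions, not about any
  physical instantiation.
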