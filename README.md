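# linkzyme

A simulator for a minimal, allosteric, ATPase-like machine built from 2D
mechanical linkages.

ATPases (myosin, kinesin, pumps, translocases) couple nucleotide turnover
to the binding and release of a second, non-consumed partner — actin,
microtubule, DNA — through negative allosteric coupling between two sites.
`linkzyme` models the smallest mechanical system with this behaviour: an
enzyme made of three generically rigid squares joined at two hinge nodes,
giving it two internal mechanical degrees of freedom. Three top nodes
(a, b, c) bind the ATP analog **S** (cleaved into the Pi analog **P1** and
the ADP analog **P2**); three bottom nodes (d, e, f) bind the effector
analog **L**. A reactant bound at two adjacent nodes braces the spanned
hinge into a triangle ("up" from the top site, "down" from the bottom),
and no hinge can be braced both ways — so the two sites compete for the
enzyme's degrees of freedom, and neither can be fully bound while the
other is multivalently attached.

The package provides:

- **`linkzyme.linkage`** — bar-joint frameworks and generic 2D rigidity
  via the (2,3) pebble game (internal floppy modes, rigid clusters,
  rigid / partially rigid / flexible classification).
- **`linkzyme.species`** — the binding/feasibility rules, the six
  elementary reaction types (inter-/intramolecular binding and
  dissociation, cleavage, ligation), and the rate table with its
  binding-energy hierarchy ε_site = Σ ln(k_off/k_uni):
  ε_S < ε_L < ε_P2 < ε_P1.
- **`linkzyme.network`** — exhaustive enumeration of the reachable state
  space as a reversible reaction network, plus the three named cycles:
  the productive *target* cycle
  {L} → {S/L} → {S} → {P1,P2} → {P2} → {P2/L} → {L}
  (13 reversible microsteps), the futile *idling* cycle (the same ligand
  stays bound through catalysis) and the futile *steric* cycle (a second
  substrate, not ligand, displaces P2).
- **`linkzyme.ssa`** — exact stochastic simulation of a single enzyme by
  the next reaction method, with a Gillespie direct-method cross-check,
  per-channel named random streams, and replayable event logs.
- **`linkzyme.turnover`** — classification of every P2 release into
  target / pci / idling / steric / other, turnover rates with batch-means
  errors, ligand activation `A = v_yesL / v_noL` and target-cycle
  efficiency `E = 100 · v_target / v_yesL`.
- **`linkzyme.experiments`** — preset substrate-concentration, cleavage-
  rate and ligation-rate sweeps, and deterministic test fixtures.

## Worked example

```python
from linkzyme import linkage, network
from linkzyme.species import RateTable, validate_rate_hierarchy
from linkzyme.experiments import paired_activation

# the bare enzyme is a 3-square chain with two free hinges
fw = linkage.build_square_chain(3, ("free", "free"))
print(linkage.count_internal_dof(fw))          # 2

# the full reaction network and the productive cycle
g = network.build_state_graph()
print(g.number_of_nodes(), g.number_of_edges())  # 449 3618
tc = network.find_named_cycles(g)["target"]
print(len(tc))                                  # 13
print(" -> ".join(tc.macro_projection()))
# {L} -> {S/L} -> {S} -> {P1,P2} -> {P2} -> {P2/L}

# the default rate table satisfies the binding-energy hierarchy
rep = validate_rate_hierarchy(RateTable())
print({k: round(v, 2) for k, v in rep.energies.items()})
# {'S': -28.3, 'L': -23.1, 'P2': -20.01, 'P1': -8.29}

# does the effector stimulate substrate turnover?  paired 120 s runs at
# [S] = [L] = 100 uM with and without ligand, same seed
out = paired_activation(RateTable(), seed=7, t_end=120.0)
print(f"v_yes={out['v_yesL']:.2f}/s  v_no={out['v_noL']:.2f}/s  "
      f"A={out['A']:.2f}  E={out['E']:.1f}%")
# v_yes=1.28/s  v_no=0.39/s  A=3.28  E=40.3%
```

`A = 3.28` means the ligand more than triples substrate turnover — the
hallmark of the allosteric cycle: substrate can displace ligand, but after
cleavage the products bind too weakly to resist a fresh ligand, which
resets the enzyme. `E = 40.3%` of ligand-present turnover goes through the
strict target cycle; most of the rest is the pci variant (a second ligand
that engaged before cleavage — still a productive exchange).

A command-line interface wraps the same functionality:

```sh
linkzyme network --out graph.json            # build + export the network
linkzyme simulate --seed 3 --t-end 10 --out traj.csv
linkzyme classify --traj traj.csv --out records.csv --metrics metrics.json
linkzyme sweep cleavage --points 9 --out silo
```

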