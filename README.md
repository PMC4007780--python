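# gtreach

Discrete dynamic modeling of cell signaling networks with **guarded
transitions**, plus a SAT-based bounded reachability engine that answers
the question biologists actually ask of a pathway map: *which
combinations of extracellular stimuli, and which event timings, suffice
to activate this gene?*

## Who this is for

Systems biologists working with mechanistic pathway knowledge (reaction
lists of complex assemblies, modifications, translocations and
transcription events, e.g. exported from a curated pathway database) who
want to turn that static knowledge into an executable Boolean model and
interrogate it for signal propagation — without enumerating a state
space that is astronomically large (a 9000-place model has 2^9000 ≈
10^2709 states).

## The formalism

A model is a set of Boolean **places** (a biomolecule in a given
activity state and compartment, e.g. `SMAD2_3_SMAD4_active_nucleus`)
connected by guarded transitions

```
A  -[ h [C] ]->  B
```

which fire at a step when the **event** `h` is present, the source `A`
is True and the **condition** `C` (a formula over places with ∧, ∨, ¬)
holds; firing deactivates `A` and activates `B`.  Events form a small
signal algebra: `h1 default h2` is present when either is,
`h when C` selects occurrences of `h` at states satisfying `C`.
Writing `h_tr = h when (A ∧ C)` for the transition event, each place
updates synchronously by

```
A' = h_in  default  (¬h_out  default  A)
```

— activation prevails over inactivation, and untouched places keep
their value.  Multi-molecule reactions (complex assembly, m-input
reactions) compile to several single-source transitions **sharing one
event atom**, so all of them fire in the same step.

Reachability of a property P within n steps (default n = 10) is decided
by unrolling these update rules into CNF via the Tseitin translation and
handing the formula to a SAT solver: a satisfying assignment is exactly
an allocation of initialization places and event timing — a **scenario
(F, T)** with F a subset of the *frontier* (places with no incoming
transition) and T a per-step set of present events.  Scenarios are
shrunk to **minimal** ones (removing any single place of F or any single
event occurrence of T breaks reachability), distinct minimal scenarios
and distinct **trajectories** (the set of places activated en route) are
enumerated with blocking clauses, and trajectories feed the downstream
analytics: binary occurrence matrices, hierarchical clustering
(Euclidean distance), Smad-only / non-Smad / mixed gene classification
and stimuli-combination extraction.

## Worked example

The packaged toy TGF-β model (16 places, 10 transitions) wires ligand /
receptor complex formation, Smad2/3 activation, Smad2/3–Smad4 complex
assembly, importin-dependent nuclear translocation and two target
genes — `SMAD7` (Smad-dependent only) and `JUN` (also reachable through
a MAPK bypass driven by the receptor complex or by EGF):

```
$ gtreach fixtures --name toy_tgfb --out toy.model
$ gtreach minimal --model toy.model --property JUN
scenario  step  frontier                                     timing
0         10    JUN_gene,MAPK,TGFB,TGFBR                     a1;a6;;;;;;;;a7
1         10    IMPORTIN,JUN_gene,SMAD2_3,SMAD4,TGFB,TGFBR   a1;a2;;;;;;a3;a4;a7
2         10    EGF,JUN_gene,MAPK                            ;;;;;;;;a8;a7
```

Three minimal scenarios: activating `JUN` requires either the Smad route
(TGF-β, its receptor, the Smad pool, Smad4 and importin), the non-Smad
TGF-β/MAPK route, or EGF-driven MAPK — each listed with one witness
timing (`;`-separated steps, empty = idle).  Because some trajectories
contain Smad places and some do not, `JUN` classifies as **mixed**,
while every trajectory to `SMAD7` contains a Smad place (**smad-only**).

```
$ gtreach graph --model toy.model
nodes   16
edges   20
components      1
largest_component       16
modularity_Q    0.4922  clusters        4
```

The same functions are available as a library
(`gtreach.check`, `gtreach.enumerate_minimal`,
`gtreach.gene_scenario_screen`, `gtreach.trajectory_analysis`, …), and
`gtreach translate` compiles reaction lists (NCI-PID-style XML or the
JSON reaction dialect) into models, merging pathways with redundancy
removal.

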