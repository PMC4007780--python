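# Methods

## Model semantics

A guarded-transition model is a tuple (P, T, I): Boolean places P,
transitions `A -[h [C]]-> B` with event expression h over atoms I and
condition C over P, and the derived maps T_in(A) / T_out(A).  One step
is a *synchronous* function of the step-k state: for each transition the
transition event `h_tr = h when (A ∧ C)` is evaluated entirely on the
prior state (including conditions nested in `when`), and each place
updates by the prioritized rule — some in-transition fired ⇒ True; else
some out-transition fired ⇒ False; else unchanged.  Consequences the
test suite checks explicitly:

* **frame property** — untouched places keep their value;
* **synchrony** — the step is invariant under transition reordering and
  under adding transitions whose events never occur;
* **complex synchronization** — transitions sharing one event atom and
  cross-conditioned on each other's sources fire in the same step,
  consuming every component and producing the complex at once.

A *realization* assigns each step a set of present atoms.  The strict
reading excludes the all-absent step; since an idle step provably
changes nothing, strictness affects only the shape of the SAT search
space, never any-step reachability.  Both modes are exposed
(`strict=True` is the default for search).

## Frontier, scenarios, minimality

The frontier — places with no in-transition — is the only set that may
be initialized True; everything else starts False.  A scenario (F, T) is
an initialization F ⊆ frontier plus a timing T.  A witness scenario is
*minimal* when deleting any single place of F, or any single event
occurrence from any step of T, breaks reachability under the remaining
timing.

One subtlety: a deletion-minimal timing keeps only load-bearing
occurrences, so its slack steps are empty.  Under a strictly-nonempty
realization no scenario shorter than the horizon could ever be minimal
(the forced filler occurrence is always deletable), so minimality
checking and shrinking simulate leniently.  Shrinking is greedy
destructive deletion to a fixpoint in a fixed order (places lexically,
then occurrences by (step, atom)): the result is reproducible and always
passes the exact single-deletion test, though it is one minimal scenario
among possibly several — deletion-minimality, not minimum cardinality.

## SAT encoding

Bounded reachability unrolls the update rule over steps 0..n: one
variable per (place, step) and (atom, step), Tseitin auxiliaries for the
guard formulas, the biconditional `A@{k+1} ↔ h_in ∨ (¬h_out ∧ A@k)` per
place and step, units forcing non-frontier places False at step 0, and
(in strict mode) an at-least-one-atom clause per step.  The property is
asserted at the final step or as a disjunction over all steps (default:
any-step — reachability, not exact-time arrival).  Variable numbering is
places, then events, then auxiliaries (lexical, then step), making
DIMACS output byte-stable.  An optional optimization pass does constant
folding and structural hashing of auxiliary definitions (common
subexpressions); it is checked to preserve satisfiability and reduces
clause count only.  Clause count grows linearly in transitions × n.

Every satisfying assignment is decoded to (F, T) and **re-simulated
before being reported**; a decode that failed re-simulation would raise,
never return "unreachable".  Enumeration of distinct minimal scenarios
blocks the exact step-0 frontier assignment of every decoded and every
returned F (termination in ≤ 2^|frontier| rounds); enumeration of
distinct trajectories for a fixed F blocks activated-sets through
indicator variables `act_p ↔ ∨_k p@k`.

The solver is a self-contained CDCL (two watched literals, first-UIP
learning, activity-based branching, phase saving toward False, which
biases witnesses toward sparse activations).  Formulas here are a few
hundred to a few thousand variables, well within its range.

## Reaction compilation and merging

An m-input, p-output reaction record compiles to m×p single-source
single-target transitions sharing one fresh event `h_<id>`; each
transition's condition conjoins the other inputs, the activators and the
negated inhibitors.  Complex assembly/dissociation are the m×1 / 1×p
cases; translocation, modification and transcription the 1×1 case with
mediators carried as activators.  Merging pathway models keys
transitions on (source, target, normalized condition) — conditions are
flattened, sorted and deduplicated so syntactic shuffles compare equal —
and combines the events of co-keyed transitions with `default`.  The
merge criterion for "same reaction seen twice" is thus syntactic
equality after normalization; semantically equivalent but structurally
different conditions stay separate, a deliberately conservative choice.
Merging is idempotent, commutative up to ordering, and loses no species.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| horizon n | 10 | bounded search depth, the representative solution size for signaling cascades of this kind; configurable per query |
| mode | any-step | property may hold at any step ≤ n |
| strict | True | ≥1 present atom per step in the SAT search |
| scenario/trajectory limits | 50–100 | blocking-clause enumeration caps; enumeration is exhaustive when it stops before the cap (UNSAT) |
| linkage | average | clustering linkage; the distance metric (Euclidean on 0/1 occurrence rows) is the fixed part |
| Smad patterns | SMAD2/SMAD3/SMAD4 | substring match on place names |

## Synthetic data

`random_model(n_places, n_transitions, condition_density, seed)` draws
uniformly random single-source transitions, each with a fresh event, and
with probability `condition_density` a 1–2 literal condition (negations
optional).  The motif grammar enumerates chains, cycles, diamonds,
complex-formation motifs, fan-in/fan-out stars and condition-decorated
chains up to 8 places.  The toy TGF-β fixture (16 places) reproduces the
canonical pathway skeleton: ligand+receptor complex, Smad2/3 activation,
Smad2/3–Smad4 complex on a shared event, importin-conditioned nuclear
translocation, a Smad-only target (SMAD7) and a bypass target (JUN)
reachable via receptor-driven or EGF-driven MAPK.  Its expected answers
(frontier, minimal F-sets, Smad classes) were computed with the
explicit-state oracle and frozen in `data/toy_tgfb.meta.json`.

What the generators do **not** emulate: realistic degree distributions,
the heavy redundancy of curated databases (families, abstractions),
self-loops, and quantitative kinetics.  Passing tests therefore certify
the semantics, the engine and the analytics — not biological fidelity of
any particular network beyond the toy topology.

## Verification strategy

Two fully independent oracles live in `tests/oracles.py`: a per-place
truth-table simulator (separate code path, no shared evaluation) and an
explicit-state BFS over all frontier subsets × event subsets.  The SAT
engine is checked against BFS verdicts, the simulator against the
truth-table oracle, enumeration against brute force over every (F, T) on
tiny models, and modularity/clustering outputs against independent
re-computation of Q and planted partitions.  Witness self-verification
is a hard assertion inside `check()` itself.

## Known limitations

* Deletion-minimality does not imply minimum size; the enumeration
  reports one representative timing per frontier set.
* Frontier-monotonicity ("enlarging F cannot lose the goal") holds only
  for inhibitor-free models; with negated condition literals an extra
  active place can block a guard or fire a consuming transition.  It is
  asserted only on negation-free models.
* The trajectory-sharing predicate between two genes (activated-set
  overlap excluding the gene places) is one reasonable operational
  definition among several; it is configurable at the record level.
* The XML importer targets a simplified Interaction/InteractionComponent
  structure; family/abstraction nodes are out of scope, and the JSON
  reaction dialect is the canonical tested path.
* The acceptance script sizes its samples (1000 random models for the
  semantics check, 200 for SAT-vs-BFS, horizon ≤ 4 for oracle-checked
  search) so the whole run finishes in seconds at full coverage of the
  motif grammar.
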