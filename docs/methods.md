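# Methods

## Formal setting

A reaction network is ⟨M, R⟩ with species M and reactions R; a reaction is
a pair of multisets (lhs, rhs) over M with positive integer
multiplicities, stored sparsely. Support and product of a reaction are the
*sets* of species on the left and right hand side — multiplicities never
matter for them. For X ⊆ M, R_X = { r : supp(r) ⊆ X }; empty-support
(inflow) reactions belong to every R_X.

- X is **closed** iff prod(r) ⊆ X for every r ∈ R_X; the **closure** of X
  is the least fixed point of adding products of applicable reactions.
- X is **semi-self-maintaining (SSM)** iff every species consumed by some
  r ∈ R_X is produced by some r′ ∈ R_X.
- X is **self-maintaining (SM)** iff some strictly positive v over R_X has
  N_X v ≥ 0 on the rows of X, with N[s, r] = rhs_mult − lhs_mult.
- An **organization** is a closed SM set; SM implies SSM (asserted as a
  runtime invariant whenever a set is analysed).
- X is **reactive** iff every member occurs in supp(r) ∪ prod(r) of some
  r ∈ R_X; the largest reactive subset is computed as a greatest fixed
  point by deleting non-participating species until stable. Non-reactive
  members carry no dynamics, so organization-level analyses focus on
  reactive organizations.

**Causal graph over X**: edge s₁ → s₂ iff some r ∈ R_X has s₁ ∈ supp(r)
and s₂ ∈ prod(r). Catalysts (same species both sides) induce self-edges —
intentionally, since a catalytic self-loop is the minimal ("trivial")
cycle. Cycles are elementary (no repeated species), counted up to
rotation, canonicalized by rotating the lexicographically smallest species
to the front. Edges come from R_X, not the global reaction set, so cycle
signatures are organization-relative.

**Cycle theorem.** If T is reactive and SSM and strictly contains a closed
set C, then the causal subgraph induced on T \ C contains a cycle. Sketch:
some species of T \ C must be consumed within R_T (otherwise closure of C
is violated by the reactions that produce the species of T \ C); SSM gives
each consumed species a producing reaction whose support cannot lie inside
C (closure again), yielding a predecessor in T \ C; finiteness closes the
chain into a cycle. The checker verifies the premises explicitly and
treats "premises hold but no cycle found" as an implementation error, not
a result.

**Corollary.** For nested reactive organizations O₁ ⊂ O₂ the larger gains
at least one cycle supported on O₂ \ O₁, and cycle-signature containment
implies set containment (so signatures identify organizations). The
second half follows from the theorem applied to T = O₁ and
C = closure(O₁ ∩ O₂): any cycle witnessing O₁ ⊄ closure(O₁ ∩ O₂) would
lie in O₁ \ O₂, contradicting signature containment. Both halves are
swept over thousands of seeded random networks in the test suite.

## Numerical decisions

- **Self-maintenance LP.** Strict positivity v > 0 is encoded as v ≥ 1,
  valid because N v ≥ 0 is invariant under positive scaling. Zero
  objective (pure feasibility), `scipy.optimize.linprog` with HiGHS.
  Constraint rows are restricted to X and columns to R_X; species outside
  X are unconstrained. An empty R_X is trivially SM with an empty witness.
  Accepted witnesses must violate constraints by at most 1e-9; otherwise
  an exact rational re-check of the witness (Fractions) must pass, and a
  solver failure distinct from clean infeasibility raises `LPError`.
  The test suite cross-validates LP verdicts against an exact
  Fourier–Motzkin elimination oracle over the rationals on every subset of
  small random networks.
- **Organization enumeration** generates all closed sets by breadth-first
  re-closing (every closed set is reachable from closure(∅) by adding one
  species at a time, since closure is monotone), then LP-filters them.
  Complexity is O(#closed sets · |M| · closure cost); an exhaustive bound
  of 22 species guards it. Beyond the bound the package refuses and
  offers the candidate-verification path (analyse one set at a time) —
  the genome-scale workflow, where organizations are imported rather than
  enumerated.
- **Cycle machinery.** Cycle existence via strongly connected components
  (linear time); enumeration via Johnson's algorithm (`networkx
  simple_cycles`) with an optional length bound; the truncation flag is
  set when the bound is below the largest nontrivial SCC. Knockout
  screens classify a reaction as "in the cycle" when it witnesses an edge
  inside a nontrivial SCC (or a self-edge): SCC membership is the notion
  that scales to genome-size networks, where elementary-cycle enumeration
  is infeasible.
- **Knockout screens.** Removing a reaction cannot break closure (this is
  still re-verified at runtime as a cheap guard), so criticality of r for
  organization O reduces to one SM LP over R_O \ {r}. Survival is *not*
  monotone under removal sets: deleting a reaction also deletes its v ≥ 1
  constraint, so a larger removal can be easier to survive (e.g. for
  {0 → a, a → 0}, O = {a} survives removing both reactions but not the
  inflow alone). The suite documents this with the counterexample rather
  than asserting a monotonicity that does not hold.
- **Mass-action dynamics.** dx/dt = N diag(k) m(x) with
  m_r(x) = ∏ x_s^lhs_mult; the Jacobian is closed-form. Simulation uses
  stiff-capable adaptive integrators (LSODA default) with a terminal
  blow-up event at ‖x‖∞ = 1e6 — polynomial fields can escape in finite
  time and would otherwise grind the integrator; tiny negative excursions
  are clipped and flagged. Fixed points are located by bounded
  trust-region least squares (non-negativity through bounds, analytic
  Jacobian) followed by a damped-Newton polish to residual 1e-9.
  Stability verdicts compare Jacobian eigenvalue real parts against
  ±1e-9: all below −tol → stable, any above +tol → unstable, otherwise
  marginal (e.g. conserved quantities). The support of a fixed point uses
  the threshold max(1e-6, 1e-6 · max concentration), which separates
  decayed from persistent species across the stiff regimes; property
  tests additionally skip fixed points with a coordinate in (1e-9, 5e-2),
  where algebraically decaying modes (high-order monomial kinetics decay
  like t^(-1/(d-1)) and can stall near the boundary at residuals below
  tolerance) make the classification genuinely ambiguous at finite time.

## The autocatalytic network family

The template couples an environment to a catalyst chain c₁ … c_n (n ≥ 2):

| reaction | form | rate | role |
|---|---|---|---|
| supply | s → s + f | cI = 2 | supply catalyses food import (trivial cycle at s) |
| freturn | f → s | 1 | food returns to the supply pool |
| sdecay | 2s → s | 1 | quadratic crowding loss of supply |
| cat_i | f + c_i → c_i + c_{i+1} | 1 | catalytic step; i = n closes the cycle iff feedback present |
| deg_i | c_i → g | cD = 1 | catalyst degradation |
| gout | g → w | 1 | debris export |
| wout | w → 0 | cD = 1 | waste dilution |

Six variants: closed vs open catalytic cycle × reversibility mode (none /
all chemical steps / all but one designated step, default the
cycle-closing catalytic step, or the last catalytic step when the cycle is
open). Reverse reactions (rate λ = 0.1) attach to the chemical
transformations only — supply, food return, catalytic steps. Reversing a
degradation would regenerate catalysts from debris and erase the very
distinction between open and closed variants, and reversing the final
outflow would create an inflow and a non-empty minimal organization.

Structure of the closed variants: reactive organizations are exactly
∅ ⊂ {s, f} ⊂ M. The middle organization carries the trivial supply cycle;
the top adds the catalyst n-cycle. Open variants lose the top
organization because c₁ has no producer: its LP row reads −v_deg1 < 0.

Parameter choices and what they do:

- **cI = 2.** The n=2 closed variant has the unique positive fixed point
  s = f = 1, c₁ = c₂ = (cI − 1)/2, g = w = cI − 1; cI = 1 is the
  transcritical boundary where the catalysts' niche vanishes, so the
  default sits the system firmly in the coexistence regime.
- **Quadratic crowding (2s → s).** With linear supply removal the
  supply/return loop has gain cI > 1 and no finite attractor once the
  catalysts are gone; the quadratic term gives the bare environment a
  stable positive state (open variants: catalysts, debris and waste
  famish while s, f persist — the dynamical picture of falling back to
  the middle organization), keeps the closed-variant fixed point at round
  values, and widens its stability margin (slowest eigenvalue real part
  −0.37 at n = 2).
- **λ = 0.1, scan {0.01, 0.05, 0.1, 0.2, 0.5}.** Existence and stability
  verdicts for every variant are constant across this weak-to-moderate
  range. At λ ≈ 1 (reverse as strong as forward) the supply step is fully
  undone and the positive branch disappears — reverse rates are weak
  perturbations, not symmetric chemistry, in this family.
- **Default initial condition 1.0 per species**; the qualitative verdicts
  are robust over random positive starts, which the suite asserts with 20
  seeded starts per open variant.

The spindle assembly checkpoint model (SAC) is the n = 4 template with
catalysts renamed O-Mad2, Cdc20, O-Mad2*, Cdc20:Mad2; the spindle
position checkpoint model (SPOC) is the n = 5 template with Kin4, Bfa1,
Kin4*, Bfa1*, SM, the SM signal closing the cycle. Opening the cycle
(removing the positive feedback) starves the checkpoint proteins while
the environment persists. Kinetic constants are the template defaults —
the point of these instantiations is the topology of the feedback, not
fitted kinetics.

The worked example network (`fig1`) — five species, one catalytic
self-loop, a two-cycle, a second catalytic trivial cycle and a
three-cycle, four elementary cycles in total — is a synthetic
reconstruction built to exhibit exactly the features it is used to teach:
a product that is a set rather than a multiset (a → a + 2b), a singleton
closed set ({c}: its only consuming reaction also needs b), and a small
but non-trivial cycle inventory.

## The random-network generator

Property-test inputs are seeded random networks: n_species species,
n_reactions reactions, up to max_arity reactants/products with
multiplicity 1–2, inflow probability 0.15, catalyst probability 0.3
(a species added to both sides). The same seed always yields the same
network. The generator emulates the combinatorial variety of small
reaction systems — inflows, outflows, catalysis, autocatalysis — not the
degree distributions or conservation structure of real metabolic
networks; what passing sweeps show is that the *theorems and
cross-validations hold across arbitrary stoichiometries*, not that any
biological frequency is reproduced. Many draws have divergent or
algebraically decaying dynamics; dynamical property tests therefore gate
on clean convergence and report how many networks passed the gate.

## Problem sizes

Default verification runs use: all six variants at n = 2..4 with 20
seeded fixed-point starts per open variant; 1000 random 5-species
networks for the cycle-theorem and corollary sweeps (≈14 000 (T, C)
pairs); 200 networks × 32 subsets for the LP/oracle cross-validation;
200 networks for the simulation-support sweep; the knockout screen on the
n = 3 closed variant. These sizes keep a full verification under two
minutes on one core while exercising every code path; all counts scale
with a single loop bound.

## Known limitations

- Exhaustive organization enumeration is exponential and capped at 22
  species; no constructive/flux-lattice enumeration is implemented.
- The SBML reader ignores kinetic laws, compartments and units; boundary
  and constant species are mapped to ordinary species, modifiers to
  catalysts. Non-integer stoichiometries are LCM-scaled (or rejected in
  strict mode).
- COT can refute but never prove the existence of a positive fixed point;
  the dynamics module provides the complementary evidence numerically,
  and a failed multi-start search is evidence, not proof, of absence.
- Stochastic semantics, bifurcation continuation and periodic-orbit
  detection are out of scope.
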