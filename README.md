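# orgcycle

Chemical organization theory (COT) with a cycle overlay: a toolkit for
asking *which self-sustaining compositions of molecular species a reaction
network can support*, and *what role cycles play in creating and
stabilizing them*.

## The problem

A reaction network is a pair ⟨M, R⟩: a set of species M and a set of
reactions R, each reaction a pair of multisets over M (left and right hand
sides). Which subsets of species can persist together? COT answers with
two conditions on a subset X ⊆ M and its applicable reactions
R_X = { r : supp(r) ⊆ X }:

- **closed** — no reaction in R_X produces a species outside X;
- **self-maintaining (SM)** — there is a strictly positive flux vector
  v > 0 over R_X with N_X v ≥ 0, where N is the stoichiometric matrix
  (right minus left multiplicities). This is a linear-programming
  feasibility problem.

A closed and self-maintaining set is a **chemical organization**. The
support of every fixed point of the mass-action ODE system
dx/dt = N diag(k) ∏ x^lhs is an organization, so the organization lattice
is a map of where steady states can live.

The cycle overlay: draw the **causal graph** with an edge s₁ → s₂ whenever
some applicable reaction consumes s₁ and produces s₂ (a catalyst gets a
self-edge). The central structural theorem implemented and property-tested
here: **a reactive semi-self-maintaining set that strictly contains a
closed set must contain a cycle among the species outside that closed
set**. Its corollary: of two nested reactive organizations the larger has
strictly more cycles, cycle-signature containment implies set containment,
and every organization is identified by its cycle set. Qualitative
transitions between self-sustaining compositions therefore require adding
or removing cycles.

The package provides:

- `network` — reaction-network data model, a plain-text reaction-list
  format, an SBML reader, stoichiometry, applicable-reaction and
  largest-reactive-subset computations;
- `organization` — the COT predicates, LP-based self-maintenance with flux
  witnesses, organization enumeration, Hasse diagrams, overproducibility;
- `cycles` — causal graphs, SCC/Johnson cycle machinery, checkers for the
  cycle theorem and its corollary;
- `knockout` — reaction switch-off screens: which reactions (inside vs
  outside the cycles) are critical for an organization's persistence;
- `dynamics` — mass-action ODEs with analytic Jacobians, stiff-capable
  simulation, bounded fixed-point search, eigenvalue stability verdicts;
- `models` — a generalized autocatalytic network family (six variants:
  closed/open catalytic cycle × irreversible/reversible chemistry), the
  spindle assembly (SAC) and spindle position (SPOC) checkpoint
  instantiations, a worked example, and a seeded random-network generator.

## Worked example

The flagship model is an autocatalytic network: an environment (supply
`s`, food `f`, debris `g`, waste `w`) feeding a chain of catalysts
`c1 .. cn`, each converting food into the next; the feedback step closes
the catalytic cycle.

```
$ orgcycle fixtures dump case1 > case1.txt
$ cat case1.txt
supply: s -> s + f
freturn: f -> s
sdecay: 2 s -> s
cat1: f + c1 -> c1 + c2
cat2: f + c2 -> c2 + c1
deg1: c1 -> g
deg2: c2 -> g
gout: g -> w
wout: w -> 0

$ orgcycle orgs case1.txt --reactive-only
{(empty)}  reactive=True
{f,s}  reactive=True
{c1,c2,f,g,s,w}  reactive=True
3 organization(s)
```

Three reactive organizations in a chain ∅ ⊂ {s, f} ⊂ M: the empty
composition, the bare environment, and the full network. Each level up
gains cycles — the middle one the trivial supply cycle (s), the top one
the catalyst cycle (c1 → c2):

```
$ orgcycle cycles case1.txt
(c1)
(c2)
(s)
(c1 -> c2)
(f -> s)
5 cycle(s)
```

Mass-action dynamics (supply rate 2, all other constants 1) confirm the
algebra — the full composition is dynamically reachable and stable:

```
$ echo '{"supply": 2.0}' > rates.json
$ orgcycle simulate case1.txt --rates rates.json --t-end 200
final state:
  s            1
  f            1
  c1           0.5
  c2           0.5
  g            1
  w            1
fixed point residual: 2.78e-15  verdict: stable
support is an organization: True
```

Removing the feedback step (`case2`) removes the catalyst cycle; the top
organization vanishes, the self-maintenance LP for the full set becomes
infeasible, and every simulation ends with the catalysts extinct. The
same contrast drives the SAC and SPOC checkpoint models
(`orgcycle fixtures dump sac`, `... spoc`): with the positive feedback all
species reach a positive steady state, without it the checkpoint proteins
starve.

Genome-scale workflow: read a metabolic model with `--sbml`, verify a
candidate organization, classify its reactions by SCC cycle membership and
screen them with `orgcycle knockout`; exhaustive organization enumeration
is deliberately refused above 22 species — at that scale organizations are
imported, not enumerated.

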