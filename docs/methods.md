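# Methods

## Model

Molecules are extended reduced graphs (ErGs): simple undirected graphs
whose nodes carry one of 15 pharmacophoric labels and whose edges carry one
of 3 bond-order labels. Dissimilarity is the normalized graph edit
distance: the minimum, over edit paths transforming G_a into G_b, of
Σ_t C_t·N_t, divided by L = |V_a| + |V_b|. Classification is plain
1-nearest-neighbour: a query takes the class (active/inactive) of its
minimum-distance reference.

### Cost parameterization

The cost model stores one parameter per unordered substitution pair and
one per label for insertion/deletion, for both alphabets:
C(15,2) + 15 + C(3,2) + 3 = 126 parameters. Consequences, all by
construction rather than by convention:

- substitution costs are symmetric and insertion equals deletion, so GED
  is symmetric in its arguments;
- identity substitutions are not edit operations: they cost exactly 0, are
  not stored, and can never be touched by learning (the diagonal of any
  learned table stays 0).

Defaults are the Harper et al. expert tables; `uniform_costs(1)` is the
no-prior baseline. Cost files are flat CSV (`kind,label1,label2,value`)
written in canonical kind order at full float precision (`repr`), so
write∘read is bit-exact.

## GED computation

**Exact solver** (`exact_ged`): depth-first branch-and-bound over
injective node mappings (each source node maps to an unused target node or
to deletion; unmatched target nodes are inserted), edge operations induced
incrementally against already-assigned nodes, with the current best as
bound. Deterministic tie-break: first-found among equal-cost mappings in
declaration/candidate order. Guarded by a combined-order bound (default
14 nodes); it exists as the oracle, not for scale.

**Bipartite approximation** (`bipartite_ged`): the standard square
assignment construction — substitution cells charge node substitution plus
an optimal assignment between the two incident-edge label multisets
(unmatched edges pay indel); deletion/insertion diagonal cells charge the
node indel plus all incident edge indels; the ε→ε block is 0. The LSAP is
solved with `scipy.optimize.linear_sum_assignment`, the induced node
mapping is converted to a full edit path, and that path's true normalized
cost is returned. Because the induced path is a valid transformation, the
value is an upper bound on the exact GED. Optimal assignments are not
unique, and transposing the matrix can select a different one, so both
orientations are solved and the cheaper induced path kept — this makes the
approximation symmetric and never looser.

Degenerate conventions: distance to an empty graph is the pure
deletion/insertion path cost normalized by the non-empty order; empty vs
empty is 0.

## Cost learning

Per iteration on the training set:

1. leave-one-out classification of every training molecule under the
   current costs (all pairwise GEDs recomputed, since costs changed);
2. for each molecule, D = nearest different-class distance and D′ =
   nearest same-class distance, with the realizing edit paths;
   *misclassified* means strictly D′ > D;
3. select the misclassified molecule with the smallest gap D′ − D (the
   cheapest to repair — minimal disturbance to everything else);
4. holding the two paths' operation counts fixed, compute
   α_t = (D′−D)·L/(m·N_t) for the different-class path and
   α_t′ = (D−D′)·L′/(m′·N_t′) for the same-class path, where m, m′ count
   the operation kinds used on each path;
5. update C̄_t = C_t + α_t, + α_t′, or + (α_t+α_t′)/2 according to which
   paths use kind t; kinds on neither path are untouched.

When the two supports are disjoint this exactly swaps the two fixed-count
path costs (asserted in the tests); with shared kinds the averaged update
moves the gap in the correcting direction. The loop runs to `max_iter`
(default 50) or stops early when nothing is misclassified. Convergence is
not guaranteed — repairing one molecule can break another — so the trace
records every iteration (selected molecule, D, D′, train accuracy, cost
snapshot) instead of hiding oscillation.

Numerical choices:

- **Clamping.** Costs are penalties; an overshooting negative update is
  clamped at 0 with a logged warning (`clamp=False` lets negatives
  propagate for diagnosis).
- **Degenerate paths.** A selected molecule whose realizing path has no
  true edit operations (m = 0, e.g. an identical twin of opposite class)
  cannot be repaired by cost changes; it is logged and skipped in favour
  of the next-smallest gap.
- **Ties.** Everywhere (nearest neighbour, molecule selection, equal-cost
  mappings): lowest input index. The tie rules make the whole pipeline a
  pure function of its inputs.
- Tolerances: the α reconstruction identities hold to 1e−9 in the tests;
  comparisons inside the solvers are plain float comparisons (no fuzz),
  which is safe because ties only affect which of several equal-cost
  results is reported.

## Screening protocol

Per target, at most the first 100 actives (file order) are kept with the
same number of leading inactives, then the published train/test split is
applied. Costs are learned per target on its train half; a *dataset* table
is the unweighted mean of its targets' tables (pooling targets into one
learning set would mix incomparable activity labels); the *cross-dataset*
table is the unweighted mean of the dataset tables. Test halves are
classified against their own train halves under the cross-dataset mean
table; `per_target: true` instead evaluates each target under its own
learned table (the diagnostic mode for datasets where mean costs
underperform). Accuracy aggregation is unweighted at both levels, and the
report recomputes its means from the per-target rows exactly.

## Synthetic data

The generator emulates the benchmark structure without chemistry. One
random connected backbone (spanning tree + density-0.3 extra edges, mostly
single bonds) is labeled twice: the active prototype from an
aromatic/hydrophobic-rich label profile, the inactive prototype from a
donor/acceptor-rich profile — the class signal lives in pharmacophore
composition, as in real ErGs. Class members are sampled by applying
`perturb_ops` (default 2) random valid edit operations to the prototype;
each perturbation also returns its generating edit path, which by
construction upper-bounds the exact GED — the oracle used throughout the
engine tests.

`crossover_fraction` plants boundary molecules: before perturbation, a
planted molecule has `crossover_ops` (default 4, half the default
prototype order of 8) node labels switched to the other prototype's label
at the same position, placing it roughly equidistant between the classes.
Under uniform costs some plants fall on the wrong side — the regime the
learning rule is meant to repair by re-weighting the class-distinguishing
substitutions. Default population sizes in the tests (16 molecules per
class, 8-node prototypes) keep a 50-iteration learning run at a few
seconds while leaving the planted/clean distinction clearly visible.

What the generator does **not** model: valence rules, ring statistics,
realistic label co-occurrence, decoy property matching, or the size
distribution of real screening libraries. Passing tests therefore show the
algorithmic contracts hold (bounds, identities, determinism, efficacy on
planted structure), not that any particular accuracy carries over to real
benchmark data.

## Known limitations

- The learning loop is O(iterations × n² ) GED computations on the train
  set; it is meant for the few-hundred-molecule-per-target regime of the
  screening protocol, not for whole libraries.
- The bipartite approximation's gap to the exact GED is unbounded in
  general; the package asserts only the upper-bound contract.
- Learning can oscillate (see the trace); accuracy is not monotone per
  iteration, and endpoint improvement is an empirical property of
  separable-after-reweighting data, not a theorem.
- The shipped learned reference table is transcribed at 2-decimal
  precision and is not re-derivable without the external benchmark
  datasets.
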