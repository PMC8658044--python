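# ergged

Graph edit distance over extended reduced graphs (ErGs), with learnable
edit costs, for ligand-based virtual screening (LBVS).

## The problem

In ligand-based virtual screening, the bioactivity of a candidate molecule
is predicted from its similarity to molecules with known activity against a
target. A compact way to compare molecules at the pharmacophore level is the
**extended reduced graph**: nodes carry one of 15 pharmacophoric feature
labels (hydrogen-bond donor `[0]`, acceptor `[1]`, charges `[2]`/`[3]`,
hydrophobic group `[4]`, aromatic ring system `[5]`, carbon/non-carbon link
nodes `[6]`/`[7]`, and the observed composite features such as `[0,1]`),
and edges carry the bond order (`-`, `=`, `≡`).

Dissimilarity between two ErGs G_a and G_b is the **normalized graph edit
distance**

    GED(G_a, G_b; C) = min_path ( Σ_t C_t · N_t ) / L ,    L = |V_a| + |V_b| ,

the minimum over all edit paths (node/edge insertion, deletion,
substitution) of the summed operation costs C_t, normalized by the total
node count. With substitution costs symmetric, insertion tied to deletion,
and identity substitutions fixed at zero, the ErG alphabets give exactly
**126 cost parameters**. A query molecule is classified active/inactive by
the class of its nearest neighbour under this distance — so classification
quality is entirely determined by the cost table.

`ergged` provides:

- the expert default cost tables of Harper et al. (`harper_defaults()`),
  a uniform baseline, and cost-table arithmetic/serialization;
- an exact branch-and-bound GED solver (small graphs; the test oracle) and
  the fast bipartite-assignment approximation (Hungarian method), both
  returning the realizing edit path;
- nearest-neighbour classification and accuracy evaluation;
- an **iterative cost-learning algorithm**: each iteration selects the
  misclassified training molecule whose nearest same-class distance D′
  exceeds its nearest different-class distance D by the smallest gap, and
  shifts the costs so the two fixed-count path costs swap:
  α_t = (D′−D)·L/(m·N_t) on the different-class path,
  α_t′ = (D−D′)·L′/(m′·N_t′) on the same-class path, averaged where the
  paths share operation kinds;
- the per-target screening protocol (first-100 subsetting, per-dataset
  learning, cross-dataset mean costs, test-half evaluation);
- a seeded synthetic-data generator so every component is testable without
  the external benchmark datasets.

## Worked example

The packaged worked-example pair transforms a four-node chain
`[1]-[6]-[5]-[7]` by six operations: delete node `[1]`, delete a single
bond, insert node `[5]`, insert a single bond, substitute `[7]` by `[2]`,
and substitute a single bond by a double bond.

```python
from ergged import harper_defaults, edit_path_cost, exact_ged, bipartite_ged
from ergged.synthetic_data import worked_example_graphs, worked_example_path

costs = harper_defaults()
path = worked_example_path()
print(edit_path_cost(path, costs, normalize=False))
# 10.0        -> 2 + 0 + 2 + 0 + 3 + 3: the printed transformation's cost

g1, g2 = worked_example_graphs()
res = exact_ged(g1, g2, costs)
print(res.raw_cost, res.path.L, res.distance)
# 6.0 8 0.75  -> the *minimal* path is cheaper than the illustrated one;
#                normalizing by L = 4 + 4 nodes gives GED = 0.75
print(bipartite_ged(g1, g2, costs).distance)
# 0.75        -> the approximation is tight on this pair
```

From the shell, the same machinery:

```sh
$ ergged synth --seed 4 --n-per-class 6 --prototype-order 5 --out demo --name demo
wrote demo/demo.graphs and demo/demo.split
$ ergged learn --train demo/demo.graphs --init ones --max-iter 10 --out learned.csv
# 1 iterations, final train accuracy 100.00%, converged_early=True
```

(Here the two synthetic classes are already perfectly separated under
uniform costs, so learning stops immediately; planted boundary molecules —
`GeneratorSpec(crossover_fraction=...)` — produce the regime where the
update rule actually fires. See `docs/methods.md`.)

## Data files

`src/ergged/data/` ships, as plain CSV/text:

- `learned_costs_reference.csv` — a reference learned cost table obtained
  with this learning procedure (Harper initialisation, averaged across the
  six public LBVS benchmark datasets: CAPST, DUD-E, GLL&GDD, NRLiSt-BDB,
  MUV, ULS-UDS). Shipped for convenience; reproducing it requires the
  external benchmark data, which this package does not download.
- `single_cost_presets.csv` — earlier published one-parameter-at-a-time
  optimisation results (experiments C1–C4 per dataset), as presets.
- `worked_example.graphs` — the hand-transcribed worked-example pair; the
  second graph is a synthetic reconstruction consistent with the printed
  operation list.
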