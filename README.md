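# ppintopo

Topological analysis and interest-bias detection for protein–protein
interaction networks (PPINs).

Interaction databases such as IntAct aggregate protein–protein interaction
records from many experiments of very different character: genome-scale
yeast-two-hybrid screens, small coimmunoprecipitation studies focused on a
single disease protein, and everything in between. The resulting networks
are not uniform samples of the interactome — a protein that received
exceptional scientific attention becomes an artificial hub, a single
dominating experiment imprints its method's blind spots on the whole graph,
and records are routinely duplicated, reversed, self-looped, or attached to
non-protein molecules. `ppintopo` is for computational biologists who want
to *measure* these distortions before drawing biological conclusions from a
PPIN: it parses the data, cleans it into a simple undirected graph with
exact accounting, computes the standard topological measure suite, runs
robustness and failure-cascade simulations, and raises rule-based bias
flags.

## What it computes

For a cleaned network G(V, E) with N = |V| nodes, L = |E| edges and
adjacency A_ij:

- **Degree structure** — the distribution p_k, the relative hub size
  k_max/N, and a discrete power-law fit p_k ∝ k^(−γ): maximum-likelihood γ
  at every candidate cutoff k_min, cutoff chosen by minimal
  Kolmogorov–Smirnov distance, goodness of fit by semiparametric bootstrap
  (plausible when p > 0.1). Scale-free networks are expected to have
  γ ∈ (2, 3).
- **Mixing** — the degree correlation coefficient r (Pearson correlation of
  degrees over the 2L directed edge ends, with the full mixing matrix e_xy
  and marginals a_x, b_y), and the average nearest-neighbour degree
  ann(i) = (1/k_i) Σ_j A_ij k_j with its k-vs-⟨ann⟩ plot table.
- **Impact curves** — for each degree cutoff K, the subnetwork G_K induced
  by nodes with degree ≤ K yields s1(K) = L_K/L and s2(M_K = N_K/N) = L_K/L:
  how much of the interaction mass the low-degree nodes carry.
- **Centralities** — betweenness B(i) = Σ σ_kl(i)/σ_kl (normalized by
  (N−1)(N−2)/2), closeness C(i) = (N−1)/Σ_j d(i,j), eigenvector centrality
  (principal eigenvector of A, unit Euclidean norm), and clustering
  Cl(i) = 2L_i/(k_i(k_i−1)).
- **Robustness** — targeted attacks removing nodes in descending order of
  degree/betweenness/closeness/eigenvector centrality, random-failure
  Monte-Carlo ensembles, and the decomposition point d: the smallest removed
  fraction at which the relative largest component falls below 0.01.
- **Failure cascades** — a threshold contagion: a seed node fails, and any
  node with a fraction ≥ F of its neighbours failed follows, iterated to
  the unique fixed point; P is the final failed fraction.
- **Bias flags** — a dominant hub (> 15 % of links on one node), γ outside
  (2, 3), one detection method (> 90 %) or one publication (> 50 %)
  dominating the records, and assortative mixing (r > 0), each reported
  with the observed value.

## Worked example

```python
from ppintopo import (assortativity, clustering, fit_power_law,
                      hub_contribution, largest_component, make_graph)
from ppintopo.fixtures import FixtureSpec
from ppintopo.simulate import (cascade_summary, decomposition_point,
                               random_failure, targeted_attack)

net = make_graph(FixtureSpec.make("barabasi_albert", n=1000, m=2, seed=42))
lcc = largest_component(net)
fit = fit_power_law(list(lcc.degrees().values()), n_bootstrap=200, seed=0)
print(f"N = {lcc.n_nodes}, L = {lcc.n_edges}")
print(f"gamma_hat = {fit.gamma_hat:.2f} at k_min = {fit.k_min}")
d_k = decomposition_point(targeted_attack(lcc, "degree"))
d_rand = decomposition_point(random_failure(lcc, mc=100, seed=0).mean_trajectory())
print(f"d_k = {d_k:.3f}, d_random = {d_rand:.3f}")
print(f"cascade F=0.25: P_max = {cascade_summary(lcc, 0.25).p_max:.2f}")
```

prints

```
N = 1000, L = 1996
gamma_hat = 2.66 at k_min = 3
d_k = 0.272, d_random = 0.888
cascade F=0.25: P_max = 1.00
```

The preferential-attachment graph behaves like a textbook scale-free
network: γ in (2, 3), collapse after removing 27 % of nodes by degree but
only after 89 % under random failure — the vulnerability/robustness
contrast that distinguishes hub-dominated networks — and at a permissive
cascade threshold (F = 0.25, any node with ≥ 25 % failed neighbours
follows) a failure can sweep the entire network.

Real datasets enter through the MITAB reader and the same pipeline:

```sh
ppintopo analyze interactions.mitab --out results/ --seed 1
ppintopo fixtures mitab --edges 100 --out synthetic.mitab --duplicates --reversed-pairs
ppintopo compare parkinson.tsv cancer.tsv huri.tsv
```

`analyze` emits a JSON report containing the dataset summary, the cleaning
log (duplicates, reversed pairs, self-loops removed), all measures above,
the attack/failure decomposition points, the cascade screen and the bias
flags.

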