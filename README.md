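# symptomnet

Network analysis of residual mood symptoms and self-reported medication
side effects in the euthymic (inter-episode) phase of bipolar disorder.

Patients who are formally euthymic — MADRS total ≤ 10 and YMRS total ≤ 12 —
still report depressive and manic residual signs alongside side-effect
complaints, and the two are easy to confuse in the clinic. `symptomnet`
treats each questionnaire item (32 PRISE-M side-effect items coded 0–2,
10 MADRS depression items coded 0–6, 11 YMRS mania items coded 0–4/0–8) as
a node in a pairwise Markov network and estimates which items are
conditionally associated, which items are central, how stable those
conclusions are under resampling, and how the items organize into
data-driven clusters that cut across the original questionnaires.

## The model

For discrete items \(x_1,\dots,x_p\), the mixed graphical model is fit by
nodewise regression: each node \(j\) is regressed on all others with an
\(\ell_1\)-penalized Poisson regression

\[
x_j \mid x_{-j} \sim \mathrm{Poisson}\!\big(\exp(\alpha_j + \textstyle\sum_{k \ne j}\beta_{jk} \tilde x_k)\big),
\qquad \hat\beta_j = \arg\min_\beta\; -\tfrac1n \ell(\beta) + \lambda \lVert\beta\rVert_1 ,
\]

with standardized predictors \(\tilde x_k\), \(\lambda\) chosen per node by
the extended BIC
\(\mathrm{EBIC}_\gamma = -2\hat\ell + \mathrm{df}\log n + 2\gamma\,\mathrm{df}\log(p-1)\)
with \(\gamma = 0.25\), and an edge \((i,j)\) kept when both directed
coefficients are nonzero (AND rule; the edge weight is their mean). On top
of the estimated network the package computes:

- **Centrality** — strength \(s_i=\sum_j |w_{ij}|\), closeness, betweenness;
- **Predictability** — per-node \(R^2\) from an unpenalized refit on the
  selected neighbors (high > 0.5, moderate 0.15–0.5);
- **Topological overlap** — flags item pairs that measure near-identical
  constructs (TO close to 1);
- **Accuracy and stability** — nonparametric bootstrap 95% CIs per edge,
  and case-dropping subset bootstrap with the correlation-stability (CS)
  coefficient (CS > 0.5 = high stability);
- **Clustering** — smart-local-moving (SLM) modularity optimization, with
  conductance/modularity/coverage quality metrics, bridge nodes (top-5
  bridge strength, ties extended) and per-cluster stabilizing nodes;
- **Power analysis** — simulation of edge-recovery sensitivity at a given
  sample size against known sparse ground-truth networks.

Because clinical cohort data cannot be redistributed, the package ships a
first-class synthetic-data module: ground-truth networks with exact edge
counts, plus two samplers (a Gaussian copula with prescribed latent
partial correlations, and a Gibbs sampler for the truncated pairwise
count model) that generate questionnaire-like datasets with known
structure for every downstream stage.

## Worked example

```python
import symptomnet as sn

schema = sn.analysis_schema("male")          # 52-item single-sex frame
truth = sn.generate_network(52, density=0.08, weight_low=0.0,
                            weight_high=0.3, seed=7)
data = sn.sample_copula(truth, schema, n=634, seed=8)

net = sn.estimate_network(data)              # gamma=0.25, AND rule
print(f"density {net.density():.4f} ({net.n_edges}/{net.n_possible_edges})")

part = sn.slm_partition(net, seed=1)
print(f"{part.n_clusters} clusters, Q = {part.modularity:.3f}")

sens, spec = sn.score_recovery(truth.edge_mask(), net.edge_mask())
print(f"sensitivity {sens:.2f}, specificity {spec:.4f}")
```

Output:

```
density 0.0392 (52/1326)
16 clusters, Q = 0.633
sensitivity 0.46, specificity 0.9975
```

Of the 1326 possible item pairs, 52 conditional associations survive the
penalized fit; essentially no spurious edges appear (specificity ≈ 1),
while at n = 634 only the stronger half of the true edges is detectable —
which is exactly what the power module quantifies. The same analysis is
scriptable from the shell:

```
symptomnet simulate --p 52 --density 0.08 --wmax 0.3 --n 634 --seed 7 \
    --out sim.csv --truth truth.tsv
symptomnet estimate --input sim.csv --schema schema.json --out net.tsv
symptomnet run --input data.csv --schema schema.json --sex male --out bundle/
```

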