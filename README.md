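# clpnet — cross-lagged panel network analysis of two-wave panel data

`clpnet` implements the complete analysis workflow for **cross-lagged panel
networks (CLPN)**: directed networks over psychological constructs measured
at two time points, where an edge quantifies how strongly one construct at
baseline predicts another at follow-up. The motivating application is
adolescent depressive symptoms and multisystem resilience factors (emotional
resilience, family resilience, teacher support, friendship quality, social
support), where such networks identify which support systems drive — and are
eroded by — depression, and how those dynamics differ by gender.

## The model

Let `z₁, …, z_p` be the standardized construct scores. For each outcome
node *j*, a lasso-penalized regression of its follow-up score on **all**
baseline scores plus covariates is fitted:

```
z_j(T2) = Σ_i  B[i,j] · z_i(T1)  +  γ_j' · covariates  +  ε_j

β̂ = argmin  (1/2n) Σ (y − Xβ)²  +  λ Σ penalty_mask·|β|
```

The p×p matrix `B` is the network: diagonal entries are **autoregressive**
paths (a construct predicting itself), off-diagonal entries are
**cross-lagged** paths (`B[i,j]` = node *i* at T1 → node *j* at T2).
Covariates (age; gender in the pooled analysis) are adjustment variables and
are exempt from the penalty. λ is chosen per node by 10-fold cross-validated
MSE (minimum rule by default; 1-SE rule available).

Around the estimator the package provides:

- **Synthetic data** (`clpnet.synthetic`) — a generative mirror of the model
  with known group-specific coefficient matrices, published-descriptives
  defaults (770 adolescents: 275 male / 495 female), and MCAR/MAR
  missingness, so every downstream stage is testable without raw data.
- **Preprocessing** (`clpnet.preprocess`) — iterative random-forest
  ("missForest"-style) single imputation, per-wave standardization, and
  Welch-t group descriptives.
- **Centrality** (`clpnet.centrality`) — out-expected-influence (sum of
  outgoing cross-lagged edges: how strongly a node shapes the network) and
  in-expected-influence (sum of incoming edges: how predictable a node is),
  raw, z-scored, and ranked.
- **Stability** (`clpnet.stability`) — case-drop bootstrapping of
  centrality rank order and correlation-stability (CS) coefficients
  (> 0.25 acceptable, > 0.50 excellent).
- **Comparison** (`clpnet.comparison`) — edge-vector correlation, sign
  ("direction") discordance, and centrality correlations between two group
  networks.
- **Pipeline & CLI** (`clpnet.pipeline`, `clpnet` command) — a fully seeded,
  byte-reproducible end-to-end run producing CSV/GraphML/JSON artifacts.

## Worked example

```python
from clpnet import (default_paper_like_config, simulate_panel, impute_random_forest,
                    standardize, estimate_network, EstimationOptions, centrality_table,
                    standardize_centrality, compare_networks)

cfg = default_paper_like_config(seed=1)      # 770 adolescents, 6 constructs, 5% MCAR
data, truth = simulate_panel(cfg)
data = impute_random_forest(data, seed=1)

nets = {}
for g in data.groups():                      # "female", "male"
    std, _ = standardize(data.group_subset(g))
    nets[g] = estimate_network(std, ["age"], EstimationOptions(seed=1))

fem = nets["female"]
i, j = fem.node_names.index("CDI"), fem.node_names.index("FARS")
print(f"female CDI->FARS edge: {fem.B[i, j]:+.3f}")
print(standardize_centrality(centrality_table(fem)).frame().round(3).to_string(index=False))
cmp = compare_networks(nets["male"], nets["female"],
                       centrality_table(nets["male"]), centrality_table(nets["female"]))
print(f"edge r = {cmp.edge_correlation:.2f}, "
      f"discordance = {100 * cmp.discordance_proportion:.2f}%")
```

Output:

```
female CDI->FARS edge: -0.102
   node  out_ei  in_ei  out_rank  in_rank  out_ei_z  in_ei_z
    CDI   0.015 -0.213       5.0      6.0     0.084   -1.092
   AERQ   0.033 -0.152       3.0      5.0     0.235   -0.789
   FARS  -0.222 -0.063       6.0      4.0    -1.946   -0.343
    FQQ   0.064  0.255       2.0      1.0     0.502    1.248
  PTESQ   0.029  0.247       4.0      2.0     0.199    1.206
SSRS-CA   0.114  -0.041      1.0      3.0     0.926   -0.231
edge r = 0.40, discordance = 50.00%
```

The recovered female network shows the generating pattern: depression (CDI)
erodes family resilience (negative CDI→FARS edge, shrunken toward zero by
the lasso), friendship quality (FQQ) is the most *predictable* construct
(highest in-EI), and half the directed edges disagree in sign between the
male and female networks.

The same analysis is available from the shell:

```bash
clpnet simulate --seed 1 --out sim/
clpnet impute --input sim/panel.csv --out sim/imputed.csv
clpnet estimate --input sim/imputed.csv --group female --out sim/edges_female.csv
clpnet run --config examples/run.yaml --out results/
```

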