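# calltif

Causal discovery for large, low-temporal-resolution multivariate time series
(designed for parcellated fMRI), plus a synthetic BOLD simulator with known
ground truth and the graph metrics needed to evaluate and analyze the
recovered networks.

The method tests every lagged pair `X_i(t-τ) → X_j(t)` (τ = 0..τ_max) with a
partial-correlation conditional-independence test, conditioning on **all**
lagged variables (never on contemporaneous ones). Significant contemporaneous
dependencies are oriented from the lagged edges of the same pair (reciprocal
`⇆` when no lagged direction exists), and the lagged graph is collapsed into
a directed summary graph by OR across lags — cycles and self-loops allowed.
Because a summary edge aggregates τ_max + 1 tests, the per-test threshold is
derived from the prescribed overall type-I bound `α` as

```
alpha_level = α / ((τ_max + 1) · 2^τ_max)
```

e.g. `α = 0.01, τ_max = 3 → alpha_level = 0.0003125` (correction factor 32).

## Library quick start

```python
import numpy as np
import calltif as ct

# simulate a 5-node ground-truth system -> BOLD sampled at TR = 1.2 s
model = ct.make_random_cyclic_graph(5, density=0.25, seed=0,
                                    duration_seconds=1200.0)
panel = ct.simulate_bold_panel(model)

# recover the summary causal graph
graph, tensor = ct.run_calltif(panel, tau_max=2, alpha_overall=0.01)

# score against the ground truth
report = ct.evaluate(model.binary_truth, graph.adjacency)
print(report.f1_adjacency, report.f1_directed)
```

Key objects: `TimeSeriesPanel` (sessions × nodes data with TR),
`EdgeTensor` (per source/target/lag partial correlations and p-values),
`SummaryGraph` (binary digraph + per-edge minimum-p strength + per-lag
provenance). Metrics: `evaluate`, `degree_and_flow`, `subnetwork_graph`,
`group_average` / `group_intersection`, `functional_graph`,
`lag_contribution`.

## CLI

```bash
# synthetic benchmark dataset (panel TSV + ground truth CSVs + manifest)
calltif simulate --n-nodes 5 --density 0.25 --duration 1200 --tr 1.2 \
    --seed 7 --out sim/

# causal discovery (multiple --input files = multiple sessions)
calltif run --input sim/panel.tsv --tr 1.2 --tau-max 2 --alpha 0.01 \
    --out run/

# score against ground truth
calltif evaluate --truth sim/truth_binary.csv \
    --predicted run/summary_adjacency.csv

# density, lag contributions, degrees/flows, optional subnetworks and FC
calltif metrics --graph-dir run/ --panel sim/panel.tsv --out metrics/
```

`run` accepts `--alpha-level` to set the per-test threshold manually
(bypassing the correction), `--no-standardize` to skip per-session z-scoring,
and `--config cfg.json` for file-based defaults (explicit flags win). Every
output directory contains a `manifest.json` with all parameters.

Panel files are TSV/CSV with a header row of node labels and one row per
time point; lags are never taken across session-file boundaries.

## Tests and acceptance report

```bash
python -m pytest tests/                                   # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities from scratch:
the corrected threshold and its correction factor at the τ_max = 3 setting,
and the pooled false-edge probability of the full pipeline on 200 null
datasets (10 independent AR(1) nodes, T = 1000), which must stay below the
prescribed α = 0.01.
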