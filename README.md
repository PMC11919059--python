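# clpnet — cross-lagged panel networks of depression and anxiety symptoms

`clpnet` estimates **cross-lagged panel networks (CLPNs)** from two-wave
DASS-21 symptom panels: a directed network over the 7 depression and 7
anxiety items in which an edge *i → j* is the unique prediction of wave-2
symptom *j* by wave-1 symptom *i*, conditional on all other wave-1 symptoms
and the covariates age and gender. It is aimed at researchers studying
depression–anxiety comorbidity who want the full chain — data screening,
estimation, centrality, stability and group comparison — as tested,
scriptable Python, plus a synthetic-panel generator so every stage can be
validated against known ground truth.

## The model

For each symptom *j*, the dichotomized wave-2 item (present iff the 0–3
Likert score exceeds 0) is regressed on all 14 dichotomized wave-1 items and
the covariates with an L1-penalized logistic regression,

&nbsp;&nbsp;logit P(Y_j^{T2} = 1) = β_{0j} + Σ_i β_{ij} X_i^{T1} + γ_j' Z,

with the penalty chosen by fivefold cross-validation (1-SE rule by default)
and covariates unpenalized. The surviving β_{jj} is the **autoregressive**
path (persistence); β_{ij}, i ≠ j, are **cross-lagged** edges; exp(β) are
the odds ratios, with OR = 1 meaning no association. On top of the network:

- **in-EI / out-EI** — a node's summed incoming/outgoing edge coefficients;
  **bridge-EI** — the part crossing the depression/anxiety boundary;
- **stability** — nonparametric edge bootstrap with percentile intervals and
  edge-difference tests, and a case-drop bootstrap yielding the
  correlation-stability coefficient (CS; ≥ 0.25 is the usual reliability
  floor);
- **global structure** — transitivity, average path length and the
  small-world index (C/C_rand)/(L/L_rand) against G(n, m) baselines;
- **comparison** — signed-edge Jaccard similarity between cohort networks.

DASS-21 subscale totals are the doubled 7-item sums; "mild or above" means
total ≥ 10 (depression) or ≥ 8 (anxiety). Missing items are screened with
Little's MCAR test and imputed by multivariate-normal EM; participants lost
to death keep their wave-1 record but are excluded from network estimation.

## Worked example

```python
from clpnet import (SimulationConfig, EstimationConfig, generate_true_network,
                    simulate_panel, build_network, expected_influence)

spec = generate_true_network(20, effect_range=(0.5, 0.8), seed=0)
panel = simulate_panel(spec, SimulationConfig(n_participants=2000, seed=1))
net = build_network(panel, EstimationConfig(seed=2))
print(expected_influence(net).nlargest(3, "in_ei")[["node", "in_ei", "out_ei"]])
```

The analysis chain lives in numbered scripts under `analysis/`, which
simulate three age-cohort panels (two sharing one ground-truth network),
screen and impute them, fit the CLPNs and compare them. A run prints, e.g.:

```
elderly: 20 cross-lagged edges
  strongest edge   A1 -> D7 (OR 2.38)
  recovery: sensitivity 0.86, precision 0.60
...
Jaccard adolescent vs college: 0.53 (19/36)
Jaccard adolescent vs elderly: 0.02 (1/47)
```

— the two cohorts drawn from the same ground truth share about half their
signed edges, while cohorts from unrelated truths share almost none, and
the estimator recovers most of the 14–24 planted edges at each cohort's
sample size. There is also a CLI (`clpn simulate|score|fit|centrality|
stability|metrics|compare|run-all`) over the same functions, driven by a
YAML config for full runs.

Real cohort files are ingested with `clpnet.read_panel(path, schema)`,
where the schema maps your column names onto the 14 items per wave, the
covariates and the follow-up status.

## Layout

```
src/clpnet/       library: simulate, dass, missing, estimate (+_cd solver),
                  centrality, stability, netmetrics, pipeline, cli
analysis/         numbered narrative scripts (01_simulate_cohorts ... 05_global_metrics)
scripts/          acceptance.py
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   modelling choices, conventions and limitations
```
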