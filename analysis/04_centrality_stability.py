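"""Centrality and its bootstrap stability per cohort.

Computes in-/out-expected influence and bridge-EI for each cohort network,
then (a) a case-drop bootstrap for the correlation-stability coefficient of
each index (reduced subsample counts keep this desk-scale) and (b) a
nonparametric edge bootstrap for the elderly cohort, reporting how many of
the other edges its strongest edge significantly exceeds.
"""

import json
from pathlib import Path

import numpy as np

from clpnet import (EstimationConfig, casedrop_bootstrap, edge_bootstrap,
                    edge_difference_test, expected_influence, read_panel)
from clpnet.estimate import SymptomNetwork
from clpnet.stability import plot_stability_curve

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "panels"
RESULTS = ROOT / "results"
SEED = 7
COHORTS = ("adolescent", "college", "elderly")
DROP_GRID = (0.05, 0.15, 0.25, 0.35, 0.45)
N_PER_LEVEL = 15


def main() -> None:
    cs_all = {}
    for k, name in enumerate(COHORTS):
        panel = read_panel(SCRATCH / f"{name}_imputed.csv")
        est = EstimationConfig(seed=SEED + 20 + k)

        with open(RESULTS / "networks" / f"{name}.json") as fh:
            raw = json.load(fh)
        net = SymptomNetwork(nodes=raw["nodes"], community=raw["community"],
                             coef=np.asarray(raw["coef"]),
                             auto=np.asarray(raw["auto"]))
        table = expected_influence(net)
        table.to_csv(RESULTS / f"centrality_{name}.csv", index=False)
        top_in = table.loc[table["in_ei"].idxmax(), "node"]
        top_out = table.loc[table["out_ei"].idxmax(), "node"]
        print(f"{name}: highest in-EI {top_in}, highest out-EI {top_out}")

        rep = casedrop_bootstrap(panel, est, drop_grid=DROP_GRID,
                                 n_boot_per_level=N_PER_LEVEL, seed=SEED + 40 + k)
        cs_all[name] = rep.cs_coefficient
        figdir = ROOT / "scratch" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        plot_stability_curve(rep, figdir / f"stability_curve_{name}.png")
        print(f"  CS coefficients: {rep.cs_coefficient} "
              f"(reliable if >= 0.25)")

    with open(RESULTS / "cs_coefficients.json", "w") as fh:
        json.dump(cs_all, fh, indent=2, sort_keys=True)

    # edge bootstrap on the smallest cohort
    panel = read_panel(SCRATCH / "elderly_imputed.csv")
    boot = edge_bootstrap(panel, EstimationConfig(seed=SEED + 22),
                          n_boot=100, seed=SEED + 60)
    table = boot.edge_table()
    table.to_csv(RESULTS / "edge_bootstrap_elderly.csv", index=False)
    top = table.loc[table["coef"].abs().idxmax()]
    frac = edge_difference_test(boot, (top["source"], top["target"]))
    print(f"elderly strongest edge {top['source']} -> {top['target']} "
          f"(OR {top['odds_ratio']:.2f}) significantly exceeds "
          f"{100 * frac:.1f}% of other edges; "
          f"same-side frequency {top['same_side_frequency']:.2f}")


if __name__ == "__main__":
    main()
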