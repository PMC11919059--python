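"""Bootstrap machinery for edge and centrality stability.

Three procedures, all exactly reproducible under a master seed:

- nonparametric edge bootstrap: resample participants with replacement,
  refit the whole network, and collect each edge's coefficient/OR
  distribution (percentile intervals plus the fraction of replicates on the
  point estimate's side of OR = 1);
- edge-difference test: bootstrap distribution of the difference between two
  edges' coefficients, significant when the central 95% interval excludes 0;
- case-drop bootstrap: refit on subsamples with a growing fraction of cases
  dropped and correlate subsample centralities with the full-sample values.
  The correlation-stability (CS) coefficient is the largest drop fraction at
  which at least 95% of subsamples still correlate >= 0.7; the conventional
  reliability floor is CS >= 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .centrality import expected_influence
from .estimate import MIN_SAMPLE, EstimationConfig, SymptomNetwork, build_network
from .panel import N_NODES, PanelDataset

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
CS_CORR_THRESHOLD = 0.7
CS_PROB_THRESHOLD = 0.95
CS_RELIABILITY_FLOOR = 0.25
CENTRALITY_INDICES = ("in_ei", "out_ei", "bridge_ei")


@dataclass
class EdgeBootstrapResult:
    point: SymptomNetwork
    boot_coef: np.ndarray          # (n_boot, 14, 14) cross-lagged coefficients
    boot_auto: np.ndarray          # (n_boot, 14)
    n_boot: int
    n_skipped: int

    def edge_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per cross-lagged edge of the point network: OR, percentile
        interval, and the fraction of replicates on the same side of 1."""
        lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
        rows = []
        nodes = self.point.nodes
        for i in range(N_NODES):
            for j in range(N_NODES):
                if i == j or self.point.coef[i, j] == 0:
                    continue
                draws = self.boot_coef[:, i, j]
                point = self.point.coef[i, j]
                same = np.mean(draws > 0) if point > 0 else np.mean(draws < 0)
                rows.append({
                    "source": nodes[i], "target": nodes[j],
                    "coef": point, "odds_ratio": float(np.exp(point)),
                    "or_lo": float(np.exp(np.percentile(draws, lo_q))),
                    "or_hi": float(np.exp(np.percentile(draws, hi_q))),
                    "same_side_frequency": float(same),
                })
        return pd.DataFrame(rows, columns=["source", "target", "coef", "odds_ratio",
                                           "or_lo", "or_hi", "same_side_frequency"])


@dataclass
class CSReport:
    cs_coefficient: dict           # index -> grid value
    curve: pd.DataFrame            # drop, index, prop_above, n_feasible
    n_boot_per_level: int
    reliable: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reliable:
            self.reliable = {k: bool(v >= CS_RELIABILITY_FLOOR)
                             for k, v in self.cs_coefficient.items()}

    def to_json(self) -> dict:
        return {
            "cs_coefficient": self.cs_coefficient,
            "reliable": self.reliable,
            "n_boot_per_level": self.n_boot_per_level,
            "curve": self.curve.to_dict(orient="records"),
        }


def _resample_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def edge_bootstrap(dataset: PanelDataset, config: EstimationConfig | None = None,
                   n_boot: int = 1000, seed: int = 0) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of the whole CLPN.

    Each replicate resamples participants with replacement and refits the
    network with a fresh fold seed drawn from the master seed.  Replicates
    that fail to fit are skipped and counted; more than 5% skipped is an
    error.
    """
    config = config or EstimationConfig()
    ds = dataset.non_deceased()
    point = build_network(ds, config)
    seeds = _resample_seeds(seed, 2 * n_boot)
    boot_coef = np.zeros((n_boot, N_NODES, N_NODES))
    boot_auto = np.zeros((n_boot, N_NODES))
    kept = 0
    skipped = 0
    for b in range(n_boot):
        rng = np.random.default_rng(seeds[2 * b])
        idx = rng.integers(0, ds.n, size=ds.n)
        rep_config = EstimationConfig(**{**config.__dict__, "seed": int(seeds[2 * b + 1])})
        try:
            net = build_network(ds.subset(idx), rep_config)
        except ValueError as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            skipped += 1
            continue
        boot_coef[kept] = net.coef
        boot_auto[kept] = net.auto
        kept += 1
    if skipped > 0.05 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap replicates failed to fit")
    return EdgeBootstrapResult(point=point, boot_coef=boot_coef[:kept],
                               boot_auto=boot_auto[:kept], n_boot=kept,
                               n_skipped=skipped)


def edge_difference_test(boot: EdgeBootstrapResult, edge: tuple,
                         alpha: float = 0.05) -> float:
    """Fraction of the network's other edges that are significantly weaker.

    ``edge`` is a (source, target) label pair that must be present (nonzero)
    in the point network.  For every other nonzero edge f, the bootstrap
    distribution of coef(e) - coef(f) is formed; f counts as significantly
    smaller when the central 95% interval of the difference lies above 0.
    The edge is never compared with itself.
    """
    nodes = boot.point.nodes
    i, j = nodes.index(edge[0]), nodes.index(edge[1])
    if i == j or boot.point.coef[i, j] == 0:
        raise ValueError(f"edge {edge} is absent from the point network")
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    draws_e = boot.boot_coef[:, i, j]
    n_smaller = 0
    n_other = 0
    for a in range(N_NODES):
        for b in range(N_NODES):
            if a == b or (a, b) == (i, j) or boot.point.coef[a, b] == 0:
                continue
            diff = draws_e - boot.boot_coef[:, a, b]
            lo = np.percentile(diff, lo_q)
            n_other += 1
            if lo > 0:
                n_smaller += 1
    if n_other == 0:
        raise ValueError("no other edges to compare against")
    return n_smaller / n_other


def _cs_from_curve(curve: pd.DataFrame, index: str) -> float:
    """Largest feasible drop fraction whose proportion of subsamples with
    correlation >= 0.7 is at least 0.95; 0.0 if none qualifies."""
    sub = curve[(curve["index"] == index) & curve["feasible"]]
    ok = sub[sub["prop_above"] >= CS_PROB_THRESHOLD]
    return float(ok["drop"].max()) if len(ok) else 0.0


def casedrop_bootstrap(dataset: PanelDataset, config: EstimationConfig | None = None,
                       drop_grid=DEFAULT_DROP_GRID, n_boot_per_level: int = 250,
                       seed: int = 0, corr_method: str = "pearson") -> CSReport:
    """Case-drop bootstrap of centrality stability.

    For each drop proportion p, subsample (1-p)*n participants without
    replacement, refit, and correlate each centrality index with the
    full-sample values.  Drop proportion 0 reuses the full-sample fit, so its
    correlation is exactly 1.  Levels whose subsample would not exceed the
    minimum sample size are marked infeasible.
    """
    if corr_method not in ("pearson", "spearman"):
        raise ValueError("corr_method must be 'pearson' or 'spearman'")
    config = config or EstimationConfig()
    ds = dataset.non_deceased()
    full_net = build_network(ds, config)
    full_cent = expected_influence(full_net)
    full_vals = {k: full_cent[k].to_numpy() for k in CENTRALITY_INDICES}
    grid = sorted(set(float(p) for p in drop_grid))
    seeds = _resample_seeds(seed, max(1, len(grid) * n_boot_per_level * 2))
    rows = []
    s = 0
    for p in grid:
        m = int(round((1 - p) * ds.n))
        feasible = m > MIN_SAMPLE
        hits = {k: 0 for k in CENTRALITY_INDICES}
        done = 0
        if p == 0.0:
            # identical data: correlation is exactly 1 by construction
            for k in CENTRALITY_INDICES:
                rows.append({"drop": p, "index": k, "prop_above": 1.0,
                             "n_feasible": n_boot_per_level, "feasible": True})
            continue
        if feasible:
            for b in range(n_boot_per_level):
                rng = np.random.default_rng(seeds[s]); s += 1
                idx = rng.choice(ds.n, size=m, replace=False)
                rep_config = EstimationConfig(**{**config.__dict__, "seed": int(seeds[s])}); s += 1
                try:
                    net = build_network(ds.subset(idx), rep_config)
                except ValueError:
                    continue
                cent = expected_influence(net)
                done += 1
                for k in CENTRALITY_INDICES:
                    x, y = full_vals[k], cent[k].to_numpy()
                    if np.std(x) == 0 or np.std(y) == 0:
                        continue  # degenerate: counted as below threshold
                    if corr_method == "pearson":
                        r = float(np.corrcoef(x, y)[0, 1])
                    else:
                        r = float(sps.spearmanr(x, y).statistic)
                    if r >= CS_CORR_THRESHOLD:
                        hits[k] += 1
        for k in CENTRALITY_INDICES:
            rows.append({"drop": p, "index": k,
                         "prop_above": hits[k] / done if done else 0.0,
                         "n_feasible": done, "feasible": feasible and done > 0})
    curve = pd.DataFrame(rows, columns=["drop", "index", "prop_above",
                                        "n_feasible", "feasible"])
    cs = {k: _cs_from_curve(curve, k) for k in CENTRALITY_INDICES}
    return CSReport(cs_coefficient=cs, curve=curve,
                    n_boot_per_level=n_boot_per_level)


def plot_stability_curve(report: CSReport, path) -> None:
    """Stability curve image: proportion of subsamples with correlation >= 0.7
    against the drop proportion, one line per centrality index."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for k in CENTRALITY_INDICES:
        sub = report.curve[(report.curve["index"] == k) & report.curve["feasible"]]
        ax.plot(sub["drop"], sub["prop_above"], marker="o", label=k)
    ax.axhline(CS_PROB_THRESHOLD, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("proportion of cases dropped")
    ax.set_ylabel(f"P(correlation >= {CS_CORR_THRESHOLD})")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
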