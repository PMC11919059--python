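"""Synthetic two-wave symptom panels with known cross-lagged structure.

The generator mirrors the estimation model: wave-2 symptom presence follows a
logistic regression on the dichotomized wave-1 symptoms plus covariates, so
node-wise logistic re-estimation targets the true log-odds coefficients.
Wave-1 items come from a correlated latent Gaussian thresholded into the 0-3
Likert range; wave-2 items extend the logistic presence model to an ordinal
value by thresholding the same logistic latent at two further cutpoints.
Item-level missingness (MCAR or MAR on age), wave-2 attrition and death
("deceased" rows, never imputed) are applied afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import COMMUNITY, N_NODES, NODE_LABELS, PanelDataset

__all__ = [
    "TrueNetworkSpec",
    "SimulationConfig",
    "generate_true_network",
    "simulate_panel",
]

#: latent-Gaussian cutpoints putting ~55/25/15/5 % mass on item values 0/1/2/3,
#: the right-skew typical of community symptom screens
DEFAULT_CUTPOINTS = tuple(stats.norm.ppf([0.55, 0.80, 0.95]))


@dataclass
class TrueNetworkSpec:
    """Ground-truth coefficients of the generating cross-lagged model.

    All coefficients are on the log-odds scale of symptom presence
    (dichotomized item > 0).  ``cross_coef[i, j]`` is the effect of wave-1
    symptom ``i`` on wave-2 symptom ``j``; the diagonal is zero, the
    autoregressive path is held in ``auto_coef``.
    """

    node_labels: list = field(default_factory=lambda: list(NODE_LABELS))
    community: dict = field(default_factory=lambda: dict(COMMUNITY))
    auto_coef: np.ndarray = field(default_factory=lambda: np.full(N_NODES, 1.2))
    cross_coef: np.ndarray = field(default_factory=lambda: np.zeros((N_NODES, N_NODES)))
    covariate_coef: np.ndarray = field(default_factory=lambda: np.zeros((N_NODES, 2)))
    intercepts: np.ndarray = None

    def __post_init__(self) -> None:
        self.auto_coef = np.asarray(self.auto_coef, dtype=float)
        self.cross_coef = np.asarray(self.cross_coef, dtype=float)
        self.covariate_coef = np.asarray(self.covariate_coef, dtype=float)
        if self.intercepts is None:
            # default: presence rate at wave 2 matches the wave-1 marginal
            p0 = stats.norm.cdf(DEFAULT_CUTPOINTS[0])
            self.intercepts = np.full(N_NODES, np.log((1 - p0) / p0))
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.cross_coef.shape != (N_NODES, N_NODES):
            raise ValueError("cross_coef must be 14x14")
        if np.any(np.diag(self.cross_coef) != 0):
            raise ValueError("cross_coef diagonal must be zero")
        for arr in (self.auto_coef, self.cross_coef, self.covariate_coef, self.intercepts):
            if not np.all(np.isfinite(arr)):
                raise ValueError("all coefficients must be finite")

    @property
    def n_cross_edges(self) -> int:
        return int(np.count_nonzero(self.cross_coef))

    def edge_list(self) -> pd.DataFrame:
        src, tgt = np.nonzero(self.cross_coef)
        return pd.DataFrame({
            "source": [self.node_labels[i] for i in src],
            "target": [self.node_labels[j] for j in tgt],
            "true_coef": self.cross_coef[src, tgt],
        })

    def to_json(self, path) -> None:
        payload = {
            "node_labels": self.node_labels,
            "community": self.community,
            "auto_coef": self.auto_coef.tolist(),
            "cross_coef": self.cross_coef.tolist(),
            "covariate_coef": self.covariate_coef.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the panel generator."""

    n_participants: int = 1000
    #: latent wave-1 correlation within / between symptom communities
    wave1_latent_corr: tuple = (0.4, 0.2)
    ordinal_cutpoints: tuple = DEFAULT_CUTPOINTS
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"     # or "MAR"
    mar_strength: float = 2.0           # log-odds shift of missingness per SD of age
    attrition_rate: float = 0.0
    death_rate: float = 0.0
    age_mean: float = 20.0
    age_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = tuple(self.ordinal_cutpoints)
        if len(c) != 3 or not (c[0] < c[1] < c[2]):
            raise ValueError("ordinal_cutpoints must be 3 strictly increasing thresholds")
        for name in ("missing_rate", "attrition_rate", "death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")


def generate_true_network(
    n_cross_edges: int,
    effect_range: tuple = (0.3, 0.6),
    seed: int = 0,
    positive_only: bool = False,
    auto_range: tuple = (1.0, 1.5),
    covariate_scale: float = 0.1,
) -> TrueNetworkSpec:
    """Draw a sparse ground-truth cross-lagged network.

    Exactly ``n_cross_edges`` off-diagonal cells of the 14x14 cross-lagged
    matrix are nonzero; magnitudes are uniform on ``effect_range`` with random
    sign unless ``positive_only``.  Autoregressive coefficients are uniform on
    ``auto_range`` (persistence is stronger than any single cross path, as in
    real symptom panels).
    """
    max_edges = N_NODES * (N_NODES - 1)
    if not 0 <= n_cross_edges <= max_edges:
        raise ValueError(f"n_cross_edges must be in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    cells = [(i, j) for i in range(N_NODES) for j in range(N_NODES) if i != j]
    chosen = rng.choice(len(cells), size=n_cross_edges, replace=False)
    cross = np.zeros((N_NODES, N_NODES))
    lo, hi = effect_range
    for k in chosen:
        i, j = cells[k]
        mag = rng.uniform(lo, hi)
        sign = 1.0 if positive_only else rng.choice([-1.0, 1.0])
        cross[i, j] = sign * mag
    auto = rng.uniform(auto_range[0], auto_range[1], size=N_NODES)
    cov = rng.normal(0.0, covariate_scale, size=(N_NODES, 2)) if covariate_scale > 0 else np.zeros((N_NODES, 2))
    return TrueNetworkSpec(auto_coef=auto, cross_coef=cross, covariate_coef=cov)


def _wave1_correlation(within: float, between: float) -> np.ndarray:
    corr = np.full((N_NODES, N_NODES), between)
    corr[:7, :7] = within
    corr[7:, 7:] = within
    np.fill_diagonal(corr, 1.0)
    return corr


def _severity_offsets(cutpoints) -> tuple:
    """Logistic-latent offsets above the presence threshold that reproduce the
    wave-1 conditional severity profile: at the calibrated default intercept,
    P(item >= k) matches the wave-1 marginal for k = 2, 3."""
    p_ge = 1.0 - stats.norm.cdf(np.asarray(cutpoints))  # P(item >= 1, 2, 3)
    t = np.log((1 - p_ge) / p_ge)
    return float(t[1] - t[0]), float(t[2] - t[0])


def simulate_panel(spec: TrueNetworkSpec, config: SimulationConfig) -> PanelDataset:
    """Generate a two-wave ordinal panel from the ground-truth network."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # covariates
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age_z = (age - config.age_mean) / config.age_sd
    gender = rng.integers(0, 2, size=n)

    # wave 1: correlated latent Gaussian -> ordinal via cutpoints
    within, between = config.wave1_latent_corr
    corr = _wave1_correlation(within, between)
    chol = np.linalg.cholesky(corr)
    latent1 = rng.standard_normal((n, N_NODES)) @ chol.T
    cuts = np.asarray(config.ordinal_cutpoints)
    wave1 = (latent1[:, :, None] > cuts[None, None, :]).sum(axis=2).astype(float)
    dich1 = (wave1 > 0).astype(float)

    # wave 2: logistic latent on dichotomized wave-1 presence + covariates
    eta = (spec.intercepts[None, :]
           + dich1 * spec.auto_coef[None, :]
           + dich1 @ spec.cross_coef
           + age_z[:, None] * spec.covariate_coef[:, 0][None, :]
           + gender[:, None] * spec.covariate_coef[:, 1][None, :])
    latent2 = eta + rng.logistic(size=(n, N_NODES))
    # presence threshold is exactly 0 so that P(item > 0) = sigmoid(eta) and
    # logistic refits on the dichotomized items recover the true coefficients
    s2, s3 = _severity_offsets(cuts)
    wave2 = ((latent2 > 0).astype(int)
             + (latent2 > s2).astype(int)
             + (latent2 > s3).astype(int)).astype(float)

    # attrition and death (wave-2 lost entirely)
    status = np.array(["complete"] * n, dtype=object)
    u = rng.random(n)
    dead = u < config.death_rate
    drop = (~dead) & (u < config.death_rate + config.attrition_rate)
    status[dead] = "deceased"
    status[drop] = "dropout"
    wave2[dead | drop] = np.nan

    # item-level missingness
    if config.missing_rate > 0:
        if config.missing_mechanism == "MCAR":
            p_miss = np.full(n, config.missing_rate)
        else:  # MAR on age
            base = np.log(config.missing_rate / (1 - config.missing_rate))
            p_miss = 1 / (1 + np.exp(-(base + config.mar_strength * age_z)))
        m1 = rng.random((n, N_NODES)) < p_miss[:, None]
        m2 = rng.random((n, N_NODES)) < p_miss[:, None]
        wave1[m1] = np.nan
        wave2[m2] = np.nan

    ids = np.array([f"P{k:05d}" for k in range(n)])
    return PanelDataset(ids=ids, wave1_items=wave1, wave2_items=wave2,
                        age=age, gender=gender, status=status)
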