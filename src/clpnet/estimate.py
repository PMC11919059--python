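"""Cross-lagged panel network estimation.

One regularized regression per wave-2 symptom: the dichotomized wave-2 item is
regressed on all 14 dichotomized wave-1 items plus the covariates age and
gender.  The L1 penalty (lambda chosen by k-fold cross-validation) zeroes
minor associations; the surviving same-symptom coefficient is the
autoregressive path, the others are cross-lagged edges, and exponentiated
coefficients are the odds ratios plotted in this literature (OR = 1 meaning
no association).  Covariates are unpenalized by default so the adjustment is
not shrunk away.

The penalized fits run through a pathwise coordinate-descent solver
(``clpnet._cd``) with warm starts along the lambda path and per-feature
penalty factors, so covariates carry factor 0 and are exactly unpenalized;
the intercept is never penalized.  The objective parameterization matches
glmnet with ``standardize=FALSE``, which the test suite uses as an
independent oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold

from ._cd import lasso_logistic_path
from .panel import COMMUNITY, N_NODES, NODE_LABELS, PanelDataset

logger = logging.getLogger(__name__)

MIN_SAMPLE = 36  # total variables across waves and covariates; n must exceed it


@dataclass
class EstimationConfig:
    n_folds: int = 5
    lambda_rule: str = "1se"          # or "min"
    dichotomize_threshold: int = 0    # symptom "present" iff item > threshold
    penalize_covariates: bool = False
    family: str = "binomial"          # or "gaussian"
    n_lambda: int = 15
    lambda_min_ratio: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.dichotomize_threshold not in (0, 1, 2):
            raise ValueError("dichotomize_threshold must be 0, 1 or 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.family not in ("binomial", "gaussian"):
            raise ValueError("family must be 'binomial' or 'gaussian'")


@dataclass
class NodeFit:
    coef: np.ndarray              # length 14, own index = autoregressive
    covariate_coef: np.ndarray
    intercept: float
    lambda_selected: float
    degenerate: bool = False


@dataclass
class SymptomNetwork:
    """Directed weighted network over the 14 symptom nodes.

    ``coef[i, j]`` is the selected cross-lagged log-odds coefficient of
    wave-1 node i on wave-2 node j (diagonal fixed at zero); ``auto`` holds
    the autoregressive coefficients.  ``or_matrix`` is the element-wise
    exponential, so absent edges sit exactly at OR = 1.
    """

    nodes: list = field(default_factory=lambda: list(NODE_LABELS))
    community: dict = field(default_factory=lambda: dict(COMMUNITY))
    coef: np.ndarray = field(default_factory=lambda: np.zeros((N_NODES, N_NODES)))
    auto: np.ndarray = field(default_factory=lambda: np.zeros(N_NODES))
    covariate_coefs: np.ndarray = field(default_factory=lambda: np.zeros((N_NODES, 2)))
    lambda_selected: np.ndarray = field(default_factory=lambda: np.zeros(N_NODES))
    family: str = "binomial"

    @property
    def or_matrix(self) -> np.ndarray:
        return np.exp(self.coef)

    def node_index(self, label: str) -> int:
        return self.nodes.index(label)

    def edges(self) -> pd.DataFrame:
        """Edge list: cross-lagged edges (nonzero cells) then autoregressive."""
        rows = []
        for i in range(N_NODES):
            for j in range(N_NODES):
                if i != j and self.coef[i, j] != 0:
                    rows.append({"source": self.nodes[i], "target": self.nodes[j],
                                 "coef": self.coef[i, j],
                                 "odds_ratio": float(np.exp(self.coef[i, j])),
                                 "edge_type": "cross_lagged"})
        for i in range(N_NODES):
            if self.auto[i] != 0:
                rows.append({"source": self.nodes[i], "target": self.nodes[i],
                             "coef": self.auto[i],
                             "odds_ratio": float(np.exp(self.auto[i])),
                             "edge_type": "autoregressive"})
        return pd.DataFrame(rows, columns=["source", "target", "coef",
                                           "odds_ratio", "edge_type"])

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, community=self.community[node])
        for _, row in self.edges().iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["coef"]),
                       odds_ratio=float(row["odds_ratio"]), edge_type=row["edge_type"])
        nx.write_graphml(g, path)

    def to_json(self, path=None):
        payload = {
            "nodes": self.nodes,
            "community": self.community,
            "family": self.family,
            "coef": self.coef.tolist(),
            "auto": self.auto.tolist(),
            "covariate_coefs": self.covariate_coefs.tolist(),
            "lambda_selected": self.lambda_selected.tolist(),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def dichotomize(items: np.ndarray, threshold: int = 0) -> np.ndarray:
    """Binary presence matrix: 1 where item > threshold."""
    items = np.asarray(items, dtype=float)
    if np.isnan(items).any():
        raise ValueError("dichotomize expects imputed (complete) items")
    return (items > threshold).astype(float)


def zero_variance_columns(binary: np.ndarray) -> np.ndarray:
    """Indices of constant columns (flagged for downstream exclusion/logging)."""
    return np.flatnonzero(binary.min(axis=0) == binary.max(axis=0))


def _lambda_path(X_pen: np.ndarray, y: np.ndarray, resid0: np.ndarray,
                 config: EstimationConfig) -> np.ndarray:
    n = len(y)
    lam_max = np.abs(X_pen.T @ resid0).max() / n
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                     penalty_factor: np.ndarray | None = None):
    """Single-lambda L1 logistic fit; returns (intercept, coefficients)."""
    B0, B = lasso_logistic_path(X, y, np.array([lam]), penalty_factor)
    return float(B0[0]), B[0]


def _mean_log_loss(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Mean binomial deviance/2 per column of the linear-predictor matrix."""
    return np.mean(np.logaddexp(0.0, eta) - y[:, None] * eta, axis=0)


def fit_node(target_wave2: np.ndarray, predictors_wave1: np.ndarray,
             covariates: np.ndarray, config: EstimationConfig,
             seed: int | None = None) -> NodeFit:
    """L1-penalized regression of one wave-2 symptom on all wave-1 symptoms.

    Returns selected coefficients (many exactly zero) and the CV-chosen
    penalty.  A single-class target yields an all-zero degenerate fit with a
    logged warning rather than an error.
    """
    y = np.asarray(target_wave2, dtype=float)
    Xp = np.asarray(predictors_wave1, dtype=float)
    Xc = np.asarray(covariates, dtype=float)
    if Xc.ndim == 1:
        Xc = Xc[:, None]
    seed = config.seed if seed is None else seed
    n, n_pred = Xp.shape
    n_cov = Xc.shape[1]

    if config.family == "gaussian":
        return _fit_node_gaussian(y, Xp, Xc, config, seed)

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < config.n_folds:
        logger.warning("degenerate target (class counts %s): returning zero fit",
                       dict(zip(classes.tolist(), counts.tolist())))
        return NodeFit(coef=np.zeros(n_pred), covariate_coef=np.zeros(n_cov),
                       intercept=0.0, lambda_selected=np.inf, degenerate=True)

    X = np.hstack([Xp, Xc])
    w = np.concatenate([np.ones(n_pred),
                        np.ones(n_cov) if config.penalize_covariates else np.zeros(n_cov)])
    resid0 = y - y.mean()
    lams = _lambda_path(Xp, y, resid0, config)

    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed % (2**32))
    scores = np.zeros((len(lams), config.n_folds))
    for f, (tr, te) in enumerate(cv.split(X, y)):
        B0, B = lasso_logistic_path(X[tr], y[tr], lams, w)
        eta_te = B0[None, :] + X[te] @ B.T
        scores[:, f] = _mean_log_loss(y[te], eta_te)
    mean = scores.mean(axis=1)
    if config.lambda_rule == "min":
        k_sel = int(np.argmin(mean))
    else:  # 1se: largest lambda within one SE of the minimum
        se = scores.std(axis=1, ddof=1) / np.sqrt(config.n_folds)
        k_min = int(np.argmin(mean))
        ok = np.flatnonzero(mean <= mean[k_min] + se[k_min])
        k_sel = int(ok[0])  # path is ordered from largest lambda down
    lam_sel = float(lams[k_sel])

    B0, B = lasso_logistic_path(X, y, lams, w)
    beta = B[k_sel]
    return NodeFit(coef=beta[:n_pred].copy(),
                   covariate_coef=beta[n_pred:].copy(),
                   intercept=float(B0[k_sel]),
                   lambda_selected=lam_sel)


def _fit_node_gaussian(y, Xp, Xc, config: EstimationConfig, seed: int) -> NodeFit:
    """Fallback family: LASSO linear regression on raw 0-3 scores with
    standardized penalized predictors (coefficients reported on the
    standardized scale)."""
    n, n_pred = Xp.shape
    sd = Xp.std(axis=0)
    keep_sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xp - Xp.mean(axis=0)) / keep_sd
    y_c = y - y.mean()
    lams = _lambda_path(Xs, y, y_c, config)
    cv = KFold(n_splits=config.n_folds, shuffle=True, random_state=seed % (2**32))
    scores = np.zeros((len(lams), config.n_folds))
    for f, (tr, te) in enumerate(cv.split(Xs)):
        base = LinearRegression().fit(Xc[tr], y[tr])
        r_tr = y[tr] - base.predict(Xc[tr])
        r_te = y[te] - base.predict(Xc[te])
        for k, lam in enumerate(lams):
            m = Lasso(alpha=lam, max_iter=10000).fit(Xs[tr], r_tr)
            scores[k, f] = np.mean((r_te - m.predict(Xs[te])) ** 2)
    mean = scores.mean(axis=1)
    if config.lambda_rule == "min":
        k_sel = int(np.argmin(mean))
    else:
        se = scores.std(axis=1, ddof=1) / np.sqrt(config.n_folds)
        k_min = int(np.argmin(mean))
        k_sel = int(np.flatnonzero(mean <= mean[k_min] + se[k_min])[0])
    lam_sel = float(lams[k_sel])
    base = LinearRegression().fit(Xc, y)
    resid = y - base.predict(Xc)
    m = Lasso(alpha=lam_sel, max_iter=10000).fit(Xs, resid)
    coef = m.coef_.copy()
    coef[sd == 0] = 0.0
    return NodeFit(coef=coef, covariate_coef=base.coef_.copy(),
                   intercept=float(m.intercept_ + base.intercept_),
                   lambda_selected=lam_sel)


def build_network(dataset: PanelDataset, config: EstimationConfig | None = None) -> SymptomNetwork:
    """Assemble the full CLPN from 14 node-wise fits.

    Requires an imputed dataset; deceased participants are excluded.  Node j's
    regression contributes column j of the coefficient matrix; the diagonal
    term is stored separately as the autoregressive path.
    """
    config = config or EstimationConfig()
    ds = dataset.non_deceased()
    if np.isnan(ds.wave1_items).any() or np.isnan(ds.wave2_items).any():
        raise ValueError("dataset has missing values: impute before estimation")
    if ds.n <= MIN_SAMPLE:
        raise ValueError(f"sample size {ds.n} must exceed the total number of "
                         f"variables ({MIN_SAMPLE})")
    X1 = dichotomize(ds.wave1_items, config.dichotomize_threshold)
    X2 = dichotomize(ds.wave2_items, config.dichotomize_threshold)
    zv = zero_variance_columns(X1)
    if zv.size:
        logger.warning("zero-variance wave-1 nodes retained with no outgoing "
                       "edges possible: %s", [NODE_LABELS[i] for i in zv])
    age_z = (ds.age - ds.age.mean()) / (ds.age.std() or 1.0)
    cov = np.column_stack([age_z, ds.gender.astype(float)])

    net = SymptomNetwork(family=config.family)
    seeds = np.random.SeedSequence(config.seed).generate_state(N_NODES)
    for j in range(N_NODES):
        target = X2[:, j] if config.family == "binomial" else ds.wave2_items[:, j]
        fit = fit_node(target, X1, cov, config, seed=int(seeds[j] % (2**31)))
        col = fit.coef.copy()
        net.auto[j] = col[j]
        col[j] = 0.0
        net.coef[:, j] = col
        net.covariate_coefs[j] = fit.covariate_coef
        net.lambda_selected[j] = fit.lambda_selected
    return net
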