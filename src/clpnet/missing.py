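"""Missing-data machinery: multivariate-normal EM and Little's MCAR test.

The EM estimator groups rows by missingness pattern and iterates conditional
expectations of the missing block given the observed block until the mean and
covariance stabilize.  Little's test then compares each pattern's observed
sub-mean against the EM estimates with the pattern's observed sub-covariance,
summing the squared Mahalanobis distances into a chi-square statistic with
``sum_j p_j - p`` degrees of freedom.

Imputation replaces missing item cells by their conditional means, rounded to
the nearest integer and clipped to the 0-3 Likert range so the downstream
dichotomization (> 0) is deterministic.  Deceased participants are never
imputed: their wave-2 data are absent by design, not missing at random.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PanelDataset

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


class EMConvergenceError(RuntimeError):
    def __init__(self, delta: float, max_iter: int):
        super().__init__(f"EM did not converge within {max_iter} iterations "
                         f"(last relative change {delta:.3e})")
        self.last_delta = delta


@dataclass
class MissingnessReport:
    little_statistic: float
    little_df: int
    little_p: float
    n_patterns: int
    verdict: str  # consistent_with_MCAR | not_MCAR


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (mask True = observed)."""
    order = {}
    for i, row in enumerate(mask):
        order.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, idx in order.items():
        obs = np.frombuffer(key, dtype=bool)
        out.append((obs.copy(), np.asarray(idx)))
    return out


def _safe_inv(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular pattern covariance: ridge-regularizing", RuntimeWarning)
        eps = _RIDGE * max(np.trace(sigma) / len(sigma), 1.0)
        return np.linalg.inv(sigma + eps * np.eye(len(sigma)))


def em_mvn(X: np.ndarray, tol: float = 1e-6, max_iter: int = 500) -> EMResult:
    """Maximum-likelihood mean/covariance of a multivariate normal with
    missing values (NaN), via EM with missingness-pattern grouping.

    The observed-data log-likelihood is non-decreasing across iterations (a
    property the test suite asserts).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mask = ~np.isnan(X)
    keep = mask.any(axis=1)
    X, mask = X[keep], mask[keep]
    n = len(X)
    if n == 0:
        raise ValueError("no rows with any observed value")

    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    # diagonal start: positive definite, so the EM ascent property holds from
    # the first iteration
    var = np.nanvar(X, axis=0)
    var = np.where(np.isnan(var) | (var <= 0), 1.0, var)
    sigma = np.diag(var)

    pats = _patterns(mask)
    logliks = []
    converged = False
    delta = np.inf
    for it in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for obs, idx in pats:
            Xg = X[np.ix_(idx, np.flatnonzero(obs))]
            ng = len(idx)
            mis = ~obs
            S_oo = sigma[np.ix_(obs, obs)]
            inv_oo = _safe_inv(S_oo)
            dev = Xg - mu[obs]
            # observed-data log-likelihood for this pattern
            sign, logdet = np.linalg.slogdet(S_oo)
            if sign <= 0:
                logdet = np.linalg.slogdet(S_oo + _RIDGE * np.eye(obs.sum()))[1]
            ll += (-0.5 * ng * (obs.sum() * np.log(2 * np.pi) + logdet)
                   - 0.5 * np.einsum("ij,jk,ik->", dev, inv_oo, dev))
            full = np.zeros((ng, p))
            full[:, obs] = Xg
            if mis.any():
                S_mo = sigma[np.ix_(mis, obs)]
                reg = S_mo @ inv_oo
                cond_mean = mu[mis] + dev @ reg.T
                full[:, mis] = cond_mean
                C_mm = sigma[np.ix_(mis, mis)] - reg @ S_mo.T
            sum_x += full.sum(axis=0)
            cross = full.T @ full
            if mis.any():
                cross[np.ix_(mis, mis)] += ng * C_mm
            sum_xx += cross
        logliks.append(ll)
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        scale = max(np.abs(mu).max(), np.abs(sigma).max(), 1.0)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()) / scale
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged and np.isfinite(delta) and delta >= tol:
        raise EMConvergenceError(delta, max_iter)
    return EMResult(mean=mu, cov=sigma, loglik_trace=np.asarray(logliks),
                    n_iter=len(logliks), converged=converged)


def _analysis_matrix(dataset: PanelDataset, include_age: bool = True) -> np.ndarray:
    """Item matrix (+ age) for the non-deceased rows, NaN = missing."""
    ds = dataset.non_deceased()
    cols = [ds.wave1_items, ds.wave2_items]
    if include_age:
        cols.append(ds.age[:, None])
    return np.hstack(cols)


def little_mcar_test(dataset: PanelDataset, include_age: bool = True) -> MissingnessReport:
    """Little's chi-square test of missing completely at random.

    Runs on the two waves' items (age appended as an always-observed
    covariate, so covariate-dependent missingness is detectable).  Deceased
    participants are excluded: their absent wave-2 data are not treated as
    missing values.
    """
    X = _analysis_matrix(dataset, include_age=include_age)
    mask = ~np.isnan(X)
    keep = mask.any(axis=1)
    X, mask = X[keep], mask[keep]
    p = X.shape[1]
    pats = _patterns(mask)
    if not (~mask).any():
        return MissingnessReport(0.0, 0, 1.0, n_patterns=len(pats),
                                 verdict="consistent_with_MCAR")
    em = em_mvn(X)
    stat = 0.0
    df = 0
    for obs, idx in pats:
        ng = len(idx)
        xbar = X[np.ix_(idx, np.flatnonzero(obs))].mean(axis=0)
        dev = xbar - em.mean[obs]
        inv = _safe_inv(em.cov[np.ix_(obs, obs)])
        stat += ng * float(dev @ inv @ dev)
        df += int(obs.sum())
    df -= p
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    verdict = "not_MCAR" if pval < 0.05 else "consistent_with_MCAR"
    return MissingnessReport(float(stat), int(df), pval,
                             n_patterns=len(pats), verdict=verdict)


def em_impute(dataset: PanelDataset, tol: float = 1e-6, max_iter: int = 500) -> PanelDataset:
    """EM imputation of missing item cells by conditional means.

    Fits the normal model on non-deceased rows (items + age), replaces missing
    item cells with conditional means given that row's observed values, then
    rounds and clips to the 0-3 range.  Deceased rows pass through untouched.
    Returns a new dataset; the input is not modified.
    """
    n_items = dataset.wave1_items.shape[1]
    miss_frac = np.concatenate([
        np.isnan(dataset.wave1_items).mean(axis=0),
        np.isnan(dataset.wave2_items).mean(axis=0)])
    alive = dataset.status != "deceased"
    alive_frac = np.concatenate([
        np.isnan(dataset.wave1_items[alive]).mean(axis=0),
        np.isnan(dataset.wave2_items[alive]).mean(axis=0)])
    if np.any(alive_frac >= 0.5):
        raise ValueError("a column has >= 50% missing among non-deceased rows")
    if not dataset.non_deceased().has_missing():
        return dataset

    X = _analysis_matrix(dataset, include_age=True)
    em = em_mvn(X, tol=tol, max_iter=max_iter)
    mask = ~np.isnan(X)
    filled = X.copy()
    for obs, idx in _patterns(mask):
        mis = ~obs
        if not mis.any():
            continue
        inv_oo = _safe_inv(em.cov[np.ix_(obs, obs)])
        reg = em.cov[np.ix_(mis, obs)] @ inv_oo
        dev = X[np.ix_(idx, np.flatnonzero(obs))] - em.mean[obs]
        filled[np.ix_(idx, np.flatnonzero(mis))] = em.mean[mis] + dev @ reg.T
    items = np.clip(np.round(filled[:, :2 * n_items]), 0, 3)

    wave1 = dataset.wave1_items.copy()
    wave2 = dataset.wave2_items.copy()
    alive_idx = np.flatnonzero(alive)
    wave1[alive_idx] = items[:, :n_items]
    wave2[alive_idx] = items[:, n_items:2 * n_items]
    logger.info("EM imputation converged in %d iterations", em.n_iter)
    return PanelDataset(ids=dataset.ids.copy(), wave1_items=wave1, wave2_items=wave2,
                        age=dataset.age.copy(), gender=dataset.gender.copy(),
                        status=dataset.status.copy())
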