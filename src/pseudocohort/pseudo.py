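"""Pseudo-observation relative-risk estimation under a competing risk.

The chain is: Aalen-Johansen cumulative incidence of the event of interest
(cause 1) with death (cause 2) competing; jackknife pseudo-values generated
within censoring strata; log-link generalized estimating equations with
working independence and an Eicker-Huber-White covariance clustered on
family; normal-quantile 95% and Bonferroni-corrected confidence intervals.

The leave-one-out recomputation behind the pseudo-values is exact (not an
influence-function approximation): subject i's removal is applied to the
risk-set and event counts at every jump time and the product-limit recursion
re-evaluated, vectorised over blocks of subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

CENSORED, ABUSE, DEATH = 0, 1, 2


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (perfectly collinear covariates)."""


@dataclass
class CIFEstimate:
    """Aalen-Johansen estimate at the distinct event times.

    ``surv`` is the all-cause Kaplan-Meier; ``cif1``/``cif2`` the cause
    specific cumulative incidences.  All arrays align with ``times``.
    """

    times: np.ndarray
    surv: np.ndarray
    cif1: np.ndarray
    cif2: np.ndarray

    def _step(self, values: np.ndarray, taus, fill: float):
        idx = np.searchsorted(self.times, np.atleast_1d(taus), side="right") - 1
        out = np.where(idx >= 0, values[np.maximum(idx, 0)] if len(values) else fill, fill)
        return out if np.ndim(taus) else float(out[0])

    def cif_at(self, cause: int, taus):
        return self._step(self.cif1 if cause == ABUSE else self.cif2, taus, 0.0)

    def surv_at(self, taus):
        return self._step(self.surv, taus, 1.0)


def aalen_johansen(time, event, entry=None) -> CIFEstimate:
    """Aalen-Johansen estimator of both cause-specific CIFs.

    ``event`` uses 0 = censored, 1 = event of interest, 2 = competing death.
    ``entry`` (optional) enables left truncation: a subject is at risk at s
    when entry < s <= time.  Censorings tied with events are handled with
    the usual events-first convention.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("need at least one record")
    if entry is not None:
        entry = np.asarray(entry, dtype=float)
        if np.any(entry >= time):
            raise ValueError("entry times must precede exit times")

    grid = np.unique(time[event > 0])
    if len(grid) == 0:
        return CIFEstimate(np.array([]), np.array([]), np.array([]), np.array([]))

    t_sorted = np.sort(time)
    n_at = len(time) - np.searchsorted(t_sorted, grid, side="left")
    if entry is not None:
        # at risk at s: entry < s <= time
        n_at = n_at - (len(time) - np.searchsorted(np.sort(entry), grid, side="left"))
        n_at = np.maximum(n_at, 0)

    d1 = np.zeros(len(grid), dtype=np.int64)
    d2 = np.zeros(len(grid), dtype=np.int64)
    pos = np.searchsorted(grid, time)
    on = (pos < len(grid)) & (grid[np.minimum(pos, len(grid) - 1)] == time)
    np.add.at(d1, pos[on & (event == ABUSE)], 1)
    np.add.at(d2, pos[on & (event == DEATH)], 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(n_at > 0, (d1 + d2) / n_at, 0.0)
        h1 = np.where(n_at > 0, d1 / n_at, 0.0)
        h2 = np.where(n_at > 0, d2 / n_at, 0.0)
    surv = np.cumprod(1.0 - haz)
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    cif1 = np.cumsum(surv_prev * h1)
    cif2 = np.cumsum(surv_prev * h2)
    return CIFEstimate(times=grid, surv=surv, cif1=cif1, cif2=cif2)


def _pseudo_stratum(time, event, taus, chunk=512):
    """Exact jackknife pseudo-values of the cause-1 CIF for one stratum."""
    n = len(time)
    taus = np.asarray(taus, dtype=float)
    if np.all(event == ABUSE):
        # no censoring, no competing events: the CIF is a sample mean of
        # indicators, whose jackknife returns the indicator itself, exactly
        k = (time[:, None] <= taus[None, :]).astype(float)
        counts = k.sum(axis=0)
        return counts[None, :] - (counts[None, :] - k)
    full = aalen_johansen(time, event)
    f_full = np.atleast_1d(full.cif_at(ABUSE, taus))

    grid = np.unique(time[(event > 0) & (time <= taus.max())])
    m = len(grid)
    out = np.empty((n, len(taus)))
    if m == 0:
        out[:] = 0.0
        return out

    t_sorted = np.sort(time)
    n_at = n - np.searchsorted(t_sorted, grid, side="left")
    d1 = np.zeros(m, dtype=np.int64)
    d2 = np.zeros(m, dtype=np.int64)
    pos = np.searchsorted(grid, time)
    on = (pos < m) & (grid[np.minimum(pos, m - 1)] == time)
    np.add.at(d1, pos[on & (event == ABUSE)], 1)
    np.add.at(d2, pos[on & (event == DEATH)], 1)

    tau_idx = np.searchsorted(grid, taus, side="right") - 1

    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        t_i = time[lo:hi, None]
        e_i = event[lo:hi, None]
        at_risk = t_i >= grid[None, :]
        is_here = t_i == grid[None, :]
        nn = n_at[None, :] - at_risk
        dd1 = d1[None, :] - (is_here & (e_i == ABUSE))
        dd2 = d2[None, :] - (is_here & (e_i == DEATH))
        with np.errstate(divide="ignore", invalid="ignore"):
            haz = np.where(nn > 0, (dd1 + dd2) / nn, 0.0)
            h1 = np.where(nn > 0, dd1 / nn, 0.0)
        surv = np.cumprod(1.0 - haz, axis=1)
        surv_prev = np.concatenate([np.ones((hi - lo, 1)), surv[:, :-1]], axis=1)
        f_cum = np.cumsum(surv_prev * h1, axis=1)
        loo = np.where(tau_idx[None, :] >= 0, f_cum[:, np.maximum(tau_idx, 0)], 0.0)
        out[lo:hi] = n * f_full[None, :] - (n - 1) * loo
    return out


def pseudo_values(time, event, taus, strata=None) -> np.ndarray:
    """Jackknife pseudo-values theta_i = n*F(tau) - (n-1)*F^(-i)(tau).

    Generated within ``strata`` when given (each stratum contributes its own
    Aalen-Johansen fit and its own n).  Strata with fewer than two records
    are skipped with a warning; their rows come back NaN.  Returns an array
    of shape (n, len(taus)).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    out = np.full((len(time), len(taus)), np.nan)
    if strata is None:
        strata = np.zeros(len(time), dtype=int)
    strata = np.asarray(strata)
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        if len(idx) < 2:
            logger.warning("stratum %r has %d record(s); skipped", s, len(idx))
            continue
        out[idx] = _pseudo_stratum(time[idx], event[idx], taus)
    return out


@dataclass
class ModelFit:
    beta: np.ndarray
    cov: np.ndarray
    names: list
    n_clusters: int
    tau_grid: np.ndarray
    converged: bool
    n_iter: int = 0

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))


def fit_gee_log(
    pseudo: np.ndarray,
    X,
    clusters,
    names=None,
    tau_grid=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelFit:
    """Log-link GEE for pseudo-value responses, working independence.

    ``pseudo`` may be (n,) or (n, K) for K evaluation times; with K > 1 a
    separate intercept per time point is used and a subject's K rows share
    its cluster.  The covariance is the Eicker-Huber-White sandwich with
    clusters summed at the family level.  Raises :class:`RankError` for a
    rank-deficient design; non-convergence is flagged, not raised.
    """
    pseudo = np.asarray(pseudo, dtype=float)
    if pseudo.ndim == 1:
        pseudo = pseudo[:, None]
    n, K = pseudo.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    clusters = np.asarray(clusters)

    # stack K rows per subject; per-tau intercepts
    y = pseudo.T.ravel()
    Xs = np.tile(X, (K, 1))
    icpt = np.zeros((n * K, K))
    for k in range(K):
        icpt[k * n : (k + 1) * n, k] = 1.0
    design = np.hstack([icpt, Xs])
    all_names = [f"intercept_tau{k}" for k in range(K)] + list(names)
    cl = np.tile(clusters, K)

    ok = np.isfinite(y) & np.isfinite(design).all(axis=1)
    y, design, cl = y[ok], design[ok], cl[ok]
    if len(y) == 0:
        raise ValueError("no complete-case rows to fit")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankError("design matrix is rank deficient")

    p = design.shape[1]
    beta = np.zeros(p)
    beta[:K] = np.log(max(float(np.mean(y)), 1e-8))
    converged = False
    it = 0
    scale = max(float(np.mean(np.abs(y))), 1e-8) * len(y)
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -30.0, 5.0)
        mu = np.exp(eta)
        resid = y - mu
        score = design.T @ (mu * resid)
        info = (design * (mu**2)[:, None]).T @ design
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(score)) / scale < tol:
            converged = True
            break

    eta = np.clip(design @ beta, -30.0, 5.0)
    mu = np.exp(eta)
    resid = y - mu
    info = (design * (mu**2)[:, None]).T @ design
    u = design * (mu * resid)[:, None]
    # cluster sums of score contributions
    uniq, inv = np.unique(cl, return_inverse=True)
    usum = np.zeros((len(uniq), p))
    np.add.at(usum, inv, u)
    meat = usum.T @ usum
    try:
        bread = np.linalg.inv(info)
        cov = bread @ meat @ bread
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return ModelFit(
        beta=beta,
        cov=cov,
        names=all_names,
        n_clusters=len(uniq),
        tau_grid=np.atleast_1d(tau_grid if tau_grid is not None else np.arange(K)),
        converged=converged,
        n_iter=it,
    )


def bonferroni_ci(beta_hat: float, se: float, m: int, alpha: float = 0.05):
    """95% and Bonferroni-corrected CIs for RR = exp(beta_hat).

    Returns ``((lo95, hi95), (lo_c, hi_c))`` on the RR scale; the corrected
    quantile is z at 1 - alpha/(2m).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if se < 0:
        raise ValueError("se must be >= 0")
    z95 = norm.ppf(1 - alpha / 2)
    zc = norm.ppf(1 - alpha / (2 * m))
    ci95 = (float(np.exp(beta_hat - z95 * se)), float(np.exp(beta_hat + z95 * se)))
    cic = (float(np.exp(beta_hat - zc * se)), float(np.exp(beta_hat + zc * se)))
    return ci95, cic


def reconstruct_se_from_ci(rr: float, lo95: float, hi95: float, alpha: float = 0.05) -> float:
    """Log-scale SE implied by a symmetric-on-log-scale 95% CI."""
    if not (0 < lo95 <= rr <= hi95):
        raise ValueError("need 0 < lo95 <= rr <= hi95")
    z95 = norm.ppf(1 - alpha / 2)
    return float((np.log(hi95) - np.log(lo95)) / (2 * z95))


@dataclass
class ResultRow:
    """One disease-category model result (a report-table row)."""

    category: str
    model_kind: str
    rr: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    ci_corrected: tuple = (np.nan, np.nan)
    m_tests: int = 33
    n: int = 0
    n_events: int = 0
    converged: bool = False
    cluster: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def significant_uncorrected(self) -> bool:
        lo, hi = self.ci95
        return bool(self.converged and np.isfinite(lo) and (lo > 1 or hi < 1))

    @property
    def significant_corrected(self) -> bool:
        lo, hi = self.ci_corrected
        return bool(self.converged and np.isfinite(lo) and (lo > 1 or hi < 1))
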