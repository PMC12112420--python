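"""Recovering welfare tradeoff ratios (lam) and inequity aversion (kappa)
from slider responses.

Layers, from cheapest to most complete:

* :func:`lambda_readout` — the identity readout: on a quadratic slider the
  interior response position *is* the lambda estimate; boundary responses
  carry only a one-sided bound.
* :func:`point_estimate_lambda_kappa` — the closed-form inversion of the
  piecewise optima on two sliders with opposite self/target payoff offsets.
* :func:`reliability_of_average` — the odds-scaling map from single-response
  test-retest reliability to the reliability of an n-response average.
* :func:`fit_censored_mvnormal` — a Bayesian multivariate-normal fit with
  interval-censored likelihood contributions for boundary responses; used
  for test-retest and convergent-validity correlations.
* :func:`fit_hierarchical_lambda_kappa` — joint posterior over a fixed
  kappa per participant and a lambda per participant-target, from responses
  on sliders with different relative offsets.
* :func:`fit_distance_trend` — mixed-effects monotone trend of the outcome
  against the social-distance rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, logsumexp
from scipy.stats import norm

from ._mcmc import bvn_cdf, run_ensemble, split_rhat
from .records import CENSOR_TOL, ResponseRecord
from .slider_design import QuadraticSliderSpec, equal_payoff_roots

_LOG_2PI = math.log(2.0 * math.pi)


def _log_normal_pdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def _log_half_cauchy(x, scale):
    # density of |Cauchy(0, scale)| evaluated at x >= 0
    return math.log(2.0 / math.pi) - math.log(scale) - math.log1p((x / scale) ** 2)


def _log_beta_sym_pdf(u: float, b: float) -> float:
    # Beta(b, b) log-density, symmetric case
    const = 2.0 * math.lgamma(b) - math.lgamma(2.0 * b)
    return (b - 1.0) * (math.log(max(u, 1e-300)) + math.log(max(1.0 - u, 1e-300))) - const


def _phi(z: float) -> float:
    return math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _me_orthant(b: np.ndarray, R: np.ndarray) -> float:
    """Mendell-Elston approximation of the lower-orthant probability
    P(Z_1 <= b_1, ..., Z_k <= b_k) under correlation matrix R.

    Sequentially conditions on each truncated coordinate, moment-matching
    the truncated normal; fast and accurate to a few percent, used only for
    the rare rows with three or more censored cells.
    """
    b = b.astype(float).copy()
    R = R.astype(float).copy()
    k = len(b)
    logp = 0.0
    for i in range(k):
        p_i = float(ndtr(b[i]))
        p_i = max(p_i, 1e-300)
        logp += math.log(p_i)
        if i == k - 1:
            break
        mu_t = -_phi(b[i]) / p_i  # E[Z | Z <= b]
        var_t = max(1.0 + b[i] * mu_t - mu_t * mu_t, 1e-12)
        shrink = 1.0 - var_t
        s = np.sqrt(np.clip(1.0 - R[i] ** 2 * shrink, 1e-12, None))
        for j in range(i + 1, k):
            b[j] = (b[j] - R[i, j] * mu_t) / s[j]
        for j in range(i + 1, k):
            for l in range(j + 1, k):
                R[j, l] = R[l, j] = (R[j, l] - R[i, j] * R[i, l] * shrink) / (s[j] * s[l])
    return logp

__all__ = [
    "ReliabilityModel",
    "GaussianFitSummary",
    "TrendFit",
    "LambdaReadout",
    "PointEstimate",
    "HierarchicalFit",
    "lambda_readout",
    "point_estimate_lambda_kappa",
    "reliability_of_average",
    "fit_censored_mvnormal",
    "fit_hierarchical_lambda_kappa",
    "fit_distance_trend",
    "CensoredMvnLikelihood",
]


# --------------------------------------------------------------------------
# simple estimators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaReadout:
    estimate: float
    censored: bool
    bound_side: Optional[str] = None  # "lower" / "upper" when censored


def lambda_readout(spec: QuadraticSliderSpec, record: ResponseRecord) -> LambdaReadout:
    """Identity readout of lambda from one response on a quadratic slider.

    The returned estimate is the response position; when the response sits
    at a bound it should be interpreted as a one-sided bound on lambda
    (right-censored at ``xmax``, left-censored at ``xmin``).
    """
    if spec.id is not None and record.slider_id != spec.id:
        raise ValueError(
            f"record slider_id {record.slider_id!r} does not match spec id {spec.id!r}"
        )
    expected = (1.0 - record.raw_position) * spec.xmin + record.raw_position * spec.xmax
    if abs(expected - record.position) > 1e-6 * max(1.0, spec.width):
        raise ValueError("record position inconsistent with its raw position and spec range")
    side = None
    if record.censored:
        side = "lower" if abs(record.position - spec.xmin) <= abs(record.position - spec.xmax) else "upper"
    return LambdaReadout(estimate=record.position, censored=record.censored, bound_side=side)


@dataclass(frozen=True)
class PointEstimate:
    lam: float
    kappa: Optional[float]
    fallback: bool  # True when only the average of the two positions is usable


def point_estimate_lambda_kappa(x1: float, x2: float) -> PointEstimate:
    """Closed-form (lam, kappa) from one response on each of two offset sliders.

    ``x1`` must come from a slider where ws > wt throughout (so the optimum
    is (lam + kappa)/(1 - kappa)) and ``x2`` from one where ws < wt
    throughout (optimum (lam - kappa)/(1 + kappa)); neither may be censored.
    Inverting,

        lam   = (x1 + x2 + 2 x1 x2) / (2 + x1 + x2)
        kappa = (x1 - x2) / (2 + x1 + x2)

    A kappa in [0, 1) exists iff x1 >= x2 > -1 or x1 <= x2 < -1; otherwise
    the average (x1 + x2)/2 is returned as a lambda estimate with no kappa.
    """
    denom = 2.0 + x1 + x2
    if abs(denom) < 1e-12:
        raise ValueError("degenerate input: x1 + x2 = -2")
    if (x1 >= x2 > -1.0) or (x1 <= x2 < -1.0):
        lam = (x1 + x2 + 2.0 * x1 * x2) / denom
        kappa = (x1 - x2) / denom
        return PointEstimate(lam=lam, kappa=kappa, fallback=False)
    return PointEstimate(lam=0.5 * (x1 + x2), kappa=None, fallback=True)


@dataclass(frozen=True)
class ReliabilityModel:
    """Classical-test-theory decomposition: rho = sigma_t2/(sigma_t2 + sigma_e2)."""

    rho: float
    sigma_t2: Optional[float] = None
    sigma_e2: Optional[float] = None
    n: int = 1


def reliability_of_average(rho: float, n: int) -> float:
    """Reliability of the mean of ``n`` parallel measurements.

    Averaging shrinks the error variance by n, so the reliability odds scale
    linearly:  rho'/(1 - rho') = n * rho/(1 - rho), i.e.
    rho' = n rho / (1 + (n - 1) rho).
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie strictly in (0, 1)")
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    return n * rho / (1.0 + (n - 1.0) * rho)


# --------------------------------------------------------------------------
# censored multivariate-normal likelihood
# --------------------------------------------------------------------------

class CensoredMvnLikelihood:
    """Log-likelihood of a multivariate normal with boundary censoring.

    Each row is a d-vector; cells within ``CENSOR_TOL`` of their column's
    bounds are treated as interval-censored (only the event "at or beyond
    the bound" is observed).  Rows are grouped by censoring pattern once;
    each evaluation factorizes the row into the density of the observed
    block times the conditional probability of the censored box (exact via
    the normal CDF for one censored cell, the bivariate normal CDF for two,
    and numeric integration for the rare higher-order patterns).
    """

    def __init__(self, data: np.ndarray, bounds: Sequence[tuple[float, float]]):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (rows x variables)")
        n, d = data.shape
        if d < 2:
            raise ValueError("need at least 2 variables")
        bounds = [(-np.inf, np.inf) if b is None else tuple(b) for b in bounds]
        if len(bounds) != d:
            raise ValueError("one (lower, upper) bound pair per column required")
        self.data = data
        self.d = d
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        self.lo, self.hi = lo, hi
        status = np.zeros(data.shape, dtype=np.int8)
        status[data <= lo + CENSOR_TOL] = -1
        status[data >= hi - CENSOR_TOL] = 1
        self.status = status
        if np.any(np.all(status != 0, axis=0)):
            raise ValueError("inestimable: a variable is censored in every row")
        self.n_complete = int(np.sum(np.all(status == 0, axis=1)))
        # group rows by censoring pattern; precompute index arrays once
        keys = [tuple(row) for row in status]
        seen: dict[tuple[int, ...], list[int]] = {}
        for i, k in enumerate(keys):
            seen.setdefault(k, []).append(i)
        self._groups: list[tuple[np.ndarray, np.ndarray]] = [
            (np.array(k), np.array(idx)) for k, idx in seen.items()
        ]
        # sufficient statistics of the fully observed rows (fast path)
        complete = data[np.all(status == 0, axis=1)]
        self._nc = complete.shape[0]
        if self._nc:
            self._xbar = complete.mean(axis=0)
            dev = complete - self._xbar
            self._scatter = dev.T @ dev
        # precomputed censored-pattern groups
        self._cgroups = []
        for pat, idx in self._groups:
            cen = np.where(pat != 0)[0]
            if len(cen) == 0:
                continue
            obs = np.where(pat == 0)[0]
            signs = pat[cen]
            thr = np.where(signs < 0, lo[cen], hi[cen])
            self._cgroups.append(
                {
                    "obs": obs,
                    "cen": cen,
                    "signs": signs,
                    "thr": thr,
                    "rows_obs": data[np.ix_(idx, obs)] if len(obs) else None,
                    "n": len(idx),
                    "ix_oo": np.ix_(obs, obs),
                    "ix_co": np.ix_(cen, obs),
                    "ix_cc": np.ix_(cen, cen),
                }
            )

    def log_likelihood(self, mu: np.ndarray, cov: np.ndarray) -> float:
        if self.d == 2:
            return self._log_likelihood_2d(mu, cov)
        return self._log_likelihood_general(mu, cov)

    def _log_likelihood_2d(self, mu: np.ndarray, cov: np.ndarray) -> float:
        """Closed-form bivariate path (the common case for test-retest fits)."""
        s0 = math.sqrt(cov[0, 0])
        s1 = math.sqrt(cov[1, 1])
        rho = cov[0, 1] / (s0 * s1)
        if not (-0.9999 < rho < 0.9999):
            return -np.inf
        om = 1.0 - rho * rho
        total = 0.0
        for pat, idx in self._groups:
            rows = self.data[idx]
            z0 = (rows[:, 0] - mu[0]) / s0
            z1 = (rows[:, 1] - mu[1]) / s1
            c0, c1 = int(pat[0]), int(pat[1])
            if c0 == 0 and c1 == 0:
                q = (z0 * z0 - 2.0 * rho * z0 * z1 + z1 * z1) / om
                total += float(
                    np.sum(-0.5 * q) - len(idx) * (math.log(2 * math.pi * s0 * s1) + 0.5 * math.log(om))
                )
            elif c0 == 0 or c1 == 0:
                # one observed cell, one censored cell
                if c0 == 0:
                    zo, so, cj, sj, muj = z0, s0, 1, s1, mu[1]
                    sign = c1
                else:
                    zo, so, cj, sj, muj = z1, s1, 0, s0, mu[0]
                    sign = c0
                total += float(np.sum(-0.5 * zo * zo) - len(idx) * (math.log(so) + 0.5 * _LOG_2PI))
                thr = self.lo[cj] if sign < 0 else self.hi[cj]
                cmu = muj + rho * sj * zo
                csd = sj * math.sqrt(om)
                zlim = (thr - cmu) / csd * (1.0 if sign < 0 else -1.0)
                total += float(np.sum(np.log(np.clip(ndtr(zlim), 1e-300, None))))
            else:
                t0 = (self.lo[0] if c0 < 0 else self.hi[0]) - mu[0]
                t1 = (self.lo[1] if c1 < 0 else self.hi[1]) - mu[1]
                a = t0 / s0 * (1.0 if c0 < 0 else -1.0)
                b = t1 / s1 * (1.0 if c1 < 0 else -1.0)
                p = bvn_cdf(a, b, rho * c0 * c1)
                total += len(idx) * float(np.log(max(float(p), 1e-300)))
            if not np.isfinite(total):
                return -np.inf
        return total

    def _log_likelihood_general(self, mu: np.ndarray, cov: np.ndarray) -> float:
        d = self.d
        total = 0.0
        # fully observed rows via sufficient statistics
        if self._nc:
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            r = self._xbar - mu
            zr = np.linalg.solve(chol, r)
            zs = np.linalg.solve(chol, self._scatter)
            tr = np.trace(np.linalg.solve(chol.T, zs))
            total += -0.5 * (
                self._nc * (d * _LOG_2PI + logdet) + tr + self._nc * float(zr @ zr)
            )
        for g in self._cgroups:
            obs, cen = g["obs"], g["cen"]
            n_g = g["n"]
            if len(obs) > 0:
                sub = cov[g["ix_oo"]]
                try:
                    chol = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    return -np.inf
                resid = g["rows_obs"] - mu[obs]
                z = np.linalg.solve(chol, resid.T)
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                total += float(
                    -0.5 * (z**2).sum() - 0.5 * n_g * (len(obs) * _LOG_2PI + logdet)
                )
                # conditional distribution of censored cells given observed
                sub_io = cov[g["ix_co"]]
                k = np.linalg.solve(sub, sub_io.T).T
                cmu = mu[cen] + resid @ k.T
                ccov = cov[g["ix_cc"]] - k @ sub_io.T
            else:
                cmu = np.broadcast_to(mu[cen], (n_g, len(cen)))
                ccov = cov[g["ix_cc"]]
            total += self._log_box_prob_group(g, cmu, ccov)
            if not np.isfinite(total):
                return -np.inf
        return total

    def log_likelihood_many(self, mus: np.ndarray, covs: np.ndarray) -> np.ndarray:
        """Batched log-likelihood over B parameter sets.

        ``mus`` is (B, d) and ``covs`` (B, d, d); returns (B,).  Uses
        numpy's stacked linear algebra so the per-group overhead is paid
        once per batch rather than once per parameter set; falls back to
        the scalar path when any covariance in the batch is not positive
        definite.
        """
        mus = np.asarray(mus, dtype=float)
        covs = np.asarray(covs, dtype=float)
        B, d = mus.shape
        good = np.linalg.eigvalsh(covs)[:, 0] > 1e-10
        out = np.full(B, -np.inf)
        if not good.any():
            return out
        try:
            out[good] = self._log_likelihood_many_inner(mus[good], covs[good])
        except np.linalg.LinAlgError:
            out[good] = np.array(
                [self.log_likelihood(mus[b], covs[b]) for b in np.where(good)[0]]
            )
        return out

    def _log_likelihood_many_inner(self, mus, covs) -> np.ndarray:
        B, d = mus.shape
        out = np.zeros(B)
        if self._nc:
            chol = np.linalg.cholesky(covs)  # (B, d, d)
            logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
            r = self._xbar[None, :] - mus
            zr = np.linalg.solve(chol, r[..., None])[..., 0]
            zs = np.linalg.solve(chol, np.broadcast_to(self._scatter, (B, d, d)))
            zz = np.linalg.solve(np.transpose(chol, (0, 2, 1)), zs)
            tr = np.trace(zz, axis1=1, axis2=2)
            out += -0.5 * (
                self._nc * (d * _LOG_2PI + logdet) + tr + self._nc * (zr**2).sum(axis=1)
            )
        for g in self._cgroups:
            obs, cen = g["obs"], g["cen"]
            n_g = g["n"]
            c = len(cen)
            if len(obs) > 0:
                sub = covs[:, obs[:, None], obs[None, :]]  # (B, k, k)
                chol = np.linalg.cholesky(sub)
                resid = g["rows_obs"][None, :, :] - mus[:, None, obs]  # (B, n_g, k)
                z = np.linalg.solve(chol, np.transpose(resid, (0, 2, 1)))
                logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
                out += -0.5 * (z**2).sum(axis=(1, 2)) - 0.5 * n_g * (
                    len(obs) * _LOG_2PI + logdet
                )
                sub_io = covs[:, cen[:, None], obs[None, :]]  # (B, c, k)
                kmat = np.transpose(
                    np.linalg.solve(sub, np.transpose(sub_io, (0, 2, 1))), (0, 2, 1)
                )  # (B, c, k)
                cmu = mus[:, None, cen] + np.einsum("bnk,bck->bnc", resid, kmat)
                ccov = covs[:, cen[:, None], cen[None, :]] - np.einsum(
                    "bck,blk->bcl", kmat, sub_io
                )
            else:
                cmu = np.broadcast_to(mus[:, cen][:, None, :], (B, n_g, c))
                ccov = covs[:, cen[:, None], cen[None, :]]
            signs, thr = g["signs"], g["thr"]
            var = np.clip(np.diagonal(ccov, axis1=1, axis2=2), 1e-300, None)  # (B, c)
            sd = np.sqrt(var)
            zlim = (thr[None, None, :] - cmu) / sd[:, None, :]
            zlim = zlim * np.where(signs < 0, 1.0, -1.0)[None, None, :]
            if c == 1:
                p = ndtr(zlim[:, :, 0])
                out += np.log(np.clip(p, 1e-300, None)).sum(axis=1)
            elif c == 2:
                rho = ccov[:, 0, 1] / (sd[:, 0] * sd[:, 1]) * signs[0] * signs[1]
                p = bvn_cdf(zlim[:, :, 0], zlim[:, :, 1], rho[:, None])
                out += np.log(np.clip(p, 1e-300, None)).sum(axis=1)
            else:
                flip = np.where(signs < 0, 1.0, -1.0)
                for b in range(B):
                    corr = (ccov[b] / np.outer(sd[b], sd[b])) * np.outer(flip, flip)
                    for r_i in range(n_g):
                        out[b] += _me_orthant(zlim[b, r_i], corr)
        bad = ~np.isfinite(out)
        out[bad] = -np.inf
        return out

    def _log_box_prob_group(self, g, cmu, ccov) -> float:
        signs, thr = g["signs"], g["thr"]
        var = np.clip(np.diag(ccov), 1e-300, None)
        sd = np.sqrt(var)
        zlim = (thr - cmu) / sd
        zlim = zlim * np.where(signs < 0, 1.0, -1.0)[None, :]
        if len(signs) == 1:
            p = ndtr(zlim[:, 0])
            return float(np.sum(np.log(np.clip(p, 1e-300, None))))
        if len(signs) == 2:
            rho = ccov[0, 1] / (sd[0] * sd[1]) * signs[0] * signs[1]
            p = bvn_cdf(zlim[:, 0], zlim[:, 1], rho)
            return float(np.sum(np.log(np.clip(p, 1e-300, None))))
        flip = np.where(signs < 0, 1.0, -1.0)
        corr = (ccov / np.outer(sd, sd)) * np.outer(flip, flip)
        total = 0.0
        for r in range(cmu.shape[0]):
            total += _me_orthant(zlim[r], corr)
        return float(total)


def _partials_to_corr(z: np.ndarray, d: int) -> tuple[np.ndarray, float]:
    """Map unconstrained partials to a correlation matrix; return (R, log prior).

    tanh-transformed canonical partial correlations with the Beta priors
    that make the implied distribution uniform over valid correlation
    matrices (the eta=1 case of the LKJ family).
    """
    r = np.tanh(z)
    p = np.zeros((d, d))
    iu = np.triu_indices(d, 1)
    p[iu] = r
    R = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            rho = p[i, j]
            for k in range(i - 1, -1, -1):
                rho = rho * math.sqrt((1 - p[k, i] ** 2) * (1 - p[k, j] ** 2)) + p[k, i] * p[k, j]
            R[i, j] = R[j, i] = rho
    logp = 0.0
    for (i, j), rr in zip(zip(*iu), r):
        lag = j - i
        b = 1.0 + 0.5 * (d - 1 - lag)
        logp += _log_beta_sym_pdf((rr + 1.0) / 2.0, b) - math.log(2.0)
        logp += math.log(max(1.0 - rr**2, 1e-300))  # Jacobian of tanh
    return R, logp


@dataclass
class GaussianFitSummary:
    """Posterior summary of a (censored) multivariate-normal fit.

    Entries are posterior medians; correlation credible intervals are 95%
    equal-tailed.  ``rhat_max`` is the largest split-R-hat across
    parameters (values near 1 indicate convergence; a warning threshold of
    1.01 is conventional).
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    corr_lo: np.ndarray
    corr_hi: np.ndarray
    rhat_max: float
    n_draws: int
    draws: Optional[np.ndarray] = None
    log_posterior: Optional[Callable] = field(default=None, repr=False)

    def corr_entry(self, i: int, j: int) -> tuple[float, float, float]:
        return self.corr[i, j], self.corr_lo[i, j], self.corr_hi[i, j]


def fit_censored_mvnormal(
    data,
    bounds=None,
    *,
    variables: Optional[list[str]] = None,
    seed: int = 0,
    n_steps: int = 900,
    n_burn: Optional[int] = None,
    n_walkers: Optional[int] = None,
    return_draws: bool = False,
) -> GaussianFitSummary:
    """Bayesian multivariate-normal fit with boundary censoring.

    ``data`` is an (n, d) array or DataFrame of repeated measurements (one
    column per variable, d in {2, 4, 6, ...}); ``bounds`` gives a (lower,
    upper) pair per column (``None`` for unbounded).  Priors: wide
    zero-centered normals on means, half-Cauchy on scales, uniform over
    valid correlation matrices.  Requires at least 10 fully observed rows.
    """
    if isinstance(data, pd.DataFrame):
        variables = variables or list(map(str, data.columns))
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    if bounds is None:
        bounds = [None] * d
    lik = CensoredMvnLikelihood(data, bounds)
    if lik.n_complete < 10:
        raise ValueError(f"need >= 10 complete rows, got {lik.n_complete}")
    variables = variables or [f"v{i}" for i in range(d)]

    interior = np.where(lik.status == 0, data, np.nan)
    mu0 = np.nanmean(interior, axis=0)
    sd0 = np.nanstd(interior, axis=0, ddof=1)
    sd0 = np.where(np.isfinite(sd0) & (sd0 > 1e-6), sd0, 1.0)
    mu0 = np.where(np.isfinite(mu0), mu0, 0.0)
    scale = float(np.median(sd0))
    n_corr = d * (d - 1) // 2

    def unpack(theta):
        mu = theta[:d]
        log_sd = theta[d : 2 * d]
        z = theta[2 * d :]
        return mu, log_sd, z

    def log_post(theta):
        mu, log_sd, z = unpack(theta)
        if np.any(np.abs(log_sd) > 15) or np.any(np.abs(z) > 12):
            return -np.inf
        sd = np.exp(log_sd)
        R, lp_corr = _partials_to_corr(z, d)
        cov = R * np.outer(sd, sd)
        lp = lp_corr
        mu_scale = 100.0 * max(scale, 1.0)
        lp += float(np.sum(-0.5 * (mu / mu_scale) ** 2)) - d * math.log(mu_scale)
        for s_i, ls_i in zip(sd, log_sd):
            lp += _log_half_cauchy(s_i, 5.0 * scale) + ls_i  # + Jacobian of log-sd
        ll = lik.log_likelihood(mu, cov)
        return lp + ll if np.isfinite(ll) else -np.inf

    x0 = np.concatenate([mu0, np.log(sd0), np.zeros(n_corr)])
    chain = run_ensemble(log_post, x0, n_steps, seed=seed, n_walkers=n_walkers)
    burn = n_burn if n_burn is not None else n_steps // 2
    post = chain[burn:]
    rhat = split_rhat(post)
    flat = post.reshape(-1, post.shape[-1])

    mus = flat[:, :d]
    sds = np.exp(flat[:, d : 2 * d])
    corrs = np.empty((flat.shape[0], d, d))
    for s in range(flat.shape[0]):
        corrs[s], _ = _partials_to_corr(flat[s, 2 * d :], d)
    summary = GaussianFitSummary(
        variables=variables,
        means=np.median(mus, axis=0),
        sds=np.median(sds, axis=0),
        corr=np.median(corrs, axis=0),
        corr_lo=np.quantile(corrs, 0.025, axis=0),
        corr_hi=np.quantile(corrs, 0.975, axis=0),
        rhat_max=float(np.nanmax(rhat)),
        n_draws=flat.shape[0],
        draws=flat if return_draws else None,
        log_posterior=log_post if return_draws else None,
    )
    return summary


# --------------------------------------------------------------------------
# hierarchical joint estimation of lambda and kappa
# --------------------------------------------------------------------------

@dataclass
class HierarchicalFit:
    """Grid-quadrature posterior over per-participant kappa and
    per-participant-target lambda."""

    kappa: pd.DataFrame  # participant_id, median, lo, hi
    lam: pd.DataFrame  # participant_id, target_id, median, lo, hi
    sigma_e: float
    kappa_grid: np.ndarray
    lambda_grid: np.ndarray


def _optimum_table(
    spec: QuadraticSliderSpec, lam_grid: np.ndarray, kap_grid: np.ndarray
) -> np.ndarray:
    """Utility-maximizing position for every (lambda, kappa) grid pair."""
    L = lam_grid[:, None]
    K = kap_grid[None, :]
    cands = [
        np.clip((L + K) / (1.0 - K), spec.xmin, spec.xmax),
        np.clip((L - K) / (1.0 + K), spec.xmin, spec.xmax),
    ]
    consts = list(equal_payoff_roots(spec)) + [spec.xmin, spec.xmax]
    shape = np.broadcast_shapes(L.shape, K.shape)
    for c in consts:
        cands.append(np.full(shape, c))
    X = np.stack(cands, axis=-1)  # (nl, nk, ncand)
    ws = -spec.a * X**2 + spec.bs
    wt = 2.0 * spec.a * X + spec.bt
    U = ws + L[..., None] * wt - K[..., None] * np.abs(ws - wt)
    best = np.argmax(U, axis=-1)
    return np.take_along_axis(X, best[..., None], axis=-1)[..., 0]


def _median_ci_from_grid(grid: np.ndarray, pmf: np.ndarray) -> tuple[float, float, float]:
    cdf = np.cumsum(pmf)
    cdf = cdf / cdf[-1]

    def q(p):
        i = int(np.searchsorted(cdf, p))
        return float(grid[min(i, len(grid) - 1)])

    return q(0.5), q(0.025), q(0.975)


def estimate_sigma_from_repeats(responses: pd.DataFrame, floor: float = 0.02) -> float:
    """Method-of-moments noise sd from uncensored repeat pairs.

    For two parallel measurements x1, x2 of the same quantity with
    independent N(0, sigma^2) errors, Var(x1 - x2) = 2 sigma^2.
    """
    diffs = []
    for _, g in responses.groupby(["participant_id", "target_id", "slider_id"]):
        g = g.sort_values("repeat_index")
        if len(g) >= 2 and not g["censored"].any():
            x = g["position"].to_numpy()
            diffs.extend(np.diff(x[:2]))
    if not diffs:
        return max(floor, 0.1)
    return max(floor, float(np.sqrt(np.mean(np.square(diffs)) / 2.0)))


def fit_hierarchical_lambda_kappa(
    responses: pd.DataFrame,
    sliders: dict[str, QuadraticSliderSpec],
    *,
    sigma_e: Optional[float] = None,
    kappa_max: float = 0.95,
    kappa_step: float = 0.01,
    lambda_range: tuple[float, float] = (-4.0, 4.0),
    lambda_step: float = 0.01,
    lambda_prior_sd: float = 2.0,
) -> HierarchicalFit:
    """Joint posterior over kappa (fixed per participant) and lambda
    (varying per target) from responses on >= 2 sliders with different
    relative payoff offsets.

    The likelihood of a response is a censored normal around the exact
    utility-maximizing position for the candidate (lambda, kappa): interior
    responses contribute a Gaussian density, boundary responses the tail
    probability of being pushed at or beyond the bound.  Priors: kappa
    uniform on [0, kappa_max]; lambda zero-centered normal with sd
    ``lambda_prior_sd``.  The posterior is evaluated exactly on a
    (lambda, kappa) grid — participants are conditionally independent, so
    no MCMC is needed.  ``sigma_e`` defaults to a method-of-moments
    estimate from repeat pairs.
    """
    slider_ids = responses["slider_id"].unique()
    if len(slider_ids) < 2:
        raise ValueError("identifiability: need responses on >= 2 sliders with different offsets")
    missing = [s for s in slider_ids if s not in sliders]
    if missing:
        raise ValueError(f"no spec provided for sliders: {missing}")
    if sigma_e is None:
        sigma_e = estimate_sigma_from_repeats(responses)
    sig = float(sigma_e)

    kap_grid = np.arange(0.0, kappa_max + 1e-9, kappa_step)
    lam_grid = np.arange(lambda_range[0], lambda_range[1] + 1e-9, lambda_step)
    tables = {sid: _optimum_table(sliders[sid], lam_grid, kap_grid) for sid in slider_ids}
    log_prior_lam = norm.logpdf(lam_grid, 0.0, lambda_prior_sd)[:, None]

    kappa_rows = []
    lam_rows = []
    for pid, pgroup in responses.groupby("participant_id", sort=False):
        per_target: dict[str, np.ndarray] = {}
        for tid, tgroup in pgroup.groupby("target_id", sort=False):
            ll = np.zeros((len(lam_grid), len(kap_grid)))
            for row in tgroup.itertuples():
                m = tables[row.slider_id]
                spec = sliders[row.slider_id]
                x = row.position
                if row.censored and x >= spec.xmax - CENSOR_TOL:
                    ll += np.log(np.clip(ndtr((m - spec.xmax) / sig), 1e-300, None))
                elif row.censored and x <= spec.xmin + CENSOR_TOL:
                    ll += np.log(np.clip(ndtr((spec.xmin - m) / sig), 1e-300, None))
                else:
                    ll += norm.logpdf(x, m, sig)
            per_target[tid] = ll
        # marginalize lambda per target -> log evidence for kappa
        log_k = np.zeros(len(kap_grid))
        evid = {}
        for tid, ll in per_target.items():
            e = logsumexp(ll + log_prior_lam, axis=0)
            evid[tid] = e
            log_k += e
        post_k = np.exp(log_k - logsumexp(log_k))
        med, lo, hi = _median_ci_from_grid(kap_grid, post_k)
        kappa_rows.append({"participant_id": pid, "median": med, "lo": lo, "hi": hi})
        for tid, ll in per_target.items():
            cond = np.exp(ll + log_prior_lam - evid[tid][None, :])  # p(lam | kappa)
            p_lam = cond @ post_k
            med, lo, hi = _median_ci_from_grid(lam_grid, p_lam)
            ranks = responses.loc[
                (responses["participant_id"] == pid) & (responses["target_id"] == tid),
                "target_rank",
            ]
            lam_rows.append(
                {
                    "participant_id": pid,
                    "target_id": tid,
                    "target_rank": int(ranks.iloc[0]),
                    "median": med,
                    "lo": lo,
                    "hi": hi,
                }
            )
    return HierarchicalFit(
        kappa=pd.DataFrame(kappa_rows),
        lam=pd.DataFrame(lam_rows),
        sigma_e=sig,
        kappa_grid=kap_grid,
        lambda_grid=lam_grid,
    )


# --------------------------------------------------------------------------
# social-distance trend
# --------------------------------------------------------------------------

@dataclass
class TrendFit:
    """Posterior of the monotone social-distance trend.

    ``b3`` is the mean per-rank slope of the outcome (posterior median with
    95% equal-tailed CI); ``rank_means`` are the fitted population means per
    rank at the posterior median parameters (monotone by construction, in
    the direction of the sign of b3).
    """

    b3: float
    b3_lo: float
    b3_hi: float
    ranks: np.ndarray
    rank_means: np.ndarray
    rhat_max: float
    n_draws: int


def fit_distance_trend(
    data: pd.DataFrame,
    outcome: str = "position",
    *,
    bounds: Optional[tuple[float, float]] = None,
    seed: int = 0,
    n_steps: int = 1500,
    n_burn: Optional[int] = None,
) -> TrendFit:
    """Monotone mixed-effects trend of an outcome against social-distance rank.

    Model: y = b0 + b3*(K-1)*c_r + u_p + e, where c is the cumulative sum of
    a simplex over per-rank increments (so the rank means are monotone, with
    direction given by the sign of the total effect), u_p is a participant
    random intercept and e is Gaussian noise.  Rank is treated as ordinal
    throughout; b3 is the average change in the outcome per unit increase
    in rank.

    When ``bounds`` (lower, upper) is given, outcomes at a bound contribute
    censored (tail-probability) likelihood terms; the random intercept is
    then integrated out by Gauss-Hermite quadrature.  Without bounds the
    intercept is marginalized in closed form.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    y = data[outcome].to_numpy(dtype=float)
    ranks_sorted = np.sort(data["target_rank"].unique())
    K = len(ranks_sorted)
    if K < 3:
        raise ValueError("need at least 3 distinct social-distance ranks")
    rank_code = np.searchsorted(ranks_sorted, data["target_rank"].to_numpy())
    pid_codes, _ = pd.factorize(data["participant_id"])
    order = np.argsort(pid_codes, kind="stable")
    y, rank_code, pid_codes = y[order], rank_code[order], pid_codes[order]
    n_p = pid_codes.max() + 1
    counts = np.bincount(pid_codes).astype(float)
    starts = np.concatenate([[0], np.cumsum(counts.astype(int))[:-1]])
    scale_y = max(float(np.std(y)), 1e-3)

    if bounds is not None:
        lo_b, hi_b = bounds
        at_lo = y <= lo_b + CENSOR_TOL
        at_hi = y >= hi_b - CENSOR_TOL
        obs = ~(at_lo | at_hi)
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(15)  # probabilists'
        log_gh_w = np.log(gh_w / np.sqrt(2 * np.pi))
    else:
        obs = np.ones_like(y, dtype=bool)
        at_lo = at_hi = np.zeros_like(y, dtype=bool)

    # theta = [b0, b3, z (K-1), log_su, log_se]
    def unpack(theta):
        b0, b3 = theta[0], theta[1]
        z = theta[2 : 2 + K - 1]
        log_su, log_se = theta[-2], theta[-1]
        return b0, b3, z, log_su, log_se

    def rank_effects(b3, z):
        w = np.exp(z - z.max())
        w = w / w.sum()
        c = np.concatenate([[0.0], np.cumsum(w)])
        return b3 * (K - 1) * c

    def log_lik(b0, b3, z, su2, se2):
        eff = rank_effects(b3, z)
        mu = b0 + eff[rank_code]
        se = math.sqrt(se2)
        if bounds is None:
            r = y - mu
            ssr = np.bincount(pid_codes, weights=r * r, minlength=n_p)
            s = np.bincount(pid_codes, weights=r, minlength=n_p)
            denom = se2 + counts * su2
            return -0.5 * float(
                np.sum(
                    counts * np.log(2 * np.pi * se2)
                    + np.log(denom / se2)
                    + ssr / se2
                    - (su2 / (se2 * denom)) * s * s
                )
            )
        # censored rows: Gauss-Hermite over the participant intercept
        u = math.sqrt(su2) * gh_x  # (H,)
        zmat = (y[:, None] - mu[:, None] - u[None, :]) / se  # (N, H)
        logf = np.empty_like(zmat)
        logf[obs] = -0.5 * zmat[obs] ** 2 - math.log(se) - 0.5 * _LOG_2PI
        if at_hi.any():
            logf[at_hi] = np.log(np.clip(ndtr(-zmat[at_hi]), 1e-300, None))
        if at_lo.any():
            logf[at_lo] = np.log(np.clip(ndtr(zmat[at_lo]), 1e-300, None))
        per_p = np.add.reduceat(logf, starts, axis=0)  # (P, H)
        return float(np.sum(logsumexp(per_p + log_gh_w[None, :], axis=1)))

    def log_post(theta):
        b0, b3, z, log_su, log_se = unpack(theta)
        if abs(log_su) > 15 or abs(log_se) > 15:
            return -np.inf
        su2 = np.exp(2 * log_su)
        se2 = np.exp(2 * log_se)
        ll = log_lik(b0, b3, z, su2, se2)
        lp = _log_normal_pdf(b0, 0.0, 10 * scale_y) + _log_normal_pdf(b3, 0.0, 5 * scale_y)
        lp += float(np.sum(-0.5 * z * z)) - 0.5 * len(z) * _LOG_2PI
        for lsd in (log_su, log_se):
            lp += _log_half_cauchy(np.exp(lsd), scale_y) + lsd
        return float(ll + lp)

    x0 = np.concatenate(
        [[float(np.mean(y)), 0.0], np.zeros(K - 1), [np.log(scale_y), np.log(scale_y)]]
    )
    chain = run_ensemble(log_post, x0, n_steps, seed=seed)
    burn = n_burn if n_burn is not None else n_steps // 2
    post = chain[burn:]
    rhat = split_rhat(post)
    flat = post.reshape(-1, post.shape[-1])
    b3s = flat[:, 1]
    med_idx = np.argsort(flat[:, 1])[len(flat) // 2]
    b0m, b3m, zm, _, _ = unpack(flat[med_idx])
    means = b0m + rank_effects(b3m, zm)
    return TrendFit(
        b3=float(np.median(b3s)),
        b3_lo=float(np.quantile(b3s, 0.025)),
        b3_hi=float(np.quantile(b3s, 0.975)),
        ranks=ranks_sorted,
        rank_means=means,
        rhat_max=float(np.nanmax(rhat)),
        n_draws=flat.shape[0],
    )
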