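"""Adjudicating utility-based responding (H-lambda) against raw-position
anchoring (H-chi) from responses on sliders with shifted ranges.

If a respondent maximizes utility, the lambda implied by her response is
invariant to the slider's range, so her raw position must shift when the
range shifts (for equal-width sliders, by a constant raw offset).  If she
instead anchors on the raw position as a qualitative kindness level, the
raw position is invariant.  The two accounts are compared by fitting a
censored multivariate normal to the per-participant-target response
vectors under each account's mean constraint and contrasting marginal
likelihoods (bridge sampling; a maximized-likelihood difference is reported
alongside as a cheap cross-check — the two models have equal dimensionality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._mcmc import bridge_log_marginal, run_ensemble, split_rhat
from .estimation import CensoredMvnLikelihood
from .slider_design import QuadraticSliderSpec

__all__ = [
    "PredictedPosition",
    "EvidenceSummary",
    "predict_h_lambda",
    "predict_h_chi",
    "compare_models",
]


class PredictedPosition(NamedTuple):
    chi: float
    clipped: bool


def predict_h_lambda(
    chi_a: float, slider_a: QuadraticSliderSpec, slider_b: QuadraticSliderSpec
) -> PredictedPosition:
    """Raw position on slider B implying the same lambda as ``chi_a`` on A.

    chi_B = (width_A / width_B) * chi_A + (xmin_A - xmin_B) / width_B,
    clipped to [0, 1] with a flag (out-of-range predictions correspond to
    lambdas the second slider cannot express).
    """
    for s in (slider_a, slider_b):
        if s.width <= 0:
            raise ValueError("degenerate slider: zero or negative width")
    chi_b = (slider_a.width * chi_a + slider_a.xmin - slider_b.xmin) / slider_b.width
    clipped = not (0.0 <= chi_b <= 1.0)
    return PredictedPosition(chi=min(max(chi_b, 0.0), 1.0), clipped=clipped)


def predict_h_chi(chi_a: float) -> float:
    """Raw-anchor prediction: the raw position carries over unchanged."""
    return chi_a


@dataclass
class EvidenceSummary:
    """Evidence for utility-based responding over raw-position anchoring.

    ``log_bf`` is the log Bayes factor (natural log, equal prior odds):
    positive favors H-lambda.  ``log_bf_maxlik`` is the maximized
    log-likelihood difference (equal parameter counts, so it doubles as a
    BIC-scale fallback).
    """

    log_bf: float
    log_bf_maxlik: float
    favored: str
    n_rows: int
    model_summaries: dict


def _wide_chi_table(
    responses: pd.DataFrame, slider_order: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    wide = responses.pivot_table(
        index=["participant_id", "target_id"],
        columns=["slider_id", "repeat_index"],
        values="raw_position",
    )
    cols = [c for s in slider_order for c in sorted(wide.columns) if c[0] == s]
    wide = wide[cols].dropna()
    return wide.to_numpy(dtype=float), list(cols)


def compare_models(
    responses: pd.DataFrame,
    sliders: dict[str, QuadraticSliderSpec],
    *,
    seed: int = 0,
    n_steps: int = 450,
    n_walkers: int = 16,
    lambda_prior_sd: float = 2.0,
) -> EvidenceSummary:
    """Fit both response accounts to multi-slider data and compare evidence.

    ``responses`` uses the standard response schema with >= 2 sliders and
    repeated measurements per participant-target; analysis is on the raw
    [0, 1] position scale with censoring at both bounds.  The mean vector
    is constrained per model: under H-lambda a single population mean
    lambda maps through each slider's range; under H-chi a single raw
    position is shared by all sliders.  The covariance is structured (one
    scale per slider shared across its repeats, one within-slider and one
    between-slider correlation), identical in form across the two models so
    the comparison isolates the mean structure.
    """
    present = [s for s in sliders if s in set(responses["slider_id"])]
    if len(present) < 2:
        raise ValueError("need responses on >= 2 sliders")
    specs = [sliders[s] for s in present]
    widths = np.array([s.width for s in specs])
    if np.any(widths <= 0):
        raise ValueError("degenerate slider: zero or negative width")
    data, cols = _wide_chi_table(responses, present)
    if data.shape[0] < 10:
        raise ValueError("need >= 10 complete participant-target rows")
    d = data.shape[1]
    slider_of_col = np.array([present.index(c[0]) for c in cols])
    lik = CensoredMvnLikelihood(data, [(0.0, 1.0)] * d)
    xmins = np.array([s.xmin for s in specs])
    n_sl = len(present)

    same = slider_of_col[:, None] == slider_of_col[None, :]
    eye = np.eye(d, dtype=bool)

    def make_log_post(model: str):
        """Vectorized log-posterior over a (B, ndim) parameter batch."""

        def log_post(thetas):
            thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
            B = thetas.shape[0]
            mu0 = thetas[:, 0]
            log_sd = thetas[:, 1 : 1 + n_sl]
            zw, zb = thetas[:, -2], thetas[:, -1]
            ok = (
                (np.abs(log_sd) <= 15).all(axis=1)
                & (np.abs(zw) <= 12)
                & (np.abs(zb) <= 12)
            )
            if model == "Hlambda":
                mu_cols = (mu0[:, None] - xmins[slider_of_col][None, :]) / widths[
                    slider_of_col
                ][None, :]
                lp = -0.5 * (mu0 / lambda_prior_sd) ** 2 - np.log(lambda_prior_sd)
            else:
                mu_cols = np.broadcast_to(mu0[:, None], (B, d)).copy()
                s = lambda_prior_sd / widths.mean()
                lp = -0.5 * ((mu0 - 0.5) / s) ** 2 - np.log(s)
            sd = np.exp(log_sd)  # (B, n_sl)
            # half-Cauchy(1) on scales, + log-scale Jacobian
            lp = lp + (np.log(2.0 / np.pi) - np.log1p(sd**2) + log_sd).sum(axis=1)
            lp = lp - 0.125 * (zw**2 + zb**2)  # N(0, 2) priors on corr transforms
            rw = np.tanh(zw)[:, None, None]
            rb = np.tanh(zb)[:, None, None]
            R = np.where(same[None, :, :], rw, rb)
            R[:, eye] = 1.0
            sd_cols = sd[:, slider_of_col]
            covs = R * (sd_cols[:, :, None] * sd_cols[:, None, :])
            ll = np.full(B, -np.inf)
            if ok.any():
                ll[ok] = lik.log_likelihood_many(mu_cols[ok], covs[ok])
            return lp + ll

        return log_post

    interior = np.where(lik.status == 0, data, np.nan)
    sd0 = np.nanstd(interior, axis=0, ddof=1)
    sd0 = np.where(np.isfinite(sd0) & (sd0 > 1e-4), sd0, 0.1)
    sd0_sl = np.array([sd0[slider_of_col == k].mean() for k in range(n_sl)])
    mu_chi0 = float(np.nanmean(interior))
    mu_lam0 = float(np.nanmean(interior[:, 0]) * widths[0] + xmins[0]) if np.isfinite(np.nanmean(interior[:, 0])) else 0.0

    results = {}
    maxll = {}
    for model, m0 in (("Hlambda", mu_lam0), ("Hchi", mu_chi0)):
        log_post = make_log_post(model)
        x0 = np.concatenate([[m0], np.log(sd0_sl), [1.0, 1.0]])
        chain, lp_chain = run_ensemble(
            log_post, x0, n_steps, seed=seed, n_walkers=n_walkers,
            vectorize=True, return_log_prob=True,
        )
        post = chain[n_steps // 2 :]
        rhat = split_rhat(post)
        flat = post.reshape(-1, post.shape[-1])
        lp_flat = lp_chain[n_steps // 2 :].reshape(-1)
        step = max(1, len(flat) // 1000)
        sub, lp_draws = flat[::step], lp_flat[::step]
        lml = bridge_log_marginal(
            log_post, sub, seed=seed + 1, log_post_at_draws=lp_draws, vectorize=True
        )
        results[model] = {
            "log_marginal": lml,
            "mean": float(np.median(flat[:, 0])),
            "sds": np.median(np.exp(flat[:, 1 : 1 + n_sl]), axis=0),
            "rho_within": float(np.median(np.tanh(flat[:, -2]))),
            "rho_between": float(np.median(np.tanh(flat[:, -1]))),
            "rhat_max": float(np.nanmax(rhat)),
        }
        maxll[model] = float(np.max(lp_draws))

    log_bf = results["Hlambda"]["log_marginal"] - results["Hchi"]["log_marginal"]
    log_bf_maxlik = maxll["Hlambda"] - maxll["Hchi"]
    return EvidenceSummary(
        log_bf=float(log_bf),
        log_bf_maxlik=float(log_bf_maxlik),
        favored="Hlambda" if log_bf > 0 else "Hchi",
        n_rows=data.shape[0],
        model_summaries=results,
    )
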