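"""Respondent models: utility, exact optima, and stochastic response policies.

The decision maker's utility for an allocation (ws, wt) is

    u = ws + lam * wt - kappa * |ws - wt|

where ``lam`` is the welfare tradeoff ratio toward the target and ``kappa``
in [0, 1) weights inequity aversion (the pull toward equal payoffs).  With
``kappa = 0`` this is the plain linear welfare-tradeoff utility.

On a quadratic slider the utility of position x is piecewise quadratic:
within the region where ws >= wt the vertex sits at (lam + kappa)/(1 - kappa),
within ws < wt at (lam - kappa)/(1 + kappa); the global optimum is one of
those vertices, an equal-payoff breakpoint, or a range bound.  With
kappa = 0 the optimum reduces to clip(lam, xmin, xmax) — the identity that
makes the slider a single-response measure of lam.

Two stochastic response policies are provided:

* ``"Hlambda"`` — the respondent maximizes utility and adds Gaussian noise on
  the lambda (x) scale, then the interface clips to the range;
* ``"Hchi"`` — the respondent anchors on a raw-position "kindness level"
  chi and adds Gaussian noise on the chi scale, ignoring the payoffs.

Clipped responses are flagged censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ResponseRecord
from .slider_design import (
    QuadraticSliderSpec,
    PayoffPair,
    equal_payoff_roots,
    position_from_raw,
    raw_from_position,
)
from .alt_measures import LinearItem

__all__ = [
    "Preference",
    "NoiseModel",
    "EvaluatedPosition",
    "POLICIES",
    "utility",
    "utility_at",
    "optimal_position",
    "simulate_response",
    "svo_item_response",
]

POLICIES = ("Hlambda", "Hchi")


@dataclass(frozen=True)
class Preference:
    """A respondent's disposition toward one target: (lam, kappa)."""

    lam: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa < 1.0):
            raise ValueError(f"kappa must lie in [0, 1), got {self.kappa}")
        if not np.isfinite(self.lam):
            raise ValueError("lam must be finite")


@dataclass(frozen=True)
class NoiseModel:
    """Response noise scales: sigma_e on the x scale, anchor_sd on the chi scale."""

    sigma_e: float = 0.0
    anchor_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_e < 0 or self.anchor_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


@dataclass(frozen=True)
class EvaluatedPosition:
    x: float
    u: float


def utility(pref: Preference, payoffs: PayoffPair) -> float:
    """u = ws + lam*wt - kappa*|ws - wt|."""
    return payoffs.ws + pref.lam * payoffs.wt - pref.kappa * abs(payoffs.ws - payoffs.wt)


def utility_at(spec: QuadraticSliderSpec, pref: Preference, x):
    """Vectorized utility over slider positions ``x`` (no range check)."""
    x = np.asarray(x, dtype=float)
    ws = -spec.a * x * x + spec.bs
    wt = 2.0 * spec.a * x + spec.bt
    return ws + pref.lam * wt - pref.kappa * np.abs(ws - wt)


def _clip(spec: QuadraticSliderSpec, x: float) -> float:
    return min(max(x, spec.xmin), spec.xmax)


def optimal_position(spec: QuadraticSliderSpec, pref: Preference) -> EvaluatedPosition:
    """Global maximizer of the respondent's utility over the slider range.

    Candidates are the two branch vertices (clipped), the equal-payoff
    breakpoints, and the range bounds; the true (piecewise) utility is
    evaluated at each and the best is returned.  Ties resolve to the
    smallest candidate position, which never arises for kappa = 0 where the
    result is exactly clip(lam, xmin, xmax).
    """
    lam, kap = pref.lam, pref.kappa
    candidates = {
        _clip(spec, (lam + kap) / (1.0 - kap)),
        _clip(spec, (lam - kap) / (1.0 + kap)),
        spec.xmin,
        spec.xmax,
    }
    candidates.update(equal_payoff_roots(spec))
    xs = np.array(sorted(candidates))
    us = utility_at(spec, pref, xs)
    i = int(np.argmax(us))
    return EvaluatedPosition(x=float(xs[i]), u=float(us[i]))


def simulate_response(
    spec: QuadraticSliderSpec,
    pref: Preference,
    policy: str = "Hlambda",
    anchor: float | None = None,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = None,
    participant_id: str = "p0",
    target_id: str = "t0",
    target_rank: int = 1,
    repeat_index: int = 0,
) -> ResponseRecord:
    """Draw one noisy response under the given policy.

    ``"Hlambda"``: x = clip(x* + eps), eps ~ N(0, sigma_e^2).
    ``"Hchi"``:    chi = clip(anchor + eps, 0, 1), eps ~ N(0, anchor_sd^2);
    ``anchor`` is required for this policy.  The record is flagged censored
    when the clipped value sits exactly at a bound.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if policy == "Hlambda":
        x_star = optimal_position(spec, pref).x
        x = x_star + (rng.normal(0.0, noise.sigma_e) if noise.sigma_e > 0 else 0.0)
        x = _clip(spec, x)
        chi = raw_from_position(spec, x)
    else:
        if anchor is None:
            raise ValueError("policy 'Hchi' requires an anchor raw position")
        chi = anchor + (rng.normal(0.0, noise.anchor_sd) if noise.anchor_sd > 0 else 0.0)
        chi = min(max(chi, 0.0), 1.0)
        x = position_from_raw(spec, chi)

    censored = x == spec.xmin or x == spec.xmax
    return ResponseRecord(
        participant_id=participant_id,
        target_id=target_id,
        target_rank=target_rank,
        slider_id=spec.id or "slider",
        repeat_index=repeat_index,
        raw_position=chi,
        position=x,
        censored=censored,
    )


def svo_item_response(
    item: LinearItem, pref: Preference, include_inequity: bool = False
) -> float:
    """Deterministic raw-position response on a linear (SVO-style) item.

    The linear utility is maximized at an endpoint; at exact indifference
    the midpoint 0.5 is returned (no utility gradient exists, so the
    midpoint is the unbiased convention).  By default kappa is ignored, as
    the classic analysis of these items is inequity-free; with
    ``include_inequity=True`` the full utility is used, in which case the
    interior equal-payoff kink is also a candidate.
    """
    kappa = pref.kappa if include_inequity else 0.0
    p = Preference(pref.lam, kappa)

    def u(chi: float) -> float:
        ws = item.ws0 + (item.ws1 - item.ws0) * chi
        wt = item.wt0 + (item.wt1 - item.wt0) * chi
        return ws + p.lam * wt - p.kappa * abs(ws - wt)

    candidates = [0.0, 1.0]
    if include_inequity:
        dws = item.ws1 - item.ws0
        dwt = item.wt1 - item.wt0
        gap0 = item.ws0 - item.wt0
        if dws != dwt:
            kink = -gap0 / (dws - dwt)
            if 0.0 < kink < 1.0:
                candidates.append(kink)
    us = [u(c) for c in candidates]
    best = max(us)
    winners = [c for c, v in zip(candidates, us) if v >= best - 1e-12]
    if len(winners) > 1 and 0.0 in winners and 1.0 in winners:
        return 0.5  # indifferent between the endpoints
    return min(winners)
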