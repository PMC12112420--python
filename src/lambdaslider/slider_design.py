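"""Quadratic welfare-tradeoff sliders: construction, validation and mappings.

A quadratic slider presents a continuum of payoff allocations between the
decision maker ("self") and a social partner ("target").  The payoff
functions of the slider position ``x`` are

    ws(x) = -a * x**2 + bs          (payoff to self)
    wt(x) =  2 * a * x + bt         (payoff to target)

with ``x`` restricted to ``[xmin, xmax]``.  The quadratic/linear pairing is
chosen so that a decision maker maximizing ``u = ws + lam * wt`` picks
``x* = lam`` whenever ``lam`` lies inside the slider range: the slider
position *is* the welfare tradeoff ratio.  On the (wt, ws) plane the slider
traces a strictly concave curve, the continuum limit of a multi-option
dominance task.

The on-screen control reports a raw position ``chi`` in [0, 1]; the affine
map :func:`position_from_raw` converts it to the ``x`` (lambda) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "QuadraticSliderSpec",
    "PayoffPair",
    "payoff_at",
    "position_from_raw",
    "raw_from_position",
    "equal_payoff_point",
    "equal_payoff_roots",
    "payoff_ranges",
    "validate",
    "slider_to_json",
    "slider_from_json",
    "load_slider_fixtures",
]


@dataclass(frozen=True)
class QuadraticSliderSpec:
    """Parameters of one quadratic slider.

    ``a`` scales the payoff ranges, ``bs``/``bt`` shift the self/target
    payoffs relative to one another, and ``[xmin, xmax]`` is the measurable
    lambda range.  ``display_min``/``display_max`` bound the payoff display
    (an arbitrary unit, conventionally 0..100); containment is a
    warning-level check performed by :func:`validate`, not a hard invariant.
    """

    a: float
    bs: float
    bt: float
    xmin: float
    xmax: float
    display_min: float = 0.0
    display_max: float = 100.0
    id: Optional[str] = None

    @property
    def width(self) -> float:
        return self.xmax - self.xmin


@dataclass(frozen=True)
class PayoffPair:
    """A (self, target) payoff allocation in display units."""

    ws: float
    wt: float


def _require_usable(spec: QuadraticSliderSpec) -> None:
    if not (spec.a > 0):
        raise ValueError("slider scale parameter a must be positive")
    if not (spec.xmin < spec.xmax):
        raise ValueError("slider range must satisfy xmin < xmax")


def payoff_at(spec: QuadraticSliderSpec, x: float) -> PayoffPair:
    """Payoffs at slider position ``x`` (lambda scale).

    Raises ``ValueError`` if ``x`` is outside ``[xmin, xmax]``.
    """
    _require_usable(spec)
    if not (spec.xmin <= x <= spec.xmax):
        raise ValueError(f"position {x} outside slider range [{spec.xmin}, {spec.xmax}]")
    return PayoffPair(ws=-spec.a * x * x + spec.bs, wt=2.0 * spec.a * x + spec.bt)


def position_from_raw(spec: QuadraticSliderSpec, chi: float) -> float:
    """Map a raw on-screen position ``chi`` in [0, 1] to the lambda scale.

    ``x = (1 - chi) * xmin + chi * xmax``; exact inverse of
    :func:`raw_from_position`.
    """
    _require_usable(spec)
    if not (0.0 <= chi <= 1.0):
        raise ValueError(f"raw position {chi} outside [0, 1]")
    return (1.0 - chi) * spec.xmin + chi * spec.xmax


def raw_from_position(spec: QuadraticSliderSpec, x: float) -> float:
    """Inverse of :func:`position_from_raw`."""
    _require_usable(spec)
    if not (spec.xmin <= x <= spec.xmax):
        raise ValueError(f"position {x} outside slider range [{spec.xmin}, {spec.xmax}]")
    return (x - spec.xmin) / spec.width


def equal_payoff_roots(spec: QuadraticSliderSpec) -> tuple[float, ...]:
    """All in-range solutions of ``ws(x) == wt(x)``, ascending.

    Solves ``-a x^2 + bs = 2 a x + bt``, i.e. ``x^2 + 2 x + (bt - bs)/a = 0``.
    """
    _require_usable(spec)
    disc = 1.0 - (spec.bt - spec.bs) / spec.a
    if disc < 0.0:
        return ()
    r = float(np.sqrt(disc))
    roots = sorted({-1.0 - r, -1.0 + r})
    return tuple(x for x in roots if spec.xmin <= x <= spec.xmax)


def equal_payoff_point(spec: QuadraticSliderSpec) -> Optional[float]:
    """The in-range position where self and target payoffs are equal.

    Returns ``None`` when no equal-payoff position exists inside the range
    (e.g. sliders engineered so one party is always better off).  If the
    parabola/line intersection has two in-range roots, the larger is
    returned; both are available from :func:`equal_payoff_roots`.
    """
    roots = equal_payoff_roots(spec)
    if not roots:
        return None
    return roots[-1]


def payoff_ranges(spec: QuadraticSliderSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exact (min, max) of the self and target payoffs over the range.

    ``ws`` is concave with vertex at x=0, so its max is at 0 when 0 is in
    range, otherwise at the bound nearest 0; its min is at an endpoint.
    ``wt`` is linear, so both extrema are at endpoints.
    """
    _require_usable(spec)
    ws_lo = payoff_at(spec, spec.xmin).ws
    ws_hi = payoff_at(spec, spec.xmax).ws
    ws_min = min(ws_lo, ws_hi)
    if spec.xmin <= 0.0 <= spec.xmax:
        ws_max = spec.bs
    else:
        ws_max = max(ws_lo, ws_hi)
    wt_a = payoff_at(spec, spec.xmin).wt
    wt_b = payoff_at(spec, spec.xmax).wt
    return (ws_min, ws_max), (min(wt_a, wt_b), max(wt_a, wt_b))


def validate(spec: QuadraticSliderSpec) -> list[str]:
    """Check the spec's invariants; return a list of human-readable violations.

    An empty list means the spec is valid.  Display-bound containment is
    included (payoffs straying outside [display_min, display_max] cannot be
    rendered faithfully), but callers may treat it as a warning.
    """
    violations: list[str] = []
    if not (spec.a > 0):
        violations.append("a must be positive")
    if not (spec.xmin < spec.xmax):
        violations.append("xmin must be strictly less than xmax")
    if violations:
        return violations  # ranges below would be meaningless
    (ws_min, ws_max), (wt_min, wt_max) = payoff_ranges(spec)
    if ws_min < spec.display_min or ws_max > spec.display_max:
        violations.append(
            f"self payoff range [{ws_min:g}, {ws_max:g}] exceeds display bounds "
            f"[{spec.display_min:g}, {spec.display_max:g}]"
        )
    if wt_min < spec.display_min or wt_max > spec.display_max:
        violations.append(
            f"target payoff range [{wt_min:g}, {wt_max:g}] exceeds display bounds "
            f"[{spec.display_min:g}, {spec.display_max:g}]"
        )
    return violations


# --- serialization -----------------------------------------------------------

def slider_to_json(spec: QuadraticSliderSpec) -> dict:
    d = asdict(spec)
    if d.get("id") is None:
        d.pop("id")
    return d


def slider_from_json(obj: dict) -> QuadraticSliderSpec:
    known = {f for f in QuadraticSliderSpec.__dataclass_fields__}
    extra = set(obj) - known
    if extra:
        raise ValueError(f"unknown slider fields: {sorted(extra)}")
    return QuadraticSliderSpec(**obj)


def load_slider_fixtures() -> dict[str, QuadraticSliderSpec]:
    """Shipped slider configurations keyed by id.

    ``standard``: the a=11.25 reference slider (ws in [25,70], wt in [5,95]).
    ``shifted_positive``/``shifted_negative``: same width, ranges shifted by
    ±0.75 on the lambda scale, used to separate utility-based responding from
    raw-position anchoring.  ``balanced``/``self_more``/``target_more``: the
    a=7 set for joint lambda/kappa estimation, with shift parameters chosen
    so the self-more slider keeps ws > wt and the target-more slider ws < wt
    over the whole range.
    """
    text = resources.files("lambdaslider.fixtures").joinpath("sliders.json").read_text()
    raw = json.loads(text)
    return {obj["id"]: slider_from_json(obj) for obj in raw}
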