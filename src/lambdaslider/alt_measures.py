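"""Comparator measures: binary allocation tasks, dominance tasks, and the
SVO Slider Measure.

A binary allocation task reveals only whether the welfare tradeoff ratio lam
is above or below one threshold; a k-option dominance task packs k-1 such
thresholds into a single response, provided the options lie on a strictly
concave self-payoff-vs-target-payoff curve so that every option is optimal
for some lam.  The SVO Slider Measure is six linear sliders whose mean
chosen payoffs are summarized as an angle; because each linear slider is
effectively a binary task, the angle is a step function of lam.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "AllocationOption",
    "DominanceValidation",
    "LinearItem",
    "SvoMeasureSpec",
    "SvoScore",
    "binary_threshold",
    "dominance_validate",
    "binary_tasks_required",
    "item_threshold",
    "svo_angle",
    "theoretical_svo_of_lambda",
    "load_svo_measure",
]


@dataclass(frozen=True)
class AllocationOption:
    """One discrete payoff option (self, target)."""

    ws: float
    wt: float


class DominanceValidation(NamedTuple):
    valid: bool
    thresholds: tuple[float, ...]
    reason: Optional[str] = None


@dataclass(frozen=True)
class LinearItem:
    """A linear slider item: payoffs interpolate endpoints at raw positions 0 and 1."""

    ws0: float
    wt0: float
    ws1: float
    wt1: float
    id: Optional[str] = None


@dataclass(frozen=True)
class SvoMeasureSpec:
    items: tuple[LinearItem, ...]


@dataclass(frozen=True)
class SvoScore:
    mean_ws: float
    mean_wt: float
    angle: float  # degrees in (-90, 90)


def binary_threshold(a: AllocationOption, b: AllocationOption) -> float:
    """Threshold lam at which preference between two options flips.

    lam_hat = (wsA - wsB) / (wtB - wtA); the option richer for the target is
    preferred above the threshold.  Undefined when the target payoffs are
    equal (the choice is then payoff dominance for self, not a tradeoff).
    """
    if a.wt == b.wt:
        raise ValueError("threshold undefined: options give the target equal payoffs")
    return (a.ws - b.ws) / (b.wt - a.wt)


def dominance_validate(options: Sequence[AllocationOption]) -> DominanceValidation:
    """Check that every option is utility-maximal for some lam.

    Options are sorted by target payoff; the task is a valid dominance task
    iff consecutive switch thresholds are strictly increasing along that
    order, which is equivalent to the options lying on a strictly concave
    ws = f(wt) curve.  Returns the per-boundary thresholds (empty on
    failure).
    """
    if len(options) < 2:
        raise ValueError("a dominance task needs at least 2 options")
    if len({(o.ws, o.wt) for o in options}) < len(options):
        return DominanceValidation(False, (), "duplicate options")
    ordered = sorted(options, key=lambda o: (o.wt, o.ws))
    if any(ordered[i].wt == ordered[i + 1].wt for i in range(len(ordered) - 1)):
        return DominanceValidation(False, (), "two options give the target equal payoffs")
    thresholds = tuple(
        binary_threshold(ordered[i], ordered[i + 1]) for i in range(len(ordered) - 1)
    )
    for i in range(len(thresholds) - 1):
        if not (thresholds[i] < thresholds[i + 1]):
            return DominanceValidation(
                False,
                thresholds,
                f"option {i + 1} (wt-order) is never dominant: "
                "options do not lie on a strictly concave ws = f(wt) curve",
            )
    return DominanceValidation(True, thresholds, None)


def binary_tasks_required(lo: float, hi: float, precision: float) -> int:
    """Number of binary tasks needed to localize lam in (lo, hi) to ``precision``.

    Thresholds are spaced ``precision`` apart strictly inside the interval:
    ceil((hi - lo)/precision) - 1 (with the exact-division convention).
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    if hi <= lo:
        raise ValueError("need hi > lo")
    if precision > hi - lo:
        raise ValueError("precision cannot exceed the interval width")
    k = (hi - lo) / precision
    k_round = round(k)
    if math.isclose(k, k_round, rel_tol=1e-9, abs_tol=1e-9):
        return int(k_round) - 1
    return math.ceil(k) - 1


def item_threshold(item: LinearItem) -> float:
    """Switch threshold of a linear item: lam_hat = -(dws)/(dwt).

    The endpoint preference flips across the threshold; undefined when the
    target payoff does not vary along the item.
    """
    dwt = item.wt1 - item.wt0
    if dwt == 0:
        raise ValueError("threshold undefined: target payoff constant along the item")
    return -(item.ws1 - item.ws0) / dwt + 0.0  # normalize -0.0


def svo_angle(responses: Sequence) -> SvoScore:
    """Angle summary of chosen payoffs: arctan((mean_wt - 50)/(mean_ws - 50)).

    ``responses`` are the chosen (ws, wt) payoff pairs, one per item of the
    measure.  The angle is reported in degrees using the plain arctangent
    (range (-90, 90), no quadrant unwrapping); it is undefined when both
    means equal the 50-unit origin.
    """
    pairs = [(float(r[0]), float(r[1])) if isinstance(r, (tuple, list)) else (r.ws, r.wt) for r in responses]
    if len(pairs) == 0:
        raise ValueError("no responses")
    mean_ws = sum(p[0] for p in pairs) / len(pairs)
    mean_wt = sum(p[1] for p in pairs) / len(pairs)
    if mean_ws == 50.0 and mean_wt == 50.0:
        raise ValueError("angle undefined: mean payoffs sit at the (50, 50) origin")
    angle = math.degrees(math.atan2(mean_wt - 50.0, mean_ws - 50.0))
    if angle > 90.0:  # keep the conventional (-90, 90) branch for ws < 50
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return SvoScore(mean_ws=mean_ws, mean_wt=mean_wt, angle=angle)


def _item_payoff(item: LinearItem, chi: float) -> tuple[float, float]:
    return (
        item.ws0 + (item.ws1 - item.ws0) * chi,
        item.wt0 + (item.wt1 - item.wt0) * chi,
    )


def theoretical_svo_of_lambda(measure: SvoMeasureSpec, lam: float) -> float:
    """Angle a noiseless utility maximizer with ratio ``lam`` would score.

    Each item is answered at the endpoint favored by u = ws + lam*wt (the
    endpoint richer for the target above the item threshold); at exact
    indifference the midpoint payoffs are used.  The result is a
    nondecreasing right-continuous step function of lam with one jump per
    distinct item threshold.
    """
    chosen = []
    for item in measure.items:
        u0 = item.ws0 + lam * item.wt0
        u1 = item.ws1 + lam * item.wt1
        if math.isclose(u0, u1, rel_tol=0.0, abs_tol=1e-12):
            chosen.append(_item_payoff(item, 0.5))
        elif u1 > u0:
            chosen.append(_item_payoff(item, 1.0))
        else:
            chosen.append(_item_payoff(item, 0.0))
    return svo_angle(chosen).angle


def load_svo_measure() -> SvoMeasureSpec:
    """The six primary linear items of the published SVO Slider Measure.

    Only the first item's payoff functions are re-derived here from first
    principles; the remaining endpoints are the canonical published values,
    shipped as an editable JSON fixture.
    """
    text = resources.files("lambdaslider.fixtures").joinpath("svo_items.json").read_text()
    raw = json.loads(text)
    items = tuple(LinearItem(**obj) for obj in raw["items"])
    return SvoMeasureSpec(items=items)
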