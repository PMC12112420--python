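"""Synthetic participant-target panels with the statistical structure of the
slider studies, so every estimator is testable without human data.

A panel draws, per participant-target pair, a welfare tradeoff ratio

    lam_pt = rank_mean[rank(t)] + participant effect + target deviation

with the rank means declining with social distance (rank 1 = socially
closest), a per-participant inequity-aversion weight kappa drawn from a
mixture of a near-zero point mass and a broad component, and then simulates
noisy slider responses (repeats per slider) under either response policy.
A dictator-style donation decision (split a small endowment between a
bonus to self and a donation) provides an external-validity outcome.

Default configurations mirror the three study shapes:

* ``reliability_panel_config`` — 30 participants x 10 ranked targets, one
  standard slider, two repeats; noise calibrated so the single-response
  test-retest correlation is about 0.86.
* ``range_shift_panel_config`` — 16 x 10 on three range-shifted sliders,
  either response policy; raw-position noise 0.05.
* ``inequity_panel_config`` — 76 x 6 on the balanced/self-more/target-more
  slider set (a = 7), for joint lambda/kappa estimation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import records_to_frame
from .respondent import NoiseModel, Preference, simulate_response
from .slider_design import QuadraticSliderSpec, load_slider_fixtures, slider_to_json

__all__ = [
    "KappaMixture",
    "PanelConfig",
    "PanelResult",
    "DonationRecord",
    "generate_panel",
    "generate_donation",
    "write_fixture_suite",
    "reliability_panel_config",
    "range_shift_panel_config",
    "inequity_panel_config",
]


@dataclass(frozen=True)
class KappaMixture:
    """Mixture prior for inequity aversion: a point mass near zero plus a
    broad uniform component on (low, high) — many respondents barely weight
    inequity while others weight it heavily."""

    point_weight: float = 0.4
    point_value: float = 0.0
    low: float = 0.05
    high: float = 0.95

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        at_point = rng.random(size) < self.point_weight
        broad = rng.uniform(self.low, self.high, size)
        return np.where(at_point, self.point_value, broad)


@dataclass(frozen=True)
class PanelConfig:
    n_participants: int
    n_targets: int
    rank_means: tuple[float, ...]  # nonincreasing, one per rank (1 = closest)
    participant_sd: float
    target_sd: float
    kappa_distribution: KappaMixture
    noise: NoiseModel
    sliders: tuple[QuadraticSliderSpec, ...]
    repeats: int = 2
    policy: str = "Hlambda"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_targets < 1 or self.repeats < 1:
            raise ValueError("counts must be positive")
        if len(self.rank_means) != self.n_targets:
            raise ValueError("rank_means must have one entry per target rank")
        diffs = np.diff(self.rank_means)
        if np.any(diffs > 1e-12):
            raise ValueError("rank_means must be nonincreasing (rank 1 = socially closest)")


@dataclass
class PanelResult:
    responses: pd.DataFrame
    truth: pd.DataFrame  # participant_id, target_id, target_rank, lam, kappa
    config: PanelConfig


def _default_sliders(names: Sequence[str]) -> tuple[QuadraticSliderSpec, ...]:
    fixtures = load_slider_fixtures()
    return tuple(fixtures[n] for n in names)


def reliability_panel_config(seed: int = 0, policy: str = "Hlambda") -> PanelConfig:
    # rank means decline linearly from +0.86 (closest) to -0.86 (most
    # distant); with participant sd 0.7 and target sd 0.5 the true-score
    # variance ~1.04, so response noise sd 0.42 gives test-retest rho ~0.86.
    means = tuple(np.linspace(0.86, -0.86, 10))
    return PanelConfig(
        n_participants=30,
        n_targets=10,
        rank_means=means,
        participant_sd=0.7,
        target_sd=0.5,
        kappa_distribution=KappaMixture(point_weight=1.0),  # kappa = 0 here
        noise=NoiseModel(sigma_e=0.42),
        sliders=_default_sliders(["standard"]),
        repeats=2,
        policy=policy,
        seed=seed,
    )


def range_shift_panel_config(seed: int = 0, policy: str = "Hlambda") -> PanelConfig:
    means = tuple(np.linspace(0.86, -0.86, 10))
    return PanelConfig(
        n_participants=16,
        n_targets=10,
        rank_means=means,
        participant_sd=0.7,
        target_sd=0.5,
        kappa_distribution=KappaMixture(point_weight=1.0),
        noise=NoiseModel(sigma_e=0.2, anchor_sd=0.05),  # 0.05 on the raw scale
        sliders=_default_sliders(["standard", "shifted_positive", "shifted_negative"]),
        repeats=2,
        policy=policy,
        seed=seed,
    )


def inequity_panel_config(seed: int = 0, noise_sd: float = 0.3) -> PanelConfig:
    means = tuple(np.linspace(1.0, -0.6, 6))
    return PanelConfig(
        n_participants=76,
        n_targets=6,
        rank_means=means,
        participant_sd=0.6,
        target_sd=0.4,
        kappa_distribution=KappaMixture(),
        noise=NoiseModel(sigma_e=noise_sd),
        sliders=_default_sliders(["balanced", "self_more", "target_more"]),
        repeats=2,
        policy="Hlambda",
        seed=seed,
    )


def generate_panel(config: PanelConfig) -> PanelResult:
    """Simulate a full response panel; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    rank_means = np.asarray(config.rank_means)
    kappas = config.kappa_distribution.sample(rng, config.n_participants)
    base = config.sliders[0]
    records = []
    truth_rows = []
    for p in range(config.n_participants):
        pid = f"p{p:03d}"
        p_eff = rng.normal(0.0, config.participant_sd)
        for t in range(config.n_targets):
            rank = t + 1
            lam = rank_means[t] + p_eff + rng.normal(0.0, config.target_sd)
            tid = f"{pid}_t{rank:02d}"
            pref = Preference(lam=lam, kappa=float(kappas[p]))
            truth_rows.append(
                {
                    "participant_id": pid,
                    "target_id": tid,
                    "target_rank": rank,
                    "lam": lam,
                    "kappa": float(kappas[p]),
                }
            )
            # under raw-position anchoring the anchor is the kindness level
            # the base slider would elicit for this lambda
            anchor = float(np.clip((lam - base.xmin) / base.width, 0.0, 1.0))
            for spec in config.sliders:
                for rep in range(config.repeats):
                    records.append(
                        simulate_response(
                            spec,
                            pref,
                            policy=config.policy,
                            anchor=anchor,
                            noise=config.noise,
                            rng=rng,
                            participant_id=pid,
                            target_id=tid,
                            target_rank=rank,
                            repeat_index=rep,
                        )
                    )
    return PanelResult(
        responses=records_to_frame(records),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


@dataclass(frozen=True)
class DonationRecord:
    """A dictator-style split of a 2-unit endowment: donation d, bonus 2 - d."""

    participant_id: str
    donation: float
    bonus: float


def generate_donation(
    pref: Preference,
    noise_sd: float = 0.15,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "p0",
    endowment: float = 2.0,
) -> DonationRecord:
    """Simulate the donation decision d in [0, endowment].

    The deterministic optimum of u(d) = (endowment - d) + lam*d
    - kappa*|endowment - 2d| is piecewise linear, so it sits at d = 0, the
    equal split, or d = endowment (ties resolve to the smallest donation);
    truncated Gaussian noise is added on top.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    half = endowment / 2.0
    candidates = np.array([0.0, half, endowment])
    u = (endowment - candidates) + pref.lam * candidates - pref.kappa * np.abs(
        endowment - 2.0 * candidates
    )
    d_star = float(candidates[int(np.argmax(u))])
    if noise_sd > 0:
        from scipy.stats import truncnorm

        a, b = (0.0 - d_star) / noise_sd, (endowment - d_star) / noise_sd
        d = float(truncnorm.rvs(a, b, loc=d_star, scale=noise_sd, random_state=rng))
    else:
        d = d_star
    return DonationRecord(participant_id=participant_id, donation=d, bonus=endowment - d)


def write_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write seeded CSV/JSON fixtures for the three panel shapes plus the
    slider and measure configurations; returns a manifest (also written as
    JSON) listing files, seeds and content hashes.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    sliders = load_slider_fixtures()
    sliders_path = out / "sliders.json"
    sliders_path.write_text(
        json.dumps([slider_to_json(s) for s in sliders.values()], indent=1) + "\n"
    )
    files["sliders.json"] = sliders_path

    from .alt_measures import load_svo_measure

    measure = load_svo_measure()
    svo_path = out / "svo_items.json"
    svo_path.write_text(
        json.dumps([item.__dict__ for item in measure.items], indent=1) + "\n"
    )
    files["svo_items.json"] = svo_path

    configs = {
        "panel_reliability": reliability_panel_config(seed=seed),
        "panel_range_shift": range_shift_panel_config(seed=seed + 1),
        "panel_inequity": inequity_panel_config(seed=seed + 2),
    }
    rng = np.random.default_rng(seed + 3)
    for name, cfg in configs.items():
        panel = generate_panel(cfg)
        rpath = out / f"{name}_responses.csv"
        tpath = out / f"{name}_truth.csv"
        panel.responses.to_csv(rpath, index=False)
        panel.truth.to_csv(tpath, index=False)
        files[rpath.name] = rpath
        files[tpath.name] = tpath

    inequity = generate_panel(configs["panel_inequity"])
    donations = [
        generate_donation(
            Preference(lam=row.lam, kappa=row.kappa), rng=rng, participant_id=row.participant_id
        )
        for row in inequity.truth.drop_duplicates("participant_id").itertuples()
    ]
    dpath = out / "donations.csv"
    pd.DataFrame([d.__dict__ for d in donations]).to_csv(dpath, index=False)
    files[dpath.name] = dpath

    manifest = {
        "seed": seed,
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest() for name, path in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
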