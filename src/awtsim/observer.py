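"""Parametric synthetic observers for the Attention-Window Task.

Two generative models turn planned trials into responses with the
statistical structure the downstream analysis assumes:

``attention_field``
    A single elliptic attention field. The probability of correctly
    reporting the triangle count of one stimulus group falls off with
    stimulus separation ``s`` as a logistic with a guessing floor,

        q(s) = γ + (1 − γ) / (1 + exp((s − E*) / τ)),

    where ``E*`` is the effective field extent along the trial's meridian
    class and ``τ`` the logistic scale. ``E*`` shrinks multiplicatively on
    invalid-cue trials (κ_inv), at short cue–target intervals (a linear SOA
    ramp saturating at ``T_full``) and under high stimulus complexity
    (ρ_c). The two stimulus groups are identified independently, so the
    pair-correct probability is q².

``spotlight_shift``
    A narrow movable beam: the first stimulus group is processed with
    probability q(s); the beam then needs ``a + b·s`` ms to shift, and if
    that exceeds the target exposure the second group is reduced to the
    guessing floor γ. This mechanism reproduces the qualitative short-SOA
    penalty without a graded field change.

``q`` is the *unconditional* per-stimulus correct-report probability: the
simulator reports the true count with identification probability
``(5q − 1)/4`` (clamped at 0) and otherwise guesses uniformly from the
five count responses, so that the realised correct rate is exactly q and
the floor q = γ = 1/5 corresponds to pure uniform guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    MERIDIAN_CLASSES,
    DesignConfig,
    TrialSpec,
    generate_session,
    session_to_frame,
)

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "identification_probability",
    "pair_correct_probability",
    "analytic_threshold",
    "simulate_response",
    "simulate_session_frame",
    "simulate_cohort",
]

RESPONSE_ALPHABET = (0, 1, 2, 3, 4)

MODELS = ("attention_field", "spotlight_shift")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic participant.

    Extents are the separations (deg visual angle) at which the per-stimulus
    report probability is halfway between the guessing floor and ceiling,
    under valid cues, long SOA and basic complexity. The two diagonal
    meridians share a single extent (the analysis pools them).
    """

    extent_horizontal_deg: float = 42.0
    extent_vertical_deg: float = 32.0
    extent_diagonal_deg: float = 34.0
    slope_deg: float = 3.0
    guess_rate: float = 0.2
    validity_factor: float = 0.88
    soa_full_ms: float = 200.0
    soa_floor_fraction: float = 0.62
    complexity_factor: float = 0.75
    model: str = "attention_field"
    shift_base_ms: float = 50.0
    shift_cost_ms_per_deg: float = 10.0
    target_duration_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.slope_deg <= 0:
            raise ValueError("slope_deg must be > 0")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError("guess_rate must lie in [0, 1]")
        for name in ("validity_factor", "complexity_factor", "soa_floor_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if min(self.extent_horizontal_deg, self.extent_vertical_deg, self.extent_diagonal_deg) < 0:
            raise ValueError("extents must be non-negative")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.soa_full_ms <= 0:
            raise ValueError("soa_full_ms must be > 0")

    def extent_for(self, meridian_class: str) -> float:
        return {
            "horizontal": self.extent_horizontal_deg,
            "vertical": self.extent_vertical_deg,
            "diagonal": self.extent_diagonal_deg,
        }[meridian_class]

    def soa_gain(self, soa_ms) -> np.ndarray | float:
        """Extent multiplier g(SOA): linear ramp saturating at 1 for SOA ≥ T_full."""
        f = self.soa_floor_fraction
        return np.minimum(1.0, f + (1.0 - f) * np.asarray(soa_ms, dtype=float) / self.soa_full_ms)

    def replace(self, **changes) -> "ObserverParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class TrialRecord:
    """A planned trial plus the observer's report."""

    spec: TrialSpec
    reported_count_a: int
    reported_count_b: int

    @property
    def correct(self) -> bool:
        return (
            self.reported_count_a == self.spec.stimulus_a.target_count
            and self.reported_count_b == self.spec.stimulus_b.target_count
        )


def effective_extent(
    params: ObserverParams,
    meridian_class,
    cue_validity,
    soa_ms,
    complexity,
) -> np.ndarray | float:
    """E* = E_m · κ_inv^[invalid] · g(SOA) · ρ_c^[high6] (vectorised)."""
    mc = np.asarray(meridian_class)
    extent = np.select(
        [mc == "horizontal", mc == "vertical"],
        [params.extent_horizontal_deg, params.extent_vertical_deg],
        default=params.extent_diagonal_deg,
    )
    invalid = np.asarray(cue_validity) == "invalid"
    high = np.asarray(complexity) == "high6"
    out = (
        extent
        * np.where(invalid, params.validity_factor, 1.0)
        * params.soa_gain(soa_ms)
        * np.where(high, params.complexity_factor, 1.0)
    )
    return out if out.shape else float(out)


def _q_from_extent(params: ObserverParams, separation_deg, extent) -> np.ndarray | float:
    g = params.guess_rate
    z = (np.asarray(separation_deg, float) - np.asarray(extent, float)) / params.slope_deg
    lam = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))  # clip: exp overflow guard
    out = g + (1.0 - g) * lam
    return out if out.shape else float(out)


def identification_probability(params: ObserverParams, trial: TrialSpec) -> float:
    """Per-stimulus correct-report probability q ∈ [γ, 1] (deterministic)."""
    e = effective_extent(
        params, trial.meridian_class, trial.cue_validity, trial.soa_ms, trial.complexity
    )
    return float(_q_from_extent(params, trial.separation_deg, e))


def _spotlight_second_q(params: ObserverParams, separation_deg, q) -> np.ndarray | float:
    """Second-stimulus report probability under the shifting-beam time budget."""
    shift = params.shift_base_ms + params.shift_cost_ms_per_deg * np.asarray(separation_deg, float)
    reached = shift < params.target_duration_ms
    out = np.where(reached, q, params.guess_rate)
    return out if out.shape else float(out)


def stimulus_probabilities(
    params: ObserverParams, separation_deg, meridian_class, cue_validity, soa_ms, complexity
):
    """(q_a, q_b) per-stimulus report probabilities, vectorised over trials."""
    e = effective_extent(params, meridian_class, cue_validity, soa_ms, complexity)
    q = _q_from_extent(params, separation_deg, e)
    if params.model == "attention_field":
        return q, q
    return q, _spotlight_second_q(params, separation_deg, q)


def pair_correct_probability(params: ObserverParams, trial: TrialSpec) -> float:
    """Probability the reported count is right for both stimulus groups."""
    qa, qb = stimulus_probabilities(
        params,
        trial.separation_deg,
        trial.meridian_class,
        trial.cue_validity,
        trial.soa_ms,
        trial.complexity,
    )
    return float(qa * qb)


def cell_pair_probability(
    params: ObserverParams,
    separations_deg,
    meridian_class: str,
    cue_validity: str = "valid",
    soa_ms: float = 200.0,
    complexity: str = "basic4",
) -> np.ndarray:
    """Pair-correct probability on a separation grid for one design cell."""
    s = np.asarray(separations_deg, dtype=float)
    qa, qb = stimulus_probabilities(
        params,
        s,
        np.full(s.shape, meridian_class, dtype=object),
        np.full(s.shape, cue_validity, dtype=object),
        np.full(s.shape, soa_ms),
        np.full(s.shape, complexity, dtype=object),
    )
    return np.asarray(qa * qb, dtype=float)


def analytic_threshold(
    params: ObserverParams,
    meridian_class: str,
    criterion: float = 0.75,
    cue_validity: str = "valid",
    soa_ms: float = 200.0,
    complexity: str = "basic4",
) -> float:
    """Separation s* at which the pair-correct probability equals ``criterion``.

    For the attention-field model P(s) = q(s)², so with q* = √criterion and
    Λ* = (q* − γ)/(1 − γ),

        s* = E* + τ · ln((1 − Λ*) / Λ*),

    which lies below the midpoint E* whenever the criterion exceeds the
    midpoint accuracy ((1+γ)/2)².
    """
    if params.model != "attention_field":
        raise ValueError("closed-form threshold exists for the attention_field model only")
    if not params.guess_rate**2 < criterion < 1.0:
        raise ValueError("criterion must lie between the guessing floor γ² and 1")
    g = params.guess_rate
    q_star = math.sqrt(criterion)
    lam_star = (q_star - g) / (1.0 - g)
    e = effective_extent(params, meridian_class, cue_validity, soa_ms, complexity)
    return float(e + params.slope_deg * math.log((1.0 - lam_star) / lam_star))


def _report_counts(
    q: np.ndarray, true_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reported counts: true count w.p. (5q−1)/4, else uniform over {0..4}."""
    q = np.asarray(q, dtype=float)
    p_id = np.clip((5.0 * q - 1.0) / 4.0, 0.0, 1.0)
    identified = rng.random(true_counts.shape) < p_id
    guesses = rng.integers(0, 5, size=true_counts.shape)
    return np.where(identified, true_counts, guesses)


def simulate_response(
    params: ObserverParams, trial: TrialSpec, rng: np.random.Generator
) -> TrialRecord:
    """Simulate one trial; reproducible given the generator state."""
    qa, qb = stimulus_probabilities(
        params,
        trial.separation_deg,
        trial.meridian_class,
        trial.cue_validity,
        trial.soa_ms,
        trial.complexity,
    )
    true = np.array([trial.stimulus_a.target_count, trial.stimulus_b.target_count])
    rep = _report_counts(np.array([qa, qb]), true, rng)
    return TrialRecord(trial, int(rep[0]), int(rep[1]))


def simulate_session_frame(
    params: ObserverParams, frame: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorised responses for a session table (adds report and correctness columns)."""
    qa, qb = stimulus_probabilities(
        params,
        frame["separation_deg"].to_numpy(),
        frame["meridian_class"].to_numpy(),
        frame["cue_validity"].to_numpy(),
        frame["soa_ms"].to_numpy(),
        frame["complexity"].to_numpy(),
    )
    out = frame.copy()
    true_a = frame["target_count_a"].to_numpy()
    true_b = frame["target_count_b"].to_numpy()
    rep_a = _report_counts(qa, true_a, rng)
    rep_b = _report_counts(qb, true_b, rng)
    out["reported_count_a"] = rep_a
    out["reported_count_b"] = rep_b
    out["correct"] = (rep_a == true_a) & (rep_b == true_b)
    return out


def simulate_cohort(
    observers: Sequence[tuple[str, ObserverParams]] | Mapping[str, ObserverParams],
    config: DesignConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate a cohort: one independent session and noise stream per observer.

    Returns a long-format trial-record table with a ``subject`` column;
    deterministic for a given (observers, config, seed).
    """
    if isinstance(observers, Mapping):
        pairs = list(observers.items())
    else:
        pairs = list(observers)
    ids = [sid for sid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject identifiers")
    if not pairs:
        raise ValueError("at least one observer required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    frames = []
    for (sid, params), child in zip(pairs, children):
        design_seed, noise_seed = child.spawn(2)
        trials = generate_session(config, design_seed)
        frame = session_to_frame(trials)
        rec = simulate_session_frame(params, frame, np.random.default_rng(noise_seed))
        rec.insert(0, "subject", sid)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)
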