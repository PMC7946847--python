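"""Trial-schedule and stimulus generation for the Attention-Window Task (AWT).

The AWT measures the maximum spread of spatial visual attention: on every
trial two four-element stimulus groups are flashed symmetrically about a
central fixation point along one of four meridians (horizontal, vertical,
and the two diagonals), at a separation drawn from a fixed grid of visual
angles. The observer reports the number of light-gray triangles in each
group. This module generates complete, balanced sessions of that task —
the basic version (all pre-cues valid) and the modified variants that
manipulate cue validity, cue–target interval (SOA) and stimulus
complexity.

A session is stratified: every (meridian, separation) cell occurs exactly
``reps_per_cell`` times; randomisation affects trial order, cue-validity
draws, invalid-cue placement and stimulus contents only. Under the default
grid (10°–45° in 5° steps, four meridians, 9 repetitions) a session has
288 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "DesignConfig",
    "StimulusGroup",
    "TrialSpec",
    "MERIDIANS",
    "MERIDIAN_ANGLES_DEG",
    "MERIDIAN_CLASSES",
    "DEFAULT_SEPARATIONS_DEG",
    "TARGET_ELEMENT",
    "element_alphabet",
    "generate_stimulus",
    "assign_invalid_cue",
    "generate_session",
    "session_to_frame",
]


class ConfigError(ValueError):
    """Raised when a design configuration is invalid or degenerate."""


#: Meridian identifiers in angular order (counterclockwise from +x axis).
MERIDIANS: tuple[str, ...] = ("horizontal", "diagonal1", "vertical", "diagonal2")

#: Axis angle of each meridian, degrees counterclockwise from horizontal.
MERIDIAN_ANGLES_DEG: dict[str, float] = {
    "horizontal": 0.0,
    "diagonal1": 45.0,
    "vertical": 90.0,
    "diagonal2": 135.0,
}

#: Analysis class of each meridian; the two diagonals are pooled.
MERIDIAN_CLASSES: dict[str, str] = {
    "horizontal": "horizontal",
    "vertical": "vertical",
    "diagonal1": "diagonal",
    "diagonal2": "diagonal",
}

DEFAULT_SEPARATIONS_DEG: tuple[float, ...] = tuple(float(s) for s in range(10, 50, 5))

DEFAULT_TIMINGS_MS: dict[str, float] = {"fixation": 1000.0, "cue": 200.0, "target": 300.0}

#: The element the observer must count: a light-gray triangle.
TARGET_ELEMENT: tuple[str, str] = ("triangle", "light")

_SHAPE_CODE = {"circle": "C", "triangle": "T", "square": "S"}
_SHADE_CODE = {"light": "l", "dark": "d"}
_CODE_SHAPE = {v: k for k, v in _SHAPE_CODE.items()}
_CODE_SHADE = {v: k for k, v in _SHADE_CODE.items()}

COMPLEXITY_LEVELS = ("basic4", "high6")


def element_alphabet(complexity: str) -> tuple[tuple[str, str], ...]:
    """Full element alphabet for a complexity level.

    ``basic4``: circles and triangles, light or dark gray (4 element types).
    ``high6``: adds light and dark squares (6 element types).
    """
    if complexity == "basic4":
        shapes = ("circle", "triangle")
    elif complexity == "high6":
        shapes = ("circle", "triangle", "square")
    else:
        raise ConfigError(f"unknown complexity level: {complexity!r}")
    return tuple((shape, shade) for shape in shapes for shade in ("light", "dark"))


def nontarget_alphabet(complexity: str) -> tuple[tuple[str, str], ...]:
    """Element types other than the light-gray triangle."""
    return tuple(e for e in element_alphabet(complexity) if e != TARGET_ELEMENT)


@dataclass(frozen=True)
class StimulusGroup:
    """One four-element stimulus group.

    Each element is a (shape, shade) pair; the task-relevant quantity is the
    number of light-gray triangles, uniform over 0–4 by design.
    """

    elements: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.elements) != 4:
            raise ValueError("a stimulus group comprises exactly 4 elements")
        for shape, shade in self.elements:
            if shape not in _SHAPE_CODE or shade not in _SHADE_CODE:
                raise ValueError(f"unknown element: {(shape, shade)!r}")

    @property
    def target_count(self) -> int:
        return sum(1 for e in self.elements if e == TARGET_ELEMENT)

    def to_code(self) -> str:
        """Compact serialisation, e.g. ``"Tl,Cd,Cl,Td"``."""
        return ",".join(_SHAPE_CODE[s] + _SHADE_CODE[g] for s, g in self.elements)

    @classmethod
    def from_code(cls, code: str) -> "StimulusGroup":
        try:
            elements = tuple(
                (_CODE_SHAPE[tok[0]], _CODE_SHADE[tok[1]])
                for tok in code.split(",")
            )
        except (KeyError, IndexError) as exc:
            raise ValueError(f"malformed stimulus code: {code!r}") from exc
        return cls(elements)


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of one AWT session.

    Parameters
    ----------
    separations_deg
        Stimulus separations in degrees of visual angle, strictly increasing.
    meridians
        Meridians used; default all four.
    reps_per_cell
        Trials per (meridian, separation) cell.
    cue_valid_fraction
        Probability that a trial's pre-cues mark the target locations
        (1.0 = basic task, 0.8 = modified task).
    soa_ms
        Blank interval between cue offset and target onset. The onset-to-onset
        asynchrony is ``soa_ms + timings_ms['cue']`` (see
        :attr:`cue_onset_asynchrony_ms`).
    complexity
        ``basic4`` (circles/triangles) or ``high6`` (adds squares).
    """

    separations_deg: tuple[float, ...] = DEFAULT_SEPARATIONS_DEG
    meridians: tuple[str, ...] = MERIDIANS
    reps_per_cell: int = 9
    cue_valid_fraction: float = 1.0
    soa_ms: float = 200.0
    complexity: str = "basic4"
    timings_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMINGS_MS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "separations_deg", tuple(float(s) for s in self.separations_deg))
        object.__setattr__(self, "meridians", tuple(self.meridians))
        if not self.separations_deg:
            raise ConfigError("separations_deg must be non-empty")
        if any(s <= 0 for s in self.separations_deg):
            raise ConfigError("separations must be positive")
        if any(b <= a for a, b in zip(self.separations_deg, self.separations_deg[1:])):
            raise ConfigError("separations must be strictly increasing")
        if not self.meridians:
            raise ConfigError("meridians must be non-empty")
        unknown = set(self.meridians) - set(MERIDIANS)
        if unknown:
            raise ConfigError(f"unknown meridians: {sorted(unknown)}")
        if len(set(self.meridians)) != len(self.meridians):
            raise ConfigError("duplicate meridians")
        if self.reps_per_cell < 1:
            raise ConfigError("reps_per_cell must be a positive integer")
        if not 0.0 <= self.cue_valid_fraction <= 1.0:
            raise ConfigError("cue_valid_fraction must lie in [0, 1]")
        if self.soa_ms < 0:
            raise ConfigError("soa_ms must be non-negative")
        if self.complexity not in COMPLEXITY_LEVELS:
            raise ConfigError(f"complexity must be one of {COMPLEXITY_LEVELS}")

    @property
    def n_trials_per_session(self) -> int:
        return len(self.separations_deg) * len(self.meridians) * self.reps_per_cell

    @property
    def cue_onset_asynchrony_ms(self) -> float:
        """Cue-onset to target-onset interval (blank interval + cue duration)."""
        return self.soa_ms + self.timings_ms.get("cue", 200.0)

    def replace(self, **changes) -> "DesignConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "separations_deg": list(self.separations_deg),
            "meridians": list(self.meridians),
            "reps_per_cell": self.reps_per_cell,
            "cue_valid_fraction": self.cue_valid_fraction,
            "soa_ms": self.soa_ms,
            "complexity": self.complexity,
            "timings_ms": dict(self.timings_ms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        return cls(**d)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: geometry, cue condition and true stimulus contents."""

    trial_id: int
    meridian: str
    separation_deg: float
    cue_validity: str  # "valid" | "invalid"
    cue_meridian: str
    cue_separation_deg: float
    soa_ms: float
    complexity: str
    stimulus_a: StimulusGroup
    stimulus_b: StimulusGroup

    @property
    def meridian_class(self) -> str:
        return MERIDIAN_CLASSES[self.meridian]

    @property
    def stimulus_positions(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Polar positions (angle_deg, radius_deg) of the two stimuli.

        Both stimuli sit at half the separation from fixation, on opposite
        half-meridians.
        """
        ang = MERIDIAN_ANGLES_DEG[self.meridian]
        r = self.separation_deg / 2.0
        return ((ang, r), ((ang + 180.0) % 360.0, r))


def generate_stimulus(
    complexity: str,
    rng: np.random.Generator,
    target_count: int | None = None,
) -> StimulusGroup:
    """Draw one stimulus group.

    The number of light-gray triangles is uniform over {0, …, 4} (20 % per
    count); the remaining elements are drawn uniformly from the non-target
    alphabet and the four positions are randomly permuted. ``target_count``
    may be forced for testing.
    """
    if target_count is None:
        target_count = int(rng.integers(0, 5))
    elif not 0 <= target_count <= 4:
        raise ValueError("target_count must lie in 0..4")
    pool = nontarget_alphabet(complexity)
    fillers = [pool[int(i)] for i in rng.integers(0, len(pool), size=4 - target_count)]
    elements = [TARGET_ELEMENT] * target_count + fillers
    order = rng.permutation(4)
    return StimulusGroup(tuple(elements[i] for i in order))


def assign_invalid_cue(
    trial: TrialSpec, rng: np.random.Generator, config: DesignConfig
) -> TrialSpec:
    """Place the cue pair of an invalid trial on a non-target meridian.

    Both cues go symmetrically on one uniformly chosen non-target meridian at
    one uniformly chosen separation from the grid; the target geometry is
    untouched.
    """
    if trial.cue_validity != "invalid":
        raise ValueError("assign_invalid_cue requires an invalid trial")
    others = [m for m in config.meridians if m != trial.meridian]
    if not others:
        raise ConfigError("invalid cues need at least one non-target meridian")
    cue_meridian = others[int(rng.integers(len(others)))]
    cue_sep = config.separations_deg[int(rng.integers(len(config.separations_deg)))]
    return replace(trial, cue_meridian=cue_meridian, cue_separation_deg=cue_sep)


def generate_session(config: DesignConfig, seed: int) -> list[TrialSpec]:
    """Generate one randomised, stratified AWT session.

    Every (meridian, separation) cell appears exactly ``reps_per_cell``
    times; trial order, per-trial cue-validity draws (independent
    Bernoulli(cue_valid_fraction)), invalid-cue placement and stimulus
    contents derive from independent child streams of ``seed``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    order_rng, validity_rng, stim_rng, cue_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    cells = [
        (m, s)
        for m in config.meridians
        for s in config.separations_deg
        for _ in range(config.reps_per_cell)
    ]
    order = order_rng.permutation(len(cells))
    trials: list[TrialSpec] = []
    for tid, idx in enumerate(order):
        meridian, sep = cells[idx]
        valid = bool(validity_rng.random() < config.cue_valid_fraction)
        trial = TrialSpec(
            trial_id=tid,
            meridian=meridian,
            separation_deg=sep,
            cue_validity="valid" if valid else "invalid",
            cue_meridian=meridian,
            cue_separation_deg=sep,
            soa_ms=config.soa_ms,
            complexity=config.complexity,
            stimulus_a=generate_stimulus(config.complexity, stim_rng),
            stimulus_b=generate_stimulus(config.complexity, stim_rng),
        )
        if not valid:
            trial = assign_invalid_cue(trial, cue_rng, config)
        trials.append(trial)
    return trials


def session_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    """Tabulate a session; stimulus groups serialise to compact codes."""
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "meridian": t.meridian,
                "meridian_class": t.meridian_class,
                "separation_deg": t.separation_deg,
                "cue_validity": t.cue_validity,
                "cue_meridian": t.cue_meridian,
                "cue_separation_deg": t.cue_separation_deg,
                "soa_ms": t.soa_ms,
                "complexity": t.complexity,
                "stimulus_a": t.stimulus_a.to_code(),
                "stimulus_b": t.stimulus_b.to_code(),
                "target_count_a": t.stimulus_a.target_count,
                "target_count_b": t.stimulus_b.target_count,
            }
        )
    return pd.DataFrame(rows)


def cell_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Trial counts per (meridian, separation) cell of a session table."""
    return (
        frame.groupby(["meridian", "separation_deg"], as_index=False)
        .size()
        .rename(columns={"size": "n_trials"})
    )
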