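"""Questionnaire-based vulnerability stratification.

Adolescents are scored on four instruments — subjective well-being (SWB,
the Satisfaction With Life Scale total) and the three Trait Meta-Mood Scale
subscales Attention (EQ-A), Clarity (EQ-C) and Mood Repair (EQ-R).  Each
variable is discretised into three levels (low / adequate-or-neutral / high)
using sex-specific cut-offs for EQ-A and EQ-C and sex-invariant cut-offs for
SWB and EQ-R.  The 3^4 = 81 level combinations ("superposed states") carry a
representative total score between 80 and 140, and that total assigns every
state — and hence every participant — to one of three vulnerability bands:

* ``high_vuln``  — total below 100 (high vulnerability to MDD, the V1 class)
* ``low_vuln``   — total between 100 and 120 inclusive (the V2 class)
* ``complete``   — total above 120 (complete mental health, the M class)

A :func:`summarize_cohort` pass over a cohort produces the band counts and
per-band lifestyle-category tables that the parameter-estimation stage
consumes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VARIABLES",
    "LEVELS",
    "BANDS",
    "SchemeError",
    "ParticipantRecord",
    "ScoringScheme",
    "SuperposedState",
    "CohortSummary",
    "default_scheme",
    "assign_level",
    "enumerate_states",
    "classify_total",
    "classify_participant",
    "summarize_cohort",
]

VARIABLES = ("swb", "eqa", "eqc", "eqr")
LEVELS = ("low", "adequate", "high")  # SWB's middle level is called "neutral"
BANDS = ("high_vuln", "low_vuln", "complete")
SEXES = ("male", "female")

EXERCISE_CATS = ("high", "medium", "low")
TECH_CATS = ("high", "medium", "low")
SOCIAL_CATS = ("excellent", "average", "poor")


class SchemeError(ValueError):
    """A scoring scheme is malformed or queried with unknown keys."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantRecord:
    """One respondent's subscale totals and lifestyle categories."""

    id: str
    sex: str
    age: float
    swb: int
    eqa: int
    eqc: int
    eqr: int
    exercise_cat: str
    tech_cat: str
    social_cat: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (15 <= self.age <= 23):
            raise ValueError(f"age {self.age} outside [15, 23]")
        for var in VARIABLES:
            score = getattr(self, var)
            if not isinstance(score, int) or isinstance(score, bool):
                raise ValueError(f"{var} score must be an integer, got {score!r}")
            if score < 0:
                raise ValueError(f"{var} score must be nonnegative, got {score}")
        if self.exercise_cat not in EXERCISE_CATS:
            raise ValueError(f"unknown exercise category {self.exercise_cat!r}")
        if self.tech_cat not in TECH_CATS:
            raise ValueError(f"unknown technology category {self.tech_cat!r}")
        if self.social_cat is not None and self.social_cat not in SOCIAL_CATS:
            raise ValueError(f"unknown social-skills category {self.social_cat!r}")

    def score(self, variable: str) -> int:
        if variable not in VARIABLES:
            raise SchemeError(f"unknown variable {variable!r}")
        return getattr(self, variable)


@dataclass(frozen=True)
class ScoringScheme:
    """Cut-offs, representative level scores and band boundaries.

    ``thresholds[var][sex] = (low_max, high_min)``: a score ``<= low_max`` is
    low, ``>= high_min`` is high, anything between is adequate/neutral.
    Storing only the two cut points makes the three level intervals partition
    the integer axis by construction; validation additionally requires a
    nonempty middle interval inside the instrument bounds.

    ``level_scores[var][level]`` are the representative points a level
    contributes to a state's total; they are sex-invariant and strictly
    increasing in the level, with all-low states totalling 80 and all-high
    states totalling 140.

    Band boundaries follow the published stratification: totals strictly
    above ``low_band[1]`` (120) are complete mental health, totals inside the
    closed interval ``low_band`` are low vulnerability, totals strictly below
    ``low_band[0]`` (100) are high vulnerability.
    """

    thresholds: Mapping[str, Mapping[str, tuple[int, int]]]
    level_scores: Mapping[str, Mapping[str, float]]
    instrument_bounds: Mapping[str, tuple[int, int]]
    low_band: tuple[float, float] = (100.0, 120.0)

    def __post_init__(self) -> None:
        for var in VARIABLES:
            if var not in self.thresholds:
                raise SchemeError(f"thresholds missing variable {var!r}")
            if var not in self.level_scores:
                raise SchemeError(f"level_scores missing variable {var!r}")
            lo_b, hi_b = self.instrument_bounds[var]
            for sex in SEXES:
                low_max, high_min = self.thresholds[var][sex]
                if not (lo_b <= low_max < high_min - 1 < hi_b):
                    raise SchemeError(
                        f"{var}/{sex}: cut points ({low_max}, {high_min}) do not "
                        f"leave a nonempty middle level within bounds {lo_b}-{hi_b}"
                    )
            scores = self.level_scores[var]
            if not scores["low"] < scores["adequate"] < scores["high"]:
                raise SchemeError(f"{var}: level scores not strictly increasing")
        if self.low_band[0] >= self.low_band[1]:
            raise SchemeError("low_band must be an increasing interval")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                v: {s: list(self.thresholds[v][s]) for s in SEXES} for v in VARIABLES
            },
            "level_scores": {v: dict(self.level_scores[v]) for v in VARIABLES},
            "instrument_bounds": {
                v: list(self.instrument_bounds[v]) for v in VARIABLES
            },
            "band_cutoffs": {"low_band": list(self.low_band)},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringScheme":
        return cls(
            thresholds={
                v: {s: tuple(d["thresholds"][v][s]) for s in SEXES}
                for v in VARIABLES
            },
            level_scores={v: dict(d["level_scores"][v]) for v in VARIABLES},
            instrument_bounds={
                v: tuple(d["instrument_bounds"][v]) for v in VARIABLES
            },
            low_band=tuple(d.get("band_cutoffs", {}).get("low_band", (100, 120))),
        )


@dataclass(frozen=True)
class SuperposedState:
    """One of the 81 level combinations, ordered (SWB, EQ-A, EQ-C, EQ-R)."""

    levels: tuple[str, str, str, str]
    total: float
    band: str


@dataclass
class CohortSummary:
    """Band counts and per-band lifestyle tables for a classified cohort."""

    n_total: int
    band_counts: dict[str, int]  # band -> count (V1 = high_vuln, V2 = low_vuln, M = complete)
    exercise_counts: dict[str, tuple[int, int, int]]  # band -> (high, medium, low)
    tech_counts: dict[str, tuple[int, int, int]]  # band -> (high, medium, low)
    sex_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_high(self) -> int:
        return self.band_counts["high_vuln"]

    @property
    def n_low(self) -> int:
        return self.band_counts["low_vuln"]

    @property
    def n_complete(self) -> int:
        return self.band_counts["complete"]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "band_counts": dict(self.band_counts),
            "exercise_counts": {b: list(t) for b, t in self.exercise_counts.items()},
            "tech_counts": {b: list(t) for b, t in self.tech_counts.items()},
            "sex_counts": dict(self.sex_counts),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSummary":
        return cls(
            n_total=int(d["n_total"]),
            band_counts={b: int(c) for b, c in d["band_counts"].items()},
            exercise_counts={b: tuple(t) for b, t in d["exercise_counts"].items()},
            tech_counts={b: tuple(t) for b, t in d["tech_counts"].items()},
            sex_counts={s: int(c) for s, c in d.get("sex_counts", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSummary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Default scheme
# ---------------------------------------------------------------------------

# (low_max, high_min) per variable and sex.  SWB and EQ-R are sex-invariant;
# EQ-A and EQ-C use the published sex-specific cut-offs.  The female EQ-A low
# cut-off is 24, the complement of the adequate range 25-35 (the published
# table carries an inconsistent value there).
_DEFAULT_THRESHOLDS: dict[str, dict[str, tuple[int, int]]] = {
    "swb": {"male": (14, 16), "female": (14, 16)},
    "eqa": {"male": (21, 33), "female": (24, 36)},
    "eqc": {"male": (25, 36), "female": (23, 35)},
    "eqr": {"male": (23, 35), "female": (23, 35)},
}

# Instrument score ranges: SWLS total 5-35, TMMS subscales 8-40.
_DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "swb": (5, 35),
    "eqa": (8, 40),
    "eqc": (8, 40),
    "eqr": (8, 40),
}

_LOW_POINTS = 20.0  # each variable's low level contributes 20 -> all-low total 80
_HIGH_POINTS = 35.0  # each variable's high level contributes 35 -> all-high total 140


def _default_level_scores() -> dict[str, dict[str, float]]:
    """Representative points per level: rescaled range midpoints.

    For each variable and sex, take the midpoint of each level's score
    interval (open-ended intervals capped at the instrument bounds), then map
    the low midpoint to 20 and the high midpoint to 35 by the affine map
    between them.  Sex-specific variables average the two sexes' mapped
    middle values so the resulting map depends only on (variable, level).
    """
    scores: dict[str, dict[str, float]] = {}
    for var in VARIABLES:
        lo_b, hi_b = _DEFAULT_BOUNDS[var]
        mids = []
        for sex in SEXES:
            low_max, high_min = _DEFAULT_THRESHOLDS[var][sex]
            m_low = (lo_b + low_max) / 2
            m_adeq = (low_max + 1 + high_min - 1) / 2
            m_high = (high_min + hi_b) / 2
            scale = (_HIGH_POINTS - _LOW_POINTS) / (m_high - m_low)
            mids.append(_LOW_POINTS + (m_adeq - m_low) * scale)
        scores[var] = {
            "low": _LOW_POINTS,
            "adequate": sum(mids) / len(mids),
            "high": _HIGH_POINTS,
        }
    return scores


def default_scheme() -> ScoringScheme:
    """The scheme encoding the published cut-offs and band boundaries."""
    return ScoringScheme(
        thresholds=_DEFAULT_THRESHOLDS,
        level_scores=_default_level_scores(),
        instrument_bounds=_DEFAULT_BOUNDS,
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assign_level(
    variable: str, score: int, sex: str, scheme: ScoringScheme | None = None
) -> str:
    """Discretise a subscale score into low / adequate / high.

    SWB's middle level is a single score (15) under the default scheme and is
    conventionally called "neutral"; this function uses "adequate" for the
    middle level of every variable.
    """
    scheme = scheme if scheme is not None else default_scheme()
    if variable not in VARIABLES:
        raise SchemeError(f"unknown variable {variable!r}")
    if sex not in SEXES:
        raise SchemeError(f"unknown sex {sex!r}")
    if not isinstance(score, int) or isinstance(score, bool):
        raise ValueError(f"score must be an integer, got {score!r}")
    if score < 0:
        raise ValueError(f"score must be nonnegative, got {score}")
    low_max, high_min = scheme.thresholds[variable][sex]
    if score <= low_max:
        return "low"
    if score >= high_min:
        return "high"
    return "adequate"


def classify_total(total: float, scheme: ScoringScheme | None = None) -> str:
    """Band of a state total: >120 complete, [100, 120] low, <100 high.

    Totals outside the nominal 80-140 span are still classified by the same
    rule; callers may warn on them if they indicate a bad level-score map.
    """
    scheme = scheme if scheme is not None else default_scheme()
    lo, hi = scheme.low_band
    if total > hi:
        return "complete"
    if total >= lo:
        return "low_vuln"
    return "high_vuln"


def enumerate_states(scheme: ScoringScheme | None = None) -> list[SuperposedState]:
    """All 81 superposed states with their totals and bands."""
    scheme = scheme if scheme is not None else default_scheme()
    states = []
    for combo in itertools.product(LEVELS, repeat=len(VARIABLES)):
        total = sum(
            scheme.level_scores[var][lvl] for var, lvl in zip(VARIABLES, combo)
        )
        states.append(
            SuperposedState(levels=combo, total=total, band=classify_total(total, scheme))
        )
    return states


def classify_participant(
    rec: ParticipantRecord, scheme: ScoringScheme | None = None
) -> tuple[SuperposedState, str]:
    """Map a participant to their superposed state and vulnerability band."""
    scheme = scheme if scheme is not None else default_scheme()
    levels = tuple(
        assign_level(var, rec.score(var), rec.sex, scheme) for var in VARIABLES
    )
    total = sum(scheme.level_scores[var][lvl] for var, lvl in zip(VARIABLES, levels))
    band = classify_total(total, scheme)
    return SuperposedState(levels=levels, total=total, band=band), band


def summarize_cohort(
    records: Sequence[ParticipantRecord] | Iterable[ParticipantRecord],
    scheme: ScoringScheme | None = None,
) -> CohortSummary:
    """Band counts and per-band exercise/technology tables for a cohort."""
    scheme = scheme if scheme is not None else default_scheme()
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    band_counts = {b: 0 for b in BANDS}
    ex_counts = {b: [0, 0, 0] for b in BANDS}
    tech_counts = {b: [0, 0, 0] for b in BANDS}
    sex_counts = {s: 0 for s in SEXES}
    for rec in records:
        _, band = classify_participant(rec, scheme)
        band_counts[band] += 1
        ex_counts[band][EXERCISE_CATS.index(rec.exercise_cat)] += 1
        tech_counts[band][TECH_CATS.index(rec.tech_cat)] += 1
        sex_counts[rec.sex] += 1
    return CohortSummary(
        n_total=len(records),
        band_counts=band_counts,
        exercise_counts={b: tuple(c) for b, c in ex_counts.items()},
        tech_counts={b: tuple(c) for b, c in tech_counts.items()},
        sex_counts=sex_counts,
    )
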