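"""Estimation of the eight compartmental-model parameters from cohort counts.

The model has three compartments — high vulnerability V1, low vulnerability
V2 and complete mental health M — with population fractions (x, y, z).  Its
parameters are

* ``mu``      — per-day per-capita rate of entering/leaving the adolescent
                system (ages 15-23);
* ``a, b, c`` — probabilities of entering V1, V2 and M at age 15;
* ``delta``   — positive peer-pressure contact rate (M pulls V2 downward);
* ``epsilon`` — negative peer-pressure contact rate (V1 pulls V2 upward);
* ``alpha``   — physical-exercise rate moving V1 -> V2;
* ``beta``    — technology-use rate moving M -> V2.

All rates are per day.  The estimation procedure mirrors the source
analysis of the 227-adolescent Bangalore cohort: entry probabilities come
from the observed band fractions, the peer-pressure rates from assumed
contact counts, and the lifestyle rates from weighted mean daily hours of
exercise/technology use combined with a persistence window.

A note on ``mu``: one over an 8-year adolescent span is 1/2920 =
0.000342/day, but the canonical value carried through the source analysis —
and required to reproduce its parameter table — is 0.00342.
:func:`estimate_mu` returns the true arithmetic; :data:`MU_CANONICAL`
supplies the canonical constant used by downstream defaults.  Both are
reported side by side rather than silently reconciled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

from .stratification import CohortSummary

__all__ = [
    "MU_CANONICAL",
    "MU_TRUE_8_YEARS",
    "EstimationError",
    "ModelParameters",
    "StateFractions",
    "EstimationConfig",
    "EstimationReport",
    "STUDY_PARAMETERS",
    "STUDY_INITIAL_FRACTIONS",
    "rescale_counts",
    "estimate_mu",
    "estimate_entry_probs",
    "contact_rate",
    "weighted_mean_hours",
    "lifestyle_rate",
    "estimate_all",
]

#: Canonical per-day turnover rate used throughout the source analysis.
MU_CANONICAL = 0.00342

#: True arithmetic of 1/(8 years x 365 days) — an order of magnitude smaller.
MU_TRUE_8_YEARS = 1.0 / (8 * 365)


class EstimationError(ValueError):
    """An estimation step received invalid or missing inputs."""


@dataclass(frozen=True)
class ModelParameters:
    """The eight rates/probabilities of the compartmental model."""

    mu: float
    a: float
    b: float
    c: float
    delta: float
    epsilon: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        for name in ("a", "b", "c"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "ModelParameters":
        d = asdict(self)
        d.update(kwargs)
        return ModelParameters(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        return cls(**{k: float(d[k]) for k in
                      ("mu", "a", "b", "c", "delta", "epsilon", "alpha", "beta")})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class StateFractions:
    """Compartment fractions x = V1/N, y = V2/N, z = M/N."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


#: Parameter estimates from the 227-adolescent Bangalore cohort analysis.
STUDY_PARAMETERS = ModelParameters(
    mu=MU_CANONICAL, a=0.3104, b=0.4799, c=0.0105,
    delta=0.5, epsilon=0.2, alpha=0.6796, beta=0.6941,
)

#: Initial compartment fractions of the same cohort (88/136/3 of 227).
STUDY_INITIAL_FRACTIONS = StateFractions(x=0.3876, y=0.5991, z=0.0132)


@dataclass
class EstimationConfig:
    """Assumed constants of the estimation procedure, all overridable.

    Contact tuples are (contacts per day, contacts needed for conversion).
    Hour weights give the representative daily hours of the high/medium/low
    lifestyle categories; persistence windows are the days of sustained
    behaviour required to move between compartments.
    """

    mu: float = MU_CANONICAL
    delta_contacts: tuple[float, float] = (5, 10)
    epsilon_contacts: tuple[float, float] = (5, 25)
    exercise_weights: tuple[float, float, float] = (1.0, 0.5, 0.15)
    tech_weights: tuple[float, float, float] = (2.0, 1.0, 0.3)
    exercise_persistence_days: float = 30.0
    tech_persistence_days: float = 15.0
    #: direct overrides for the peer-pressure rates (skip the contact product)
    delta: float | None = None
    epsilon: float | None = None
    #: round intermediate quantities (fractions, weighted means) to 4 decimal
    #: places, emulating the chained rounding of the source analysis
    chained_rounding: bool = False


@dataclass
class EstimationReport:
    """Full estimation output: parameters plus every intermediate quantity."""

    params: ModelParameters
    fractions: StateFractions
    hr: float  # weighted mean exercise hours, high-vulnerability band
    lr: float  # weighted mean exercise hours, low-vulnerability band
    cmh: float  # weighted mean technology hours, complete-mental-health band
    lrt: float  # weighted mean technology hours, low-vulnerability band
    mu_true: float = MU_TRUE_8_YEARS
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def disp(v):
            return round(v, 4)

        d = {
            "params": self.params.to_dict(),
            "params_display": {k: disp(v) for k, v in self.params.to_dict().items()},
            "fractions": {"x": self.fractions.x, "y": self.fractions.y,
                          "z": self.fractions.z},
            "intermediates": {"hr": self.hr, "lr": self.lr,
                              "cmh": self.cmh, "lrt": self.lrt},
            "mu_true": self.mu_true,
            "notes": list(self.notes),
        }
        return d


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def rescale_counts(v1: int, v2: int, m: int, n: int) -> StateFractions:
    """Compartment counts to fractions (x, y, z) = (V1, V2, M)/N."""
    if n <= 0:
        raise EstimationError(f"total population must be positive, got {n}")
    if v1 + v2 + m != n:
        raise EstimationError(
            f"band counts {v1}+{v2}+{m} do not sum to the total {n}"
        )
    return StateFractions(x=v1 / n, y=v2 / n, z=m / n)


def estimate_mu(span_years: float) -> float:
    """Per-day turnover rate 1/(span x 365) for a residence span in years.

    Note that for the canonical 8-year adolescent span this returns
    ``1/2920 = 0.000342``; the source analysis carried :data:`MU_CANONICAL`
    = 0.00342 instead, and downstream defaults use the canonical value so
    that its parameter table is reproduced.
    """
    if span_years <= 0:
        raise EstimationError(f"life span must be positive, got {span_years}")
    return 1.0 / (span_years * 365.0)


def estimate_entry_probs(
    frac: StateFractions, mu: float = MU_CANONICAL
) -> tuple[float, float, float]:
    """Entry probabilities (a, b, c) from band fractions.

    Follows the source procedure: each probability is the corresponding
    fraction divided by ``mu`` (giving a residence time in days) and then by
    365.
    """
    if mu <= 0:
        raise EstimationError(f"mu must be positive, got {mu}")
    return tuple((f / mu) / 365.0 for f in frac.as_tuple())


def contact_rate(contacts_per_day: float, contacts_needed: float) -> float:
    """Peer-pressure rate: daily contacts times conversion probability.

    The conversion probability is one over the number of contacts needed to
    convert (correct or infect) a low-vulnerability adolescent.
    """
    if contacts_needed <= 0:
        raise EstimationError(
            f"contacts needed must be positive, got {contacts_needed}"
        )
    if contacts_per_day < 0:
        raise EstimationError(
            f"contacts per day must be nonnegative, got {contacts_per_day}"
        )
    return contacts_per_day / contacts_needed


def weighted_mean_hours(
    counts: tuple[float, float, float], hour_weights: tuple[float, float, float]
) -> float:
    """Category-count-weighted mean daily hours, sum(n_i h_i) / sum(n_i)."""
    total = sum(counts)
    if total <= 0:
        raise EstimationError("category counts sum to zero")
    if any(c < 0 for c in counts) or any(w < 0 for w in hour_weights):
        raise EstimationError("counts and hour weights must be nonnegative")
    return sum(c * w for c, w in zip(counts, hour_weights)) / total


def lifestyle_rate(
    mean_hours_group1: float, mean_hours_group2: float, persistence_days: float
) -> float:
    """Per-day transition rate from sustained daily lifestyle hours.

    The two group means (hours/day) are averaged, multiplied by the
    persistence window (days of sustained behaviour needed to change
    compartment) and divided by 24 hours.
    """
    if persistence_days <= 0:
        raise EstimationError(
            f"persistence window must be positive, got {persistence_days}"
        )
    return (mean_hours_group1 + mean_hours_group2) / 2 * persistence_days / 24.0


# ---------------------------------------------------------------------------
# Composite estimation
# ---------------------------------------------------------------------------


def estimate_all(
    summary: CohortSummary, config: EstimationConfig | None = None
) -> EstimationReport:
    """All eight model parameters from a cohort summary.

    Raises :class:`EstimationError` naming the missing input when a band
    needed by a sub-estimate is empty (e.g. the complete-mental-health band
    for the technology rate beta).
    """
    cfg = config if config is not None else EstimationConfig()

    def maybe_round(v: float) -> float:
        return round(v, 4) if cfg.chained_rounding else v

    frac = rescale_counts(
        summary.n_high, summary.n_low, summary.n_complete, summary.n_total
    )
    frac = StateFractions(*(maybe_round(f) for f in frac.as_tuple()))
    a, b, c = estimate_entry_probs(frac, cfg.mu)

    delta = cfg.delta if cfg.delta is not None else contact_rate(*cfg.delta_contacts)
    epsilon = (
        cfg.epsilon if cfg.epsilon is not None else contact_rate(*cfg.epsilon_contacts)
    )

    def band_mean(table: dict, band: str, weights, what: str) -> float:
        counts = table.get(band)
        if counts is None or sum(counts) == 0:
            raise EstimationError(
                f"cannot estimate {what}: no {band.replace('_', '-')} "
                f"participants in the category table"
            )
        return maybe_round(weighted_mean_hours(tuple(counts), weights))

    hr = band_mean(summary.exercise_counts, "high_vuln", cfg.exercise_weights,
                   "alpha (exercise rate)")
    lr = band_mean(summary.exercise_counts, "low_vuln", cfg.exercise_weights,
                   "alpha (exercise rate)")
    alpha = lifestyle_rate(hr, lr, cfg.exercise_persistence_days)

    cmh = band_mean(summary.tech_counts, "complete", cfg.tech_weights,
                    "beta (technology rate)")
    lrt = band_mean(summary.tech_counts, "low_vuln", cfg.tech_weights,
                    "beta (technology rate)")
    beta = lifestyle_rate(cmh, lrt, cfg.tech_persistence_days)

    notes = [
        f"mu: canonical value {cfg.mu} used; true 8-year arithmetic is "
        f"{MU_TRUE_8_YEARS:.6f}/day",
    ]
    if cfg.chained_rounding:
        notes.append("intermediate quantities rounded to 4 decimal places")

    params = ModelParameters(
        mu=cfg.mu, a=a, b=b, c=c,
        delta=delta, epsilon=epsilon, alpha=alpha, beta=beta,
    )
    return EstimationReport(
        params=params, fractions=frac, hr=hr, lr=lr, cmh=cmh, lrt=lrt, notes=notes
    )
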