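"""Synthetic questionnaire cohorts with controlled band structure.

Two generators are provided:

* :func:`reference_cohort` — a fully deterministic 227-record cohort whose
  marginal counts reproduce every figure published for the Bangalore
  adolescent study: the 88/136/3 band split, the exercise tables of the
  high- and low-vulnerability bands (32/13/43 and 60/20/56), the technology
  tables of the low-vulnerability and complete bands (63/52/21 and 1/0/2)
  and the 99 female / 128 male sex split.  Cross-tabulations the study never
  printed (sex-by-band joints, high-band technology, complete-band exercise)
  are synthetic fill-ins chosen deterministically and documented below.

* :func:`generate_cohort` — a seeded random generator over the same
  configuration space, sampling scores uniformly within the level ranges of
  a state belonging to each record's target band, so that generation and
  stratification are consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stratification import (
    BANDS,
    EXERCISE_CATS,
    SEXES,
    TECH_CATS,
    VARIABLES,
    ParticipantRecord,
    ScoringScheme,
    default_scheme,
    enumerate_states,
)

__all__ = ["SynthConfig", "generate_cohort", "reference_cohort",
            "cohort_to_csv", "cohort_from_csv"]


# Study conditions: cohort size and composition of the Bangalore sample.
_N = 227
_SEX_SPLIT = (99, 128)  # (female, male)
_AGE_MEAN = 18.58
_AGE_SD = 0.29
_GROUP_TARGETS = {"high_vuln": 88, "low_vuln": 136, "complete": 3}
_EXERCISE_TABLES = {"high_vuln": (32, 13, 43), "low_vuln": (60, 20, 56)}
_TECH_TABLES = {"low_vuln": (63, 52, 21), "complete": (1, 0, 2)}


@dataclass
class SynthConfig:
    """Cohort-generation settings; defaults are the study conditions.

    Category tables are given per band as (high, medium, low) counts; bands
    absent from a table get categories sampled uniformly at random.
    """

    n: int = _N
    sex_split: tuple[int, int] = _SEX_SPLIT  # (n_female, n_male)
    age_mean: float = _AGE_MEAN
    age_sd: float = _AGE_SD
    group_targets: dict[str, int] = field(
        default_factory=lambda: dict(_GROUP_TARGETS)
    )
    exercise_tables: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_EXERCISE_TABLES)
    )
    tech_tables: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_TECH_TABLES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"cohort size must be nonnegative, got {self.n}")
        if sum(self.group_targets.values()) != self.n:
            raise ValueError(
                f"group targets {self.group_targets} do not sum to n = {self.n}"
            )
        if sum(self.sex_split) != self.n:
            raise ValueError(
                f"sex split {self.sex_split} does not sum to n = {self.n}"
            )
        for name, tables in (("exercise", self.exercise_tables),
                             ("tech", self.tech_tables)):
            for band, triple in tables.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r} in {name} table")
                if sum(triple) != self.group_targets.get(band, 0):
                    raise ValueError(
                        f"{name} table for band {band!r} sums to {sum(triple)}, "
                        f"expected {self.group_targets.get(band, 0)}"
                    )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _level_ranges(scheme: ScoringScheme, var: str, sex: str) -> dict[str, tuple[int, int]]:
    """Integer score range of each level, capped at the instrument bounds."""
    lo_b, hi_b = scheme.instrument_bounds[var]
    low_max, high_min = scheme.thresholds[var][sex]
    return {
        "low": (lo_b, low_max),
        "adequate": (low_max + 1, high_min - 1),
        "high": (high_min, hi_b),
    }


def _states_by_band(scheme: ScoringScheme) -> dict[str, list[tuple[str, ...]]]:
    by_band: dict[str, list[tuple[str, ...]]] = {b: [] for b in BANDS}
    for st in enumerate_states(scheme):
        by_band[st.band].append(st.levels)
    return by_band


def _expand_categories(triple, cats) -> list[str]:
    labels: list[str] = []
    for cat, count in zip(cats, triple):
        labels.extend([cat] * count)
    return labels


# ---------------------------------------------------------------------------
# Random generator
# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: SynthConfig | None = None, scheme: ScoringScheme | None = None
) -> list[ParticipantRecord]:
    """Sample a cohort matching the configured band and category marginals.

    Every record is built from a superposed state drawn uniformly among the
    states of its target band, with each variable's score drawn uniformly
    over that level's integer range for the record's sex — so the record is
    guaranteed to stratify back into the target band.  Ages are
    truncated-normal on [15, 23].  Identical configurations (including the
    seed) produce identical cohorts.
    """
    cfg = cfg if cfg is not None else SynthConfig()
    cfg.validate()
    scheme = scheme if scheme is not None else default_scheme()
    if cfg.n == 0:
        return []
    rng = np.random.default_rng(cfg.seed)

    by_band = _states_by_band(scheme)
    for band, target in cfg.group_targets.items():
        if target > 0 and not by_band.get(band):
            raise ValueError(
                f"infeasible config: band {band!r} has a target of {target} "
                "but no attainable superposed state under this scheme"
            )

    # sex labels over the whole cohort, then shuffled
    sexes = np.array(["female"] * cfg.sex_split[0] + ["male"] * cfg.sex_split[1])
    rng.shuffle(sexes)

    lo, hi = 15.0, 23.0
    a_, b_ = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    ages = stats.truncnorm.rvs(
        a_, b_, loc=cfg.age_mean, scale=cfg.age_sd, size=cfg.n, random_state=rng
    )

    records: list[ParticipantRecord] = []
    idx = 0
    for band in BANDS:
        target = cfg.group_targets.get(band, 0)
        if target == 0:
            continue
        if band in cfg.exercise_tables:
            ex_labels = _expand_categories(cfg.exercise_tables[band], EXERCISE_CATS)
            rng.shuffle(ex_labels)
        else:
            ex_labels = list(rng.choice(EXERCISE_CATS, size=target))
        if band in cfg.tech_tables:
            tech_labels = _expand_categories(cfg.tech_tables[band], TECH_CATS)
            rng.shuffle(tech_labels)
        else:
            tech_labels = list(rng.choice(TECH_CATS, size=target))

        states = by_band[band]
        for k in range(target):
            sex = str(sexes[idx])
            levels = states[rng.integers(len(states))]
            scores = {}
            for var, lvl in zip(VARIABLES, levels):
                s_lo, s_hi = _level_ranges(scheme, var, sex)[lvl]
                scores[var] = int(rng.integers(s_lo, s_hi + 1))
            records.append(
                ParticipantRecord(
                    id=f"S{idx + 1:04d}",
                    sex=sex,
                    age=float(ages[idx]),
                    swb=scores["swb"],
                    eqa=scores["eqa"],
                    eqc=scores["eqc"],
                    eqr=scores["eqr"],
                    exercise_cat=ex_labels[k],
                    tech_cat=tech_labels[k],
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# Deterministic reference cohort
# ---------------------------------------------------------------------------

# Fixed representative scores per band and sex, each comfortably inside the
# intended level of the default scheme (all-low / all-adequate / all-high).
_BAND_SCORES = {
    "high_vuln": {
        "male": {"swb": 12, "eqa": 15, "eqc": 16, "eqr": 15},
        "female": {"swb": 12, "eqa": 16, "eqc": 15, "eqr": 15},
    },
    "low_vuln": {
        "male": {"swb": 15, "eqa": 27, "eqc": 30, "eqr": 29},
        "female": {"swb": 15, "eqa": 30, "eqc": 29, "eqr": 29},
    },
    "complete": {
        "male": {"swb": 20, "eqa": 36, "eqc": 38, "eqr": 37},
        "female": {"swb": 20, "eqa": 38, "eqc": 37, "eqr": 37},
    },
}

# Female counts per band by largest-remainder proportional allocation of the
# 99 females over the 88/136/3 band sizes (synthetic: the study prints no
# sex-by-band joint counts).
_FEMALE_PER_BAND = {"high_vuln": 39, "low_vuln": 59, "complete": 1}

# Category triples the study never printed, filled by round-robin cycling
# over (high, medium, low) — synthetic values, marked as such.
_FILL_TECH_HIGH_BAND = (30, 29, 29)  # 88 participants
_FILL_EXERCISE_COMPLETE = (1, 1, 1)  # 3 participants


def reference_cohort() -> list[ParticipantRecord]:
    """The deterministic 227-record cohort mirroring the published marginals.

    Band sizes, the printed exercise/technology tables and the overall sex
    split are exact.  Unprinted cross-tabulations are synthetic:
    sex-by-band counts use largest-remainder proportional allocation,
    high-band technology is filled 30/29/29 and complete-band exercise
    1/1/1.  Every participant carries the fixed representative scores of an
    all-low, all-adequate or all-high state and the cohort mean age 18.58.
    No randomness is involved.
    """
    exercise_tables = dict(_EXERCISE_TABLES)
    exercise_tables["complete"] = _FILL_EXERCISE_COMPLETE
    tech_tables = dict(_TECH_TABLES)
    tech_tables["high_vuln"] = _FILL_TECH_HIGH_BAND

    records: list[ParticipantRecord] = []
    idx = 0
    for band in BANDS:
        target = _GROUP_TARGETS[band]
        n_female = _FEMALE_PER_BAND[band]
        ex_labels = _expand_categories(exercise_tables[band], EXERCISE_CATS)
        tech_labels = _expand_categories(tech_tables[band], TECH_CATS)
        for k in range(target):
            sex = "female" if k < n_female else "male"
            scores = _BAND_SCORES[band][sex]
            records.append(
                ParticipantRecord(
                    id=f"R{idx + 1:04d}",
                    sex=sex,
                    age=_AGE_MEAN,
                    exercise_cat=ex_labels[k],
                    tech_cat=tech_labels[k],
                    **scores,
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "sex", "age", "swb", "eqa", "eqc", "eqr",
                "exercise_cat", "tech_cat", "social_cat"]


def cohort_to_csv(records: list[ParticipantRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id, "sex": r.sex, "age": r.age,
                "swb": r.swb, "eqa": r.eqa, "eqc": r.eqc, "eqr": r.eqr,
                "exercise_cat": r.exercise_cat, "tech_cat": r.tech_cat,
                "social_cat": r.social_cat if r.social_cat is not None else "",
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def cohort_from_csv(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - {"social_cat"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        social = getattr(row, "social_cat", "")
        records.append(
            ParticipantRecord(
                id=str(row.id), sex=str(row.sex), age=float(row.age),
                swb=int(row.swb), eqa=int(row.eqa), eqc=int(row.eqc),
                eqr=int(row.eqr),
                exercise_cat=str(row.exercise_cat), tech_cat=str(row.tech_cat),
                social_cat=str(social) if social else None,
            )
        )
    return records
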