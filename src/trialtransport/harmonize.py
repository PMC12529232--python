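"""Variable harmonization and dataset stacking.

Trial and target-population survey records are mapped onto one shared
schema so that a selection model can be fitted on the stacked data.  The
schema is deliberately narrow: every covariate used for weighting is a
small categorical, ages are recoded to the 12/13 band covered by both
sources, and the six school-level stratification variables ride along on
trial rows only.

Missing values are represented as ``NaN`` in memory and as empty cells
in CSV.  Fields that do not apply to a source (arm and follow-up outcome
for survey rows, stratification variables for survey rows) are also
``NaN``; applicability is recovered from ``source``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Categorical levels, in model (reference-first) order.
CATEGORY_LEVELS: dict[str, list] = {
    "source": ["trial", "target"],
    "arm": ["control", "intervention"],
    "gender": ["boy", "girl"],
    "age": [12, 13],
    "ethnicity": ["white", "minority"],
    "smoking_status": ["never", "occ_exp_ex", "weekly"],
    "age_first_cig": ["never", "le10", "y11", "y12", "y13"],
    "lives_with_smoker": ["yes", "no"],
    "lesson_smoking": ["yes", "no", "dont_know"],
    "country": ["england", "wales"],
    "school_type": ["state", "independent"],
    "sex_mix": ["mixed", "single_sex"],
    "language": ["english", "welsh"],
    "large_year_group": ["no", "yes"],
    "fsm_high": ["no", "yes"],
}

#: Columns of a harmonized participant table, in order.
SCHEMA_COLUMNS: list[str] = [
    "source", "year", "school_id", "arm",
    "gender", "age", "ethnicity", "smoking_status", "age_first_cig",
    "lives_with_smoker", "lesson_smoking", "outcome_weekly",
    "country", "school_type", "sex_mix", "language",
    "large_year_group", "fsm_high",
]

#: Covariates entering the selection model (individual level).
SELECTION_COVARIATES: list[str] = [
    "gender", "smoking_status", "ethnicity", "age", "age_first_cig",
    "lives_with_smoker", "lesson_smoking",
]

#: School-level stratification variables used at randomization.
STRATIFICATION_VARIABLES: list[str] = [
    "country", "school_type", "sex_mix", "language",
    "large_year_group", "fsm_high",
]

#: Raw six-level ethnicity labels accepted by :func:`collapse_ethnicity`.
RAW_ETHNICITY_LEVELS = ["white", "mixed", "asian", "black", "chinese", "other"]

#: Survey years where the questionnaire routed about half the students
#: away from the lives-with-a-smoker question.
ROUTED_YEARS = (2016, 2021)


class SchemaError(ValueError):
    """A record table violates the harmonized schema."""


# ---------------------------------------------------------------------------
# elementary recodes

def recode_age(raw_age: int) -> int:
    """Collapse survey ages onto the 12/13 band of the trial cohort.

    11-year-olds are re-coded as 12 and 14-year-olds as 13; 12 and 13
    pass through unchanged.
    """
    if raw_age == 11:
        return 12
    if raw_age == 14:
        return 13
    if raw_age in (12, 13):
        return int(raw_age)
    raise ValueError(f"age {raw_age!r} outside the harmonizable range 11-14")


def collapse_ethnicity(raw: str) -> str:
    """Collapse the six-level trial ethnicity onto white / minority."""
    if raw not in RAW_ETHNICITY_LEVELS:
        raise ValueError(f"unknown ethnicity level {raw!r}")
    return "white" if raw == "white" else "minority"


def derive_weekly_outcome(cigs_per_week: float) -> int:
    """Weekly smoking: at least one cigarette per week."""
    if cigs_per_week < 0:
        raise ValueError("cigarettes per week cannot be negative")
    return int(cigs_per_week >= 1)


def code_routed_missing(records: pd.DataFrame, routed: np.ndarray | pd.Series | None = None) -> pd.DataFrame:
    """Set lives_with_smoker to missing for survey students routed away
    from that question (2016 and 2021 questionnaires only).

    Parameters
    ----------
    records:
        Harmonized record table.
    routed:
        Boolean flag per row marking students whose questionnaire route
        skipped the question.  Defaults to a ``routed`` column if the
        table carries one; rows from other years are never altered.
    """
    out = records.copy()
    if routed is None:
        if "routed" not in out.columns:
            return out
        routed = out["routed"].fillna(False).astype(bool)
    routed = np.asarray(routed, dtype=bool)
    if routed.shape[0] != len(out):
        raise ValueError("routed flag length does not match records")
    applicable = out["year"].isin(ROUTED_YEARS) & (out["source"] == "target")
    mask = applicable.to_numpy() & routed
    out.loc[mask, "lives_with_smoker"] = np.nan
    if mask.any():
        logger.info("code_routed_missing: %d lives_with_smoker values set missing", int(mask.sum()))
    return out


def collapse_unsupported_levels(
    trial: pd.DataFrame,
    target: pd.DataFrame,
    covariates: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, object, object]]]:
    """Merge covariate levels with no target-population support.

    A level observed among trial students but absent from the target
    wave (e.g. an age-at-first-cigarette category the survey never
    recorded that year) would make the selection model quasi-separate:
    its coefficient diverges and those students' weights tend to zero.
    Such trial students represent nobody in the target, so their level
    is collapsed into the nearest preceding level the target does
    support (or the nearest following one for a reference level),
    mirroring how sparse categories are merged in practice.  Returns the
    recoded copies and the (variable, from, to) merges applied.

    Note the asymmetry: a level present in the *target* but not the
    trial is a genuine positivity violation and is left alone here so
    the selection model can refuse loudly.
    """
    trial = trial.copy()
    target = target.copy()
    merges: list[tuple[str, object, object]] = []
    for var in covariates:
        levels = CATEGORY_LEVELS.get(var)
        if levels is None:
            continue
        supported = [l for l in levels if (target[var] == l).any()]
        if not supported:
            continue
        for i, level in enumerate(levels):
            if level in supported or not (trial[var] == level).any():
                continue
            before = [l for l in levels[:i] if l in supported]
            after = [l for l in levels[i + 1:] if l in supported]
            dest = before[-1] if before else after[0]
            trial.loc[trial[var] == level, var] = dest
            target.loc[target[var] == level, var] = dest
            merges.append((var, level, dest))
            logger.warning("collapsed %s[%s] into %s[%s]: no target-population support",
                           var, level, var, dest)
    return trial, target, merges


# ---------------------------------------------------------------------------
# stacking

@dataclass
class StackedDataset:
    """Trial and one survey wave appended, with selection indicator S.

    S = 1 marks trial rows, S = 0 target rows; trial rows come first.
    """

    records: pd.DataFrame
    year: int

    @property
    def S(self) -> np.ndarray:
        return self.records["S"].to_numpy()

    @property
    def n_trial(self) -> int:
        return int(self.records["S"].sum())

    @property
    def n_target(self) -> int:
        return len(self.records) - self.n_trial


def _namespace_school_ids(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    ids = df["school_id"].astype(str)
    missing_prefix = ~ids.str.startswith(("trial:", "survey:"))
    if missing_prefix.any():
        df = df.copy()
        df.loc[missing_prefix, "school_id"] = prefix + ids[missing_prefix]
    return df

def stack_datasets(trial: pd.DataFrame, target: pd.DataFrame, year: int) -> StackedDataset:
    """Append a target survey below the trial records with S assigned.

    School identifiers are namespaced by source so a multilevel model
    can never pool a trial school with a survey school.
    """
    if len(target) == 0:
        raise ValueError(f"no target records for year {year}: nothing to transport to")
    if len(trial) == 0:
        raise ValueError("no trial records to transport from")
    for name, df, src in (("trial", trial, "trial"), ("target", target, "target")):
        if not set(SCHEMA_COLUMNS) <= set(df.columns):
            missing = sorted(set(SCHEMA_COLUMNS) - set(df.columns))
            raise SchemaError(f"{name} table missing columns {missing}")
        if not (df["source"] == src).all():
            raise SchemaError(f"{name} table contains rows with source != {src!r}")
    trial = _namespace_school_ids(trial, "trial:")
    target = _namespace_school_ids(target, "survey:")
    stacked = pd.concat([trial, target], ignore_index=True, sort=False)
    stacked["S"] = np.concatenate([np.ones(len(trial), dtype=int), np.zeros(len(target), dtype=int)])
    logger.info("stacked %d trial + %d target rows for year %d", len(trial), len(target), year)
    return StackedDataset(records=stacked, year=int(year))


# ---------------------------------------------------------------------------
# validation and CSV round trip

def check_consistency(records: pd.DataFrame) -> pd.Series:
    """Flag records whose smoking answers contradict each other.

    A self-reported never-smoker whose age-at-first-cigarette is not
    'never' (or vice versa) is kept but flagged, mirroring the
    measurement error acknowledged for self-reported smoking.
    """
    status = records["smoking_status"]
    af = records["age_first_cig"]
    both = status.notna() & af.notna()
    flag = both & ((status == "never") != (af == "never"))
    return flag.rename("inconsistent_smoking")


def validate_records(records: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate (and in lenient mode clean) a harmonized record table.

    Strict mode raises on unknown category labels; lenient mode maps
    them to missing with a logged warning.  Row count is conserved.
    """
    n_in = len(records)
    out = records.copy()
    for col in SCHEMA_COLUMNS:
        if col not in out.columns:
            raise SchemaError(f"missing column {col!r}")
    for col, levels in CATEGORY_LEVELS.items():
        if col not in out.columns:
            continue
        vals = out[col]
        bad = vals.notna() & ~vals.isin(levels)
        if bad.any():
            labels = sorted(map(str, vals[bad].unique()))
            if strict:
                raise SchemaError(f"unknown levels in {col!r}: {labels}")
            logger.warning("mapping %d unknown %r values to missing: %s", int(bad.sum()), col, labels)
            out.loc[bad, col] = np.nan
    # applicability invariants
    tgt = out["source"] == "target"
    if out.loc[tgt, "arm"].notna().any():
        raise SchemaError("target rows must not carry a trial arm")
    if out.loc[tgt, "outcome_weekly"].notna().any():
        raise SchemaError("target rows must not carry a follow-up outcome")
    ages = out["age"].dropna().unique()
    if not set(ages) <= {12, 13}:
        raise SchemaError(f"ages {sorted(ages)} found; run recode_age first")
    assert len(out) == n_in, "validation must not drop rows"
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write a harmonized table as CSV (missing values as empty cells)."""
    cols = [c for c in SCHEMA_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in cols and c != "S"]
    records[cols + extra].to_csv(path, index=False)


def read_records(path, strict: bool = True) -> pd.DataFrame:
    """Read a harmonized CSV, validating against the data dictionary."""
    df = pd.read_csv(
        path,
        dtype={"school_id": str, "source": str},
        keep_default_na=True,
    )
    for col in ("age", "year"):
        if col in df.columns:
            df[col] = df[col].astype("Int64").astype("float").astype(object)
            df[col] = df[col].where(df[col].notna(), np.nan)
            df[col] = df[col].map(lambda v: int(v) if v == v else np.nan)
    if "outcome_weekly" in df.columns:
        df["outcome_weekly"] = pd.to_numeric(df["outcome_weekly"], errors="coerce")
    return validate_records(df, strict=strict)


DATA_DICTIONARY = {
    "source": "origin of the record: trial (cRCT) or target (survey wave)",
    "year": "survey year for target rows; trial follow-up year (2004) for trial rows",
    "school_id": "school cluster identifier, namespaced 'trial:' / 'survey:'",
    "arm": "randomized condition (trial rows only): control or intervention",
    "gender": "self-reported gender identity: boy or girl",
    "age": "age in years after harmonization: 12 or 13",
    "ethnicity": "collapsed ethnicity: white or minority",
    "smoking_status": "baseline smoking status: never / occ_exp_ex (occasional, experimental or ex-smoker) / weekly",
    "age_first_cig": "age first smoked a cigarette: never, le10 (10 or younger), y11, y12, y13",
    "lives_with_smoker": "lives with a smoker: yes or no (empty = missing, incl. routed questionnaires)",
    "lesson_smoking": "lesson on smoking in the past 12 months: yes, no or dont_know",
    "outcome_weekly": "weekly smoking at 2-year follow-up (trial rows only): 0 or 1",
    "country": "school stratification: england or wales (trial rows; surveys sample England only)",
    "school_type": "school stratification: state or independent",
    "sex_mix": "school stratification: mixed or single_sex",
    "language": "school stratification: english or welsh medium",
    "large_year_group": "school stratification: year group at or above the sampling-frame median",
    "fsm_high": "school stratification: free-school-meal entitlement above the national median",
}
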