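"""Subject-level case-control data: loading, validation, and analysis coding.

Turns raw questionnaire-style records (one row per subject) into the coded
analytic variables the association and attributable-fraction stages consume:
binary 0/1 exposure indicators, a continuous age covariate, and NaN for
missing values.  Two study-specific coding rules are applied here:

* exposures reported in the same calendar year as, or after, disease onset
  are censored to "no event" in cases (reverse-causality guard), and
* a head-injury indicator restricted to events more than 10 years before
  onset is derived alongside the raw indicator.

Censoring always recodes yes -> no; it never creates missingness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

YES, NO, MISSING = "yes", "no", "missing"
_TRISTATE = {YES, NO, MISSING}

CASE, CONTROL = "case", "control"
MALE, FEMALE = "male", "female"

#: analytic variable names produced by :func:`code_cohort`
CODED_VARIABLES = (
    "age",
    "family_history",
    "mtbi",
    "mtbi_10yr",
    "repeated_blows",
    "pesticide",
    "pesticide_duration",
    "military_chemicals",
    "constipation",
    "rbd",
    "weight_loss",
)


class SchemaError(ValueError):
    """A required column is absent or the column mapping is malformed."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


def _parse_tristate(value: object) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "missing"):
        return MISSING
    if s in ("yes", "y", "1", "true"):
        return YES
    if s in ("no", "n", "0", "false"):
        return NO
    raise ValueError(s)


def _parse_optional_number(value: object) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return None
    return float(s)


@dataclass
class SubjectRecord:
    """One study participant.

    Years may be given directly (``onset_year``, ``mtbi_event_year``,
    ``pesticide_start_year``) or derived from ages: when an absolute year is
    absent but ``survey_year`` and the relevant age are known, the year is
    reconstructed as ``survey_year - floor(age_years) + floor(event age)``.
    """

    subject_id: str
    status: str  # case | control
    sex: str  # male | female
    age_years: float | None = None
    onset_age_years: float | None = None
    survey_year: int | None = None
    onset_year: int | None = None
    family_history: str = MISSING  # positive | negative | unknown
    mtbi_event: str = MISSING
    mtbi_event_year: int | None = None
    repeated_blows_head: str = MISSING
    pesticide_exposure: str = MISSING
    pesticide_start_year: int | None = None
    pesticide_duration_years: float | None = None
    military_chemical_exposure: str = MISSING
    constipation: str = MISSING
    rbd: str = MISSING
    weight_loss: str = MISSING
    ethnicity_hispanic: str = MISSING
    race: str = MISSING
    spousal_pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise ValidationError(f"status must be case/control, got {self.status!r}")
        if self.sex not in (MALE, FEMALE):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.family_history not in ("positive", "negative", "unknown", MISSING):
            raise ValidationError(f"bad family_history {self.family_history!r}")
        for name in ("mtbi_event", "repeated_blows_head", "pesticide_exposure",
                     "military_chemical_exposure", "constipation", "rbd",
                     "weight_loss", "ethnicity_hispanic"):
            if getattr(self, name) not in _TRISTATE:
                raise ValidationError(f"bad {name} {getattr(self, name)!r}")
        if self.onset_age_years is not None:
            if self.status != CASE:
                raise ValidationError(
                    f"subject {self.subject_id}: onset age on a control record")
            if self.age_years is not None and self.onset_age_years > self.age_years:
                raise ValidationError(
                    f"subject {self.subject_id}: onset age exceeds survey age")
        if self.onset_year is not None and self.status != CASE:
            raise ValidationError(
                f"subject {self.subject_id}: onset year on a control record")
        if self.pesticide_duration_years is not None and self.pesticide_exposure != YES:
            raise ValidationError(
                f"subject {self.subject_id}: pesticide duration without exposure")

    @property
    def is_case(self) -> bool:
        return self.status == CASE

    def resolved_onset_year(self) -> int | None:
        """Onset year, reconstructed from ages when not given directly."""
        if self.onset_year is not None:
            return self.onset_year
        if (self.survey_year is not None and self.age_years is not None
                and self.onset_age_years is not None):
            birth = self.survey_year - math.floor(self.age_years)
            return birth + math.floor(self.onset_age_years)
        return None


# ---------------------------------------------------------------------------
# loading

def default_schema() -> dict[str, str]:
    """CSV column -> SubjectRecord field mapping shipped with the package."""
    text = resources.files("pafcc").joinpath("data/schema.yaml").read_text()
    doc = yaml.safe_load(text)
    return dict(doc["columns"])


_REQUIRED_FIELDS = ("subject_id", "status", "sex")

_TRISTATE_FIELDS = (
    "mtbi_event", "repeated_blows_head", "pesticide_exposure",
    "military_chemical_exposure", "constipation", "rbd", "weight_loss",
    "ethnicity_hispanic",
)
_NUMBER_FIELDS = (
    "age_years", "onset_age_years", "pesticide_duration_years",
)
_YEAR_FIELDS = ("survey_year", "onset_year", "mtbi_event_year", "pesticide_start_year")


def load_cohort(path: str | Path,
                schema: Mapping[str, str] | None = None) -> list[SubjectRecord]:
    """Read a subject-level CSV into validated :class:`SubjectRecord` rows.

    ``schema`` maps CSV column names to record field names; by default the
    identity mapping from ``data/schema.yaml`` is used.  Empty cells are
    missing.  Unparseable categorical cells are coerced to missing and the
    total is reported through the module logger.
    """
    schema = dict(schema) if schema is not None else default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    field_to_col = {f: c for c, f in schema.items()}
    for f in _REQUIRED_FIELDS:
        col = field_to_col.get(f, f)
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (field {f!r}) not in CSV")

    records: list[SubjectRecord] = []
    n_coerced = 0
    for _, row in df.iterrows():
        kw: dict[str, object] = {}
        for col in df.columns:
            f = schema.get(col, col)
            if f not in SubjectRecord.__dataclass_fields__:
                continue
            raw = row[col]
            if f in _TRISTATE_FIELDS:
                try:
                    kw[f] = _parse_tristate(raw)
                except ValueError:
                    kw[f] = MISSING
                    n_coerced += 1
            elif f in _NUMBER_FIELDS:
                kw[f] = _parse_optional_number(raw)
            elif f in _YEAR_FIELDS:
                v = _parse_optional_number(raw)
                kw[f] = int(v) if v is not None else None
            elif f == "family_history":
                s = str(raw).strip().lower()
                kw[f] = s if s in ("positive", "negative", "unknown") else MISSING
                if s not in ("positive", "negative", "unknown", "", "missing", "na", "nan"):
                    n_coerced += 1
            else:
                s = str(raw).strip()
                kw[f] = s if s != "" else (MISSING if f in ("race",) else None)
        if kw.get("spousal_pair_id") in ("", None):
            kw["spousal_pair_id"] = None
        kw.setdefault("race", MISSING)
        records.append(SubjectRecord(**kw))  # type: ignore[arg-type]

    if n_coerced:
        logger.warning("load_cohort: %d unparseable categorical cells coerced to missing",
                       n_coerced)

    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate subject_id values: {dup}")
    _check_spousal_pairs(records)
    return records


def _check_spousal_pairs(records: Sequence[SubjectRecord]) -> None:
    pairs: dict[str, list[SubjectRecord]] = {}
    for r in records:
        if r.spousal_pair_id is not None:
            pairs.setdefault(r.spousal_pair_id, []).append(r)
    for pid, members in pairs.items():
        statuses = sorted(m.status for m in members)
        if statuses != [CASE, CONTROL]:
            raise ValidationError(
                f"spousal pair {pid!r} must link exactly one case and one control")


# ---------------------------------------------------------------------------
# censoring & derivation

def apply_exposure_censoring(record: SubjectRecord) -> SubjectRecord:
    """Censor case exposures occurring at or after disease onset.

    For cases with a known onset year, a head-injury event or pesticide
    exposure whose event/start year is >= the onset year is recoded from yes
    to no (it cannot have contributed to disease).  Controls are returned
    unchanged.  Idempotent.
    """
    for flag, year in (("mtbi_event", record.mtbi_event_year),
                       ("pesticide_exposure", record.pesticide_start_year)):
        if year is not None and getattr(record, flag) == MISSING:
            raise ValidationError(
                f"subject {record.subject_id}: {flag} year given but flag missing")

    if not record.is_case:
        return record
    onset = record.resolved_onset_year()
    if onset is None:
        return record

    changes: dict[str, str] = {}
    if (record.mtbi_event == YES and record.mtbi_event_year is not None
            and record.mtbi_event_year >= onset):
        changes["mtbi_event"] = NO
    if (record.pesticide_exposure == YES and record.pesticide_start_year is not None
            and record.pesticide_start_year >= onset):
        changes["pesticide_exposure"] = NO
        changes["pesticide_duration_years"] = None  # type: ignore[assignment]
    return replace(record, **changes) if changes else record


def derive_mtbi_10yr(record: SubjectRecord) -> float:
    """Indicator for head injury more than 10 years before onset.

    Returns 1.0 iff the (already censored) event is yes and occurred strictly
    more than 10 years before onset; events within the 10-year window count
    as no event.  Controls keep their raw indicator (they have no onset).
    Missing propagates as NaN.
    """
    if record.mtbi_event == MISSING:
        return math.nan
    if record.mtbi_event == NO:
        return 0.0
    if not record.is_case:
        return 1.0
    onset = record.resolved_onset_year()
    if onset is None or record.mtbi_event_year is None:
        return math.nan
    return 1.0 if record.mtbi_event_year < onset - 10 else 0.0


# ---------------------------------------------------------------------------
# coded dataset

@dataclass
class CodedDataset:
    """Analysis-ready rows: status 0/1 plus named numeric covariates.

    Missing values are NaN.  ``stratum`` labels the subset (e.g. "male",
    "female/singletons") purely for reporting.
    """

    df: pd.DataFrame
    stratum: str = "all"

    def __post_init__(self) -> None:
        if "status" not in self.df.columns:
            raise ValidationError("CodedDataset requires a 'status' column")
        status = self.df["status"]
        if not status.isin([0, 1]).all():
            raise ValidationError("status must be coded 0 (control) / 1 (case)")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c != "status"]

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == 0).sum())

    def status_counts(self) -> tuple[int, int]:
        """(cases, controls) — the per-model "N with data"."""
        return self.n_cases, self.n_controls


def code_cohort(records: Iterable[SubjectRecord],
                sex: str | None = None,
                censor: bool = True,
                stratum: str | None = None) -> CodedDataset:
    """Code subject records into a :class:`CodedDataset`.

    Applies onset-year censoring (unless ``censor=False``), derives the
    10-year head-injury indicator, and maps the tri-state fields to 1/0/NaN.
    family_history "unknown" is treated as missing.  ``sex`` restricts to one
    stratum; the sexes are modeled separately downstream.
    """
    tri = {YES: 1.0, NO: 0.0, MISSING: math.nan}
    rows = []
    for rec in records:
        if sex is not None and rec.sex != sex:
            continue
        if censor:
            rec = apply_exposure_censoring(rec)
        fh = {"positive": 1.0, "negative": 0.0}.get(rec.family_history, math.nan)
        rows.append({
            "status": 1 if rec.is_case else 0,
            "age": rec.age_years if rec.age_years is not None else math.nan,
            "family_history": fh,
            "mtbi": tri[rec.mtbi_event],
            "mtbi_10yr": derive_mtbi_10yr(rec),
            "repeated_blows": tri[rec.repeated_blows_head],
            "pesticide": tri[rec.pesticide_exposure],
            "pesticide_duration": (rec.pesticide_duration_years
                                   if rec.pesticide_duration_years is not None
                                   else (0.0 if rec.pesticide_exposure == NO else math.nan)),
            "military_chemicals": tri[rec.military_chemical_exposure],
            "constipation": tri[rec.constipation],
            "rbd": tri[rec.rbd],
            "weight_loss": tri[rec.weight_loss],
        })
    df = pd.DataFrame(rows, columns=["status", *CODED_VARIABLES])
    return CodedDataset(df.reset_index(drop=True), stratum=stratum or (sex or "all"))


def complete_case_subset(dataset: CodedDataset,
                         variables: Sequence[str]) -> CodedDataset:
    """Rows with no missing value among ``variables`` (complete-case subset).

    The retained per-status counts — ``result.status_counts()`` — are the
    "N with data" reported alongside every test.
    """
    unknown = [v for v in variables if v not in dataset.df.columns]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    mask = dataset.df[list(variables)].notna().all(axis=1)
    return CodedDataset(dataset.df.loc[mask].reset_index(drop=True),
                        stratum=dataset.stratum)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x disease counts: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


def build_two_by_two(dataset: CodedDataset, exposure: str) -> TwoByTwoTable:
    """Cross-tabulate status against a binary exposure (no missing allowed)."""
    if exposure not in dataset.df.columns:
        raise KeyError(f"unknown exposure {exposure!r}")
    col = dataset.df[exposure]
    if col.isna().any():
        raise ValidationError(
            f"{exposure!r} has missing values; complete-case subset first")
    if not col.isin([0, 1]).all():
        raise ValidationError(f"{exposure!r} is not binary")
    status = dataset.df["status"]
    a = int(((status == 1) & (col == 1)).sum())
    b = int(((status == 1) & (col == 0)).sum())
    c = int(((status == 0) & (col == 1)).sum())
    d = int(((status == 0) & (col == 0)).sum())
    return TwoByTwoTable(a, b, c, d)


def write_coded_csv(dataset: CodedDataset, path: str | Path) -> None:
    """Write the coded analytic dataset to CSV for audit (empty = missing)."""
    dataset.df.to_csv(path, index=False)


def write_subject_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to the CSV schema read by :func:`load_cohort`.

    None and "missing" serialize to the empty string, so a written file
    round-trips through ``load_cohort`` unchanged.
    """
    fields = list(SubjectRecord.__dataclass_fields__)
    rows = []
    for r in records:
        row = {}
        for f in fields:
            v = getattr(r, f)
            row[f] = "" if v is None or v == MISSING else v
        rows.append(row)
    pd.DataFrame(rows, columns=fields).to_csv(path, index=False)
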