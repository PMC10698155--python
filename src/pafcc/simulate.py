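"""Synthetic case-control cohorts with known generative parameters.

Case-control sampling is emulated retrospectively: exposures are drawn
conditional on disease status, at prevalence p0 in controls and at the
implied case prevalence

    p1 = OR * p0 / (1 - p0 + OR * p0)

so the expected 2x2 cross-product ratio equals the specified OR.  Ages are
normal per status; per-variable missingness is applied independently; the
seed fully determines the output.  An optional interaction term generates a
pair of exposures from the joint Bernoulli model whose disease log-odds
include a product term — the alternative the interaction screen should
detect.

The default cohort dimensions mirror a sex-stratified study of roughly 800
cases and 400 controls; ``male_study_spec``/``female_study_spec`` preset the
published stratum sizes, exposure prevalences and odds ratios so every
analysis stage can be exercised against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, MISSING, NO, YES, CodedDataset, SubjectRecord

#: coded variable -> SubjectRecord tri-state field, for CSV round-trips
_RECORD_FIELDS = {
    "pesticide": "pesticide_exposure",
    "repeated_blows": "repeated_blows_head",
    "military_chemicals": "military_chemical_exposure",
    "mtbi": "mtbi_event",
    "family_history": "family_history",
    "constipation": "constipation",
    "rbd": "rbd",
    "weight_loss": "weight_loss",
}


@dataclass(frozen=True)
class ExposureSpec:
    """One binary exposure: control prevalence and true odds ratio."""

    name: str
    control_prevalence: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.control_prevalence < 1:
            raise ValueError("control prevalence must be in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic case-control cohort."""

    n_cases: int = 808
    n_controls: int = 415
    exposures: tuple[ExposureSpec, ...] = (
        ExposureSpec("pesticide", 0.15, 2.41),
    )
    #: (control mean, case mean, shared SD), years
    age_model: tuple[float, float, float] = (68.2, 68.8, 9.0)
    #: optional ((name_a, name_b), interaction log-OR)
    interaction: tuple[tuple[str, str], float] | None = None
    #: per-variable missingness probability
    missingness: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        names = [e.name for e in self.exposures]
        if len(set(names)) != len(names):
            raise ValueError("exposure names must be distinct")
        for p in self.missingness.values():
            if not 0 <= p < 1:
                raise ValueError("missingness probabilities must be in [0,1)")
        if self.interaction is not None:
            (a, b), _ = self.interaction
            if a not in names or b not in names:
                raise ValueError("interaction pair must name defined exposures")


def implied_case_prevalence(p0: float, or_value: float) -> float:
    """Exposure prevalence among cases implied by (p0, OR)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0,1)")
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return or_value * p0 / (1 - p0 + or_value * p0)


def male_study_spec(seed: int = 0) -> CohortSpec:
    """Male-stratum-like cohort: three risk factors at published p0/OR."""
    return CohortSpec(
        n_cases=512, n_controls=125,
        exposures=(
            ExposureSpec("pesticide", 0.15, 2.41),
            ExposureSpec("repeated_blows", 0.11, 2.31),
            ExposureSpec("military_chemicals", 0.02, 3.78),
        ),
        age_model=(68.2, 68.8, 9.0),
        seed=seed,
    )


def female_study_spec(seed: int = 0) -> CohortSpec:
    """Female-stratum-like cohort: pesticide exposure at published p0/OR."""
    return CohortSpec(
        n_cases=296, n_controls=290,
        exposures=(ExposureSpec("pesticide", 0.14, 3.26),),
        age_model=(65.3, 67.5, 8.6),
        seed=seed,
    )


def _sample_interacting_pair(rng: np.random.Generator, spec: CohortSpec,
                             status: np.ndarray) -> dict[str, np.ndarray]:
    (name_a, name_b), gamma = spec.interaction  # type: ignore[misc]
    ex = {e.name: e for e in spec.exposures}
    ea, eb = ex[name_a], ex[name_b]
    # control joint: independent Bernoulli; case joint tilted by the disease
    # log-odds beta_a*xa + beta_b*xb + gamma*xa*xb (retrospective sampling)
    cells = np.array([(0, 0), (1, 0), (0, 1), (1, 1)])
    p_ctl = np.array([
        (ea.control_prevalence if xa else 1 - ea.control_prevalence)
        * (eb.control_prevalence if xb else 1 - eb.control_prevalence)
        for xa, xb in cells
    ])
    tilt = np.array([
        math.exp(math.log(ea.odds_ratio) * xa + math.log(eb.odds_ratio) * xb
                 + gamma * xa * xb)
        for xa, xb in cells
    ])
    p_case = p_ctl * tilt
    p_case /= p_case.sum()
    out_a = np.empty(len(status))
    out_b = np.empty(len(status))
    for value, probs in ((1, p_case), (0, p_ctl)):
        idx = np.flatnonzero(status == value)
        draws = rng.choice(4, size=len(idx), p=probs)
        out_a[idx] = cells[draws, 0]
        out_b[idx] = cells[draws, 1]
    return {name_a: out_a, name_b: out_b}


def generate_cohort(spec: CohortSpec) -> CodedDataset:
    """Sample a coded case-control dataset from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    status = np.concatenate([np.ones(spec.n_cases, dtype=int),
                             np.zeros(spec.n_controls, dtype=int)])

    cols: dict[str, np.ndarray] = {"status": status}
    ctl_mean, case_mean, sd = spec.age_model
    means = np.where(status == 1, case_mean, ctl_mean)
    cols["age"] = rng.normal(means, sd)

    pair_names: set[str] = set()
    if spec.interaction is not None:
        pair_cols = _sample_interacting_pair(rng, spec, status)
        pair_names = set(pair_cols)
        cols.update(pair_cols)
    for e in spec.exposures:
        if e.name in pair_names:
            continue
        p1 = implied_case_prevalence(e.control_prevalence, e.odds_ratio)
        prob = np.where(status == 1, p1, e.control_prevalence)
        cols[e.name] = (rng.random(n) < prob).astype(float)

    df = pd.DataFrame(cols)
    for var, rate in spec.missingness.items():
        if var not in df.columns or var == "status":
            raise ValueError(f"missingness names unknown variable {var!r}")
        mask = rng.random(n) < rate
        df.loc[mask, var] = np.nan
    return CodedDataset(df, stratum="synthetic")


def make_separated_cohort(n: int = 20, seed: int = 0) -> CodedDataset:
    """A cohort with a zero exposed-control cell (quasi-complete separation).

    Every exposed subject is a case, so the unpenalized exposure coefficient
    diverges while a Firth fit stays finite — the canonical stress case for
    the penalty.
    """
    if n < 8:
        raise ValueError("need n >= 8")
    rng = np.random.default_rng(seed)
    n_cases = n // 2
    status = np.concatenate([np.ones(n_cases, dtype=int),
                             np.zeros(n - n_cases, dtype=int)])
    exposure = np.zeros(n)
    exposure[: max(2, n_cases // 2)] = 1.0  # exposed cases only
    age = rng.normal(np.where(status == 1, 68.8, 68.2), 9.0)
    df = pd.DataFrame({"status": status, "age": age, "exposure": exposure})
    return CodedDataset(df, stratum="separated")


def generate_subject_records(spec: CohortSpec, sex: str = "male",
                             survey_year: int = 2019) -> list[SubjectRecord]:
    """Sample a cohort and express it as subject-level records.

    Exposure names must be coded variables with a subject-level field
    (pesticide, repeated_blows, ...).  Written with
    :func:`pafcc.cohort.write_subject_csv`, the records round-trip through
    ``load_cohort`` + ``code_cohort`` to the same coded values.
    """
    unknown = [e.name for e in spec.exposures if e.name not in _RECORD_FIELDS]
    if unknown:
        raise ValueError(f"no subject-level field for exposure(s) {unknown}")
    ds = generate_cohort(spec)
    records = []
    for i, row in ds.df.iterrows():
        kw: dict[str, object] = {
            "subject_id": f"S{i:05d}",
            "status": CASE if row["status"] == 1 else CONTROL,
            "sex": sex,
            "age_years": round(float(row["age"]), 1) if not math.isnan(row["age"]) else None,
            "survey_year": survey_year,
        }
        for e in spec.exposures:
            v = row[e.name]
            if e.name == "family_history":
                kw["family_history"] = (
                    MISSING if math.isnan(v)
                    else ("positive" if v == 1 else "negative"))
            else:
                kw[_RECORD_FIELDS[e.name]] = (
                    MISSING if math.isnan(v) else (YES if v == 1 else NO))
        records.append(SubjectRecord(**kw))  # type: ignore[arg-type]
    return records
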