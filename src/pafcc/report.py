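"""End-to-end analysis pipeline and table rendering.

Reproduces the staged structure of a risk-factor study report from a
subject-level CSV (or a synthetic cohort spec): per sex stratum,

(a) univariable one-sided odds ratios for every risk factor, each on its own
    complete-case subset ("N with data"),
(b) multivariable adjusted odds ratios on the joint complete-case subset,
    auto-switching to the Firth penalty on separation,
(c) adjusted Miettinen PAFs for the modifiable factors, and a joint PAF
    gated by the pairwise interaction screen,

plus a descriptive feature table (continuity-corrected Woolf odds ratios).
All results serialize to TSV and deterministic JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import association as assoc
from . import paf as paf_mod
from .cohort import (CodedDataset, build_two_by_two, code_cohort,
                     complete_case_subset, load_cohort)
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The analysis configuration references variables absent from the data."""


@dataclass(frozen=True)
class StratumModel:
    """Model definition for one sex stratum."""

    name: str
    sex: str | None
    risk_factors: tuple[str, ...]
    covariates: tuple[str, ...]  # multivariable adjustment set
    modifiable: tuple[str, ...]  # factors carried into PAF


#: shipped defaults mirroring the sex-specific multivariable models:
#: males adjust for age, family history, head injury (both forms),
#: pesticides and military chemicals; females lack the two male-only
#: exposures (no exposed females).
DEFAULT_STRATA = (
    StratumModel(
        name="male", sex="male",
        risk_factors=("age", "family_history", "mtbi", "mtbi_10yr",
                      "repeated_blows", "pesticide", "military_chemicals"),
        covariates=("age", "family_history", "mtbi", "repeated_blows",
                    "pesticide", "military_chemicals"),
        modifiable=("repeated_blows", "pesticide", "military_chemicals"),
    ),
    StratumModel(
        name="female", sex="female",
        risk_factors=("age", "family_history", "mtbi", "mtbi_10yr", "pesticide"),
        covariates=("age", "family_history", "mtbi", "pesticide"),
        modifiable=("pesticide",),
    ),
)

DEFAULT_FEATURES = ("constipation", "rbd", "weight_loss")


@dataclass
class AnalysisConfig:
    """Input, stratification, models and thresholds for a full run."""

    input: str | Path | CohortSpec
    strata: tuple[StratumModel, ...] = DEFAULT_STRATA
    features: tuple[str, ...] = DEFAULT_FEATURES
    interaction_alpha: float = 0.05
    ci_level: float = 0.95
    out_dir: str | Path | None = None
    seed: int = 0


def _or_row(r: assoc.ORResult) -> dict:
    return {
        "term": r.term, "or": r.or_point, "ci_low": r.ci_low,
        "ci_high": None if math.isinf(r.ci_high) else r.ci_high,
        "p": r.p_value, "method": r.method,
        "n_cases": r.n_cases, "n_controls": r.n_controls,
    }


def _paf_row(r: paf_mod.PAFResult) -> dict:
    return {
        "exposure": r.exposure, "adj_or": r.rr, "prev_in_cases": r.p_c,
        "paf": r.paf, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "adjusted": r.adjusted,
    }


def _load_dataset(config: AnalysisConfig, stratum: StratumModel) -> CodedDataset:
    if isinstance(config.input, CohortSpec):
        spec = dataclasses.replace(config.input, seed=config.seed)
        ds = generate_cohort(spec)
        return CodedDataset(ds.df, stratum=stratum.name)
    records = load_cohort(config.input)
    return code_cohort(records, sex=stratum.sex, stratum=stratum.name)


def analyze_stratum(dataset: CodedDataset, model: StratumModel,
                    interaction_alpha: float = 0.05,
                    ci_level: float = 0.95) -> dict:
    """Run stages (a)-(c) on one coded stratum; returns a JSON-able dict."""
    missing = [v for v in (*model.risk_factors, *model.covariates)
               if v not in dataset.df.columns]
    if missing:
        raise ConfigurationError(
            f"stratum {model.name!r}: variable(s) {missing} not in data")

    out: dict = {"stratum": model.name, "n_with_data": {}}

    univariable = []
    for factor in model.risk_factors:
        sub = complete_case_subset(dataset, [factor])
        out["n_with_data"][factor] = list(sub.status_counts())
        try:
            fit = assoc.fit_auto(sub, assoc.ModelSpec(covariates=(factor,)))
            univariable.append(_or_row(assoc.one_sided_wald_summary(fit, factor)))
        except ValueError as err:
            logger.warning("stratum %s, factor %s: not testable (%s)",
                           model.name, factor, err)
            univariable.append({"term": factor, "not_testable": True,
                                "reason": str(err)})
    out["univariable"] = univariable

    sub = complete_case_subset(dataset, model.covariates)
    out["n_with_data"]["multivariable"] = list(sub.status_counts())
    mspec = assoc.ModelSpec(covariates=model.covariates)
    try:
        fit = assoc.fit_auto(sub, mspec)
        fit.require_converged()
    except (ValueError, assoc.ConvergenceError) as err:
        raise RuntimeError(
            f"stratum {model.name!r}, stage multivariable: {err}") from err
    out["adjusted"] = [_or_row(assoc.one_sided_wald_summary(fit, t))
                       for t in model.covariates]
    out["penalty_used"] = fit.penalty

    try:
        out["paf"] = [
            _paf_row(paf_mod.adjusted_paf(sub, mspec, f, level=ci_level))
            for f in model.modifiable
        ]
    except (ValueError, assoc.ConvergenceError) as err:
        raise RuntimeError(f"stratum {model.name!r}, stage paf: {err}") from err
    if len(model.modifiable) >= 2:
        joint = paf_mod.joint_adjusted_paf(sub, mspec, model.modifiable,
                                           threshold=interaction_alpha,
                                           level=ci_level)
        out["joint_paf"] = {
            "joint_paf": joint.joint_paf, "ci_low": joint.ci_low,
            "ci_high": joint.ci_high,
            "interaction_checked": joint.interaction_checked,
            "interaction_pvalues": list(joint.interaction_pvalues),
        }
    return out


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stratum and optionally write TSV/JSON/text artifacts."""
    bundle: dict = {"seed": config.seed, "strata": {}}
    for model in config.strata:
        dataset = _load_dataset(config, model)
        logger.info("stratum %s: %d cases / %d controls loaded",
                    model.name, dataset.n_cases, dataset.n_controls)
        bundle["strata"][model.name] = analyze_stratum(
            dataset, model, interaction_alpha=config.interaction_alpha,
            ci_level=config.ci_level)

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(to_json(bundle))
        for name, res in bundle["strata"].items():
            pd.DataFrame(res["univariable"]).to_csv(
                out_dir / f"{name}_univariable.tsv", sep="\t", index=False)
            pd.DataFrame(res["adjusted"]).to_csv(
                out_dir / f"{name}_adjusted.tsv", sep="\t", index=False)
            if res["paf"]:
                pd.DataFrame(res["paf"]).to_csv(
                    out_dir / f"{name}_paf.tsv", sep="\t", index=False)
        (out_dir / "report.txt").write_text(render_text_report(bundle))
        manifest = {
            "seed": config.seed,
            "strata": {n: r["n_with_data"] for n, r in bundle["strata"].items()},
            "penalties": {n: r["penalty_used"] for n, r in bundle["strata"].items()},
        }
        (out_dir / "manifest.json").write_text(to_json(manifest))
    return bundle


def to_json(obj: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(obj, sort_keys=True, indent=1, allow_nan=True)


# ---------------------------------------------------------------------------
# rendering

def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def render_feature_table(dataset: CodedDataset,
                         features: Sequence[str] = DEFAULT_FEATURES
                         ) -> pd.DataFrame:
    """Descriptive feature table with corrected Woolf odds ratios.

    One row per feature: per-status N with data, positive counts and
    percentages, OR with two-sided 95% CI and p.  Features with no positives
    in either group are flagged not testable.
    """
    rows = []
    for feat in features:
        sub = complete_case_subset(dataset, [feat])
        table = build_two_by_two(sub, feat)
        row: dict = {
            "feature": feat,
            "n_cases": table.n_cases, "n_controls": table.n_controls,
            "cases_positive": table.a,
            "cases_pct": _round_half_away(100 * table.a / table.n_cases, 0)
            if table.n_cases else math.nan,
            "controls_positive": table.c,
            "controls_pct": _round_half_away(100 * table.c / table.n_controls, 0)
            if table.n_controls else math.nan,
        }
        if table.a == 0 and table.c == 0:
            row.update({"or": math.nan, "ci_low": math.nan,
                        "ci_high": math.nan, "p": math.nan,
                        "not_testable": True})
        else:
            r = assoc.corrected_or_woolf(table)
            row.update({"or": _round_half_away(r.or_point, 1),
                        "ci_low": _round_half_away(r.ci_low, 1),
                        "ci_high": _round_half_away(r.ci_high, 1),
                        "p": r.p_value, "not_testable": False})
        rows.append(row)
    return pd.DataFrame(rows)


def render_text_report(bundle: dict) -> str:
    """Plain-text rendering of a full-analysis bundle."""
    lines: list[str] = []
    for name, res in bundle["strata"].items():
        lines.append(f"=== Stratum: {name} ===")
        lines.append("-- (a) univariable (one-sided) --")
        lines.append(pd.DataFrame(res["univariable"]).to_string(index=False))
        lines.append("-- (b) multivariable adjusted "
                     f"(penalty: {res['penalty_used']}) --")
        lines.append(pd.DataFrame(res["adjusted"]).to_string(index=False))
        if res["paf"]:
            lines.append("-- (c) attributable fractions --")
            lines.append(pd.DataFrame(res["paf"]).to_string(index=False))
        if "joint_paf" in res:
            j = res["joint_paf"]
            gate = "passed" if j["interaction_checked"] else "FAILED"
            lines.append(
                f"joint PAF = {j['joint_paf']:.3f} "
                f"[{j['ci_low']:.3f}, {j['ci_high']:.3f}] "
                f"(interaction screen {gate})")
        lines.append("")
    return "\n".join(lines)
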