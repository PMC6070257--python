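"""End-to-end cohort analysis.

Reads and validates a cohort table, applies the sequential exclusion
accounting (shuttle score → BMI inputs → waist → screen time →
physical activity), scores the shuttle run, derives obesity labels,
and runs the cut-point and association analysis per
(sex × age × outcome × metric) stratum, emitting report tables that
mirror the usual descriptive / diagnostic-properties / odds-ratio
layout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anthro import EmpiricalZScorer, LmsZScorer, ObesityLabeler, compute_bmi, \
    consolidate_repeats, RepeatMeasure, IncompleteMeasurementError
from .association import LogisticOddsModel, SeparationError, cohens_d, cramers_v
from .roc import CutpointClassifier, DegenerateOutcomeError, compare_aucs_delong
from .scoring import ShuttleRunScorer

logger = logging.getLogger("shuttlefit")

__all__ = ["AnalysisReport", "read_cohort", "run_analysis", "write_report"]

BASE_COLUMNS = ("id", "age", "sex", "laps", "screen_time", "mvpa", "site")
METRICS = ("vo2_leger", "vo2_fitnessgram", "laps_20m", "speed")
OUTCOMES = {"bmi": "bmi_obese", "wc": "wc_obese", "combined": "combined_obese"}
POOLED = "8-12"


@dataclass
class AnalysisReport:
    descriptive: pd.DataFrame
    cutpoints: pd.DataFrame
    delong: pd.DataFrame
    odds_ratios: pd.DataFrame
    warnings: list = field(default_factory=list)


def _consolidate_column(df: pd.DataFrame, stem: str) -> pd.Series:
    """Collapse <stem>_1/_2[/_3] repeat readings to one value (NaN if unusable)."""
    cols = [c for c in (f"{stem}_1", f"{stem}_2", f"{stem}_3") if c in df.columns]
    out = []
    for _, row in df[cols].iterrows():
        readings = tuple(v for v in row if pd.notna(v))
        if len(readings) < 2:
            out.append(np.nan)
            continue
        try:
            out.append(consolidate_repeats(RepeatMeasure(readings)))
        except IncompleteMeasurementError:
            out.append(np.nan)
    return pd.Series(out, index=df.index)


def read_cohort(path, require_covariates: bool = True):
    """Read a cohort CSV and apply the sequential exclusions.

    Adiposity may arrive as precomputed ``bmi_z``/``wc_z`` columns, as
    single ``height``/``mass``/``waist`` measurements, or as duplicate
    readings ``height_1``, ``height_2`` (optional ``height_3``) etc.,
    which are consolidated by the closest-pair rule.

    Returns (records, exclusion_log).  Exclusions are counted in order:
    shuttle score, BMI inputs, waist inputs, screen time, physical
    activity — each count is among records surviving the prior steps.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("id", "age", "sex", "laps") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")

    for stem in ("height", "mass", "waist"):
        if f"{stem}_1" in df.columns and stem not in df.columns:
            df[stem] = _consolidate_column(df, stem)

    has_z = "bmi_z" in df.columns and "wc_z" in df.columns
    n0 = len(df)
    log: dict[str, int] = {}

    ineligible = ~df["age"].between(8, 12)
    if ineligible.any():
        log["age_eligibility"] = int(ineligible.sum())
        df = df[~ineligible]

    ok = df["laps"].notna()
    log["20mSRT"] = int((~ok).sum())
    df = df[ok]

    if has_z:
        ok = df["bmi_z"].notna()
    else:
        ok = df["height"].notna() & df["mass"].notna()
    log["BMI"] = int((~ok).sum())
    df = df[ok]

    ok = df["wc_z"].notna() if has_z else df["waist"].notna()
    log["WC"] = int((~ok).sum())
    df = df[ok]

    if require_covariates:
        for name, col in (("screen_time", "screen_time"), ("physical_activity", "mvpa")):
            if col in df.columns:
                ok = df[col].notna()
                log[name] = int((~ok).sum())
                df = df[ok]

    logger.info("read %d records, kept %d after exclusions %s", n0, len(df), log)
    return df.reset_index(drop=True).copy(), log


def _derive(records: pd.DataFrame, conversion=None, lms_table=None) -> pd.DataFrame:
    """Attach shuttle metrics, z-scores and obesity labels."""
    df = ShuttleRunScorer(conversion=conversion).fit(records).transform(records)
    if "bmi_z" not in df.columns:
        df["bmi"] = [compute_bmi(m, h) for m, h in zip(df["mass"], df["height"])]
        if lms_table is not None:
            df = LmsZScorer(table=lms_table, column="bmi").fit(df).transform(df)
        else:
            df = EmpiricalZScorer(columns=("bmi",)).fit(df).transform(df)
    if "wc_z" not in df.columns:
        df = (
            EmpiricalZScorer(columns=("waist",)).fit(df).transform(df)
            .rename(columns={"waist_z": "wc_z"})
        )
    return ObesityLabeler().fit(df).transform(df)


def _strata(df: pd.DataFrame):
    for sex in sorted(df["sex"].unique()):
        sub_sex = df[df.sex == sex]
        for age in [*sorted(sub_sex["age"].unique()), POOLED]:
            yield sex, age, sub_sex if age == POOLED else sub_sex[sub_sex.age == age]


def run_analysis(
    records: pd.DataFrame,
    conversion=None,
    lms_table=None,
    criterion: str = "youden",
    or_outcome: str = "bmi",
    covariates: tuple[str, ...] = ("age", "site", "screen_time", "mvpa"),
) -> AnalysisReport:
    """Full cut-point and association analysis.

    Per sex × (each age and the pooled 8–12 sample) × outcome × metric:
    AUC with DeLong CI and discrimination band, the optimal cut-point
    and its diagnostic properties; a DeLong comparison of the two
    V̇O2peak equations per stratum; and crude plus adjusted odds ratios
    for the low-fitness indicator built from the age-and-sex-specific
    and the sex-specific cut-point families.  Single-class strata are
    skipped with a logged warning, never silently.
    """
    df = _derive(records, conversion=conversion, lms_table=lms_table)
    warns: list[str] = []
    rows, dl_rows = [], []

    for sex, age, sub in _strata(df):
        for outcome, label_col in OUTCOMES.items():
            y = sub[label_col].to_numpy()
            if y.all() or not y.any():
                msg = f"stratum sex={sex} age={age} outcome={outcome}: single class, skipped"
                warns.append(msg)
                logger.warning(msg)
                continue
            for metric in METRICS:
                clf = CutpointClassifier(criterion=criterion).fit(sub[metric], y)
                d = clf.diagnostics_
                rows.append({
                    "sex": sex, "age": str(age), "outcome": outcome, "metric": metric,
                    "n": len(sub), "n_obese": int(y.sum()),
                    "auc": clf.auc_.auc, "auc_se": clf.auc_.se,
                    "auc_lo": clf.auc_.ci95[0], "auc_hi": clf.auc_.ci95[1],
                    "band": clf.auc_.effect_band,
                    "cutpoint": clf.cutpoint_,
                    "cutpoint_mets": clf.cutpoint_ / 3.5 if metric.startswith("vo2") else np.nan,
                    "sens": d.sens, "sens_lo": d.sens_ci[0], "sens_hi": d.sens_ci[1],
                    "spec": d.spec, "spec_lo": d.spec_ci[0], "spec_hi": d.spec_ci[1],
                    "ppv": d.ppv, "npv": d.npv,
                    "lr_pos": d.lr_pos, "lr_neg": d.lr_neg,
                })
            try:
                cmp = compare_aucs_delong(
                    sub["vo2_leger"], sub["vo2_fitnessgram"], y
                )
            except DegenerateOutcomeError as exc:
                msg = (f"stratum sex={sex} age={age} outcome={outcome}: "
                       f"DeLong comparison skipped ({exc})")
                warns.append(msg)
                logger.warning(msg)
                continue
            dl_rows.append({
                "sex": sex, "age": str(age), "outcome": outcome,
                "auc_leger": cmp.auc_a, "auc_fitnessgram": cmp.auc_b,
                "difference": cmp.difference, "se_diff": cmp.se_diff,
                "z": cmp.z, "p": cmp.p,
            })

    cutpoints = pd.DataFrame(rows)
    delong = pd.DataFrame(dl_rows)
    odds = _odds_ratio_table(df, cutpoints, or_outcome, covariates, warns)
    return AnalysisReport(
        descriptive=_descriptive_table(df),
        cutpoints=cutpoints,
        delong=delong,
        odds_ratios=odds,
        warnings=warns,
    )


def _low_crf_flag(df, cutpoints, metric, outcome, family):
    """Low-fitness indicator from a fitted cut-point family.

    family="age_sex" uses each child's (sex, age) cut-point;
    family="sex" uses the pooled 8–12 cut-point of the child's sex.
    """
    sel = cutpoints[(cutpoints.metric == metric) & (cutpoints.outcome == outcome)]
    flag = pd.Series(np.nan, index=df.index)
    for _, row in sel.iterrows():
        if family == "age_sex" and row["age"] == POOLED:
            continue
        if family == "sex" and row["age"] != POOLED:
            continue
        if family == "age_sex":
            mask = (df.sex == row.sex) & (df.age.astype(str) == row.age)
        else:
            mask = df.sex == row.sex
        flag[mask] = (df.loc[mask, metric] <= row.cutpoint).astype(float)
    return flag


def _odds_ratio_table(df, cutpoints, outcome, covariates, warns):
    rows = []
    if cutpoints.empty:
        return pd.DataFrame(rows)
    label_col = OUTCOMES[outcome]
    for metric in METRICS:
        for family in ("age_sex", "sex"):
            flag = _low_crf_flag(df, cutpoints, metric, outcome, family)
            for sex in sorted(df.sex.unique()):
                sub = df[(df.sex == sex) & flag.notna()].copy()
                sub["low_crf"] = flag[sub.index]
                y = sub[label_col].to_numpy()
                for adjusted in (False, True):
                    covs = tuple(covariates) if adjusted else ()
                    try:
                        model = LogisticOddsModel(
                            exposure="low_crf", covariates=covs
                        ).fit(sub, y)
                    except (SeparationError, ValueError) as exc:
                        warns.append(
                            f"OR model sex={sex} metric={metric} family={family} "
                            f"adjusted={adjusted}: {exc}"
                        )
                        continue
                    rows.append({
                        "sex": sex, "metric": metric, "outcome": outcome,
                        "cutpoint_family": family,
                        "adjusted": adjusted,
                        "or": model.or_.or_value,
                        "ci_lo": model.or_.ci95[0], "ci_hi": model.or_.ci95[1],
                        "n": len(sub),
                    })
    return pd.DataFrame(rows)


def _descriptive_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    boys, girls = df[df.sex == "M"], df[df.sex == "F"]
    continuous = [c for c in (
        "age", "screen_time", "mvpa", "bmi", "waist", "laps_20m",
        "vo2_leger", "vo2_fitnessgram", "mets_leger", "mets_fitnessgram",
    ) if c in df.columns]
    for col in continuous:
        m_b, s_b = boys[col].mean(), boys[col].std(ddof=1)
        m_g, s_g = girls[col].mean(), girls[col].std(ddof=1)
        rows.append({
            "variable": col, "kind": "continuous",
            "all_mean": df[col].mean(), "all_sd": df[col].std(ddof=1),
            "boys_mean": m_b, "boys_sd": s_b,
            "girls_mean": m_g, "girls_sd": s_g,
            "effect_size": cohens_d(m_b, s_b, m_g, s_g)
            if s_b > 0 and s_g > 0 else np.nan,
        })
    for name, col in (("obesity_bmi", "bmi_obese"), ("obesity_wc", "wc_obese"),
                      ("obesity_combined", "combined_obese")):
        tab = np.array([
            [int((~boys[col]).sum()), int(boys[col].sum())],
            [int((~girls[col]).sum()), int(girls[col].sum())],
        ])
        rows.append({
            "variable": name, "kind": "categorical",
            "all_mean": df[col].mean(), "all_sd": np.nan,
            "boys_mean": boys[col].mean(), "boys_sd": np.nan,
            "girls_mean": girls[col].mean(), "girls_sd": np.nan,
            "effect_size": cramers_v(tab) if tab.min() > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# per-column rounding policy for the CSV reports (raw values stay in JSON)
_ROUNDING = {
    "auc": 2, "auc_se": 3, "auc_lo": 2, "auc_hi": 2,
    "cutpoint": 1, "cutpoint_mets": 1,
    "sens": 3, "sens_lo": 3, "sens_hi": 3,
    "spec": 3, "spec_lo": 3, "spec_hi": 3,
    "ppv": 3, "npv": 3, "lr_pos": 1, "lr_neg": 1,
    "or": 1, "ci_lo": 1, "ci_hi": 1,
    "difference": 3, "se_diff": 4, "z": 2, "p": 4,
    "auc_leger": 2, "auc_fitnessgram": 2,
}


def write_report(report: AnalysisReport, outdir) -> dict[str, Path]:
    """Write CSVs (rounded per the reporting policy) and a raw JSON bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(df: pd.DataFrame, name: str):
        rounded = df.copy()
        for col, nd in _ROUNDING.items():
            if col in rounded.columns:
                rounded[col] = rounded[col].round(nd)
        path = outdir / f"{name}.csv"
        rounded.to_csv(path, index=False)
        files[name] = path

    _write(report.descriptive, "table1_descriptive")
    _write(report.cutpoints, "cutpoints")
    _write(report.delong, "delong")
    _write(report.odds_ratios, "table6_odds_ratios")

    bundle = {
        "descriptive": report.descriptive.to_dict(orient="records"),
        "cutpoints": report.cutpoints.to_dict(orient="records"),
        "delong": report.delong.to_dict(orient="records"),
        "odds_ratios": report.odds_ratios.to_dict(orient="records"),
        "warnings": report.warnings,
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(bundle, indent=1, sort_keys=True, default=str))
    files["report"] = path
    return files
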