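"""End-to-end validation study: data in, agreement analyses out.

:class:`FatMassStudy` is the model object: it is built from a participant
table (CSV or DataFrame, one row per subject), validates the schema, applies
the study's inclusion filters, and holds the per-subject measurement records.
``fit()`` computes everything the validation design calls for and returns a
:class:`StudyResults`:

* per-subject FM% under the three methods (4C reference, Evans equation with
  caliper skinfolds, Evans equation with doubled-US skinfolds);
* a per-sex mean ± SD characteristics table;
* two full agreement analyses (each alternative vs the 4C reference): paired
  t, Bland–Altman bias/limits of agreement with the proportional-bias trend,
  and Lin's CCC with its strength class;
* the per-sex, per-site compressibility-ratio summary (mean of per-subject
  skinfold ÷ raw-US ratios);
* three nested OLS regressions of caliper skinfold on raw US thickness
  (pooled over sites, one observation per subject × site): raw US only,
  + site, + site + gender — plus per-site and per-gender stratified fits.

Results serialize to a versioned JSON report and round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementReport,
    CCCClass,
    R2Class,
    RegressionReport,
    agreement_report,
    regression_with_covariates,
)
from .cohort import SyntheticCohort, TABLE1_GROUPS
from .equations import (
    SITES,
    ParticipantRecord,
    estimate_all,
    evans_fm_percent,
    four_component_inputs_from_record,
)
from .exceptions import DegenerateInputError, InvalidInputError

REPORT_SCHEMA_VERSION = "1"

REQUIRED_COLUMNS = (
    "id", "sex", "body_mass_kg", "stature_cm",
    "skf_triceps_mm", "skf_abdominal_mm", "skf_thigh_mm",
    "us_triceps_mm", "us_abdominal_mm", "us_thigh_mm",
    "dxa_fat_pct", "lean_soft_mass_kg", "bmc_kg", "resistance_ohm",
)

_NESTED_MODELS = ("raw_us", "raw_us+site", "raw_us+site+gender")


# --------------------------------------------------------------------------- #
# Input handling
# --------------------------------------------------------------------------- #

def _records_from_frame(data: pd.DataFrame,
                        race_default: str) -> tuple[list[ParticipantRecord], list[str]]:
    """Validate the table and build records; collect per-row/column errors."""
    errors: list[str] = []
    notes: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise InvalidInputError(f"missing required columns: {missing}")
    if "race" not in data.columns or data["race"].isna().all():
        notes.append(f"race column absent or empty; default {race_default!r} applied")

    records: list[ParticipantRecord] = []
    for idx, row in data.iterrows():
        row_errors: list[str] = []
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            row_errors.append(f"sex: expected M or F, got {row['sex']!r}")
        race = row.get("race")
        if race is None or (isinstance(race, float) and math.isnan(race)) or str(race).strip() == "":
            race = race_default
        race = str(race).strip().lower()
        if race not in ("white", "black"):
            row_errors.append(f"race: expected white or black, got {race!r}")
        values: dict[str, float] = {}
        for col in REQUIRED_COLUMNS:
            if col in ("id", "sex"):
                continue
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                row_errors.append(f"{col}: not numeric ({row[col]!r})")
        if row_errors:
            errors.extend(f"row {idx} (id={row.get('id')!r}): {e}" for e in row_errors)
            continue
        try:
            records.append(ParticipantRecord(
                id=str(row["id"]),
                sex_code_evans=0 if sex == "M" else 1,
                sex_code_tbw=1 if sex == "M" else 0,
                race_code=0 if race == "white" else 1,
                body_mass=values["body_mass_kg"],
                stature=values["stature_cm"],
                skinfold_mm={s: values[f"skf_{s}_mm"] for s in SITES},
                us_thickness_mm={s: values[f"us_{s}_mm"] for s in SITES},
                dxa_fat_pct=values["dxa_fat_pct"],
                lean_soft_mass=values["lean_soft_mass_kg"],
                bone_mineral_content=values["bmc_kg"],
                resistance=values["resistance_ohm"],
            ))
        except InvalidInputError as exc:
            errors.append(f"row {idx} (id={row.get('id')!r}): {exc}")
    if errors:
        raise InvalidInputError("input table failed validation:\n  " + "\n  ".join(errors))
    return records, notes


# --------------------------------------------------------------------------- #
# Results object
# --------------------------------------------------------------------------- #

@dataclass
class StudyResults:
    """Fitted validation-study results; see module docstring for contents."""

    estimates: pd.DataFrame
    cohort_summary: pd.DataFrame
    agreement_us_vs_4c: AgreementReport | None
    agreement_anthro_vs_4c: AgreementReport | None
    ratio_summary: pd.DataFrame
    regression_nested: dict[str, RegressionReport]
    regression_by_site: dict[str, RegressionReport]
    regression_by_gender: dict[str, RegressionReport]
    excluded: list[dict[str, str]]
    notes: list[str]
    provenance: dict[str, Any]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def report(r: AgreementReport | None) -> dict[str, Any] | None:
            if r is None:
                return None
            d = asdict(r)
            d["ccc_class"] = r.ccc_class.value
            return d

        def reg(r: RegressionReport) -> dict[str, Any]:
            d = asdict(r)
            d["r2_class"] = r.r2_class.value
            return d

        return _jsonify({
            "schema_version": REPORT_SCHEMA_VERSION,
            "estimates": self.estimates.to_dict(orient="records"),
            "cohort_summary": {
                "index": list(self.cohort_summary.index),
                "columns": list(self.cohort_summary.columns),
                "data": self.cohort_summary.to_numpy().tolist(),
            },
            "agreement_us_vs_4c": report(self.agreement_us_vs_4c),
            "agreement_anthro_vs_4c": report(self.agreement_anthro_vs_4c),
            "ratio_summary": {
                "index": list(self.ratio_summary.index),
                "columns": list(self.ratio_summary.columns),
                "data": self.ratio_summary.to_numpy().tolist(),
            },
            "regression_nested": {k: reg(v) for k, v in self.regression_nested.items()},
            "regression_by_site": {k: reg(v) for k, v in self.regression_by_site.items()},
            "regression_by_gender": {k: reg(v) for k, v in self.regression_by_gender.items()},
            "excluded": self.excluded,
            "notes": self.notes,
            "provenance": self.provenance,
        })

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, allow_nan=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StudyResults":
        def report(raw: Mapping[str, Any] | None) -> AgreementReport | None:
            if raw is None:
                return None
            raw = dict(raw)
            raw["ccc_class"] = CCCClass(raw["ccc_class"])
            return AgreementReport(**raw)

        def reg(raw: Mapping[str, Any]) -> RegressionReport:
            raw = dict(raw)
            raw["r2_class"] = R2Class(raw["r2_class"])
            return RegressionReport(**raw)

        def frame(raw: Mapping[str, Any]) -> pd.DataFrame:
            return pd.DataFrame(np.asarray(raw["data"], dtype=float),
                                index=raw["index"], columns=raw["columns"])

        return cls(
            estimates=pd.DataFrame(d["estimates"]),
            cohort_summary=frame(d["cohort_summary"]),
            agreement_us_vs_4c=report(d["agreement_us_vs_4c"]),
            agreement_anthro_vs_4c=report(d["agreement_anthro_vs_4c"]),
            ratio_summary=frame(d["ratio_summary"]),
            regression_nested={k: reg(v) for k, v in d["regression_nested"].items()},
            regression_by_site={k: reg(v) for k, v in d["regression_by_site"].items()},
            regression_by_gender={k: reg(v) for k, v in d["regression_by_gender"].items()},
            excluded=list(d["excluded"]),
            notes=list(d["notes"]),
            provenance=dict(d["provenance"]),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "StudyResults":
        text = Path(source).read_text(encoding="utf-8") if (
            isinstance(source, Path) or "\n" not in str(source) and Path(str(source)).exists()
        ) else str(source)
        return cls.from_dict(json.loads(text))

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        """Aligned-text summary of the fitted study."""
        lines: list[str] = []
        n = len(self.estimates)
        lines.append("Fat-mass method validation study")
        lines.append("=" * 64)
        lines.append(f"subjects analysed: {n}   excluded: {len(self.excluded)}")
        lines.append("")
        lines.append("Mean FM% by method")
        for col, label in (("fm_pct_4c", "4C reference"),
                           ("fm_pct_evans_anthro", "Evans (caliper)"),
                           ("fm_pct_evans_us", "Evans (doubled US)")):
            vals = self.estimates[col]
            lines.append(f"  {label:<22}{vals.mean():7.1f} ± {vals.std(ddof=1):.1f}")
        lines.append("")
        for name, rep in (("Evans (doubled US) vs 4C", self.agreement_us_vs_4c),
                          ("Evans (caliper) vs 4C", self.agreement_anthro_vs_4c)):
            lines.append(name)
            if rep is None:
                lines.append("  degenerate input — agreement not computable")
                continue
            lines.append(f"  bias {rep.bias:+.2f}%  (95% CI {rep.ci_low:+.2f} to {rep.ci_high:+.2f})"
                         f"   t = {rep.t_stat:.2f}, p = {_fmt_p(rep.t_p)}")
            lines.append(f"  LoA {rep.loa_lower:+.2f} to {rep.loa_upper:+.2f}   "
                         f"CCC = {rep.ccc:.2f} ({rep.ccc_class.value})")
            if rep.trend_r is None:
                lines.append(f"  trend: {rep.trend_flag}")
            else:
                lines.append(f"  trend r = {rep.trend_r:.2f}, p = {_fmt_p(rep.trend_p)}")
            lines.append("")
        lines.append("Nested skinfold ~ raw US regressions (pooled sites)")
        for name in _NESTED_MODELS:
            rep = self.regression_nested[name]
            lines.append(f"  {name:<22} R² = {rep.r2:.2f} ({rep.r2_class.value}), "
                         f"SEE = {rep.see:.2f} mm, n = {rep.n}")
        lines.append("")
        lines.append("Compressibility ratios (skinfold ÷ raw US), mean ± SD")
        for site in SITES:
            parts = []
            for sex in ("male", "female"):
                mean = self.ratio_summary.loc[site, f"{sex}_mean"]
                sd = self.ratio_summary.loc[site, f"{sex}_sd"]
                if np.isnan(mean):
                    parts.append(f"{sex}: n/a")
                else:
                    parts.append(f"{sex}: {mean:.2f} ± {sd:.2f}")
            lines.append(f"  {site:<10} " + "   ".join(parts))
        return "\n".join(lines)


def _fmt_p(p: float | None) -> str:
    # exact to 3 significant figures; never "0.000"
    if p is None:
        return "n/a"
    if p < 1e-12:
        return "< 1e-12"
    return f"{p:.3g}"


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


# --------------------------------------------------------------------------- #
# Model object
# --------------------------------------------------------------------------- #

class FatMassStudy:
    """Validation-study model built from a participant table.

    Parameters
    ----------
    data:
        One row per participant; required columns are ``REQUIRED_COLUMNS``
        (``race`` is optional and defaults to ``race_default``). Unknown
        columns are preserved but ignored.
    race_default:
        Race label applied where the column is absent or empty.
    loa_multiplier:
        Multiplier for the limits of agreement (1.96 for the 95% limits).
    apply_exclusions:
        Apply the study's inclusion criteria: BMI < ``bmi_max`` and, when an
        ``age_y`` column is present, age ≥ ``age_min``. Excluded rows are
        logged per subject on the results.
    """

    def __init__(self, data: pd.DataFrame, *, race_default: str = "white",
                 loa_multiplier: float = 1.96, apply_exclusions: bool = True,
                 bmi_max: float = 30.0, age_min: float = 16.0,
                 source: str | None = None):
        if not isinstance(data, pd.DataFrame):
            raise InvalidInputError("data: expected a pandas DataFrame")
        self.data = data.reset_index(drop=True)
        self.race_default = race_default
        self.loa_multiplier = float(loa_multiplier)
        self.apply_exclusions = apply_exclusions
        self.bmi_max = float(bmi_max)
        self.age_min = float(age_min)
        self.source = source

        records, notes = _records_from_frame(self.data, race_default)
        self._notes = notes
        self.records, self.excluded = self._apply_exclusions(records)
        if len(self.records) < 3:
            raise InvalidInputError(
                f"need at least 3 participants after exclusions, have {len(self.records)}"
            )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, **kwargs: Any) -> "FatMassStudy":
        frame = pd.read_csv(path)
        return cls(frame, source=str(path), **kwargs)

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kwargs: Any) -> "FatMassStudy":
        study = cls(cohort.to_dataframe(),
                    source=f"synthetic cohort (seed={cohort.config_echo.seed})",
                    **kwargs)
        return study

    # -- internals ----------------------------------------------------------
    def _apply_exclusions(
        self, records: list[ParticipantRecord]
    ) -> tuple[list[ParticipantRecord], list[dict[str, str]]]:
        if not self.apply_exclusions:
            return records, []
        ages = None
        if "age_y" in self.data.columns:
            ages = {str(row["id"]): row["age_y"] for _, row in self.data.iterrows()}
        kept: list[ParticipantRecord] = []
        excluded: list[dict[str, str]] = []
        for rec in records:
            bmi = rec.body_mass / (rec.stature / 100.0) ** 2
            if bmi >= self.bmi_max:
                excluded.append({"id": rec.id,
                                 "reason": f"BMI {bmi:.1f} >= {self.bmi_max:g}"})
                continue
            if ages is not None and not math.isnan(float(ages.get(rec.id, math.nan))):
                age = float(ages[rec.id])
                if age < self.age_min:
                    excluded.append({"id": rec.id,
                                     "reason": f"age {age:g} < {self.age_min:g}"})
                    continue
            kept.append(rec)
        return kept, excluded

    def _estimates_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            est = estimate_all(rec)
            rows.append({
                "id": est.id,
                "sex": "M" if rec.sex_code_evans == 0 else "F",
                "fm_pct_4c": est.fm_pct_4c,
                "fm_pct_evans_anthro": est.fm_pct_evans_anthro,
                "fm_pct_evans_us": est.fm_pct_evans_us,
                "flags": "; ".join(est.flags),
            })
        return pd.DataFrame(rows)

    def _cohort_summary(self) -> pd.DataFrame:
        per_subject = []
        for rec in self.records:
            fci = four_component_inputs_from_record(rec)
            est = estimate_all(rec)
            row = {
                "sex": "male" if rec.sex_code_evans == 0 else "female",
                "body_mass_kg": rec.body_mass,
                "stature_cm": rec.stature,
                "bmi_kg_m2": rec.body_mass / (rec.stature / 100.0) ** 2,
                **{f"skf_{s}_mm": rec.skinfold_mm[s] for s in SITES},
                **{f"us_derived_skf_{s}_mm": 2.0 * rec.us_thickness_mm[s] for s in SITES},
                **{f"ratio_{s}": rec.skinfold_mm[s] / rec.us_thickness_mm[s] for s in SITES},
                "total_body_water_kg": fci.total_body_water,
                "body_volume_l": fci.body_volume,
                "bmc_kg": rec.bone_mineral_content,
                "lean_soft_mass_kg": rec.lean_soft_mass,
                "fm_pct_4c": est.fm_pct_4c,
                "fm_pct_dxa": rec.dxa_fat_pct,
            }
            per_subject.append(row)
        frame = pd.DataFrame(per_subject)
        out = {}
        for sex in ("male", "female"):
            sub = frame[frame["sex"] == sex].drop(columns="sex")
            out[f"{sex}_mean"] = sub.mean() if len(sub) else sub.reindex().mean()
            out[f"{sex}_sd"] = sub.std(ddof=1) if len(sub) else sub.reindex().std()
        return pd.DataFrame(out)

    def _ratio_summary(self) -> pd.DataFrame:
        # mean of per-subject ratios, not ratio of group means
        out = {}
        for sex_code, sex in ((0, "male"), (1, "female")):
            recs = [r for r in self.records if r.sex_code_evans == sex_code]
            means, sds = [], []
            for site in SITES:
                ratios = [r.skinfold_mm[site] / r.us_thickness_mm[site] for r in recs]
                means.append(float(np.mean(ratios)) if ratios else math.nan)
                sds.append(float(np.std(ratios, ddof=1)) if len(ratios) > 1 else math.nan)
            out[f"{sex}_mean"] = means
            out[f"{sex}_sd"] = sds
        return pd.DataFrame(out, index=list(SITES))

    def _long_format(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for site in SITES:
                rows.append({
                    "id": rec.id,
                    "site": site,
                    "gender": "M" if rec.sex_code_evans == 0 else "F",
                    "skinfold_mm": rec.skinfold_mm[site],
                    "raw_us_mm": rec.us_thickness_mm[site],
                })
        return pd.DataFrame(rows)

    # -- fitting ------------------------------------------------------------
    def fit(self) -> StudyResults:
        estimates = self._estimates_frame()
        notes = list(self._notes)

        def safe_agreement(alt: Sequence[float]) -> AgreementReport | None:
            try:
                return agreement_report(alt, estimates["fm_pct_4c"],
                                        self.loa_multiplier)
            except DegenerateInputError as exc:
                notes.append(f"agreement flagged degenerate: {exc}")
                return None

        agreement_us = safe_agreement(estimates["fm_pct_evans_us"])
        agreement_anthro = safe_agreement(estimates["fm_pct_evans_anthro"])

        long = self._long_format()
        nested = {
            "raw_us": regression_with_covariates(
                long["skinfold_mm"], long["raw_us_mm"]),
            "raw_us+site": regression_with_covariates(
                long["skinfold_mm"], long["raw_us_mm"],
                site=long["site"], include={"site"}),
            "raw_us+site+gender": regression_with_covariates(
                long["skinfold_mm"], long["raw_us_mm"],
                site=long["site"], gender=long["gender"],
                include={"site", "gender"}),
        }
        by_site = {}
        for site in SITES:
            sub = long[long["site"] == site]
            by_site[site] = regression_with_covariates(
                sub["skinfold_mm"], sub["raw_us_mm"])
        by_gender = {}
        for g in ("M", "F"):
            sub = long[long["gender"] == g]
            if len(sub) >= 3:
                by_gender[g] = regression_with_covariates(
                    sub["skinfold_mm"], sub["raw_us_mm"])

        provenance = {
            "source": self.source,
            "input_sha256": hashlib.sha256(
                self.data.to_csv(index=False).encode()).hexdigest(),
            "n_input": int(len(self.data)),
            "n_analysed": int(len(self.records)),
            "options": {
                "race_default": self.race_default,
                "loa_multiplier": self.loa_multiplier,
                "apply_exclusions": self.apply_exclusions,
                "bmi_max": self.bmi_max,
                "age_min": self.age_min,
            },
            "software_version": __version__,
            "created_at": datetime.now(timezone.utc).isoformat(),
        }
        return StudyResults(
            estimates=estimates,
            cohort_summary=self._cohort_summary(),
            agreement_us_vs_4c=agreement_us,
            agreement_anthro_vs_4c=agreement_anthro,
            ratio_summary=self._ratio_summary(),
            regression_nested=nested,
            regression_by_site=by_site,
            regression_by_gender=by_gender,
            excluded=self.excluded,
            notes=notes,
            provenance=provenance,
        )


def run_study(source: str | Path | pd.DataFrame, **kwargs: Any) -> StudyResults:
    """Convenience wrapper: build a :class:`FatMassStudy` and fit it."""
    if isinstance(source, pd.DataFrame):
        return FatMassStudy(source, **kwargs).fit()
    return FatMassStudy.from_csv(source, **kwargs).fit()


# --------------------------------------------------------------------------- #
# Group-level reproduction from published summary statistics
# --------------------------------------------------------------------------- #

def group_mean_reproduction(
    skf_sums: Mapping[str, float],
    fm_pct_4c: Mapping[str, float],
    group_sizes: Mapping[str, int],
    race_code: int = 0,
) -> float:
    """Group-size-weighted mean (Evans FM% − reference FM%) from per-sex means.

    Because the Evans equation is linear in the skinfold sum, the per-sex mean
    Evans FM% equals the equation evaluated at the per-sex mean sum; only
    published summary statistics are needed. ``skf_sums`` may carry either the
    caliper or the doubled-US sums — the comparison follows the source given.

    Keys must be ``"male"`` and ``"female"``.
    """
    for name, mapping in (("skf_sums", skf_sums), ("fm_pct_4c", fm_pct_4c),
                          ("group_sizes", group_sizes)):
        missing = {"male", "female"} - set(mapping)
        if missing:
            raise InvalidInputError(f"{name}: missing per-sex entries {sorted(missing)}")
    total = group_sizes["male"] + group_sizes["female"]
    if total <= 0:
        raise InvalidInputError("group_sizes: total must be positive")
    weighted = 0.0
    for sex, sex_code in (("male", 0), ("female", 1)):
        evans = evans_fm_percent(skf_sums[sex], sex_code, race_code)
        weighted += group_sizes[sex] * (evans - fm_pct_4c[sex])
    return weighted / total


def published_group_difference(source: str = "us") -> float:
    """The weighted group-level difference from the packaged published table.

    ``source`` selects the skinfold origin: ``"us"`` (doubled ultrasound) or
    ``"anthro"`` (caliper).
    """
    if source not in ("us", "anthro"):
        raise InvalidInputError("source: expected 'us' or 'anthro'")
    key = "skf_sum_us" if source == "us" else "skf_sum_anthro"
    return group_mean_reproduction(
        skf_sums={sex: TABLE1_GROUPS[sex][key] for sex in ("male", "female")},
        fm_pct_4c={sex: TABLE1_GROUPS[sex]["fm_pct_4c"] for sex in ("male", "female")},
        group_sizes={sex: TABLE1_GROUPS[sex]["n"] for sex in ("male", "female")},
    )
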