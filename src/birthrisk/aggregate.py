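"""Survey-level aggregation of individual birth histories.

Turns a survey's woman roster and birth records into one
:class:`SurveyAggregate`: modern contraceptive prevalence (mCPR) among
women 15-49 in union, the method-mix shares (% permanent, % long-acting
reversible among modern users), the distribution of recent births across
risk categories, and the period total fertility rate (TFR) over the
observation window (default: the 36 months before the survey).

Dates use the DHS century-month code (CMC): integer months since
January 1900. Optional per-woman sampling weights are honoured by every
rate; with all weights equal the unweighted results are reproduced
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .categories import (DIMENSIONS, CategorySpec, classify_birth,
                         default_specs)
from .errors import ValidationError

#: enumerated contraceptive method codes
METHOD_CODES = ("none", "pill", "injectable", "condom", "other_modern_short",
                "iud", "implant", "female_sterilization",
                "male_sterilization", "traditional")
#: modern methods = everything except no use and traditional methods
MODERN_METHODS = frozenset(METHOD_CODES) - {"none", "traditional"}
PERMANENT_METHODS = frozenset({"female_sterilization", "male_sterilization"})
LARC_METHODS = frozenset({"iud", "implant"})
SHORT_TERM_METHODS = MODERN_METHODS - PERMANENT_METHODS - LARC_METHODS

#: the seven 5-year reproductive age groups 15-19 ... 45-49
AGE_GROUPS = tuple((lo, lo + 4) for lo in range(15, 50, 5))


@dataclass
class SurveyAggregate:
    """One survey's covariates and observed risk distribution.

    ``category_pct`` maps ``(dimension, label)`` to a percent; within each
    dimension the values sum to 100 when any births fall in the window
    (spacing percentages are among births of order >= 2 only). ``tfr`` may
    be ``None`` when exposure cannot be reconstructed.
    """

    survey_id: str
    country_id: str
    year: int
    mcpr_pct: float
    pct_permanent: float
    pct_larc: float
    n_births_window: int
    category_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    tfr: float | None = None

    def check_composition(self, tol: float = 1e-6) -> None:
        """Assert the sum-to-100 invariant per dimension (when births exist).

        Generator output with ``renormalize=False`` intentionally breaks
        this; the aggregation and io paths enforce it.
        """
        if self.n_births_window == 0:
            return
        for dim in DIMENSIONS:
            vals = [v for (d, _), v in self.category_pct.items() if d == dim]
            if vals and abs(sum(vals) - 100.0) > tol:
                raise ValidationError(
                    f"survey {self.survey_id}: {dim} percentages sum to "
                    f"{sum(vals):.6f}, not 100", field=dim)


def _weights(women: pd.DataFrame) -> pd.Series:
    if "sample_weight" in women.columns:
        w = women["sample_weight"].astype(float).fillna(1.0)
        if (w < 0).any():
            raise ValidationError("sample weights must be nonnegative",
                                  field="sample_weight")
        return w
    return pd.Series(1.0, index=women.index)


def _eligible(women: pd.DataFrame) -> pd.Series:
    """Women 15-49 currently in union: the mCPR denominator."""
    in_union = women["in_union"].astype(bool)
    return in_union & women["age_years"].between(15, 49)


def compute_mcpr(women: pd.DataFrame) -> float:
    """Percent of women 15-49 in union currently using a modern method."""
    w = _weights(women)
    elig = _eligible(women)
    denom = w[elig].sum()
    if denom <= 0:
        raise ValidationError(
            "mCPR undefined: no in-union women aged 15-49", field="in_union")
    modern = elig & women["method_code"].isin(MODERN_METHODS)
    return 100.0 * w[modern].sum() / denom


def compute_method_mix(women: pd.DataFrame) -> tuple[float, float]:
    """(% permanent, % LARC) among modern users in union aged 15-49."""
    w = _weights(women)
    modern = _eligible(women) & women["method_code"].isin(MODERN_METHODS)
    denom = w[modern].sum()
    if denom <= 0:
        raise ValidationError(
            "method-mix undefined: no modern users", field="method_code")
    perm = modern & women["method_code"].isin(PERMANENT_METHODS)
    larc = modern & women["method_code"].isin(LARC_METHODS)
    return (100.0 * w[perm].sum() / denom, 100.0 * w[larc].sum() / denom)


def extract_window_births(births: pd.DataFrame, survey_cmc: int,
                          window_months: int = 36) -> pd.DataFrame:
    """Births with ``survey_cmc - birth_cmc`` in ``[0, window_months)``.

    Order is preserved; a negative window is rejected.
    """
    if window_months < 0:
        raise ValidationError("window_months must be nonnegative",
                              field="window_months")
    if len(births) == 0:
        return births.copy()
    lag = survey_cmc - births["birth_cmc"]
    return births[(lag >= 0) & (lag < window_months)].copy()


def compute_category_pct(births: pd.DataFrame,
                         specs: Mapping[str, CategorySpec] | None = None,
                         weights: pd.Series | None = None,
                         ) -> dict[tuple[str, str], float]:
    """Percent of (window-filtered) births per risk category.

    Parity and mother's-age percentages are over all births; spacing
    percentages are over births of order >= 2 only (first births have no
    preceding interval). Zero-count categories are reported as 0. An empty
    input returns an empty map.
    """
    specs = specs or default_specs()
    if len(births) == 0:
        return {}
    if weights is None:
        weights = pd.Series(1.0, index=births.index)
    weights = weights.astype(float)

    totals: dict[tuple[str, str], float] = {
        (dim, lab): 0.0 for dim in DIMENSIONS for lab in specs[dim].labels}
    denom = {dim: 0.0 for dim in DIMENSIONS}
    wvals = weights.to_numpy()
    for w, rec in zip(wvals, births.to_dict("records")):
        labels = classify_birth(rec, specs)
        for dim, lab in labels.items():
            totals[(dim, lab)] += w
            denom[dim] += w

    out: dict[tuple[str, str], float] = {}
    for (dim, lab), count in totals.items():
        if denom[dim] > 0:
            out[(dim, lab)] = 100.0 * count / denom[dim]
        # a dimension with zero denominator (e.g. spacing with only first
        # births in the window) is omitted entirely
    return out


def compute_period_tfr(women: pd.DataFrame, births: pd.DataFrame,
                       survey_cmc: int, window_months: int = 36) -> float:
    """Period TFR over the window before the survey.

    TFR = 5 x sum over the seven age groups 15-19 ... 45-49 of
    (births in the window to mothers in the group) / (woman-years of
    exposure in the group during the window). Exposure is reconstructed
    from completed age at survey: the 12 months immediately before the
    survey are lived at ``age_years``, the 12 before those at
    ``age_years - 1``, and so on.
    """
    if window_months <= 0:
        raise ValidationError("window_months must be positive",
                              field="window_months")
    w = _weights(women)
    n_slices = int(np.ceil(window_months / 12))
    exposure = {g: 0.0 for g in AGE_GROUPS}
    ages = women["age_years"].to_numpy()
    for k in range(n_slices):
        months = min(12, window_months - 12 * k)
        slice_ages = ages - k
        for (lo, hi) in AGE_GROUPS:
            mask = (slice_ages >= lo) & (slice_ages <= hi)
            exposure[(lo, hi)] += (w.to_numpy()[mask].sum()) * months / 12.0

    win = extract_window_births(births, survey_cmc, window_months)
    bw = (win["sample_weight"].astype(float).to_numpy()
          if "sample_weight" in win.columns
          else np.ones(len(win)))
    births_by_group = {g: 0.0 for g in AGE_GROUPS}
    if len(win):
        mage = win["mother_age_at_birth_years"].to_numpy()
        for (lo, hi) in AGE_GROUPS:
            mask = (mage >= lo) & (mage <= hi)
            births_by_group[(lo, hi)] = bw[mask].sum()

    tfr = 0.0
    for g in AGE_GROUPS:
        if births_by_group[g] > 0 and exposure[g] <= 0:
            raise ValidationError(
                f"births in age group {g} with zero exposure",
                field="age_years")
        if exposure[g] > 0:
            tfr += births_by_group[g] / exposure[g]
    return 5.0 * tfr


def aggregate_survey(women: pd.DataFrame, births: pd.DataFrame, *,
                     survey_id: str, country_id: str, year: int,
                     survey_cmc: int, window_months: int = 36,
                     specs: Mapping[str, CategorySpec] | None = None,
                     ) -> SurveyAggregate:
    """Compose the survey-level aggregate from individual records.

    All women/births must belong to ``survey_id``; component errors are
    re-raised with the survey id attached.
    """
    specs = specs or default_specs()
    if len(women) == 0:
        raise ValidationError(f"survey {survey_id}: no woman records",
                              field="survey_id")
    for df, name in ((women, "women"), (births, "births")):
        if len(df) and not (df["survey_id"] == survey_id).all():
            raise ValidationError(
                f"{name} table contains records for other surveys",
                field="survey_id")
    # births inherit their mother's sampling weight
    if len(births) and "sample_weight" not in births.columns and \
            "sample_weight" in women.columns:
        wt = women.set_index("woman_id")["sample_weight"]
        births = births.assign(
            sample_weight=births["woman_id"].map(wt).fillna(1.0).to_numpy())
    try:
        mcpr = compute_mcpr(women)
        perm, larc = compute_method_mix(women)
        win = extract_window_births(births, survey_cmc, window_months)
        weights = (win["sample_weight"].astype(float)
                   if "sample_weight" in win.columns else None)
        cat = compute_category_pct(win, specs, weights)
        tfr = compute_period_tfr(women, births, survey_cmc, window_months)
    except ValidationError as err:
        raise ValidationError(f"survey {survey_id}: {err}",
                              field=err.field) from err
    agg = SurveyAggregate(
        survey_id=survey_id, country_id=country_id, year=year,
        mcpr_pct=mcpr, pct_permanent=perm, pct_larc=larc,
        n_births_window=int(len(win)), category_pct=cat, tfr=tfr)
    agg.check_composition()
    return agg
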