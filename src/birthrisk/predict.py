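"""Renormalized risk-distribution predictions and scale-up scenarios.

A fitted model gives, for each category, an unnormalized prediction
``exp(b0 + b1*mCPR + b2*%perm + b3*%LARC + b_i)``; within each dimension
these are rescaled to sum to 100% of births. Three scenarios examine a
fixed increase in mCPR (default +10 percentage points) delivered entirely
through one method class:

* **A** — permanent methods (sterilization),
* **B** — long-acting reversible methods (IUD, implant),
* **C** — short-term methods (pill, injectable, condom, other modern).

New users do not displace existing users between classes, so the class
shares shift purely through the changed denominator (and, for the target
class, its grown numerator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import SurveyAggregate
from .categories import DIMENSIONS, CategorySpec, default_specs
from .errors import PredictionError, ValidationError
from .models import ModelFit

METHOD_CLASSES = ("permanent", "larc", "short_term")
_SCENARIO_CLASS = {"A": "permanent", "B": "larc", "C": "short_term"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A scale-up instruction: mCPR increase routed to one method class."""

    label: str
    delta_mcpr_pp: float = 10.0
    target_class: str = ""

    def __post_init__(self):
        if self.label not in _SCENARIO_CLASS:
            raise ValidationError(f"unknown scenario label {self.label!r}",
                                  field="label")
        expected = _SCENARIO_CLASS[self.label]
        tc = self.target_class or expected
        if tc != expected:
            raise ValidationError(
                f"scenario {self.label} targets {expected!r}, not {tc!r}",
                field="target_class")
        object.__setattr__(self, "target_class", tc)
        if self.delta_mcpr_pp <= 0:
            raise ValidationError("delta_mcpr_pp must be positive",
                                  field="delta_mcpr_pp")


def default_scenarios(delta_mcpr_pp: float = 10.0) -> list[ScenarioSpec]:
    return [ScenarioSpec(lab, delta_mcpr_pp) for lab in "ABC"]


@dataclass
class PredictionResult:
    """A renormalized predicted risk distribution for one covariate set."""

    country_id: str
    mcpr_pct: float
    pct_permanent: float
    pct_larc: float
    distribution: dict[str, dict[str, float]]   # dimension -> label -> pct
    random_effect_source: str                    # country|regional_average|zero


def _fit_index(fits: Iterable[ModelFit]) -> dict[tuple[str, str], ModelFit]:
    return {(f.dimension, f.category_label): f for f in fits}


def _random_effect(fit: ModelFit, country_id: str | None, fallback: str,
                   regions: Mapping[str, str] | None) -> tuple[float, str]:
    re = fit.random_effects or {}
    if country_id is not None and country_id in re:
        return re[country_id], "country"
    if fallback == "country":
        raise PredictionError(
            f"no random effect for country {country_id!r} and "
            f"fallback='country'")
    if fallback == "zero" or not re:
        return 0.0, "zero"
    if fallback == "regional_average":
        if regions is None:
            raise PredictionError(
                "fallback='regional_average' needs a country->region table")
        region = regions.get(country_id)
        peers = [re[c] for c in re if regions.get(c) == region]
        if region is None or not peers:
            return 0.0, "zero"
        return float(np.mean(peers)), "regional_average"
    raise ValidationError(f"unknown fallback {fallback!r}", field="fallback")


def predict_distribution(fits: Iterable[ModelFit], *, mcpr_pct: float,
                         pct_permanent: float, pct_larc: float,
                         country_id: str | None = None,
                         fallback: str = "zero",
                         regions: Mapping[str, str] | None = None,
                         specs: Mapping[str, CategorySpec] | None = None,
                         ) -> PredictionResult:
    """Predict the percent of births in every risk category.

    One fit per category of each dimension is required (checked against
    the taxonomy in ``specs``). The country random effect is used when the
    country was observed at fit time; otherwise the ``fallback`` policy
    applies (``zero``, ``regional_average`` with a region table, or
    ``country`` to insist on an observed country).
    """
    specs = specs or default_specs()
    index = _fit_index(fits)
    sources = set()
    distribution: dict[str, dict[str, float]] = {}
    for dim in DIMENSIONS:
        raw = {}
        for lab in specs[dim].labels:
            fit = index.get((dim, lab))
            if fit is None:
                raise PredictionError(f"missing fit for category "
                                      f"({dim}, {lab})")
            b_i, src = _random_effect(fit, country_id, fallback, regions)
            sources.add(src)
            eta = fit.linear_predictor(mcpr_pct, pct_permanent, pct_larc)
            raw[lab] = float(np.exp(eta + b_i))
        total = sum(raw.values())
        distribution[dim] = {lab: 100.0 * v / total
                             for lab, v in raw.items()}
    if "country" in sources:
        source = "country"
    elif "regional_average" in sources:
        source = "regional_average"
    else:
        source = "zero"
    return PredictionResult(
        country_id=str(country_id), mcpr_pct=mcpr_pct,
        pct_permanent=pct_permanent, pct_larc=pct_larc,
        distribution=distribution, random_effect_source=source)


def apply_scenario(baseline: SurveyAggregate | tuple[float, float, float],
                   scenario: ScenarioSpec) -> tuple[float, float, float]:
    """Scale up mCPR with one method class; return new covariates.

    With user-shares in percentage points of women,
    ``u_perm = mcpr * %perm / 100`` (similarly LARC and short-term), the
    whole increase is added to the target class's user-share and the
    shares are re-expressed against the new prevalence:
    ``%perm' = 100 * u_perm' / mcpr'``.
    """
    if isinstance(baseline, SurveyAggregate):
        mcpr, perm, larc = (baseline.mcpr_pct, baseline.pct_permanent,
                            baseline.pct_larc)
    else:
        mcpr, perm, larc = baseline
    new_mcpr = mcpr + scenario.delta_mcpr_pp
    if new_mcpr > 100.0:
        raise ValidationError(
            f"scenario pushes mCPR to {new_mcpr:.1f}% (> 100%)",
            field="delta_mcpr_pp")
    u_perm = mcpr * perm / 100.0
    u_larc = mcpr * larc / 100.0
    if scenario.target_class == "permanent":
        u_perm += scenario.delta_mcpr_pp
    elif scenario.target_class == "larc":
        u_larc += scenario.delta_mcpr_pp
    # short_term: the residual class absorbs the increase implicitly
    return (new_mcpr, 100.0 * u_perm / new_mcpr, 100.0 * u_larc / new_mcpr)


def run_scenarios(fits: Iterable[ModelFit],
                  baselines: Sequence[SurveyAggregate],
                  scenarios: Sequence[ScenarioSpec] | None = None,
                  fallback: str = "zero",
                  regions: Mapping[str, str] | None = None,
                  specs: Mapping[str, CategorySpec] | None = None,
                  ) -> pd.DataFrame:
    """Baseline plus per-scenario predictions for each baseline survey.

    Returns a long table with one row per (country, scenario, dimension,
    category); the baseline prediction is labelled ``baseline``.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    fits = list(fits)
    records = []

    def emit(country, scen_label, covs):
        mcpr, perm, larc = covs
        pred = predict_distribution(
            fits, mcpr_pct=mcpr, pct_permanent=perm, pct_larc=larc,
            country_id=country, fallback=fallback, regions=regions,
            specs=specs)
        for dim, labmap in pred.distribution.items():
            for lab, pct in labmap.items():
                records.append({
                    "country_id": country, "scenario": scen_label,
                    "dimension": dim, "category": lab, "percent": pct,
                    "mcpr_pct": mcpr, "pct_permanent": perm,
                    "pct_larc": larc,
                    "random_effect_source": pred.random_effect_source,
                })

    for agg in baselines:
        base = (agg.mcpr_pct, agg.pct_permanent, agg.pct_larc)
        emit(agg.country_id, "baseline", base)
        for scen in scenarios:
            emit(agg.country_id, scen.label, apply_scenario(agg, scen))
    return pd.DataFrame.from_records(records)
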