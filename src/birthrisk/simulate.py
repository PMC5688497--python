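"""Synthetic data generators for the full pipeline.

Two levels are emulated, each from explicit parameters and a single seed:

* :func:`generate_panel` draws survey-level aggregates directly from the
  log-linear random-intercept model: per category,
  ``log(pct) = b0 + b1*mCPR + b2*%perm + b3*%LARC + u_country + eps`` with
  ``u ~ N(0, tau2)`` shared by a country's surveys and independent
  survey-level noise ``eps ~ N(0, sigma2)``. The generating truth (betas,
  country effects, residuals) is returned alongside.
* :func:`generate_birth_histories` draws individual women and dated birth
  histories. Fertility is a pure age-dependent monthly Bernoulli hazard
  (annual age-specific rate / 12), so the implied period TFR has the
  closed form ``5 * sum(asfr)`` and the implied distribution of window
  births across risk categories is exactly computable
  (:func:`implied_category_distribution`) — both serve as independent
  oracles for the classification pipeline.

Default truth slopes carry the signs of the fitted hierarchical model on
the real survey library (mCPR negatively associated with high parity and
older mothers, positively with long preceding intervals and first
births); magnitudes are configurable.

All randomness flows from the seed through ``numpy.random.SeedSequence``
with one spawned child stream per survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import AGE_GROUPS, SurveyAggregate
from .categories import (DIMENSIONS, MOTHERS_AGE, PARITY, SPACING,
                         CategorySpec, default_specs)
from .errors import ValidationError

#: default annual age-specific fertility rates for 15-19 ... 45-49
#: (a mid-transition schedule; closed-form TFR 5*sum = 4.375)
DEFAULT_ASFR = (0.09, 0.21, 0.22, 0.18, 0.11, 0.05, 0.015)

#: method composition within each class: (method_code, probability)
_CLASS_METHODS = {
    "permanent": (("female_sterilization", 0.8), ("male_sterilization", 0.2)),
    "larc": (("iud", 0.5), ("implant", 0.5)),
    "short_term": (("pill", 0.4), ("injectable", 0.3), ("condom", 0.2),
                   ("other_modern_short", 0.1)),
}


def default_betas(specs: Mapping[str, CategorySpec] | None = None,
                  ) -> dict[tuple[str, str], np.ndarray]:
    """Default generating coefficients per (dimension, category).

    Each value is ``(b0, b1, b2, b3)`` on the per-unit-percent scale for
    (intercept, mCPR, %permanent, %LARC). Slopes for mCPR follow the
    sign and magnitude pattern of the hierarchical fit on the real survey
    library (per-10-point estimates divided by 10); method-mix slopes are
    modest values consistent with its qualitative findings (a
    permanent-heavy mix associated with relatively more high-parity
    births, a short-term-heavy mix with longer intervals). Intercepts
    anchor each category's percent near the cross-survey average at
    reference covariates (mCPR 30, %perm 15, %LARC 20).
    """
    # (anchor percent at reference, b1, b2, b3)
    table = {
        (MOTHERS_AGE, "<18"): (6.5, -0.001, 0.000, -0.002),
        (MOTHERS_AGE, "18-34"): (80.3, 0.001, -0.001, 0.001),
        (MOTHERS_AGE, "35+"): (13.2, -0.006, 0.004, 0.000),
        (SPACING, "<18mo"): (6.0, -0.011, 0.002, -0.004),
        (SPACING, "18-23mo"): (9.1, -0.010, 0.001, -0.002),
        (SPACING, "24-35mo"): (23.6, -0.012, 0.001, -0.001),
        (SPACING, "36+mo"): (61.3, 0.007, -0.003, -0.001),
        (PARITY, "first"): (26.1, 0.009, -0.004, 0.000),
        (PARITY, "2-4"): (37.2, 0.006, -0.002, 0.000),
        (PARITY, "5+"): (36.6, -0.014, 0.008, 0.002),
    }
    ref = np.array([1.0, 30.0, 15.0, 20.0])
    out = {}
    for key, (anchor, b1, b2, b3) in table.items():
        slopes = np.array([0.0, b1, b2, b3])
        b0 = math.log(anchor) - float(slopes @ ref)
        out[key] = np.array([b0, b1, b2, b3])
    return out


@dataclass
class PanelParams:
    """Parameters of the survey-level panel generator.

    Defaults reproduce the scale of the real survey library: 71 countries
    and 207 surveys in total (the deterministic allocation gives the
    first 65 countries three surveys and the rest two), country variance
    ``tau2 = 0.04`` and survey residual variance ``sigma2 = 0.01`` on the
    log-percent scale, mCPR uniform on [5, 75] and a Dirichlet method-mix
    averaging roughly 15% permanent / 20% LARC / 65% short-term.
    """

    n_countries: int = 71
    total_surveys: int | None = 207
    surveys_per_country: int | tuple[int, int] = 3
    betas: dict[tuple[str, str], np.ndarray] = field(
        default_factory=default_betas)
    tau2: float = 0.04
    sigma2: float = 0.01
    mcpr_range: tuple[float, float] = (5.0, 75.0)
    mix_alpha: tuple[float, float, float] = (1.5, 2.0, 6.5)
    year_range: tuple[int, int] = (1990, 2015)
    n_births_window: int = 3000
    renormalize: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tau2 < 0 or self.sigma2 <= 0:
            raise ValidationError("need tau2 >= 0 and sigma2 > 0",
                                  field="tau2")
        if any(a <= 0 for a in self.mix_alpha) or len(self.mix_alpha) != 3:
            raise ValidationError(
                "mix_alpha must be 3 positive Dirichlet weights",
                field="mix_alpha")


def _survey_counts(params: PanelParams, rng: np.random.Generator,
                   ) -> np.ndarray:
    k = params.n_countries
    if params.total_surveys is not None:
        if params.total_surveys < k:
            raise ValidationError("total_surveys < n_countries",
                                  field="total_surveys")
        base, extra = divmod(params.total_surveys, k)
        counts = np.full(k, base)
        counts[:extra] += 1
        return counts
    spc = params.surveys_per_country
    if isinstance(spc, int):
        return np.full(k, spc)
    lo, hi = spc
    return rng.integers(lo, hi + 1, size=k)


def generate_panel(params: PanelParams,
                   ) -> tuple[list[SurveyAggregate], dict]:
    """Draw a panel of survey aggregates from the log-linear model.

    Returns the aggregates and a truth record carrying the generating
    betas, variance components, per-country effects and per-survey
    residuals. With ``renormalize=False`` (default) the emitted category
    percentages follow the model exactly and do not sum to 100 within a
    dimension; ``renormalize=True`` rescales them (slightly breaking the
    generating model, as real compositional data would).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_global, rng_country = [np.random.default_rng(s)
                               for s in ss.spawn(2)]
    counts = _survey_counts(params, rng_global)
    keys = list(params.betas)

    country_effects = {}
    for c in range(params.n_countries):
        cid = f"C{c + 1:03d}"
        draws = rng_country.normal(0.0, math.sqrt(params.tau2), len(keys))
        for key, b in zip(keys, draws):
            country_effects[(cid, *key)] = float(b)

    n_total = int(counts.sum())
    survey_streams = ss.spawn(n_total)
    aggregates: list[SurveyAggregate] = []
    residuals = {}
    truth_surveys = []
    idx = 0
    for c in range(params.n_countries):
        cid = f"C{c + 1:03d}"
        for s in range(int(counts[c])):
            rng = np.random.default_rng(survey_streams[idx])
            idx += 1
            sid = f"{cid}-S{s + 1}"
            mcpr = float(rng.uniform(*params.mcpr_range))
            perm, larc, _short = 100.0 * rng.dirichlet(params.mix_alpha)
            year = int(rng.integers(params.year_range[0],
                                    params.year_range[1] + 1))
            tfr = float(np.clip(8.0 - 0.075 * mcpr + rng.normal(0, 0.3),
                                1.0, 8.5))
            x = np.array([1.0, mcpr, perm, larc])
            cat = {}
            for key in keys:
                eps = float(rng.normal(0.0, math.sqrt(params.sigma2)))
                residuals[(sid, *key)] = eps
                eta = float(params.betas[key] @ x) \
                    + country_effects[(cid, *key)] + eps
                cat[key] = math.exp(eta)
            if params.renormalize:
                for dim in DIMENSIONS:
                    tot = sum(v for (d, _), v in cat.items() if d == dim)
                    for key in keys:
                        if key[0] == dim:
                            cat[key] = 100.0 * cat[key] / tot
            aggregates.append(SurveyAggregate(
                survey_id=sid, country_id=cid, year=year, mcpr_pct=mcpr,
                pct_permanent=float(perm), pct_larc=float(larc),
                n_births_window=params.n_births_window,
                category_pct=dict(cat), tfr=tfr))
            truth_surveys.append({"survey_id": sid, "country_id": cid,
                                  "mcpr_pct": mcpr, "pct_permanent": perm,
                                  "pct_larc": larc})
    truth = {
        "seed": params.seed, "tau2": params.tau2, "sigma2": params.sigma2,
        "betas": {key: params.betas[key].tolist() for key in keys},
        "country_effects": country_effects, "residuals": residuals,
        "surveys": truth_surveys,
    }
    return aggregates, truth


def assign_regions(country_ids: Sequence[str], n_regions: int = 8,
                   ) -> dict[str, str]:
    """Deterministic round-robin country -> region table for fallbacks."""
    return {cid: f"R{(i % n_regions) + 1}"
            for i, cid in enumerate(country_ids)}


# --------------------------------------------------------------------------
# individual-level birth histories


@dataclass
class HistoryParams:
    """Parameters of the individual-level birth-history generator.

    ``asfr`` gives annual age-specific fertility rates for the seven
    5-year groups 15-49; each woman gives birth in a month with
    probability ``asfr[group]/12`` independently (no postpartum
    infecundability, no union/contraception feedback — see the package
    methods note), which keeps the implied TFR and category distribution
    exactly computable. ``interval_months_override`` replaces the hazard
    process with deterministic renewal at a fixed interval, for forcing a
    single spacing category.
    """

    n_surveys: int = 1
    n_women: int = 500
    n_countries: int | None = None
    age_range: tuple[int, int] = (15, 49)
    union_prob: float = 0.72
    mcpr_range: tuple[float, float] = (5.0, 75.0)
    mix_alpha: tuple[float, float, float] = (1.5, 2.0, 6.5)
    traditional_prob: float = 0.05
    asfr: tuple[float, ...] = DEFAULT_ASFR
    interval_months_override: int | None = None
    year_range: tuple[int, int] = (1995, 2015)
    seed: int = 0

    def __post_init__(self):
        if len(self.asfr) != len(AGE_GROUPS):
            raise ValidationError(
                f"asfr needs {len(AGE_GROUPS)} rates", field="asfr")
        if any(f < 0 or f > 1 for f in self.asfr):
            raise ValidationError("asfr rates must lie in [0, 1]",
                                  field="asfr")
        if self.interval_months_override is None and \
                all(f == 0 for f in self.asfr):
            raise ValidationError("fertility hazard has zero mass",
                                  field="asfr")

    @property
    def tfr_closed_form(self) -> float:
        return 5.0 * float(sum(self.asfr))


def _age_group_index(age: int) -> int | None:
    if age < 15 or age > 49:
        return None
    return min((age - 15) // 5, 6)


def _monthly_hazards(asfr: Sequence[float], n_months: int) -> np.ndarray:
    """Hazard per month since the 15th birthday (age 15 + s//12)."""
    s = np.arange(n_months)
    ages = 15 + s // 12
    h = np.zeros(n_months)
    for i, a in enumerate(ages):
        g = _age_group_index(int(a))
        h[i] = asfr[g] / 12.0 if g is not None else 0.0
    return h


def _draw_method(rng: np.random.Generator, eligible: bool, mcpr_frac: float,
                 mix: np.ndarray, traditional_prob: float) -> str:
    if eligible and rng.random() < mcpr_frac:
        cls = ("permanent", "larc", "short_term")[
            rng.choice(3, p=mix)]
        methods, probs = zip(*_CLASS_METHODS[cls])
        return methods[rng.choice(len(methods), p=np.array(probs))]
    if eligible and rng.random() < traditional_prob:
        return "traditional"
    return "none"


def generate_birth_histories(params: HistoryParams,
                             ) -> tuple[pd.DataFrame, pd.DataFrame,
                                        pd.DataFrame, dict]:
    """Draw women, their dated births, and survey metadata.

    Returns ``(women, births, surveys, truth)``: frames matching the
    ``women.csv`` / ``births.csv`` / ``surveys.csv`` schemas plus a truth
    record with the generating rates (closed-form TFR ``5*sum(asfr)``,
    per-survey target mCPR and method-mix).
    """
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(params.n_surveys + 1)
    rng_meta = np.random.default_rng(streams[0])
    n_countries = params.n_countries or max(1,
                                            math.ceil(params.n_surveys / 3))

    women_rows, birth_rows, survey_rows = [], [], []
    truth_surveys = []
    for si in range(params.n_surveys):
        rng = np.random.default_rng(streams[si + 1])
        sid = f"S{si + 1:03d}"
        cid = f"C{(si % n_countries) + 1:03d}"
        year = int(rng_meta.integers(params.year_range[0],
                                     params.year_range[1] + 1))
        survey_cmc = (year - 1900) * 12 + int(rng_meta.integers(1, 13))
        mcpr_target = float(rng.uniform(*params.mcpr_range))
        mix = rng.dirichlet(params.mix_alpha)
        survey_rows.append({"survey_id": sid, "country_id": cid,
                            "year": year, "survey_cmc": survey_cmc})
        truth_surveys.append({"survey_id": sid, "mcpr_pct": mcpr_target,
                              "pct_permanent": 100.0 * mix[0],
                              "pct_larc": 100.0 * mix[1]})

        ages = rng.integers(params.age_range[0], params.age_range[1] + 1,
                            size=params.n_women)
        offsets = rng.integers(0, 12, size=params.n_women)
        unions = rng.random(params.n_women) < params.union_prob
        for wi in range(params.n_women):
            wid = f"{sid}-W{wi + 1:05d}"
            age, u = int(ages[wi]), int(offsets[wi])
            in_union = bool(unions[wi])
            eligible = in_union and 15 <= age <= 49
            method = _draw_method(rng, eligible, mcpr_target / 100.0, mix,
                                  params.traditional_prob)
            women_rows.append({
                "woman_id": wid, "survey_id": sid, "age_years": age,
                "in_union": in_union, "method_code": method,
                "sample_weight": 1.0})

            cmc0 = survey_cmc - (age - 15) * 12 - u  # 15th birthday month
            n_months = survey_cmc - cmc0
            if n_months <= 0:
                continue
            if params.interval_months_override is not None:
                first = int(rng.integers(12, 37))
                birth_offsets = np.arange(
                    first, n_months, params.interval_months_override)
            else:
                h = _monthly_hazards(params.asfr, n_months)
                birth_offsets = np.nonzero(rng.random(n_months) < h)[0]
            prev = None
            for order, off in enumerate(birth_offsets, start=1):
                t = cmc0 + int(off)
                birth_rows.append({
                    "woman_id": wid, "survey_id": sid, "birth_cmc": t,
                    "birth_order": order,
                    "preceding_interval_months":
                        (t - prev) if prev is not None else None,
                    "mother_age_at_birth_years": 15 + int(off) // 12})
                prev = t

    women = pd.DataFrame(women_rows)
    births = pd.DataFrame(
        birth_rows, columns=["woman_id", "survey_id", "birth_cmc",
                             "birth_order", "preceding_interval_months",
                             "mother_age_at_birth_years"])
    surveys = pd.DataFrame(survey_rows)
    truth = {
        "seed": params.seed, "asfr": list(params.asfr),
        "tfr_closed_form": params.tfr_closed_form,
        "union_prob": params.union_prob, "surveys": truth_surveys,
    }
    return women, births, surveys, truth


def implied_category_distribution(asfr: Sequence[float] = DEFAULT_ASFR,
                                  window_months: int = 36,
                                  age_range: tuple[int, int] = (15, 49),
                                  specs: Mapping[str, CategorySpec]
                                  | None = None,
                                  parity_cap: int = 24,
                                  ) -> dict[str, dict[str, float]]:
    """Exact expected risk distribution under the hazard birth process.

    Averages over women with integer ages uniform on ``age_range`` and a
    uniform 0-11 month birthday offset — the same population law the
    history generator draws from. For each (age, offset) chain the
    expected number of window births per category follows from the
    independence of the monthly Bernoulli events: a birth in month ``s``
    is first with probability ``h_s * prod_{j<s}(1 - h_j)``, has
    preceding interval ``d`` with probability
    ``h_s * h_{s-d} * prod_{s-d<j<s}(1 - h_j)``, and its order
    distribution comes from the Poisson-binomial count of prior months.
    Used as the independent oracle for the classification pipeline.
    """
    specs = specs or default_specs()
    spacing_bins = specs[SPACING].bins
    age_bins = specs[MOTHERS_AGE].bins
    parity_bins = specs[PARITY].bins

    spacing_exp = {b.label: 0.0 for b in spacing_bins}
    age_exp = {b.label: 0.0 for b in age_bins}
    parity_exp = {b.label: 0.0 for b in parity_bins}
    total_births = 0.0
    nonfirst_births = 0.0

    for a in range(age_range[0], age_range[1] + 1):
        for u in range(12):
            T = (a - 15) * 12 + u
            if T == 0:
                continue
            h = _monthly_hazards(asfr, T)
            # logS[s] = log prod_{j<s} (1 - h_j)
            logS = np.concatenate([[0.0], np.cumsum(np.log1p(-h))])
            # birth at month s has lag T - s; the window keeps
            # lag in [0, window), hence s >= T - window + 1
            w_lo = max(0, T - window_months + 1)

            # parity: evolve the distribution of prior birth counts
            q = np.zeros(parity_cap + 1)
            q[0] = 1.0
            for s in range(T):
                if s >= w_lo and h[s] > 0:
                    for b in parity_bins:
                        # order k+1 in [lo, hi) <=> prior count k in
                        # [lo-1, hi-1)
                        lo = int(b.lo) - 1
                        hi = parity_cap if math.isinf(b.hi) \
                            else min(parity_cap, int(b.hi) - 2)
                        parity_exp[b.label] += h[s] * q[lo:hi + 1].sum()
                q = q * (1.0 - h[s]) + np.concatenate([[0.0],
                                                       q[:-1]]) * h[s]

            # mother's age and totals
            for s in range(w_lo, T):
                if h[s] <= 0:
                    continue
                total_births += h[s]
                age_at_birth = 15 + s // 12
                age_exp[specs[MOTHERS_AGE].locate(age_at_birth)] += h[s]

                # spacing: previous birth in month m < s, none in between
                if s > 0:
                    m = np.arange(s)
                    probs = h[s] * h[m] * np.exp(logS[s] - logS[m + 1])
                    d = s - m
                    for b in spacing_bins:
                        mask = (d >= b.lo) & (d < b.hi)
                        spacing_exp[b.label] += float(probs[mask].sum())
                    nonfirst_births += float(probs.sum())

    n_chains = (age_range[1] - age_range[0] + 1) * 12
    for acc in (spacing_exp, age_exp, parity_exp):
        for k in acc:
            acc[k] /= n_chains
    total_births /= n_chains
    nonfirst_births /= n_chains

    out = {
        SPACING: {k: 100.0 * v / nonfirst_births
                  for k, v in spacing_exp.items()},
        MOTHERS_AGE: {k: 100.0 * v / total_births
                      for k, v in age_exp.items()},
        PARITY: {k: 100.0 * v / total_births for k, v in parity_exp.items()},
    }
    return out
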