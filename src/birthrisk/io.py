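"""CSV schemas, readers/writers and validation for every pipeline table.

All tables are UTF-8, comma-delimited, headered CSV with LF line endings;
floats are serialized with 6 decimal places. A missing preceding birth
interval (first births) is an empty field. Schema violations raise
:class:`~birthrisk.errors.SchemaError` or
:class:`~birthrisk.errors.ValidationError` carrying the 0-based data row
index.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import METHOD_CODES, SurveyAggregate
from .categories import all_category_keys
from .errors import SchemaError, ValidationError
from .models import COEF_NAMES, ModelFit

SCHEMA_VERSION = "1"
_FLOAT_FMT = "%.6f"

WOMEN_COLUMNS = ("woman_id", "survey_id", "age_years", "in_union",
                 "method_code", "sample_weight")
BIRTH_COLUMNS = ("woman_id", "survey_id", "birth_cmc", "birth_order",
                 "preceding_interval_months", "mother_age_at_birth_years")
SURVEY_COLUMNS = ("survey_id", "country_id", "year", "survey_cmc")


def _require(df: pd.DataFrame, cols: Sequence[str], what: str,
             optional: Sequence[str] = ()) -> None:
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}",
                          field="in_union", row=row)


def read_women(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, WOMEN_COLUMNS, "women.csv", optional=("sample_weight",))
    if "sample_weight" not in df.columns:
        df["sample_weight"] = 1.0
    df["in_union"] = [_parse_bool(v, i)
                      for i, v in enumerate(df["in_union"])]
    for i, age in enumerate(df["age_years"]):
        if not 10 <= age <= 60:
            raise ValidationError(f"age {age} outside [10, 60]",
                                  field="age_years", row=i)
    bad = ~df["method_code"].isin(METHOD_CODES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"unknown method code {df['method_code'].iloc[i]!r}",
            field="method_code", row=i)
    if (df["sample_weight"].astype(float) < 0).any():
        i = int((df["sample_weight"].astype(float) < 0).idxmax())
        raise ValidationError("negative sample weight",
                              field="sample_weight", row=i)
    return df


def write_women(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["in_union"] = out["in_union"].astype(bool).astype(int)
    _to_csv(out[list(WOMEN_COLUMNS)], path)


def read_births(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, BIRTH_COLUMNS, "births.csv")
    for i, rec in enumerate(df.to_dict("records")):
        order = rec["birth_order"]
        prev = rec["preceding_interval_months"]
        missing = prev is None or (isinstance(prev, float)
                                   and math.isnan(prev))
        if order == 1 and not missing:
            raise ValidationError(
                "preceding interval present on a first birth",
                field="preceding_interval_months", row=i)
        if order > 1 and missing:
            raise ValidationError(
                "preceding interval missing for a birth of order >= 2",
                field="preceding_interval_months", row=i)
    # each woman's birth dates must increase strictly with order
    for wid, grp in df.groupby("woman_id", sort=False):
        g = grp.sort_values("birth_order")
        cmc = g["birth_cmc"].to_numpy()
        if len(cmc) > 1 and not (np.diff(cmc) > 0).all():
            i = int(g.index[np.argmin(np.diff(cmc) > 0) + 1])
            raise ValidationError(
                f"birth dates of woman {wid!r} not strictly increasing "
                f"with order", field="birth_cmc", row=i)
    return df


def write_births(df: pd.DataFrame, path: str | Path) -> None:
    _to_csv(df[list(BIRTH_COLUMNS)], path)


def read_surveys(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SURVEY_COLUMNS, "surveys.csv")
    return df


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    _to_csv(df[list(SURVEY_COLUMNS)], path)


# --------------------------------------------------------------------------
# survey aggregates

def _category_columns(specs=None) -> list[str]:
    return [f"{dim}__{lab}" for dim, lab in all_category_keys(specs)]


def write_aggregates(aggregates: Iterable[SurveyAggregate],
                     path: str | Path, specs=None) -> None:
    rows = []
    for agg in aggregates:
        row = {
            "survey_id": agg.survey_id, "country_id": agg.country_id,
            "year": agg.year, "mcpr_pct": agg.mcpr_pct,
            "pct_permanent": agg.pct_permanent, "pct_larc": agg.pct_larc,
            "n_births_window": agg.n_births_window, "tfr": agg.tfr,
        }
        for (dim, lab) in all_category_keys(specs):
            row[f"{dim}__{lab}"] = agg.category_pct.get((dim, lab))
        rows.append(row)
    _to_csv(pd.DataFrame(rows), path)


def read_aggregates(path: str | Path, specs=None,
                    check_composition: bool = True,
                    ) -> list[SurveyAggregate]:
    df = pd.read_csv(path)
    base = ("survey_id", "country_id", "year", "mcpr_pct", "pct_permanent",
            "pct_larc", "n_births_window")
    _require(df, base + tuple(_category_columns(specs)), "aggregates.csv",
             optional=("tfr",))
    out = []
    for i, rec in enumerate(df.to_dict("records")):
        for col in ("mcpr_pct", "pct_permanent", "pct_larc"):
            v = rec[col]
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{col}={v} outside [0, 100]",
                                      field=col, row=i)
        if rec["pct_permanent"] + rec["pct_larc"] > 100.0 + 1e-9:
            raise ValidationError("pct_permanent + pct_larc > 100",
                                  field="pct_permanent", row=i)
        cat = {}
        for dim, lab in all_category_keys(specs):
            v = rec.get(f"{dim}__{lab}")
            if v is not None and not (isinstance(v, float)
                                      and math.isnan(v)):
                cat[(dim, lab)] = float(v)
        tfr = rec.get("tfr")
        if tfr is not None and isinstance(tfr, float) and math.isnan(tfr):
            tfr = None
        agg = SurveyAggregate(
            survey_id=str(rec["survey_id"]),
            country_id=str(rec["country_id"]), year=int(rec["year"]),
            mcpr_pct=float(rec["mcpr_pct"]),
            pct_permanent=float(rec["pct_permanent"]),
            pct_larc=float(rec["pct_larc"]),
            n_births_window=int(rec["n_births_window"]),
            category_pct=cat, tfr=tfr)
        if check_composition:
            # serialized percentages carry 6 decimals -> loose tolerance
            agg.check_composition(tol=1e-3)
        out.append(agg)
    return out


# --------------------------------------------------------------------------
# model fits

def write_fits(fits: Iterable[ModelFit], path: str | Path) -> None:
    rows = []
    for f in fits:
        row = {
            "dimension": f.dimension, "category": f.category_label,
            "variant": f.model_variant, "n_surveys": f.n_surveys,
            "n_countries": f.n_countries, "df_resid": f.df_resid,
            "sigma2": f.sigma2, "tau2": f.tau2,
            "reml_loglik": f.reml_loglik,
        }
        for name in COEF_NAMES:
            row[f"coef_{name}"] = f.coef.get(name)
            row[f"se_{name}"] = f.se.get(name)
            row[f"p_{name}"] = f.p_value.get(name)
        rows.append(row)
    _to_csv(pd.DataFrame(rows), path)


def write_random_effects(fits: Iterable[ModelFit], path: str | Path) -> None:
    rows = []
    for f in fits:
        if f.random_effects is None:
            continue
        for cid, b in f.random_effects.items():
            rows.append({"country_id": cid, "dimension": f.dimension,
                         "category": f.category_label, "b_hat": b})
    _to_csv(pd.DataFrame(rows,
                         columns=["country_id", "dimension", "category",
                                  "b_hat"]), path)


def read_fits(fits_path: str | Path,
              random_effects_path: str | Path | None = None,
              ) -> list[ModelFit]:
    df = pd.read_csv(fits_path)
    _require(df, ("dimension", "category", "variant", "sigma2"), "fits.csv")
    re_map: dict[tuple[str, str], dict[str, float]] = {}
    if random_effects_path is not None and \
            Path(random_effects_path).exists():
        re_df = pd.read_csv(random_effects_path)
        for rec in re_df.to_dict("records"):
            key = (rec["dimension"], rec["category"])
            re_map.setdefault(key, {})[str(rec["country_id"])] = \
                float(rec["b_hat"])
    fits = []
    for rec in df.to_dict("records"):
        coef, se, pv = {}, {}, {}
        for name in COEF_NAMES:
            v = rec.get(f"coef_{name}")
            if v is not None and not (isinstance(v, float)
                                      and math.isnan(v)):
                coef[name] = float(v)
                se[name] = float(rec[f"se_{name}"])
                pv[name] = float(rec[f"p_{name}"])
        tau2 = rec.get("tau2")
        if isinstance(tau2, float) and math.isnan(tau2):
            tau2 = None
        rll = rec.get("reml_loglik")
        if isinstance(rll, float) and math.isnan(rll):
            rll = None
        key = (rec["dimension"], rec["category"])
        fits.append(ModelFit(
            dimension=rec["dimension"], category_label=rec["category"],
            model_variant=rec["variant"], coef=coef, se=se, p_value=pv,
            sigma2=float(rec["sigma2"]), tau2=tau2,
            random_effects=re_map.get(key) if rec["variant"] == "m3"
            else None,
            n_surveys=int(rec.get("n_surveys", 0)),
            n_countries=int(rec.get("n_countries", 0)),
            df_resid=int(rec.get("df_resid", 0)), reml_loglik=rll))
    return fits


# --------------------------------------------------------------------------
# predictions, regions, truth records

def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    _to_csv(table, path)


def read_regions(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    _require(df, ("country_id", "region"), "regions.csv")
    return {str(r["country_id"]): str(r["region"])
            for r in df.to_dict("records")}


def write_regions(regions: Mapping[str, str], path: str | Path) -> None:
    _to_csv(pd.DataFrame({"country_id": list(regions),
                          "region": list(regions.values())}), path)


def _flatten(value, prefix: str, out: dict[str, str]) -> None:
    if isinstance(value, Mapping):
        for k, v in value.items():
            key = ".".join(str(p) for p in k) if isinstance(k, tuple) \
                else str(k)
            if isinstance(v, Mapping) or (isinstance(v, list)
                                          and not _is_leaf_list(v)):
                _flatten(v, f"{prefix}{key}.", out)
            else:
                out[f"{prefix}{key}"] = _fmt_leaf(v)
    elif isinstance(value, list):
        for i, v in enumerate(value):
            if isinstance(v, (Mapping, list)) and not _is_leaf_list(v):
                _flatten(v, f"{prefix}{i}.", out)
            else:
                out[f"{prefix}{i}"] = _fmt_leaf(v)
    else:
        out[prefix.rstrip(".")] = _fmt_leaf(value)


def _is_leaf_list(v) -> bool:
    return isinstance(v, list) and all(
        not isinstance(x, (Mapping, list)) for x in v)


def _fmt_leaf(v) -> str:
    if isinstance(v, list):
        return ",".join(repr(x) if isinstance(x, str) else f"{x}"
                        for x in v)
    return f"{v}"


def write_truth(truth: Mapping, path: str | Path) -> None:
    """Serialize a (possibly nested) truth record as `key = value` lines."""
    flat: dict[str, str] = {}
    _flatten(dict(truth), "", flat)
    with open(path, "w", encoding="utf-8") as fh:
        for k in sorted(flat):
            fh.write(f"{k} = {flat[k]}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
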