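import numpy as np
import pandas as pd
import pytest

from birthrisk import default_specs


@pytest.fixture
def specs():
    return default_specs()


def oracle_classify(order, mother_age, preceding=None):
    """Exhaustive if/else over the stated category bounds.

    Independent of the packaged interval machinery; used to cross-check
    classify_birth.
    """
    out = {}
    if order == 1:
        out["parity"] = "first"
    elif 2 <= order <= 4:
        out["parity"] = "2-4"
    else:
        out["parity"] = "5+"
    if mother_age < 18:
        out["mothers_age"] = "<18"
    elif mother_age < 35:
        out["mothers_age"] = "18-34"
    else:
        out["mothers_age"] = "35+"
    if order > 1:
        if preceding < 18:
            out["spacing"] = "<18mo"
        elif preceding < 24:
            out["spacing"] = "18-23mo"
        elif preceding < 36:
            out["spacing"] = "24-35mo"
        else:
            out["spacing"] = "36+mo"
    return out


def random_births(rng, n):
    """Random valid birth records spanning all category boundaries."""
    orders = rng.integers(1, 10, size=n)
    # force boundary ages/intervals to appear often
    ages = rng.choice([15, 16, 17, 18, 19, 25, 34, 35, 36, 45], size=n)
    intervals = rng.choice([1, 6, 17, 18, 19, 23, 24, 25, 35, 36, 37, 90],
                           size=n)
    rows = []
    for o, a, iv in zip(orders, ages, intervals):
        rows.append({"birth_order": int(o),
                     "mother_age_at_birth_years": int(a),
                     "preceding_interval_months":
                         int(iv) if o > 1 else None})
    return rows


@pytest.fixture
def survey_fixture():
    """Five-woman survey with hand-computable aggregates.

    Expected values (derived by hand):
      mCPR = 2/3 * 100 (W1 pill, W3 iud modern of eligible W1,W2,W3)
      method mix = (0, 50)
      window births (survey cmc 1260, 36 mo): 4 of the 5 births
      parity: first 50, 2-4 50, 5+ 0
      mothers_age: <18 25, 18-34 75, 35+ 0
      spacing (2 non-first births, intervals 25 and 140): 24-35mo 50,
        36+mo 50
      TFR = 5 * (1/3 + 2/2 + 1/3) = 25/3
    """
    women = pd.DataFrame([
        {"woman_id": "W1", "survey_id": "S1", "age_years": 25,
         "in_union": True, "method_code": "pill", "sample_weight": 1.0},
        {"woman_id": "W2", "survey_id": "S1", "age_years": 30,
         "in_union": True, "method_code": "none", "sample_weight": 1.0},
        {"woman_id": "W3", "survey_id": "S1", "age_years": 17,
         "in_union": True, "method_code": "iud", "sample_weight": 1.0},
        {"woman_id": "W4", "survey_id": "S1", "age_years": 40,
         "in_union": False, "method_code": "none", "sample_weight": 1.0},
        {"woman_id": "W5", "survey_id": "S1", "age_years": 52,
         "in_union": True, "method_code": "pill", "sample_weight": 1.0},
    ])
    births = pd.DataFrame([
        {"woman_id": "W1", "survey_id": "S1", "birth_cmc": 1230,
         "birth_order": 1, "preceding_interval_months": None,
         "mother_age_at_birth_years": 22},
        {"woman_id": "W1", "survey_id": "S1", "birth_cmc": 1255,
         "birth_order": 2, "preceding_interval_months": 25,
         "mother_age_at_birth_years": 24},
        {"woman_id": "W2", "survey_id": "S1", "birth_cmc": 1100,
         "birth_order": 1, "preceding_interval_months": None,
         "mother_age_at_birth_years": 16},
        {"woman_id": "W2", "survey_id": "S1", "birth_cmc": 1240,
         "birth_order": 2, "preceding_interval_months": 140,
         "mother_age_at_birth_years": 28},
        {"woman_id": "W3", "survey_id": "S1", "birth_cmc": 1259,
         "birth_order": 1, "preceding_interval_months": None,
         "mother_age_at_birth_years": 16},
    ])
    meta = {"survey_id": "S1", "country_id": "C1", "year": 2005,
            "survey_cmc": 1260}
    return women, births, meta


def ols_oracle(X, y):
    """Independent normal-equations solve: beta = (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)
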