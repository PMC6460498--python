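"""Shared fixtures: a default lexicon, tiny hand-built cohorts, and builders."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from medconcord import Lexicon


@lru_cache(maxsize=1)
def _default_lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def lexicon():
    return _default_lexicon()


def med_frame(rows, stream="prescribing"):
    """Build a minimal medication-record frame.

    rows: iterable of (record_id, patid, day, code) or
    (record_id, patid, day, code, institution_id).
    """
    recs = []
    for row in rows:
        rid, patid, day, code = row[:4]
        inst = row[4] if len(row) > 4 else "I1"
        recs.append({"record_id": rid, "patid": patid, "day": int(day),
                     "code": str(code), "raw_name": "", "stream": stream,
                     "institution_id": inst})
    cols = ["record_id", "patid", "institution_id", "day", "code", "raw_name", "stream"]
    return pd.DataFrame(recs, columns=cols) if recs else pd.DataFrame(columns=cols)


def prepared_frame(rows, stream="prescribing", lexicon=None):
    """Medication frame with lexicon attributes already attached."""
    lexicon = lexicon or _default_lexicon()
    df = med_frame(rows, stream=stream)
    out = lexicon.classify_frame(df)
    if out["name"].isna().any():
        raise ValueError("fixture uses codes missing from the lexicon")
    out["same_day_enc"] = "AV"
    out["tier"] = "2"
    return out


def patient_frame(patids, institution_type="cIDS", **overrides):
    n = len(patids)
    rng = np.random.default_rng(0)
    base = {
        "patid": list(patids),
        "institution_id": ["I1"] * n,
        "institution_type": [institution_type] * n,
        "sex": ["male"] * n,
        "race": ["White"] * n,
        "hispanic": ["no_unknown"] * n,
        "chronic_condition": [False] * n,
        "asthma": [False] * n,
        "preterm": [False] * n,
        "encounter_count": rng.integers(1, 60, n),
    }
    base.update(overrides)
    return pd.DataFrame(base)


# commonly used codes (bundled lexicon)
AMOX_RX = "1002"          # amoxicillin, RxNorm-style
AMOX_NDC = "55555-0002-01"
PCN_RX = "1001"           # penicillin (same class/spectrum as amoxicillin)
AZITHRO_RX = "1013"       # azithromycin, broad
AZITHRO_NDC = "55555-0013-01"
AUGMENTIN_RX = "1004"     # amoxicillin-clavulanate, broad combination
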