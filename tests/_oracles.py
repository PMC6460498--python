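"""Independent oracles used by the unit and acceptance tests.

Each oracle re-implements an operation's definition with deliberately naive
machinery (exhaustive scans, direct formula evaluation) so it shares no code
with the pipeline implementation it checks.
"""

import numpy as np
import pandas as pd


def oracle_match(source: pd.DataFrame, target: pd.DataFrame, direction: str,
                 window: int = 7):
    """Exhaustive per-source matching under the stated resolution rule.

    Sources in (day, record_id) order; for each, scan EVERY target record
    and keep the eligible, unconsumed one with the smallest gap (ties:
    earliest target day, then smallest record_id).  O(n*m), no grouping, no
    sorting tricks.
    """
    pairs = []
    consumed = set()
    src = sorted(source.to_dict("records"), key=lambda r: (r["day"], r["record_id"]))
    tgt = target.to_dict("records")
    for s in src:
        best = None
        for t in tgt:
            if t["record_id"] in consumed:
                continue
            if t["patid"] != s["patid"]:
                continue
            if (t["spectrum"], t["med_class"], t["name"]) != \
                    (s["spectrum"], s["med_class"], s["name"]):
                continue
            delta = t["day"] - s["day"] if direction == "rx_to_disp" \
                else s["day"] - t["day"]
            if not 0 <= delta <= window:
                continue
            gap = abs(t["day"] - s["day"])
            key = (gap, t["day"], t["record_id"])
            if best is None or key < best[0]:
                best = (key, t)
        if best is not None:
            consumed.add(best[1]["record_id"])
            pairs.append((s["record_id"], best[1]["record_id"], best[0][0]))
    return sorted(pairs)


def random_instance(seed: int, max_records: int = 20):
    """A small random two-stream instance over few patients/medications/days."""
    from conftest import prepared_frame
    rng = np.random.default_rng(seed)
    codes_rx = ["1002", "1001", "1013", "1004"]
    codes_ndc = ["55555-0002-01", "55555-0001-01", "55555-0013-01", "55555-0004-01"]
    n_rx = int(rng.integers(0, max_records + 1))
    n_dp = int(rng.integers(0, max_records + 1))
    rx_rows, dp_rows = [], []
    for i in range(n_rx):
        rx_rows.append((f"r{i:02d}", f"P{rng.integers(3)}", int(rng.integers(20)),
                        codes_rx[rng.integers(len(codes_rx))]))
    for i in range(n_dp):
        dp_rows.append((f"d{i:02d}", f"P{rng.integers(3)}", int(rng.integers(20)),
                        codes_ndc[rng.integers(len(codes_ndc))]))
    rx = prepared_frame(rx_rows, stream="prescribing")
    dp = prepared_frame(dp_rows, stream="dispensing")
    # instances must be de-duplicated like real prepared streams
    rx = rx.drop_duplicates(["patid", "day", "stream"]).reset_index(drop=True)
    dp = dp.drop_duplicates(["patid", "day", "stream"]).reset_index(drop=True)
    return rx, dp


def oracle_weighted_kappa(table: np.ndarray, scheme: str = "linear") -> float:
    """Direct evaluation of kappa_w = 1 - sum(wO)/sum(wE), element by element."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    n = table.sum()
    w = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            w[i, j] = abs(i - j) / (k - 1)
            if scheme == "quadratic":
                w[i, j] = w[i, j] ** 2
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    num = sum(w[i, j] * table[i, j] for i in range(k) for j in range(k))
    den = sum(w[i, j] * row[i] * col[j] / n for i in range(k) for j in range(k))
    return 1.0 - num / den


def simulate_logit_design(seed: int, n: int = 20000, *, beta: float = 0.0,
                          n_inst: int = 20, re_sd: float = 0.1,
                          intercept: float = -2.0, p_x: float = 0.3):
    """Clustered binary-outcome design with one binary covariate of known log-OR."""
    rng = np.random.default_rng(seed)
    inst = rng.integers(0, n_inst, n)
    u = rng.normal(0.0, re_sd, n_inst)
    x = rng.random(n) < p_x
    p = 1.0 / (1.0 + np.exp(-(intercept + beta * x + u[inst])))
    y = rng.random(n) < p
    return pd.DataFrame({
        "outcome": y,
        "xcov": np.where(x, "yes", "no"),
        "institution_id": [f"I{i}" for i in inst],
        "patid": [f"P{i}" for i in range(n)],
    })
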