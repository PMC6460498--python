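"""Directional prescribing<->dispensing matching within a day window.

The core operation of the concordance analysis.  Each source record (say, a
prescription) is matched to a target record (a pharmacy fill) of the same
patient and the same medication specification (spectrum, class, name) whose
day falls within a window after the prescription — by default 0 to 7 days
inclusive, since same-day fills dominate in practice.  The same procedure is
run in the opposite direction to match dispensings back to prescriptions.

When a source has several eligible targets, the pair with the smallest day
gap wins.  Targets are consumed one-to-one: once paired, a target is
unavailable to later sources, which keeps the per-record match flags
well-defined and prevents double counting.  Sources are processed in
(day, record_id) order and every tie-break is fixed, so the assignment is
invariant under shuffling of the input rows.

The resulting per-record binary flag (1 = match, 0 = no match) is the
outcome variable for all downstream agreement and missingness analyses.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MatchedPair", "MatchResult", "match_directional", "unmatched"]

#: Columns that define "same medication specification".
SPEC_KEYS = ["spectrum", "med_class", "name"]

_SOURCE_STREAM = {"rx_to_disp": "prescribing", "disp_to_rx": "dispensing"}
_TARGET_STREAM = {"rx_to_disp": "dispensing", "disp_to_rx": "prescribing"}


@dataclass(frozen=True)
class MatchedPair:
    source_id: str
    target_id: str
    gap_days: int


@dataclass
class MatchResult:
    """Pairs plus per-record flags for one matching direction."""

    direction: str                      # "rx_to_disp" | "disp_to_rx"
    pairs: pd.DataFrame                 # source_id, target_id, gap_days
    source_flags: pd.Series             # record_id -> bool, every source record
    target_flags: pd.Series             # record_id -> bool, every target record
    window_days: int = 7

    @property
    def flags(self) -> pd.Series:
        """record_id -> matched, over both streams."""
        return pd.concat([self.source_flags, self.target_flags])

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def flags_for(self, stream: str) -> pd.Series:
        if stream == _SOURCE_STREAM[self.direction]:
            return self.source_flags
        if stream == _TARGET_STREAM[self.direction]:
            return self.target_flags
        raise ValueError(f"unknown stream {stream!r}")

    def to_frame(self) -> pd.DataFrame:
        """Audit table: record_id, stream, direction, matched, gap_days."""
        gap_by_source = self.pairs.set_index("source_id")["gap_days"]
        gap_by_target = self.pairs.set_index("target_id")["gap_days"]
        rows = []
        for stream, flags, gaps in (
            (_SOURCE_STREAM[self.direction], self.source_flags, gap_by_source),
            (_TARGET_STREAM[self.direction], self.target_flags, gap_by_target),
        ):
            f = flags.rename("matched").rename_axis("record_id").reset_index()
            f["stream"] = stream
            f["direction"] = self.direction
            f["gap_days"] = f["record_id"].map(gaps)
            rows.append(f)
        return pd.concat(rows, ignore_index=True)[
            ["record_id", "stream", "direction", "matched", "gap_days"]]


def _match_group(src_day, src_id, tgt_day, tgt_id, lo_off, hi_off, consumed,
                 consume_targets):
    """Greedy min-gap assignment within one (patient, specification) group.

    Sources arrive sorted by (day, record_id); targets are sorted likewise.
    Eligibility: tgt_day in [src_day + lo_off, src_day + hi_off].
    """
    pairs = []
    for s in range(len(src_day)):
        lo = bisect_left(tgt_day, src_day[s] + lo_off)
        hi = bisect_right(tgt_day, src_day[s] + hi_off)
        best = -1
        best_gap = None
        for t in range(lo, hi):
            if consumed[t]:
                continue
            gap = abs(tgt_day[t] - src_day[s])
            # min gap, then earliest target day, then smallest record_id;
            # targets are day-then-id sorted, so on equal (gap, day) the
            # first unconsumed index wins.
            if best_gap is None or gap < best_gap or (
                    gap == best_gap and (tgt_day[t], tgt_id[t]) < (tgt_day[best], tgt_id[best])):
                best, best_gap = t, gap
        if best >= 0:
            if consume_targets:
                consumed[best] = True
            pairs.append((src_id[s], tgt_id[best], best_gap))
    return pairs


def match_directional(source: pd.DataFrame, target: pd.DataFrame, direction: str,
                      window_days: int = 7, *,
                      consume_targets: bool = True) -> MatchResult:
    """Match each source record to its closest eligible target record.

    Parameters
    ----------
    source, target
        Prepared (classified, de-duplicated) record frames with columns
        ``record_id``, ``patid``, ``day`` and the specification columns
        ``spectrum``/``med_class``/``name``.
    direction
        ``"rx_to_disp"``: source = prescribing, target = dispensing, and a
        target is eligible when ``0 <= day(target) - day(source) <= window``.
        ``"disp_to_rx"``: source = dispensing, target = prescribing, with
        the prescription preceding the fill by 0..window days.
    window_days
        Inclusive window width in days (default 7).
    consume_targets
        One-to-one assignment (default).  ``False`` lets several sources
        share a target, in which case only source flags are one-to-one.

    Returns a :class:`MatchResult` with the pair list and complete match
    flags for every input record on both sides.
    """
    if direction not in _SOURCE_STREAM:
        raise ValueError(f"direction must be rx_to_disp or disp_to_rx, got {direction!r}")
    if window_days < 0:
        raise ValueError(f"window_days must be >= 0, got {window_days}")

    # prescription must precede the fill: offsets relative to the source day
    lo_off, hi_off = (0, window_days) if direction == "rx_to_disp" else (-window_days, 0)

    all_pairs: list[tuple[str, str, int]] = []
    if len(source) and len(target):
        keys = ["patid", *SPEC_KEYS]
        src_sorted = source.sort_values(["day", "record_id"], kind="mergesort")
        tgt_sorted = target.sort_values(["day", "record_id"], kind="mergesort")
        tgt_groups = {k: g for k, g in tgt_sorted.groupby(keys, sort=False)}
        for key, sgrp in src_sorted.groupby(keys, sort=False):
            tgrp = tgt_groups.get(key)
            if tgrp is None:
                continue
            consumed = np.zeros(len(tgrp), dtype=bool)
            all_pairs.extend(_match_group(
                sgrp["day"].tolist(), sgrp["record_id"].tolist(),
                tgrp["day"].tolist(), tgrp["record_id"].tolist(),
                lo_off, hi_off, consumed, consume_targets))

    pairs = pd.DataFrame(all_pairs, columns=["source_id", "target_id", "gap_days"])
    src_ids = source["record_id"] if len(source) else pd.Series([], dtype=str)
    tgt_ids = target["record_id"] if len(target) else pd.Series([], dtype=str)
    source_flags = pd.Series(False, index=pd.Index(src_ids, name="record_id"))
    target_flags = pd.Series(False, index=pd.Index(tgt_ids, name="record_id"))
    if len(pairs):
        source_flags[pairs["source_id"].values] = True
        target_flags.loc[target_flags.index.isin(pairs["target_id"])] = True
    return MatchResult(direction=direction, pairs=pairs,
                       source_flags=source_flags, target_flags=target_flags,
                       window_days=window_days)


def unmatched(result: MatchResult, stream: str) -> set[str]:
    """Record ids in ``stream`` that did not receive a match."""
    flags = result.flags_for(stream)
    return set(flags.index[~flags])
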