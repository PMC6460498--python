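"""Record cleaning: same-day annotation, IP/ED exclusion, same-day de-duplication."""

import numpy as np
import pandas as pd
import pytest

from medconcord import (annotate_same_day, classify_records, dedup_same_day,
                        exclude_ip_ed, prepare_stream)

from conftest import med_frame, prepared_frame


def _enc(rows):
    return pd.DataFrame(rows, columns=["patid", "day", "enc_type"])


def _dx(rows):
    return pd.DataFrame(rows, columns=["patid", "day", "tier"])


class TestAnnotateSameDay:
    def test_same_day_encounter_attached(self, lexicon):
        recs = prepared_frame([("r1", "A", 10, "1002")], lexicon=lexicon)
        out = annotate_same_day(recs.drop(columns=["same_day_enc", "tier"]),
                                _enc([("A", 10, "AV")]), _dx([("A", 10, "1")]))
        assert out.loc[0, "same_day_enc"] == "AV"
        assert out.loc[0, "tier"] == "1"

    def test_no_encounter_that_day_is_missing(self, lexicon):
        recs = prepared_frame([("r1", "A", 10, "1002")], lexicon=lexicon)
        out = annotate_same_day(recs.drop(columns=["same_day_enc", "tier"]),
                                _enc([("A", 11, "AV")]), _dx([]))
        assert out.loc[0, "same_day_enc"] == "missing"
        assert out.loc[0, "tier"] == "other_missing"

    def test_multiple_encounters_use_priority(self, lexicon):
        """IP outranks AV when both happen on the record's day."""
        recs = prepared_frame([("r1", "A", 10, "1002")], lexicon=lexicon)
        base = recs.drop(columns=["same_day_enc", "tier"])
        out = annotate_same_day(base, _enc([("A", 10, "AV"), ("A", 10, "IP")]), _dx([]))
        assert out.loc[0, "same_day_enc"] == "IP"
        # exhaustive pairwise check of the stated priority IP > ED > AV > OT > UN
        order = ["IP", "ED", "AV", "OT", "UN"]
        for i, hi in enumerate(order):
            for lo in order[i + 1:]:
                out = annotate_same_day(
                    base, _enc([("A", 10, lo), ("A", 10, hi)]), _dx([]))
                assert out.loc[0, "same_day_enc"] == hi, (hi, lo)

    def test_multiple_diagnoses_keep_lowest_tier(self, lexicon):
        recs = prepared_frame([("r1", "A", 5, "1002")], lexicon=lexicon)
        out = annotate_same_day(recs.drop(columns=["same_day_enc", "tier"]),
                                _enc([]), _dx([("A", 5, "3"), ("A", 5, "2")]))
        assert out.loc[0, "tier"] == "2"


class TestExcludeIpEd:
    def test_keeps_av_and_missing_only(self, lexicon):
        recs = prepared_frame([(f"r{i}", "A", i, "1002") for i in range(4)],
                              lexicon=lexicon)
        recs["same_day_enc"] = ["AV", "IP", "ED", "missing"]
        kept, n_excl = exclude_ip_ed(recs)
        assert n_excl == 2
        assert sorted(kept["same_day_enc"]) == ["AV", "missing"]

    def test_all_ambulatory_is_identity(self, lexicon):
        recs = prepared_frame([("r1", "A", 1, "1002")], lexicon=lexicon)
        kept, n_excl = exclude_ip_ed(recs)
        assert n_excl == 0 and len(kept) == 1

    def test_empty_input(self, lexicon):
        recs = prepared_frame([], lexicon=lexicon)
        kept, n_excl = exclude_ip_ed(recs)
        assert len(kept) == 0 and n_excl == 0

    def test_idempotent(self, lexicon):
        recs = prepared_frame([(f"r{i}", "A", i, "1002") for i in range(4)],
                              lexicon=lexicon)
        recs["same_day_enc"] = ["AV", "IP", "ED", "UN"]
        once, _ = exclude_ip_ed(recs)
        twice, n = exclude_ip_ed(once)
        pd.testing.assert_frame_equal(once, twice)
        assert n == 0


class TestDedupSameDay:
    def test_broadest_spectrum_wins(self, lexicon):
        recs = prepared_frame([("r1", "A", 5, "1002"),   # amoxicillin, narrow
                               ("r2", "A", 5, "1013")],  # azithromycin, broad
                              lexicon=lexicon)
        out = dedup_same_day(recs)
        assert len(out) == 1
        assert out.loc[0, "name"] == "azithromycin"

    def test_equal_spectrum_tiebreak_is_order_invariant(self, lexicon):
        # two broad records, different classes: lexicographic class wins
        rows = [("r9", "A", 5, "1013"),   # macrolides
                ("r1", "A", 5, "1006")]   # cephalosporins_1st_gen
        survivors = set()
        for perm in ([0, 1], [1, 0]):
            recs = prepared_frame([rows[i] for i in perm], lexicon=lexicon)
            out = dedup_same_day(recs)
            survivors.add(out.loc[0, "record_id"])
        assert survivors == {"r1"}  # cephalosporins < macrolides

    def test_single_record_untouched(self, lexicon):
        recs = prepared_frame([("r1", "A", 5, "1002")], lexicon=lexicon)
        pd.testing.assert_frame_equal(dedup_same_day(recs), recs)

    def test_idempotent_and_unique_per_patient_day_stream(self, lexicon):
        rng = np.random.default_rng(3)
        codes = ["1002", "1013", "1004", "1001", "1006"]
        rows = [(f"r{i}", f"P{rng.integers(3)}", int(rng.integers(4)),
                 codes[rng.integers(len(codes))]) for i in range(40)]
        recs = prepared_frame(rows, lexicon=lexicon)
        out = dedup_same_day(recs)
        assert len(out) <= len(recs)
        assert not out.duplicated(["patid", "day", "stream"]).any()
        pd.testing.assert_frame_equal(dedup_same_day(out), out)

    def test_survivor_spectrum_is_daily_max(self, lexicon):
        rng = np.random.default_rng(4)
        codes = ["1002", "1013", "1004", "1001"]
        rows = [(f"r{i}", "A", int(rng.integers(3)),
                 codes[rng.integers(len(codes))]) for i in range(20)]
        recs = prepared_frame(rows, lexicon=lexicon)
        out = dedup_same_day(recs).set_index("day")
        for day, grp in recs.groupby("day"):
            want = "broad" if (grp["spectrum"] == "broad").any() else "narrow"
            assert out.loc[day, "spectrum"] == want


class TestPrepareStream:
    def test_unclassified_codes_dropped_and_counted(self, lexicon):
        recs = med_frame([("r1", "A", 1, "1002"), ("r2", "A", 2, "junk")])
        out, n_bad = classify_records(recs, lexicon)
        assert n_bad == 1 and len(out) == 1

    def test_full_chain_audit_reconciles(self, lexicon):
        recs = med_frame([("r1", "A", 1, "1002"), ("r2", "A", 1, "1013"),
                          ("r3", "A", 2, "junk"), ("r4", "B", 3, "1002")])
        out, log = prepare_stream(recs, _enc([("B", 3, "IP")]), _dx([]), lexicon)
        assert log.n_input == 4
        assert log.n_unclassified == 1
        assert log.n_excluded_ip_ed == 1
        assert log.n_dedup_removed == 1
        assert log.n_final == len(out) == 1
        assert log.n_input - log.n_unclassified - log.n_excluded_ip_ed \
            - log.n_dedup_removed == log.n_final

    def test_enc_filter_toggle(self, lexicon):
        recs = med_frame([("r1", "A", 1, "1002")])
        out, log = prepare_stream(recs, _enc([("A", 1, "ED")]), _dx([]), lexicon,
                                  apply_enc_filter=False)
        assert len(out) == 1 and log.n_excluded_ip_ed == 0
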