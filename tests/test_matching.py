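"""Directional 7-day-window matching: examples, tie-breaks, and oracle agreement."""

import pandas as pd
import pytest

from medconcord import match_directional, unmatched

from _oracles import oracle_match, random_instance
from conftest import prepared_frame


def _pairs(result):
    return sorted(map(tuple, result.pairs.to_numpy()))


class TestExamples:
    def test_same_day_same_med_matches_with_gap_zero(self):
        rx = prepared_frame([("r1", "A", 5, "1002")])
        dp = prepared_frame([("d1", "A", 5, "55555-0002-01")], stream="dispensing")
        res = match_directional(rx, dp, "rx_to_disp")
        assert _pairs(res) == [("r1", "d1", 0)]

    def test_smaller_gap_preferred(self):
        rx = prepared_frame([("r1", "A", 0, "1002")])
        dp = prepared_frame([("d3", "A", 3, "55555-0002-01"),
                             ("d5", "A", 5, "55555-0002-01")], stream="dispensing")
        res = match_directional(rx, dp, "rx_to_disp")
        assert _pairs(res) == [("r1", "d3", 3)]

    def test_gap_beyond_window_no_pair(self):
        rx = prepared_frame([("r1", "A", 0, "1002")])
        dp = prepared_frame([("d1", "A", 8, "55555-0002-01")], stream="dispensing")
        res = match_directional(rx, dp, "rx_to_disp")
        assert res.n_pairs == 0
        assert not res.source_flags["r1"]

    def test_gap_exactly_seven_matches(self):
        rx = prepared_frame([("r1", "A", 0, "1002")])
        dp = prepared_frame([("d1", "A", 7, "55555-0002-01")], stream="dispensing")
        assert match_directional(rx, dp, "rx_to_disp").n_pairs == 1

    def test_different_specification_no_pair(self):
        rx = prepared_frame([("r1", "A", 0, "1002")])          # amoxicillin
        dp = prepared_frame([("d1", "A", 2, "55555-0013-01")],  # azithromycin
                            stream="dispensing")
        assert match_directional(rx, dp, "rx_to_disp").n_pairs == 0

    def test_dispensing_before_prescription_ineligible(self):
        # prescription must precede the fill in both directions
        rx = prepared_frame([("r1", "A", 5, "1002")])
        dp = prepared_frame([("d1", "A", 3, "55555-0002-01")], stream="dispensing")
        assert match_directional(rx, dp, "rx_to_disp").n_pairs == 0
        assert match_directional(dp, rx, "disp_to_rx").n_pairs == 0
        # with the fill after the prescription both directions pair them
        dp2 = prepared_frame([("d1", "A", 6, "55555-0002-01")], stream="dispensing")
        assert match_directional(rx, dp2, "rx_to_disp").n_pairs == 1
        assert match_directional(dp2, rx, "disp_to_rx").n_pairs == 1

    def test_negative_window_rejected(self):
        rx = prepared_frame([("r1", "A", 0, "1002")])
        with pytest.raises(ValueError, match="window"):
            match_directional(rx, rx, "rx_to_disp", window_days=-1)


class TestConsumption:
    def test_target_consumed_once(self):
        rx = prepared_frame([("r1", "A", 0, "1002"), ("r2", "A", 1, "1002")])
        dp = prepared_frame([("d1", "A", 1, "55555-0002-01")], stream="dispensing")
        res = match_directional(rx, dp, "rx_to_disp")
        assert res.n_pairs == 1
        assert _pairs(res) == [("r1", "d1", 1)]  # earlier source wins

    def test_no_consumption_allows_sharing(self):
        rx = prepared_frame([("r1", "A", 0, "1002"), ("r2", "A", 1, "1002")])
        dp = prepared_frame([("d1", "A", 1, "55555-0002-01")], stream="dispensing")
        res = match_directional(rx, dp, "rx_to_disp", consume_targets=False)
        assert res.n_pairs == 2
        assert res.source_flags.all()


class TestFlagsAndUnmatched:
    def test_flags_partition_each_stream(self):
        rx, dp = random_instance(42)
        res = match_directional(rx, dp, "rx_to_disp")
        assert set(res.source_flags.index) == set(rx["record_id"])
        assert set(res.target_flags.index) == set(dp["record_id"])
        assert int(res.source_flags.sum()) == res.n_pairs
        assert int(res.target_flags.sum()) == res.n_pairs

    def test_unmatched_is_flag_complement(self):
        rx, dp = random_instance(7)
        res = match_directional(rx, dp, "rx_to_disp")
        assert unmatched(res, "prescribing") == \
            set(rx["record_id"]) - set(res.pairs["source_id"])
        assert unmatched(res, "dispensing") == \
            set(dp["record_id"]) - set(res.pairs["target_id"])

    def test_empty_streams(self):
        empty = prepared_frame([])
        res = match_directional(empty, empty, "disp_to_rx")
        assert res.n_pairs == 0
        assert unmatched(res, "prescribing") == set()


class TestProperties:
    @pytest.mark.parametrize("seed", range(60))
    def test_agrees_with_exhaustive_oracle(self, seed):
        """Grouped/sorted implementation == naive full-scan oracle."""
        rx, dp = random_instance(seed)
        for direction, (src, tgt) in {"rx_to_disp": (rx, dp),
                                      "disp_to_rx": (dp, rx)}.items():
            got = _pairs(match_directional(src, tgt, direction))
            assert got == oracle_match(src, tgt, direction), (seed, direction)

    @pytest.mark.parametrize("seed", range(20))
    def test_window_monotonicity(self, seed):
        rx, dp = random_instance(seed + 1000)
        counts = [match_directional(rx, dp, "rx_to_disp", w).n_pairs
                  for w in (0, 3, 7, 14)]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(20))
    def test_pair_count_bounded(self, seed):
        rx, dp = random_instance(seed + 2000)
        res = match_directional(rx, dp, "rx_to_disp")
        assert res.n_pairs <= min(len(rx), len(dp))

    def test_input_order_invariance(self):
        rx, dp = random_instance(5)
        res1 = match_directional(rx, dp, "rx_to_disp")
        res2 = match_directional(rx.sample(frac=1, random_state=0),
                                 dp.sample(frac=1, random_state=1), "rx_to_disp")
        assert _pairs(res1) == _pairs(res2)

    def test_directions_agree_on_one_to_one_instances(self):
        """When eligibility is one-to-one, both directions find identical pairs."""
        rx = prepared_frame([("r1", "A", 0, "1002"), ("r2", "A", 30, "1013"),
                             ("r3", "B", 10, "1004")])
        dp = prepared_frame([("d1", "A", 2, "55555-0002-01"),
                             ("d2", "A", 31, "55555-0013-01"),
                             ("d3", "B", 17, "55555-0004-01")], stream="dispensing")
        fwd = match_directional(rx, dp, "rx_to_disp")
        rev = match_directional(dp, rx, "disp_to_rx")
        assert {(a, b) for a, b, _ in _pairs(fwd)} == \
            {(b, a) for a, b, _ in _pairs(rev)}


def test_audit_frame_covers_every_record():
    rx, dp = random_instance(3)
    res = match_directional(rx, dp, "rx_to_disp")
    audit = res.to_frame()
    assert len(audit) == len(rx) + len(dp)
    assert audit.loc[audit["matched"], "gap_days"].notna().all()
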