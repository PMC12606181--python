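import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dyadseq as dq
from dyadseq.ethogram import FormatError, RepertoireError


@pytest.mark.parametrize("behavior,tier", [
    ("proximity", dq.RiskTier.LOW),
    ("shoulder_contact", dq.RiskTier.MODERATE),
    ("allopreen", dq.RiskTier.MODERATE),
    ("beak_touch", dq.RiskTier.MODERATE),
    ("allofeed", dq.RiskTier.HIGH),
    ("copulation", dq.RiskTier.HIGH),
])
def test_risk_tier_mapping_is_total(behavior, tier):
    assert dq.tier_of(behavior) == tier


def test_unknown_behavior_raises():
    with pytest.raises(RepertoireError):
        dq.tier_of("flying")


class TestEnumerateDyads:
    def test_study_design_site_sizes(self):
        """Sites of 5/6/7/4 birds give 52 same-site and 179 cross-site pairs."""
        sizes = [5, 6, 7, 4]
        ids, sexes, sites = [], [], []
        for s, n in enumerate(sizes):
            for k in range(n):
                ids.append(f"S{s}B{k}")
                sexes.append("F" if (s + k) % 3 == 0 else "M")
                sites.append(f"site{s}")
        roster = pd.DataFrame({"id": ids, "sex": sexes, "site": sites})
        dyads = dq.enumerate_dyads(roster)
        counts = dyads["familiarity"].value_counts()
        assert counts["familiar"] == 52
        assert counts["stranger"] == 179

    def test_single_bird_has_no_dyads(self):
        roster = pd.DataFrame({"id": ["A"], "sex": ["F"], "site": ["S1"]})
        assert len(dq.enumerate_dyads(roster)) == 0

    def test_single_site_all_familiar(self):
        roster = pd.DataFrame({"id": list("ABC"), "sex": ["F", "M", "M"], "site": ["S1"] * 3})
        dyads = dq.enumerate_dyads(roster)
        assert len(dyads) == 3
        assert (dyads["familiarity"] == "familiar").all()

    def test_duplicate_id_rejected(self):
        roster = pd.DataFrame({"id": ["A", "A"], "sex": ["F", "M"], "site": ["S1", "S2"]})
        with pytest.raises(FormatError):
            dq.enumerate_dyads(roster)

    def test_sex_composition_is_canonical(self, tiny_roster):
        dyads = dq.enumerate_dyads(tiny_roster)
        assert set(dyads["sex_composition"]) <= {"FF", "MF", "MM"}
        row = dyads.set_index(["member_low", "member_high"])
        assert row.loc[("A", "B"), "sex_composition"] == "MF"  # F+M
        assert row.loc[("A", "D"), "sex_composition"] == "FF"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=5))
    def test_familiar_and_stranger_partition_all_pairs(self, sizes):
        ids, sites = [], []
        for s, n in enumerate(sizes):
            ids += [f"S{s}B{k}" for k in range(n)]
            sites += [f"site{s}"] * n
        roster = pd.DataFrame({"id": ids, "sex": ["M"] * len(ids), "site": sites})
        dyads = dq.enumerate_dyads(roster)
        n = len(ids)
        assert len(dyads) == n * (n - 1) // 2
        n_fam = sum(m * (m - 1) // 2 for m in sizes)
        assert (dyads["familiarity"] == "familiar").sum() == n_fam


def _obs(rows):
    return pd.DataFrame(rows, columns=[
        "session_id", "observer_id", "timestamp", "behavior", "actor", "receiver"
    ])


class TestReadObservations:
    def test_well_formed_rows_pass_through(self, tmp_path, tiny_roster):
        df = _obs([
            ("s1", "o1", "10", "proximity", "A", "B"),
            ("s1", "o1", "400", "allopreen", "C", "D"),
            ("s1", "o2", "3000", "copulation", "A", "C"),
        ])
        p = tmp_path / "obs.csv"
        df.to_csv(p, index=False)
        recs = dq.read_observations(p, tiny_roster)
        assert len(recs) == 3
        assert recs["time_s"].tolist() == [10.0, 400.0, 3000.0]

    def test_out_of_repertoire_and_unknown_bird_rejected(self, tmp_path, tiny_roster, caplog):
        df = _obs([
            ("s1", "o1", "10", "flying", "A", "B"),
            ("s1", "o1", "20", "proximity", "A", "Z"),
            ("s1", "o1", "30", "proximity", "A", "A"),
            ("s1", "o1", "40", "proximity", "A", ""),
            ("s1", "o1", "50", "proximity", "A", "B"),
        ])
        p = tmp_path / "obs.csv"
        df.to_csv(p, index=False)
        with caplog.at_level("WARNING"):
            recs = dq.read_observations(p, tiny_roster)
        assert len(recs) == 1
        assert "flying" in caplog.text

    def test_missing_column_is_format_error(self, tmp_path, tiny_roster):
        p = tmp_path / "obs.csv"
        pd.DataFrame({"session_id": ["s1"], "actor": ["A"]}).to_csv(p, index=False)
        with pytest.raises(FormatError):
            dq.read_observations(p, tiny_roster)

    def test_empty_file_gives_empty_frame(self, tmp_path, tiny_roster):
        p = tmp_path / "obs.csv"
        p.write_text("")
        assert len(dq.read_observations(p, tiny_roster)) == 0

    def test_exact_duplicate_rows_survive_until_binarize(
        self, tmp_path, tiny_roster, one_session_schedule
    ):
        df = _obs([
            ("s1", "o1", "100", "allopreen", "A", "B"),
            ("s1", "o1", "100", "allopreen", "A", "B"),
        ])
        p = tmp_path / "obs.csv"
        df.to_csv(p, index=False)
        recs = dq.read_observations(p, tiny_roster)
        assert len(recs) == 2  # dedup is a bin-level concept
        m = dq.binarize(recs, tiny_roster, one_session_schedule)
        assert len(m.occurrences) == 1

    def test_iso_timestamps_normalized_from_schedule(
        self, tmp_path, tiny_roster, one_session_schedule
    ):
        df = _obs([("s1", "o1", "2021-04-01T08:10:01", "proximity", "A", "B")])
        p = tmp_path / "obs.csv"
        df.to_csv(p, index=False)
        recs = dq.read_observations(p, tiny_roster, one_session_schedule)
        assert recs["time_s"].tolist() == [601.0]


class TestBinarize:
    def test_two_observers_same_interaction_single_occurrence(
        self, tiny_roster, one_session_schedule
    ):
        recs = _obs([
            ("s1", "o1", 601.0, "allopreen", "A", "B"),
            ("s1", "o2", 655.0, "allopreen", "B", "A"),
        ])
        m = dq.binarize(recs, tiny_roster, one_session_schedule)
        assert len(m.occurrences) == 1
        row = m.occurrences.iloc[0]
        assert row["bin"] == 2 and row["behavior"] == "allopreen"

    def test_half_open_bin_boundaries(self, tiny_roster, one_session_schedule):
        recs = _obs([
            ("s1", "o1", 0.0, "proximity", "A", "B"),
            ("s1", "o1", 299.0, "proximity", "A", "B"),
            ("s1", "o1", 300.0, "proximity", "A", "B"),
        ])
        m = dq.binarize(recs, tiny_roster, one_session_schedule)
        assert sorted(m.occurrences["bin"]) == [0, 1]

    def test_sessions_concatenate_into_global_bins(self, tiny_roster):
        sched = pd.DataFrame({
            "session_id": ["am", "pm"],
            "date": ["2021-04-01", "2021-04-01"],
            "start": ["08:00:00", "15:00:00"],
            "end": ["09:00:00", "16:00:00"],
        })
        recs = _obs([("pm", "o1", 10.0, "proximity", "A", "B")])
        m = dq.binarize(recs, tiny_roster, sched)
        assert m.n_bins == 24
        assert m.occurrences["bin"].tolist() == [12]  # first bin of second session
        assert m.hours_observed == 2.0

    def test_no_records_gives_empty_tensor(self, tiny_roster, one_session_schedule):
        m = dq.binarize(_obs([]), tiny_roster, one_session_schedule)
        assert len(m.occurrences) == 0 and m.n_bins == 12

    def test_record_outside_session_rejected(self, tiny_roster, one_session_schedule, caplog):
        recs = _obs([
            ("s1", "o1", 4000.0, "proximity", "A", "B"),   # past 1 h session
            ("s1", "o1", 10.0, "proximity", "A", "B"),
        ])
        with caplog.at_level("WARNING"):
            m = dq.binarize(recs, tiny_roster, one_session_schedule)
        assert len(m.occurrences) == 1
        assert "outside" in caplog.text

    def test_order_invariance_and_duplication_idempotence(
        self, tiny_roster, one_session_schedule
    ):
        rows = [
            ("s1", "o1", 10.0, "proximity", "A", "B"),
            ("s1", "o2", 700.0, "allopreen", "C", "A"),
            ("s1", "o1", 1500.0, "copulation", "B", "A"),
            ("s1", "o3", 900.0, "beak_touch", "D", "C"),
        ]
        base = dq.binarize(_obs(rows), tiny_roster, one_session_schedule)
        shuffled = dq.binarize(_obs(rows[::-1]), tiny_roster, one_session_schedule)
        doubled = dq.binarize(_obs(rows + [rows[1]]), tiny_roster, one_session_schedule)
        for other in (shuffled, doubled):
            pd.testing.assert_frame_equal(base.occurrences, other.occurrences)

    def test_every_occurrence_traceable_to_a_record(
        self, tiny_roster, one_session_schedule
    ):
        rows = [
            ("s1", "o1", t, beh, a, b)
            for t, beh, a, b in [
                (10.0, "proximity", "A", "B"), (320.0, "allofeed", "C", "D"),
                (330.0, "allofeed", "D", "C"), (2000.0, "shoulder_contact", "A", "C"),
            ]
        ]
        m = dq.binarize(_obs(rows), tiny_roster, one_session_schedule)
        idx = m.dyad_index()
        raw = {
            (idx[(min(a, b), max(a, b))], beh, math.floor(t / 300))
            for _, _, t, beh, a, b in rows
        }
        got = set(map(tuple, m.occurrences[["dyad", "behavior", "bin"]].itertuples(index=False)))
        assert got == raw
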