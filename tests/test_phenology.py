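"""Checklist filtering, occurrence, window averaging, community snapshots."""

import numpy as np
import pandas as pd
import pytest

import signalniche as sn
from signalniche.errors import ConfigError, DataIntegrityError
from signalniche.phenology import to_day_of_year


def checklist(cid="C1", date=120, protocol="stationary", complete=True,
              n_observers=2, duration_h=1.0, distance_km=0.0, species=""):
    return {
        "checklist_id": cid,
        "date": date,
        "protocol": protocol,
        "complete": complete,
        "n_observers": n_observers,
        "duration_h": duration_h,
        "distance_km": distance_km,
        "species_reported": species,
    }


def table(rows):
    return pd.DataFrame(rows)


class TestFilterChecklists:
    @pytest.mark.parametrize(
        "field,keep_value,reject_value",
        [
            ("n_observers", 10, 11),
            ("duration_h", 5.0, 5.01),
            ("distance_km", 5.0, 5.01),
        ],
    )
    def test_boundary_semantics_strict_inequalities(self, field, keep_value, reject_value):
        rows = [checklist(cid="keep", **{field: keep_value}),
                checklist(cid="drop", **{field: reject_value})]
        kept, _ = sn.filter_checklists(table(rows))
        assert list(kept["checklist_id"]) == ["keep"]

    def test_incomplete_and_protocol_rules(self):
        rows = [
            checklist(cid="a"),
            checklist(cid="b", complete=False),
            checklist(cid="c", protocol="incidental"),
            checklist(cid="d", protocol="traveling", distance_km=2.0),
        ]
        kept, tally = sn.filter_checklists(table(rows))
        assert sorted(kept["checklist_id"]) == ["a", "d"]
        assert tally["incomplete"] == 1
        assert tally["protocol"] == 1

    def test_date_window_rule(self):
        rows = [checklist(cid="in", date=92), checklist(cid="out", date=91),
                checklist(cid="in2", date=167), checklist(cid="out2", date=168)]
        kept, tally = sn.filter_checklists(table(rows))
        assert sorted(kept["checklist_id"]) == ["in", "in2"]
        assert tally["out_of_window"] == 2

    def test_duplicate_ids_dropped(self):
        rows = [checklist(cid="x"), checklist(cid="x"), checklist(cid="y")]
        kept, tally = sn.filter_checklists(table(rows))
        assert sorted(kept["checklist_id"]) == ["x", "y"]
        assert tally["duplicate"] == 1

    def test_idempotent(self):
        rows = [checklist(cid=f"c{i}", n_observers=i) for i in range(1, 15)]
        once, _ = sn.filter_checklists(table(rows))
        twice, _ = sn.filter_checklists(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_field_names_rows(self):
        rows = [checklist(cid="ok"), checklist(cid="bad", duration_h=np.nan)]
        with pytest.raises(DataIntegrityError, match="bad"):
            sn.filter_checklists(table(rows))

    def test_calendar_dates_mapped_to_leap_numbering(self):
        assert to_day_of_year("2020-04-05") == 96
        assert to_day_of_year("2019-04-05") == 96  # non-leap year shifted
        assert to_day_of_year("2020-06-06") == 158
        assert to_day_of_year("2019-02-01") == 32  # pre-March unshifted


class TestOccurrence:
    def test_simple_percentages(self):
        rows = [
            checklist(cid="a", species="X"),
            checklist(cid="b"),
            checklist(cid="c"),
            checklist(cid="d"),
        ]
        occ = sn.occurrence(table(rows), "X")
        assert occ.loc[120] == pytest.approx(25.0)

    def test_species_on_all_checklists(self):
        rows = [checklist(cid=f"c{i}", species="X") for i in range(5)]
        occ = sn.occurrence(table(rows), "X")
        assert occ.loc[120] == pytest.approx(100.0)

    def test_days_without_checklists_are_missing_not_zero(self):
        rows = [checklist(cid="a", date=100, species="X")]
        occ = sn.occurrence(table(rows), "X", day_range=(99, 101))
        assert np.isnan(occ.loc[99])
        assert occ.loc[100] == 100.0
        assert np.isnan(occ.loc[101])

    def test_adding_nonreporting_checklist_never_raises_occurrence(self):
        rows = [checklist(cid="a", species="X"), checklist(cid="b", species="X")]
        before = sn.occurrence(table(rows), "X").loc[120]
        rows.append(checklist(cid="c"))
        after = sn.occurrence(table(rows), "X").loc[120]
        assert after <= before


class TestWindowAverage:
    def test_study_window_yields_21_windows(self):
        daily = pd.DataFrame({"X": 1.0}, index=range(96, 159))
        means, windows = sn.window_average(daily)
        assert len(windows) == 21
        assert windows[0] == (96, 98)
        assert windows[-1] == (156, 158)
        assert len(means) == 21

    def test_constant_series_preserved(self):
        daily = pd.DataFrame({"X": 7.5}, index=range(96, 159))
        means, _ = sn.window_average(daily)
        assert np.allclose(means["X"], 7.5)

    def test_hand_computable_triples(self):
        daily = pd.DataFrame({"X": range(1, 10)}, index=range(1, 10))
        means, windows = sn.window_average(daily, start_day=1, end_day=9, width=3)
        assert list(means["X"]) == [2.0, 5.0, 8.0]
        assert windows == [(1, 3), (4, 6), (7, 9)]

    def test_partition_covers_range_exactly(self):
        _, windows = sn.window_average(
            pd.DataFrame({"X": 0.0}, index=range(96, 159))
        )
        days = [d for ws, we in windows for d in range(ws, we + 1)]
        assert days == list(range(96, 159))

    def test_indivisible_range_rejected(self):
        with pytest.raises(ConfigError):
            sn.window_average(pd.DataFrame({"X": [1.0]}), 96, 157, 3)

    def test_missing_days_excluded_from_mean(self):
        daily = pd.DataFrame({"X": [10.0, np.nan, 20.0]}, index=[96, 97, 98])
        means, _ = sn.window_average(daily, 96, 98, 3)
        assert means["X"].iloc[0] == pytest.approx(15.0)


class TestReconstructCommunities:
    def _snapshot_for(self, value):
        wm = pd.DataFrame({"X": [value]}, index=pd.RangeIndex(1, name="window_index"))
        return sn.reconstruct_communities(wm, [(96, 98)], {"X": "migrant"})[0]

    def test_threshold_boundary_inclusive(self):
        assert "X" in self._snapshot_for(1.5).present_species
        assert "X" not in self._snapshot_for(1.4999).present_species

    def test_all_zero_gives_empty_snapshot(self):
        snap = self._snapshot_for(0.0)
        assert snap.present_species == frozenset()
        assert snap.n_migrants == snap.n_breeders == 0

    def test_presence_monotone_in_threshold(self, demo_snapshots, demo_community):
        wm, windows = demo_snapshots["window_means"], demo_snapshots["windows"]
        statuses = demo_community["statuses"]
        lo = sn.reconstruct_communities(wm, windows, statuses, threshold=1.5)
        hi = sn.reconstruct_communities(wm, windows, statuses, threshold=5.0)
        for a, b in zip(hi, lo):
            assert a.present_species <= b.present_species

    def test_staggered_phenology_matches_analytic_presence(self):
        # detectability 1, constant curve: occurrence is 100% on every day
        # in [arrival, departure] and 0 outside, so a species is present in
        # a window iff the window mean clears the threshold analytically
        from signalniche.synthetic import SpeciesProfile

        profiles = [
            SpeciesProfile(
                code=f"S{i}", status="migrant",
                trait_mean=(2.0, 10.0, 5000.0, 4000.0, 7000.0, 3000.0),
                arrival_day=arr, departure_day=dep, peak_detectability=1.0,
            )
            for i, (arr, dep) in enumerate([(96, 110), (105, 140), (130, 158)])
        ]
        checklists = sn.simulate_checklists(
            profiles, n_per_day=5, day_range=(96, 158), seed=0, curve="constant"
        )
        filtered, _ = sn.filter_checklists(checklists)
        occ = sn.occurrence_matrix(filtered, species=[p.code for p in profiles])
        wm, windows = sn.window_average(occ)
        snaps = sn.reconstruct_communities(
            wm, windows, {p.code: "migrant" for p in profiles}, threshold=1.5
        )
        for snap in snaps:
            ws, we = snap.window_days
            for p in profiles:
                overlap_days = max(0, min(we, p.departure_day) - max(ws, p.arrival_day) + 1)
                expected_mean = 100.0 * overlap_days / 3.0
                assert (p.code in snap.present_species) == (expected_mean >= 1.5)

    def test_pooled_and_per_year_agree_on_balanced_data(self):
        from signalniche.synthetic import SpeciesProfile

        p = SpeciesProfile(
            code="S", status="breeding",
            trait_mean=(2.0, 10.0, 5000.0, 4000.0, 7000.0, 3000.0),
            arrival_day=100, departure_day=150, peak_detectability=0.4,
        )
        years = [
            sn.simulate_checklists([p], 50, (96, 158), seed=s, year=y)
            for y, s in enumerate((1, 2, 3))
        ]
        allyears = pd.concat(years, ignore_index=True)
        pooled = sn.occurrence_matrix(allyears, species=["S"])
        per_year = sn.occurrence_matrix(allyears, species=["S"], per_year=True)
        # balanced design (equal checklists per day per year): identical
        pd.testing.assert_frame_equal(pooled, per_year)
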