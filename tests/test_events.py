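"""Independent-event construction, effort computation and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wildshift import events


def _detections(minutes, station="s1", species="Lynx lynx", project="p1"):
    t0 = pd.Timestamp("2020-05-01T00:00:00Z")
    return pd.DataFrame({
        "project_id": project, "station_id": station,
        "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minutes],
        "species": species, "is_human": False,
        "is_research_personnel": False, "is_domestic": False})


def brute_force_event_count(minutes, window=30.0):
    """Transitive gap clustering oracle: new cluster iff gap > window."""
    ms = sorted(minutes)
    return 1 + sum(b - a > window for a, b in zip(ms, ms[1:])) if ms else 0


class TestBuildEvents:
    def test_thirty_minute_gap_rule(self):
        ev = events.build_events(_detections([0, 10, 25, 45, 80]))
        assert len(ev) == 2
        starts = ev["event_start"].dt.minute.tolist()
        assert starts == [0, 20]  # 0 min and 80 min = 01:20
        assert ev["n_images"].tolist() == [4, 1]

    def test_single_detection_single_event(self):
        ev = events.build_events(_detections([5]))
        assert len(ev) == 1 and ev["n_images"].iloc[0] == 1

    def test_matches_brute_force_on_random_timestamps(self):
        rng = np.random.default_rng(7)
        minutes = np.sort(rng.uniform(0, 7 * 24 * 60, size=500))
        ev = events.build_events(_detections(minutes))
        assert len(ev) == brute_force_event_count(minutes)

    def test_species_and_stations_do_not_chain_together(self):
        a = _detections([0, 10], species="Lynx lynx")
        b = _detections([5, 15], species="Capreolus capreolus")
        c = _detections([2, 12], station="s2")
        ev = events.build_events(pd.concat([a, b, c], ignore_index=True))
        assert len(ev) == 3

    def test_window_zero_returns_one_event_per_detection(self):
        minutes = [0, 1, 2, 50, 51]
        ev = events.build_events(_detections(minutes), window_minutes=0)
        assert len(ev) == len(minutes)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            events.build_events(_detections([0]), window_minutes=-1)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 5000, allow_nan=False), min_size=1, max_size=60),
           st.floats(1, 120))
    def test_event_count_monotone_in_window(self, minutes, window):
        det = _detections(sorted(minutes))
        n_small = len(events.build_events(det, window_minutes=window))
        n_large = len(events.build_events(det, window_minutes=window * 2))
        assert n_large <= n_small


def _period(start, end, project="p1", label="A"):
    return pd.DataFrame({
        "project_id": project, "period_label": label,
        "start": [pd.Timestamp(start, tz="UTC")], "end": [pd.Timestamp(end, tz="UTC")],
        "comparison_type": "between_year", "human_change_override": None})


def _deployment(start, end, station="s1", project="p1"):
    return pd.DataFrame({
        "project_id": project, "station_id": station, "latitude": 50.0,
        "longitude": 10.0, "start": [pd.Timestamp(start, tz="UTC")],
        "end": [pd.Timestamp(end, tz="UTC")]})


class TestComputeEffort:
    def test_full_coverage(self):
        eff = events.compute_effort(_deployment("2020-01-01", "2020-03-01"),
                                    _period("2020-01-05", "2020-01-15"))
        assert eff["camera_days"].iloc[0] == pytest.approx(10.0)

    def test_half_coverage(self):
        eff = events.compute_effort(_deployment("2020-01-10", "2020-03-01"),
                                    _period("2020-01-05", "2020-01-15"))
        assert eff["camera_days"].iloc[0] == pytest.approx(5.0)

    def test_disjoint_deployments_sum_matches_day_enumeration(self):
        dep = pd.concat([_deployment("2020-01-06", "2020-01-09"),
                         _deployment("2020-01-11", "2020-01-15")], ignore_index=True)
        per = _period("2020-01-05", "2020-01-20")
        eff = events.compute_effort(dep, per)
        # brute force: count deployed days one by one
        days = pd.date_range("2020-01-05", "2020-01-19", freq="D", tz="UTC")
        covered = sum(
            any(row.start <= d < row.end for row in dep.itertuples())
            for d in days)
        assert covered == 7
        assert eff["camera_days"].sum() == pytest.approx(7.0)

    def test_zero_overlap_station_omitted(self):
        eff = events.compute_effort(_deployment("2019-01-01", "2019-02-01"),
                                    _period("2020-01-05", "2020-01-15"))
        assert eff.empty


class TestFilterAnalysisSpecies:
    @pytest.fixture()
    def traits(self):
        return pd.DataFrame({
            "species": ["sus scrofa", "mustela nivalis", "capra ibex"],
            "body_mass_kg": [90.0, 0.8, 1.0],
            "trophic_level": ["omnivore", "carnivore", "herbivore"],
            "diet_breadth": [3, 2, 1], "habitat_breadth": [4, 3, 2],
            "diel_activity": ["cathemeral", "nocturnal", "diurnal"],
            "brain_mass_g": [180.0, 1.4, 120.0], "family": ["Suidae", "Mustelidae", "Bovidae"]})

    def _events(self, species, is_human=False, personnel=False, domestic=False):
        return pd.DataFrame({
            "project_id": "p1", "station_id": "s1", "species": species,
            "is_human": is_human, "is_research_personnel": personnel,
            "is_domestic": domestic,
            "event_start": [pd.Timestamp("2020-05-01T12:00:00Z")] * len(species),
            "n_images": 1})

    def test_sub_kilogram_species_excluded_boundary_inclusive(self, traits):
        ev = self._events(["Sus scrofa", "Mustela nivalis", "Capra ibex"])
        animals, _ = events.filter_analysis_species(ev, traits)
        assert sorted(animals["species"]) == ["capra ibex", "sus scrofa"]

    def test_personnel_removed_from_human_stream(self, traits):
        ev = pd.concat([
            self._events(["human"], is_human=True),
            self._events(["human"], is_human=True, personnel=True)],
            ignore_index=True)
        animals, humans = events.filter_analysis_species(ev, traits)
        assert len(humans) == 1 and not humans["is_research_personnel"].any()
        assert animals.empty

    def test_domestic_and_unknown_species_dropped(self, traits):
        ev = self._events(["canis familiaris", "sus scrofa", "mystery beast"],
                          domestic=[True, False, False])
        with pytest.warns(UserWarning, match="mystery beast"):
            animals, _ = events.filter_analysis_species(ev, traits)
        assert animals["species"].tolist() == ["sus scrofa"]


class TestAggregateCounts:
    def test_counts_by_period_and_conservation(self):
        t0 = pd.Timestamp("2020-01-05T10:00:00Z")
        ev = pd.DataFrame({
            "project_id": "p1",
            "station_id": ["s1"] * 3 + ["s2"] * 5,
            "species": "cervus elaphus",
            "event_start": [t0 + pd.Timedelta(hours=h) for h in range(3)]
                           + [t0 + pd.Timedelta(days=40, hours=h) for h in range(5)],
            "day_night": ["day", "night", "day"] + ["night"] * 5})
        per = pd.concat([_period("2020-01-01", "2020-02-01", label="A"),
                         _period("2020-02-10", "2020-03-10", label="B")],
                        ignore_index=True)
        counts = events.aggregate_counts(ev, per)
        totals = events.population_totals(counts)
        a = totals[totals["period_label"] == "A"].iloc[0]
        b = totals[totals["period_label"] == "B"].iloc[0]
        assert (a["n_events"], b["n_events"]) == (3, 5)
        assert a["n_night"] + a["n_day"] == a["n_events"]
        assert counts.groupby("period_label")["n_events"].sum().tolist() == [3, 5]

    def test_event_on_period_start_included_on_end_excluded(self):
        per = _period("2020-01-05", "2020-01-15")
        ev = pd.DataFrame({
            "project_id": "p1", "station_id": "s1", "species": "x",
            "event_start": [pd.Timestamp("2020-01-05T00:00:00Z"),
                            pd.Timestamp("2020-01-15T00:00:00Z")]})
        counts = events.aggregate_counts(ev, per)
        assert counts["n_events"].sum() == 1
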