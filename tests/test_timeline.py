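"""Run-length filtering, hourly binning, tide/season assignment, GVIF screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sharketho.io import LabelTrack
from sharketho.timeline import (
    assign_season,
    assign_tide_phase,
    behaviour_runs,
    filter_short_headshakes,
    gvif_screen,
    hourly_presence,
)

T0 = pd.Timestamp("2012-07-29T00:00:00")


def _track(labels, start=T0):
    return LabelTrack(labels=np.array(labels, dtype=object), epoch_start=start)


class TestFilterShortHeadshakes:
    def test_single_second_run_removed(self):
        out = filter_short_headshakes(_track(["swim", "headshake", "swim"]))
        assert list(out.labels) == ["swim", "swim", "swim"]

    def test_two_second_run_retained(self):
        labels = ["swim", "headshake", "headshake", "swim"]
        out = filter_short_headshakes(_track(labels))
        assert list(out.labels) == labels

    @given(st.lists(st.sampled_from(["swim", "headshake", "rest"]),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_run_length_oracle(self, labels):
        out = filter_short_headshakes(_track(labels))
        n_in = sum(l == "headshake" for l in labels)
        n_out = sum(l == "headshake" for l in out.labels)
        assert n_out <= n_in
        for _, length in behaviour_runs(out.labels, "headshake"):
            assert length >= 2
        # non-headshake labels untouched
        for a, b in zip(labels, out.labels):
            if a != "headshake":
                assert b == a

    @given(st.lists(st.sampled_from(["swim", "headshake"]), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, labels):
        once = filter_short_headshakes(_track(labels))
        twice = filter_short_headshakes(once)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestHourlyPresence:
    def test_hour_with_surviving_run_is_present(self):
        labels = ["swim"] * 3600
        labels[100:102] = ["headshake", "headshake"]
        rec = hourly_presence(_track(labels))
        assert len(rec) == 1
        assert bool(rec["present"].iloc[0])

    def test_presence_not_counts(self):
        labels = ["swim"] * 7200
        # three runs in hour 0, one run in hour 1 -> both simply present
        for s in (10, 500, 900):
            labels[s : s + 2] = ["headshake", "headshake"]
        labels[4000:4002] = ["headshake", "headshake"]
        rec = hourly_presence(_track(labels))
        assert list(rec["present"]) == [True, True]

    def test_no_headshakes_all_absent(self):
        rec = hourly_presence(_track(["swim"] * 7200))
        assert not rec["present"].any()
        assert len(rec) == 2

    def test_short_partial_edge_hour_dropped(self):
        # 90 min track: full hour kept, trailing 30-min hour kept at the
        # coverage threshold; a 10-min trailing hour would be dropped
        rec = hourly_presence(_track(["swim"] * 5400))
        assert len(rec) == 2
        rec2 = hourly_presence(_track(["swim"] * 4200))
        assert len(rec2) == 1

    def test_monotone_in_filtering(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["swim", "headshake"], p=[0.97, 0.03], size=4 * 3600)
        raw = _track(labels)
        filtered = filter_short_headshakes(raw)
        pres_raw = hourly_presence(raw)["present"]
        pres_filt = hourly_presence(filtered)["present"]
        # removing the filter can only add present-hours, never remove them
        assert (pres_raw | ~pres_filt).all()
        assert (~pres_filt | pres_raw).all()


class TestTidePhase:
    PEAKS = [
        ("2012-07-29T12:00:00", "high"),
        ("2012-07-29T18:10:00", "low"),
        ("2012-07-30T00:25:00", "high"),
    ]

    def test_station_peak_lagged_one_hour(self):
        # station high at 12:00, +1 h lag -> local peak 13:00, window 12-14
        assert assign_tide_phase(["2012-07-29T12:00:01"], self.PEAKS)[0] == "High"
        assert assign_tide_phase(["2012-07-29T13:59:59"], self.PEAKS)[0] == "High"
        assert assign_tide_phase(["2012-07-29T14:00:01"], self.PEAKS)[0] == "Ebb"

    def test_between_high_and_low_is_ebb(self):
        for t in ("2012-07-29T14:00:00", "2012-07-29T16:30:00", "2012-07-29T18:09:00"):
            assert assign_tide_phase([t], self.PEAKS)[0] == "Ebb"

    def test_between_low_and_high_is_flood(self):
        assert assign_tide_phase(["2012-07-29T21:00:00"], self.PEAKS)[0] == "Flood"

    def test_phases_partition_covered_interval(self):
        # coverage: first shifted peak - 1 h (12:00) to last + 1 h (02:25)
        times = pd.date_range("2012-07-29T12:00:00", "2012-07-30T02:20:00", freq="7min")
        phases = assign_tide_phase(times, self.PEAKS)
        assert set(phases) == {"Ebb", "Low", "Flood", "High"}
        assert len(phases) == len(times)  # every covered time got exactly one phase

    def test_outside_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            assign_tide_phase(["2012-07-28T00:00:00"], self.PEAKS)

    def test_non_alternating_table_rejected(self):
        with pytest.raises(ValueError, match="alternate"):
            assign_tide_phase(
                ["2012-07-29T13:00:00"],
                [("2012-07-29T12:00:00", "high"), ("2012-07-29T18:00:00", "high")],
            )


class TestSeason:
    @pytest.mark.parametrize(
        "date, season",
        [
            ("2012-07-29", "wet"),
            ("2013-01-12", "dry"),
            ("2014-03-31", "dry"),
            ("2014-04-01", "wet"),
            ("2014-09-30", "wet"),
            ("2014-10-01", "dry"),
        ],
    )
    def test_wet_april_to_september(self, date, season):
        assert assign_season([date])[0] == season


class TestGvifScreen:
    def test_orthogonal_covariates_score_one(self):
        rng = np.random.default_rng(0)
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        cov = pd.DataFrame({"a": a, "b": b})
        retained, hist = gvif_screen(cov)
        assert retained == ["a", "b"]
        np.testing.assert_allclose(hist["gvif"], 1.0, atol=1e-10)

    def test_two_correlated_numerics_match_closed_form(self):
        # closed-form oracle: for two numerics, VIF = 1 / (1 - r^2)
        rng = np.random.default_rng(1)
        n = 500
        x = rng.normal(size=n)
        y = 0.95 * x + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        cov = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        with pytest.warns(UserWarning, match="removing"):
            retained, hist = gvif_screen(cov)
        first = hist[hist["round"] == 1]
        np.testing.assert_allclose(first["gvif"], expected, rtol=0.01)
        assert len(retained) == 1

    def test_temperature_confounded_with_season_removed(self):
        rng = np.random.default_rng(2)
        hours = np.arange(2400) % 24
        season = np.where((np.arange(2400) // 1200) == 0, "wet", "dry")
        temp = (
            np.where(season == "wet", 30.5, 24.1)
            + 1.5 * np.cos(2 * np.pi * (hours - 15) / 24)
            + rng.normal(0, 0.4, 2400)
        )
        tide = rng.choice(["Ebb", "Low", "Flood", "High"], size=2400)
        cov = pd.DataFrame({
            "hour": hours.astype(float),
            "season": season,
            "tide": tide,
            "temperature": temp,
        })
        with pytest.warns(UserWarning, match="temperature"):
            retained, hist = gvif_screen(cov, threshold=3.0)
        assert "temperature" not in retained
        assert "season" in retained

    def test_single_covariate_rejected(self):
        with pytest.raises(ValueError, match="two"):
            gvif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
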