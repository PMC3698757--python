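import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from telebp import SimConfig, make_strain_preset, simulate_beats, DrugSchedule
from telebp.circadian import (
    bin_telemetry,
    classify_cohort_dipper,
    classify_dipper,
    dose_response,
    period_summary,
)
from telebp.errors import DataError
from telebp.schedule import LightDarkSchedule


@pytest.fixture
def quiet_day(quiet_preset):
    beats, _ = simulate_beats(quiet_preset, SimConfig(duration_hours=24.0, seed=1))
    return beats


class TestBinning:
    def test_constant_map_and_hr(self, quiet_day):
        bins = bin_telemetry(quiet_day)
        assert len(bins) == 288  # 24 h x 12 bins/h
        valid = bins[bins["valid"]]
        assert np.allclose(valid["map"], 100.0, atol=1e-6)
        assert np.allclose(valid["hr"], 360.0, atol=0.5)

    def test_sampling_window_is_head_of_bin(self, quiet_day):
        bins = bin_telemetry(quiet_day)
        # ~30 s of beats at HR 360 -> about 180 beats per bin sample
        assert bins["n_beats"].median() == pytest.approx(180, abs=5)

    def test_sparse_bins_flagged_invalid(self, quiet_day):
        df = quiet_day.df[quiet_day.df["systolic_time_s"] < 10.0]
        from telebp.beats import BeatSeries

        short = BeatSeries(df.reset_index(drop=True))
        bins = bin_telemetry(short, min_beats=100)
        assert not bins["valid"].iloc[0]
        assert np.isnan(bins["map"].iloc[0])

    def test_activity_passthrough(self, quiet_day):
        act = np.arange(288, dtype=float)
        bins = bin_telemetry(quiet_day, activity=act)
        assert np.allclose(bins["activity"], act)


class TestPeriodSummary:
    def make_bins(self, dark_map, light_map, days=1):
        # record starts at dark onset; 144 bins per 12-h period
        n = days * 288
        t = np.arange(n) * 300.0
        in_dark = (t % 86400.0) < 43200.0
        return pd.DataFrame(
            {
                "bin_start": t,
                "map": np.where(in_dark, dark_map, light_map),
                "hr": 350.0,
                "activity": np.where(in_dark, 8.0, 3.0),
                "n_beats": 100,
                "valid": True,
            }
        )

    def test_square_wave_means(self, schedule):
        bins = self.make_bins(110.0, 100.0)
        out = period_summary(bins, schedule, "2013-06-01 20:00:00", animal="a")
        by = out.set_index("period")["mean_map"]
        assert by["dark"] == 110.0 and by["light"] == 100.0
        assert (out["n_bins"] == 144).all()

    def test_day_partition_counts(self, schedule):
        bins = self.make_bins(110.0, 100.0, days=3)
        out = period_summary(bins, schedule, "2013-06-01 20:00:00")
        assert len(out) == 6
        assert out["n_bins"].sum() == 3 * 288

    def test_invalid_bins_excluded(self, schedule):
        bins = self.make_bins(110.0, 100.0)
        bins.loc[bins.index[:144], "valid"] = False  # whole dark period invalid
        out = period_summary(bins, schedule, "2013-06-01 20:00:00")
        assert set(out["period"]) == {"light"}


class TestDipper:
    def summaries(self, dips, noise_sd, seed=0, animal="a"):
        rng = np.random.default_rng(seed)
        rows = []
        for day, dip in enumerate(dips):
            dark = 110 + rng.normal(0, noise_sd)
            rows.append(dict(animal=animal, day=day, period="dark", mean_map=dark,
                             mean_hr=350.0, mean_activity=5.0, n_bins=144))
            rows.append(dict(animal=animal, day=day, period="light", mean_map=dark - dip,
                             mean_hr=340.0, mean_activity=3.0, n_bins=144))
        return pd.DataFrame(rows)

    def test_identical_periods_nondipper(self):
        s = self.summaries([0.0] * 5, noise_sd=0.0)
        call = classify_dipper(s)
        assert call.classification == "nondipper"
        assert call.dip_percent == 0.0

    def test_clear_dip_detected(self):
        rng_dips = 8.0 + np.random.default_rng(1).normal(0, 0.5, 7)
        call = classify_dipper(self.summaries(rng_dips, noise_sd=0.3, seed=2))
        assert call.classification == "dipper"
        assert call.p_value < 0.05
        assert call.dip_percent == pytest.approx(100 * 8 / 110, rel=0.15)

    def test_requires_three_pairs(self):
        with pytest.raises(DataError):
            classify_dipper(self.summaries([5.0, 5.0], noise_sd=0.1))

    def test_cohort_majority_vote(self):
        frames = []
        for k in range(5):
            dips = [8.0, 7.5, 8.5, 8.2] if k < 3 else [0.1, -0.1, 0.2, 0.0]
            frames.append(self.summaries(dips, noise_sd=0.2, seed=k, animal=f"r-{k}"))
        call, per_animal = classify_cohort_dipper(pd.concat(frames))
        assert call.classification == "dipper"
        assert len(per_animal) == 5
        assert sum(c.classification == "dipper" for c in per_animal) == 3


class TestDoseResponse:
    def summaries(self, animal, day_maps):
        rows = []
        for day, (dark, light) in enumerate(day_maps):
            rows.append(dict(animal=animal, day=day, period="dark", mean_map=dark))
            rows.append(dict(animal=animal, day=day, period="light", mean_map=light))
        return pd.DataFrame(rows)

    def test_identical_treated_gives_zero_delta(self):
        base = self.summaries("WKY-0", [(110, 100)] * 3)
        treated = self.summaries("WKY-0", [(110, 100)] * 8)
        out = dose_response(base, treated, {7: 1.0})
        assert np.allclose(out["delta_map"], 0.0)
        assert set(out["strain"]) == {"WKY"}

    def test_monotone_dose_ladder(self):
        base = self.summaries("SHRcp-0", [(130, 128)] * 3)
        maps = [(130 - d, 128 - d) for d in [2] * 7 + [6] * 7 + [15] * 7]
        treated = self.summaries("SHRcp-0", maps)
        dose_by_day = {d: 0.1 for d in range(7)}
        dose_by_day.update({d: 0.3 for d in range(7, 14)})
        dose_by_day.update({d: 1.0 for d in range(14, 21)})
        out = dose_response(base, treated, dose_by_day)
        deltas = out.groupby("dose")["delta_map"].mean()
        assert list(deltas.index) == [0.1, 0.3, 1.0]
        assert np.allclose(deltas.to_numpy(), [-2.0, -6.0, -15.0])

    def test_missing_baseline_rejected(self):
        with pytest.raises(DataError):
            dose_response(pd.DataFrame(), self.summaries("a", [(1, 1)]), {0: 0.1})


def test_generator_drug_delta_recovered(wky):
    """Full chain: dosed generator -> bins -> summaries -> dose_response."""
    sched = DrugSchedule(
        dose_by_week=((0, 1.0),),
        effect_map=((1.0, (15.0, 15.0)),),
        effect_brg=((1.0, 0.0),),
        effect_lf=((1.0, 1.0),),
        treatment_start_day=1,
    )
    cfg = SimConfig(duration_hours=8 * 24.0, seed=13)
    beats, _ = simulate_beats(wky, cfg, schedule=sched)
    bins = bin_telemetry(beats)
    summ = period_summary(bins, beats.schedule, beats.start, animal="WKY-0")
    base = summ[summ["day"] == 0]
    out = dose_response(base, summ, {d: sched.dose_on_day(d) for d in range(8)})
    by_period = out.set_index("period")["delta_map"]
    assert by_period["dark"] == pytest.approx(-15.0, abs=1.0)
    assert by_period["light"] == pytest.approx(-15.0, abs=1.0)
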