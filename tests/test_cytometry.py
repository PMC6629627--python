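"""Event processing: gating, bead calibration, summaries, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from optogate import (
    EventTable,
    density_gate,
    detect,
    fit_bead_calibration,
    fold_change,
    gen_bead_sample,
    gen_events,
    read_event_csv,
    subtract_autofluorescence,
    summarize_sample,
    to_mefl,
    welch_test,
    write_event_csv,
)
from optogate.synthetic import EventGenSpec

RCP_PEAKS = [792.0, 2079.0, 6588.0, 16471.0, 47497.0, 137049.0]


def make_events(fl, fsc=None, ssc=None):
    n = len(fl)
    return EventTable(data=pd.DataFrame({
        "fsc": np.full(n, 500.0) if fsc is None else fsc,
        "ssc": np.full(n, 300.0) if ssc is None else ssc,
        "fl1": np.asarray(fl, dtype=float),
    }))


class TestDensityGate:
    def test_identity_at_full_fraction(self):
        ev = gen_events(EventGenSpec(n_events=100, median_fluorescence=10.0,
                                     seed=1))
        out = density_gate(ev, 1.0)
        pd.testing.assert_frame_equal(out.data, ev.data)

    def test_exact_count_contract(self, rng):
        ev = make_events(rng.lognormal(3, 1, 10), fsc=rng.normal(500, 50, 10),
                         ssc=rng.normal(300, 30, 10))
        assert density_gate(ev, 0.5).n_events == 5

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=400),
           fraction=st.floats(min_value=0.05, max_value=1.0))
    def test_count_contract_property(self, n, fraction):
        r = np.random.default_rng(n)
        ev = make_events(r.lognormal(3, 1, n), fsc=r.normal(500, 50, n),
                         ssc=r.normal(300, 30, n))
        expected = max(int(np.floor(fraction * n + 0.5)), 1)
        assert density_gate(ev, fraction).n_events == expected

    def test_cluster_retained_over_uniform_background(self):
        """With 90% of events in one tight scatter cluster and 10% uniform
        background, gating at 50% keeps essentially only cluster events."""
        ev = gen_events(EventGenSpec(
            n_events=2000, median_fluorescence=1000.0, event_cv=0.3,
            background_fraction=0.1, scatter_spread=0.05, seed=7))
        gated = density_gate(ev, 0.5)
        n_cluster = 2000 - int(0.1 * 2000)
        frac_cluster = np.mean(gated.data["event_id"].to_numpy() < n_cluster)
        assert frac_cluster >= 0.99

    def test_deterministic(self, rng):
        ev = make_events(rng.lognormal(3, 1, 200),
                         fsc=rng.normal(500, 50, 200),
                         ssc=rng.normal(300, 30, 200))
        a = density_gate(ev, 0.5)
        b = density_gate(ev, 0.5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_bad_fraction_rejected(self, rng):
        ev = make_events(rng.lognormal(3, 1, 10))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                density_gate(ev, bad)


class TestBeadCalibration:
    def test_identity_mapping_on_noise_free_peaks(self):
        ev, _ = gen_bead_sample([100.0, 1000.0, 10000.0, 100000.0],
                                channel_gain=1.0, peak_cv=0.0,
                                events_per_peak=500, seed=0)
        cal = fit_bead_calibration(ev, [100.0, 1000.0, 10000.0, 100000.0],
                                   channel="fl1")
        assert cal.slope == pytest.approx(1.0, abs=1e-6)
        assert cal.intercept == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_recovers_gain(self):
        """Generator truth round trip: a 0.05 channel gain over six peaks
        spanning 10^2-10^6 is recovered within 5%."""
        vals = [100.0, 1000.0, 8000.0, 40000.0, 200000.0, 1000000.0]
        ev, truth = gen_bead_sample(vals, channel_gain=0.05, peak_cv=0.05,
                                    events_per_peak=2000, seed=3)
        cal = fit_bead_calibration(ev, vals, channel="fl1")
        # mapping applied at the true channel centers returns the true values
        mapped = cal.apply(truth["peak_channel_centers"])
        np.testing.assert_allclose(mapped, vals, rtol=0.05)
        # identity in log-log (exponent 1): slope 1, 10^-intercept/slope = gain
        assert cal.slope == pytest.approx(1.0, rel=0.02)
        assert 10.0 ** (-cal.intercept / cal.slope) == pytest.approx(0.05,
                                                                     rel=0.05)

    def test_monotone_mapping(self):
        ev, _ = gen_bead_sample(RCP_PEAKS, channel_gain=0.05, peak_cv=0.05,
                                seed=1)
        cal = fit_bead_calibration(ev, RCP_PEAKS, channel="fl1")
        x = np.geomspace(1.0, 1e5, 50)
        assert np.all(np.diff(cal.apply(x)) > 0)

    def test_single_assigned_value_rejected(self):
        ev, _ = gen_bead_sample([100.0, 1000.0], seed=0)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_bead_calibration(ev, [100.0], channel="fl1")

    def test_too_few_modes_reported(self):
        ev, _ = gen_bead_sample([100.0, 1000.0], channel_gain=1.0,
                                peak_cv=0.05, seed=0)
        with pytest.raises(ValueError, match="2"):
            fit_bead_calibration(ev, RCP_PEAKS, channel="fl1")


class TestToMefl:
    def test_identity_calibration_keeps_values(self):
        ev, _ = gen_bead_sample([100.0, 1000.0, 10000.0], channel_gain=1.0,
                                peak_cv=0.0, events_per_peak=300, seed=0)
        cal = fit_bead_calibration(ev, [100.0, 1000.0, 10000.0], channel="fl1")
        sample = make_events([50.0, 500.0, 5000.0])
        out = to_mefl(sample, cal, "fl1")
        np.testing.assert_allclose(out.data["fl1"], sample.data["fl1"],
                                   rtol=1e-5)

    def test_double_calibration_rejected(self):
        ev, _ = gen_bead_sample([100.0, 1000.0, 10000.0], channel_gain=1.0,
                                peak_cv=0.0, events_per_peak=300, seed=0)
        cal = fit_bead_calibration(ev, [100.0, 1000.0, 10000.0], channel="fl1")
        once = to_mefl(make_events([50.0, 500.0]), cal, "fl1")
        with pytest.raises(ValueError, match="calibrate"):
            to_mefl(once, cal, "fl1")


class TestSummaries:
    @pytest.mark.parametrize("vals,expected", [
        ([1.0, 2.0, 3.0], 2.0),
        ([1.0, 2.0, 3.0, 4.0], 2.5),  # mean-of-middle convention
    ])
    def test_median_conventions(self, vals, expected):
        assert summarize_sample(make_events(vals), "fl1") == expected

    def test_large_sample_median_matches_generator(self):
        ev = gen_events(EventGenSpec(n_events=100_000,
                                     median_fluorescence=1000.0,
                                     event_cv=0.3, seed=1))
        assert summarize_sample(ev, "fl1") == pytest.approx(1000.0, rel=0.01)

    def test_subtraction_arithmetic(self):
        assert subtract_autofluorescence(1100.0, 100.0) == 1000.0
        assert subtract_autofluorescence(100.0, 100.0) == 0.0

    def test_subtraction_unit_mismatch(self):
        with pytest.raises(ValueError, match="unit"):
            subtract_autofluorescence(1100.0, 100.0, units=("MEFL", "MEAP"))

    def test_generator_round_trip_reporter_median(self):
        """Sample minus same-condition autofluorescence control recovers the
        generator's reporter median within sampling error."""
        sample = gen_events(EventGenSpec(n_events=50_000,
                                         median_fluorescence=500.0,
                                         autofluorescence_median=80.0,
                                         event_cv=0.3, seed=5))
        control = gen_events(EventGenSpec(n_events=50_000,
                                          median_fluorescence=0.0,
                                          autofluorescence_median=80.0,
                                          event_cv=0.3, seed=6))
        rep = subtract_autofluorescence(summarize_sample(sample, "fl1"),
                                        summarize_sample(control, "fl1"))
        # medians are not additive under convolution; allow a few percent
        assert rep == pytest.approx(500.0, rel=0.05)


class TestDetect:
    def test_zero_signal_not_detected(self):
        st_ = detect([0.0, 0.0, 0.0])
        assert not st_.detected and st_.p_value == 1.0 and st_.degenerate_sd

    def test_degenerate_positive_detected(self):
        st_ = detect([10.0, 10.0, 10.0])
        assert st_.detected and st_.p_value == 0.0 and st_.degenerate_sd

    def test_matches_reference_t_test(self, rng):
        vals = rng.normal(5, 2, 6)
        st_ = detect(vals)
        ref = sps.ttest_1samp(vals, 0.0, alternative="greater").pvalue
        assert st_.p_value == pytest.approx(ref, abs=1e-12)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            detect([1.0])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_reference(self, rng):
        """Statistic, Welch-Satterthwaite df, and p agree with the textbook
        formulas to 1e-10 on random inputs."""
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 12))
            b = rng.normal(0.5, 2, rng.integers(2, 12))
            t, df, p = welch_test(a, b)
            va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
            t_ref = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
            df_ref = (va + vb) ** 2 / (va**2 / (len(a) - 1)
                                       + vb**2 / (len(b) - 1))
            p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert df == pytest.approx(df_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestFoldChange:
    def test_equal_groups_give_unity(self):
        st_ = fold_change([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert st_.mean == 1.0 and st_.sd == 0.0

    def test_by_day_arithmetic(self):
        st_ = fold_change([20.0, 22.0, 18.0], [2.0, 2.0, 2.0])
        assert st_.mean == pytest.approx(10.0)
        assert st_.sd == pytest.approx(1.0)

    def test_ratio_of_means_propagation(self):
        st_ = fold_change([20.0, 22.0, 18.0], [2.0, 2.0, 2.0],
                          pairing="ratio_of_means")
        assert st_.mean == pytest.approx(10.0)
        assert st_.sd == pytest.approx(10.0 * np.std([20, 22, 18.0], ddof=1)
                                       / 20.0)

    def test_recovers_known_ratio_under_noise(self, rng):
        """Matched samples generated at a 70-fold activation ratio with 15%
        replicate noise give a mean fold change near 70 across trials."""
        means = []
        for i in range(50):
            r = np.random.default_rng(1000 + i)
            den = 100.0 * np.exp(r.normal(0, 0.15, 3))
            num = 7000.0 * np.exp(r.normal(0, 0.15, 3))
            means.append(fold_change(num, den).mean)
        assert np.median(means) == pytest.approx(70.0, rel=0.15)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0, 2.0], [0.0, 1.0])


def test_event_csv_round_trip(tmp_path):
    ev = gen_events(EventGenSpec(n_events=50, median_fluorescence=100.0,
                                 seed=9))
    path = tmp_path / "events.csv"
    write_event_csv(ev, path)
    back = read_event_csv(path)
    assert back.sample_id == ev.sample_id
    assert back.calibration_state == ev.calibration_state
    np.testing.assert_allclose(back.data["fl1"], ev.data["fl1"])
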