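import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rumordyn as rd
from rumordyn.errors import (
    DegenerateFitError,
    DegenerateSeriesError,
    InputError,
    MissingStageError,
    PhaseDegenerateError,
)
from rumordyn.records import corpus_to_frame


def brute_force_landmarks(t, r, thresholds=(0.1, 0.7, 0.2)):
    """Independent oracle: exhaustive scan with explicit strict inequalities."""
    r_max = max(r)
    te = tp = td = tr = None
    for ti, ri in zip(t, r):
        if ri > thresholds[0] * r_max:
            te = ti
            break
    best = -math.inf
    for ti, ri in zip(t, r):
        if ri > best:
            best, tp = ri, ti
    for ti, ri in zip(t, r):
        if ti > tp and ri < thresholds[1] * r_max:
            td = ti
            break
    if td is not None:
        for ti, ri in zip(t, r):
            if ti > td and ri < thresholds[2] * r_max:
                tr = ti
                break
    return te, tp, td, tr


def random_unimodal_series(rng):
    """Random strictly-unimodal series on a random increasing grid."""
    n_up = int(rng.integers(2, 12))
    n_down = int(rng.integers(2, 12))
    peak = float(rng.uniform(1.0, 50.0))
    up = np.sort(rng.uniform(0, peak, size=n_up))
    down = np.sort(rng.uniform(0, peak, size=n_down))[::-1]
    r = np.concatenate([up, [peak], down])
    t = np.cumsum(rng.uniform(0.1, 2.0, size=r.size))
    return rd.IntensitySeries(t=t, R=r)


@pytest.fixture
def triangular():
    t = np.arange(21.0)
    return rd.IntensitySeries(t=t, R=np.minimum(t, 20.0 - t))


class TestDetectLifecycleTimes:
    def test_triangular_worked_example(self, triangular):
        times = rd.detect_lifecycle_times(triangular)
        assert (times.te, times.tp, times.td, times.tr) == (2.0, 10.0, 14.0, 19.0)
        assert times.R_max == 10.0

    def test_constant_series_has_undefined_decline_and_dissipation(self):
        s = rd.IntensitySeries(t=np.arange(10.0), R=np.full(10, 5.0))
        times = rd.detect_lifecycle_times(s)
        assert times.te == 0.0  # 5 > 0.1 * 5 at the first point
        assert times.td is None and times.tr is None
        assert times.undefined == ("td", "tr")

    def test_plateau_peak_takes_earliest_point(self):
        r = np.array([0.0, 2.0, 8.0, 8.0, 8.0, 1.0, 0.0])
        times = rd.detect_lifecycle_times(rd.IntensitySeries(t=np.arange(7.0), R=r))
        assert times.tp == 2.0

    def test_zero_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            rd.detect_lifecycle_times(rd.IntensitySeries(t=np.arange(5.0), R=np.zeros(5)))

    def test_agrees_with_brute_force_scan_on_random_unimodal_series(self, rng):
        for _ in range(1000):
            s = random_unimodal_series(rng)
            times = rd.detect_lifecycle_times(s)
            expected = brute_force_landmarks(list(s.t), list(s.R))
            assert (times.te, times.tp, times.td, times.tr) == expected

    @given(data=st.data())
    def test_raising_emergence_threshold_never_lowers_te(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        s = random_unimodal_series(rng)
        th_lo = data.draw(st.floats(0.05, 0.5))
        th_hi = data.draw(st.floats(th_lo, 0.95))
        te_lo = rd.detect_lifecycle_times(s, (th_lo, 0.7, 0.2)).te
        te_hi = rd.detect_lifecycle_times(s, (th_hi, 0.7, 0.2)).te
        if te_lo is not None and te_hi is not None:
            assert te_hi >= te_lo

    def test_interpolated_landmarks_bracket_the_grid_ones(self, triangular):
        grid = rd.detect_lifecycle_times(triangular)
        interp = rd.detect_lifecycle_times(triangular, interpolate=True)
        assert interp.tp == grid.tp  # the peak stays a grid point
        assert interp.te <= grid.te and interp.td <= grid.td


class TestDurationsAndRates:
    def test_triangular_durations(self, triangular):
        d = rd.compute_durations(rd.detect_lifecycle_times(triangular))
        assert (d.d_emerge, d.d_growthdecline, d.d_decline, d.d_total) == (8.0, 4.0, 5.0, 17.0)

    def test_additivity_holds_on_random_series(self, rng):
        for _ in range(200):
            times = rd.detect_lifecycle_times(random_unimodal_series(rng))
            d = rd.compute_durations(times)
            if d.d_total is not None:
                assert d.d_total == pytest.approx(d.d_emerge + d.d_growthdecline + d.d_decline, abs=1e-9)

    def test_undefined_landmarks_propagate(self):
        times = rd.LifecycleTimes(te=1.0, tp=2.0, td=None, tr=None, R_max=5.0)
        d = rd.compute_durations(times)
        assert d.d_emerge == 1.0
        assert d.d_growthdecline is None and d.d_decline is None and d.d_total is None

    def test_collapsed_landmarks_give_zero_durations(self):
        times = rd.LifecycleTimes(te=3.0, tp=3.0, td=3.0, tr=3.0, R_max=1.0)
        d = rd.compute_durations(times)
        assert (d.d_emerge, d.d_growthdecline, d.d_decline, d.d_total) == (0.0, 0.0, 0.0, 0.0)

    def test_triangular_transition_rates(self, triangular):
        times = rd.detect_lifecycle_times(triangular)
        rates = rd.compute_transition_rates(triangular, times)
        assert (rates.r_eg, rates.r_gd, rates.r_dr) == (1.0, -1.0, -1.0)

    def test_rates_scale_linearly_with_intensity(self, triangular):
        scaled = rd.IntensitySeries(t=triangular.t, R=3.5 * triangular.R)
        times = rd.detect_lifecycle_times(scaled)
        rates = rd.compute_transition_rates(scaled, times)
        assert (rates.r_eg, rates.r_gd, rates.r_dr) == (3.5, -3.5, -3.5)

    def test_zero_duration_phase_is_an_explicit_error(self, triangular):
        times = rd.LifecycleTimes(te=10.0, tp=10.0, td=14.0, tr=19.0, R_max=10.0)
        with pytest.raises(PhaseDegenerateError):
            rd.compute_transition_rates(triangular, times)


class TestTrustTransfer:
    def test_zero_delay_gives_alpha_times_credibility(self):
        p = rd.TrustTransferParams(alpha_tt=0.8, C_cred=0.9, beta_tt=0.5, D_time=0.0)
        assert rd.trust_transfer_efficiency(p) == pytest.approx(0.72)

    def test_hand_evaluated_example(self):
        p = rd.TrustTransferParams(alpha_tt=0.8, C_cred=0.9, beta_tt=0.5, D_time=2.0)
        assert rd.trust_transfer_efficiency(p) == pytest.approx(0.264873, abs=1e-6)

    def test_zero_credibility_annihilates(self):
        for delay in (0.0, 1.0, 10.0):
            assert rd.trust_transfer_efficiency(
                rd.TrustTransferParams(C_cred=0.0, D_time=delay)
            ) == 0.0

    def test_log_linear_in_delay(self):
        logs = [
            math.log(rd.trust_transfer_efficiency(rd.TrustTransferParams(D_time=d)))
            for d in (1.0, 2.0, 3.0)
        ]
        assert logs[1] - logs[0] == pytest.approx(logs[2] - logs[1], abs=1e-9)

    def test_negative_delay_rejected(self):
        with pytest.raises(InputError):
            rd.TrustTransferParams(D_time=-1.0)


class TestStageLevels:
    def test_arithmetic_mean_per_stage(self, small_corpus):
        frame = corpus_to_frame(small_corpus)
        expected = frame.groupby("stage")["trust_level"].mean()
        levels = rd.stage_levels(small_corpus)
        for stage in ("early", "mid", "late"):
            assert levels.loc[stage, "mean_trust"] == pytest.approx(expected[stage])

    def test_order_invariance(self, small_corpus):
        shuffled = list(small_corpus)[::-1]
        assert rd.stage_levels(shuffled).equals(rd.stage_levels(small_corpus))

    def test_missing_stage_is_reported_by_name(self, small_corpus):
        frame = corpus_to_frame(small_corpus)
        only_early = frame[frame["stage"] == "early"]
        with pytest.raises(MissingStageError) as err:
            rd.stage_levels(only_early)
        assert set(err.value.missing) == {"mid", "late"}


class TestHijackSpreadRelation:
    def test_collinear_points_fit_exactly(self):
        import pandas as pd

        frame = pd.DataFrame({
            "hijack_index": [0.0, 0.05, 0.10],
            "spread_intensity": [1.0, 0.9, 0.8],
        })
        fit = rd.hijack_spread_relation(frame)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.correlation == pytest.approx(-1.0)

    def test_generator_link_yields_weak_negative_correlation(self):
        corpus = rd.generate_corpus(rd.GeneratorConfig(n_records=5000, seed=5))
        fit = rd.hijack_spread_relation(corpus)
        assert -0.5 < fit.correlation < 0.0

    def test_duplicating_the_dataset_leaves_the_fit_unchanged(self, small_corpus):
        once = rd.hijack_spread_relation(small_corpus)
        twice = rd.hijack_spread_relation(list(small_corpus) * 2)
        assert twice.slope == pytest.approx(once.slope)
        assert twice.intercept == pytest.approx(once.intercept)
        assert twice.correlation == pytest.approx(once.correlation)

    def test_zero_variance_predictor_is_degenerate(self):
        import pandas as pd

        frame = pd.DataFrame({"hijack_index": [0.1] * 5, "spread_intensity": range(5)})
        with pytest.raises(DegenerateFitError):
            rd.hijack_spread_relation(frame)

    def test_band_covers_the_fitted_line(self, small_corpus):
        fit = rd.hijack_spread_relation(small_corpus)
        assert np.all(fit.band_low <= fit.fitted) and np.all(fit.fitted <= fit.band_high)


def test_intensity_series_validation():
    with pytest.raises(InputError):
        rd.IntensitySeries(t=np.array([0.0, 1.0]), R=np.array([1.0]))
    with pytest.raises(InputError):
        rd.IntensitySeries(t=np.array([1.0, 0.5]), R=np.array([1.0, 1.0]))
    with pytest.raises(InputError):
        rd.IntensitySeries(t=np.array([0.0, 1.0]), R=np.array([1.0, -1.0]))
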