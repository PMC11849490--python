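import numpy as np
import pytest

from wormfreq.hu import HuVector
from wormfreq.mser import OrientationProfile
from wormfreq.rhythm import (
    AutocorrSeries,
    EnsembleMatrix,
    Extremum,
    ExtremaRunFamily,
    build_ensemble,
    ensemble_autocorrelation,
    estimate_frequency,
    find_extrema_with_prominence,
    frequency_from_autocorr,
    select_runs,
    standardize,
)

from .oracles import autocorr_brute_force, prominence_brute_force


def _profile(values):
    values = np.asarray(values, dtype=float)
    return OrientationProfile(
        psi=values, query_areas=np.arange(len(values)) + 1.0, circ_mean=0.0,
        recentered=values, empty=False,
    )


class TestEnsemble:
    def test_shape_and_row_order(self):
        hu = [HuVector(np.arange(8) + t) for t in range(3)]
        psi = [_profile([0.1 * t] * 4) for t in range(3)]
        ens = build_ensemble(hu, psi, fps=30.0)
        assert ens.values.shape == (12, 3)
        np.testing.assert_allclose(ens.values[0], [0, 1, 2])  # h1 row
        np.testing.assert_allclose(ens.values[8], [0.0, 0.1, 0.2])  # first psi row

    def test_identical_frames_constant_rows(self):
        hu = [HuVector(np.ones(8))] * 5
        psi = [_profile([0.3, 0.1])] * 5
        ens = build_ensemble(hu, psi, fps=30.0)
        assert np.all(ens.values.std(axis=1) == 0)

    def test_missing_frames_imputed(self):
        hu = [HuVector(np.arange(8) * 1.0) if t != 4 else None for t in range(10)]
        psi = [
            _profile([0.2, 0.4]) if t != 7
            else OrientationProfile(np.zeros(2), np.array([1.0, 2.0]), 0.0, np.zeros(2), empty=True)
            for t in range(10)
        ]
        ens = build_ensemble(hu, psi, fps=30.0)
        std = standardize(ens)
        assert np.isfinite(ens.values).all()
        assert np.isfinite(std.values).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_ensemble([HuVector(np.zeros(8))], [], fps=30.0)

    def test_ablation_flags(self):
        hu = [HuVector(np.arange(8) * 1.0)] * 3
        psi = [_profile([0.1, 0.2, 0.3])] * 3
        assert build_ensemble(hu, psi, 30.0, include_hu=False).values.shape == (3, 3)
        assert build_ensemble(hu, psi, 30.0, include_mser=False).values.shape == (8, 3)
        with pytest.raises(ValueError):
            build_ensemble(hu, psi, 30.0, include_hu=False, include_mser=False)


class TestStandardize:
    def test_population_zscore_example(self):
        ens = EnsembleMatrix(np.array([[1.0, 2.0, 3.0, 4.0]]), fps=30.0)
        out = standardize(ens).values[0]
        np.testing.assert_allclose(
            out, [-1.34164079, -0.4472136, 0.4472136, 1.34164079], atol=1e-8
        )

    def test_constant_row_zeroed(self):
        ens = EnsembleMatrix(np.array([[7.0, 7.0, 7.0]]), fps=30.0)
        np.testing.assert_array_equal(standardize(ens).values, np.zeros((1, 3)))

    def test_postcondition_mean_zero_popvar_one(self):
        rng = np.random.default_rng(0)
        ens = EnsembleMatrix(rng.normal(size=(6, 40)), fps=30.0)
        out = standardize(ens).values
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-9)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            standardize(EnsembleMatrix(np.ones((2, 1)), fps=30.0))


class TestAutocorrelation:
    def test_r0_is_one(self):
        rng = np.random.default_rng(1)
        ens = standardize(EnsembleMatrix(rng.normal(size=(4, 30)), fps=30.0))
        r = ensemble_autocorrelation(ens, tau_max=10).r
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(r) <= 1 + 1e-12)

    def test_rotating_phasor_gives_cosine(self):
        t = np.arange(100)
        ens = EnsembleMatrix(
            np.vstack([np.cos(2 * np.pi * t / 10), np.sin(2 * np.pi * t / 10)]),
            fps=30.0,
            standardized=True,
        )
        r = ensemble_autocorrelation(ens, tau_max=40).r
        np.testing.assert_allclose(r, np.cos(2 * np.pi * np.arange(41) / 10), atol=1e-9)

    def test_zero_norm_columns_count_in_denominator(self):
        v = np.zeros((2, 6))
        v[:, ::2] = [[1.0], [0.5]]  # odd columns all-zero
        ens = EnsembleMatrix(v, fps=30.0, standardized=True)
        r = ensemble_autocorrelation(ens, tau_max=2).r
        assert r[0] == pytest.approx(0.5)  # 3 self-cosines / 6 columns
        assert r[1] == pytest.approx(0.0)

    def test_tau_max_validation(self):
        ens = EnsembleMatrix(np.ones((2, 5)), fps=30.0, standardized=True)
        with pytest.raises(ValueError):
            ensemble_autocorrelation(ens, tau_max=4)
        with pytest.raises(ValueError):
            ensemble_autocorrelation(EnsembleMatrix(np.ones((2, 5)), fps=30.0), tau_max=2)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(5, 50))
        ens = EnsembleMatrix(v, fps=30.0, standardized=True)
        r = ensemble_autocorrelation(ens, tau_max=20).r
        np.testing.assert_allclose(r, autocorr_brute_force(v, 20), atol=1e-12)


class TestExtrema:
    def test_simple_peak(self):
        fam = find_extrema_with_prominence(AutocorrSeries(np.array([0.0, 1.0, 0.0]), fps=30.0))
        peaks = [e for e in fam.extrema if e.kind == "peak" and e.lag > 0]
        assert len(peaks) == 1
        assert peaks[0].lag == 1
        assert peaks[0].prominence == pytest.approx(1.0)

    def test_five_point_prominences(self):
        r = np.array([0.0, 2.0, 1.0, 3.0, 0.0])
        fam = find_extrema_with_prominence(AutocorrSeries(r, fps=30.0), refine=False)
        by_lag = {e.lag: e for e in fam.extrema}
        assert by_lag[1].kind == "peak" and by_lag[1].prominence == pytest.approx(1.0)
        assert by_lag[3].kind == "peak" and by_lag[3].prominence == pytest.approx(3.0)
        assert by_lag[2].kind == "trough" and by_lag[2].prominence == pytest.approx(1.0)

    def test_cosine_alternation(self):
        tau = np.arange(61)
        fam = find_extrema_with_prominence(
            AutocorrSeries(np.cos(2 * np.pi * tau / 20), fps=30.0)
        )
        lags = [e.lag for e in fam.extrema]
        kinds = [e.kind for e in fam.extrema]
        assert lags == [0, 10, 20, 30, 40, 50, 60]
        assert kinds == ["peak", "trough", "peak", "trough", "peak", "trough", "peak"]

    def test_lag_zero_peak_always_included(self):
        r = np.array([1.0, 0.6, 0.2, -0.1, 0.0, 0.1])
        fam = find_extrema_with_prominence(AutocorrSeries(r, fps=30.0))
        assert fam.extrema[0].lag == 0
        assert fam.extrema[0].prominence == pytest.approx(1.1)  # 1.0 - min(r)

    def test_matches_prominence_oracle(self):
        rng = np.random.default_rng(3)
        series = np.cumsum(rng.normal(size=60))
        series = series / np.abs(series).max()
        fam = find_extrema_with_prominence(AutocorrSeries(series, fps=30.0), refine=False)
        for e in fam.extrema:
            if e.lag == 0:
                continue
            assert e.prominence == pytest.approx(
                prominence_brute_force(series, e.lag, e.kind), abs=1e-12
            )

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            find_extrema_with_prominence(AutocorrSeries(np.array([1.0, 0.0]), fps=30.0))


def _family(lags, kinds, proms):
    ext = [
        Extremum(lag=l, value=0.0, kind=k, prominence=p)
        for l, k, p in zip(lags, kinds, proms)
    ]
    return ExtremaRunFamily(extrema=ext)


class TestRuns:
    def test_all_survivors_one_run(self):
        fam = _family(range(7), ["peak", "trough"] * 3 + ["peak"], [1.0] * 7)
        out = select_runs(fam, threshold=0.14, adjacency="original")
        assert out.runs == [list(range(7))]

    def test_spec_hand_trace_original_adjacency(self):
        # survivors {E1,E2,E4,E5} with E3 discarded -> two runs of two
        fam = _family(range(5), ["peak", "trough", "peak", "trough", "peak"],
                      [1.0, 1.0, 0.05, 1.0, 1.0])
        out = select_runs(fam, threshold=0.14, adjacency="original")
        assert out.runs == [[0, 1], [3, 4]]
        assert out.discarded == [2]

    def test_alternate_discards_empty_family(self):
        fam = _family(range(5), ["peak", "trough", "peak", "trough", "peak"],
                      [1.0, 0.05, 1.0, 0.05, 1.0])
        out = select_runs(fam, threshold=0.14, adjacency="original")
        assert out.runs == []
        # survivor adjacency: remaining extrema are all peaks, so alternation
        # never holds and the family is empty there too
        out2 = select_runs(fam, threshold=0.14, adjacency="survivors")
        assert out2.runs == []

    def test_survivor_adjacency_bridges_wiggle_pairs(self):
        # a discarded peak+trough noise pair between two major extrema
        fam = _family(
            [0, 10, 13, 15, 30],
            ["peak", "trough", "peak", "trough", "peak"],
            [1.0, 0.5, 0.02, 0.02, 0.5],
        )
        out = select_runs(fam, threshold=0.14, adjacency="survivors")
        assert out.runs == [[0, 1, 4]]  # alternation preserved across the pair

    def test_survivor_adjacency_splits_same_kind(self):
        # discarding a single trough leaves two adjacent peaks: runs split
        fam = _family(
            [0, 10, 20, 30, 40],
            ["peak", "trough", "peak", "trough", "peak"],
            [1.0, 0.5, 0.5, 0.02, 0.5],
        )
        out = select_runs(fam, threshold=0.14, adjacency="survivors")
        assert out.runs == [[0, 1, 2]]  # E4 dropped; E2(peak)->E4(peak) would repeat kinds


class TestFrequency:
    def test_cosine_full_path(self):
        t = np.arange(100)
        ens = EnsembleMatrix(
            np.vstack([np.cos(2 * np.pi * t / 20), np.sin(2 * np.pi * t / 20)]),
            fps=30.0,
            standardized=True,
        )
        series = ensemble_autocorrelation(ens, tau_max=60)
        result, family = frequency_from_autocorr(series)
        assert result.frequency_hz == pytest.approx(1.5, rel=1e-6)
        assert result.mean_interval_lags == pytest.approx(10.0, rel=1e-6)

    def test_empty_family_is_quiescent(self):
        fam = ExtremaRunFamily(extrema=[], runs=[])
        res = estimate_frequency(fam, fps=30.0)
        assert res.frequency_hz == 0.0
        assert res.quiescent

    def test_two_run_interval_formula(self):
        # intervals (10, 10) and (12): delta = 32/3, f = fps * 3 / 64
        fam = _family(
            [0, 10, 20, 40, 52],
            ["peak", "trough", "peak", "trough", "peak"],
            [1.0] * 5,
        )
        fam.runs = [[0, 1, 2], [3, 4]]
        res = estimate_frequency(fam, fps=30.0, use_refined_lags=False)
        assert res.mean_interval_lags == pytest.approx(32 / 3)
        assert res.frequency_hz == pytest.approx(30.0 * 3 / 64)

    def test_full_period_conversion_flag(self):
        fam = _family([0, 10, 20], ["peak", "trough", "peak"], [1.0] * 3)
        fam.runs = [[0, 1, 2]]
        half = estimate_frequency(fam, fps=30.0, conversion="half_period")
        full = estimate_frequency(fam, fps=30.0, conversion="full_period")
        assert full.frequency_hz == pytest.approx(2 * half.frequency_hz)

    def test_pure_tone_recovery_property(self):
        """Sinusoidal rows at a common frequency: estimate within the
        resolution bound f0 * (1 +- 2/n_periods)."""
        fps = 25.0
        for f0 in (0.8, 1.6, 3.1):
            t = np.arange(200) / fps
            rows = [np.sin(2 * np.pi * f0 * t + ph) for ph in (0, 1.0, 2.1, 4.0)]
            ens = standardize(EnsembleMatrix(np.array(rows), fps=fps))
            series = ensemble_autocorrelation(ens, tau_max=100)
            res, _ = frequency_from_autocorr(series)
            n_periods = f0 * 200 / fps
            assert abs(res.frequency_hz - f0) <= f0 * 2 / n_periods

    def test_halved_sampling_equivariance(self):
        fps = 30.0
        f0 = 1.3
        t = np.arange(300) / fps
        rows = np.array([np.sin(2 * np.pi * f0 * t + ph) for ph in (0, 0.9, 2.2)])
        full = standardize(EnsembleMatrix(rows, fps=fps))
        half = standardize(EnsembleMatrix(rows[:, ::2], fps=fps / 2))
        r_full, _ = frequency_from_autocorr(ensemble_autocorrelation(full, tau_max=150))
        r_half, _ = frequency_from_autocorr(ensemble_autocorrelation(half, tau_max=74))
        assert abs(r_half.frequency_hz - r_full.frequency_hz) < 0.05 * r_full.frequency_hz
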