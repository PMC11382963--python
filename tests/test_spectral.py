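"""Wavelet power spectra, red-noise significance and mode labelling."""

import numpy as np
import pytest

from mobstates.io import Dataset
from mobstates.spectral import (
    cwt_power,
    dominant_mode,
    global_spectrum,
    mode_shares,
    profile_series,
    rednoise_threshold,
)
from mobstates.synthetic import CohortSpec, gen_cohort, gen_periodic_series

SCALE_STEP = 2 ** (1 / 12)  # 12 sub-octaves per octave


class TestCwtPower:
    def test_pure_tone_localises_at_its_period(self):
        x = gen_periodic_series([24], [1.0], 0.0, 4 * 168, 0)
        periods, power, coi = cwt_power(x)
        # at each interior time, the argmax scale maps to ~24 h
        mid = slice(100, len(x) - 100)
        peak_periods = periods[np.argmax(power[:, mid], axis=0)]
        assert np.all(peak_periods / 24 < SCALE_STEP * 1.01)
        assert np.all(24 / peak_periods < SCALE_STEP * 1.01)

    def test_constant_series_has_zero_power(self):
        _, power, _ = cwt_power(np.ones(100))
        assert power.max() == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            cwt_power(np.arange(30))

    def test_heavily_gapped_series_rejected(self):
        x = np.sin(np.arange(200) / 5.0)
        x[:80] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cwt_power(x)

    def test_white_noise_spectrum_is_flat(self):
        x = np.random.default_rng(13).normal(0, 1, 1024)
        spec = global_spectrum(x)
        assert np.mean(spec.power > 3 * np.median(spec.power)) <= 0.10


class TestGlobalSpectrum:
    def test_two_tone_mixture_peaks_at_both_periods(self):
        x = gen_periodic_series([24, 12], [2.0, 1.0], 0.2, 8 * 168, 1)
        spec = global_spectrum(x)
        p, g = spec.periods, spec.power
        local_max = [
            i for i in range(1, len(g) - 1) if g[i] > g[i - 1] and g[i] >= g[i + 1]
        ]
        peaks = p[local_max]
        assert any(abs(np.log(pk / 24)) <= np.log(SCALE_STEP) * 1.01 for pk in peaks)
        assert any(abs(np.log(pk / 12)) <= np.log(SCALE_STEP) * 1.01 for pk in peaks)
        assert g[np.argmin(abs(p - 24))] > g[np.argmin(abs(p - 12))]

    def test_single_tone_has_single_dominant_maximum(self):
        x = gen_periodic_series([24], [1.0], 0.0, 4 * 168, 0)
        spec = global_spectrum(x)
        assert abs(np.log(spec.peak_period / 24)) <= np.log(SCALE_STEP) * 1.01

    def test_population_profile_peaks_circadian(self, small_cohort):
        from mobstates.states import population_profile

        ds, _ = small_cohort
        prof = population_profile(ds)
        spec = global_spectrum(prof.mean, max_period=42.0)
        assert abs(spec.peak_period - 24) <= 2.0

    def test_positive_rescaling_leaves_spectrum_shape(self):
        x = gen_periodic_series([12], [1.0], 0.3, 4 * 168, 5)
        a = global_spectrum(x)
        b = global_spectrum(5.0 * x)
        assert a.peak_period == b.peak_period
        assert np.allclose(a.power, b.power)


class TestRednoiseThreshold:
    def test_white_noise_background_is_flat(self):
        x = np.random.default_rng(2).normal(0, 1, 512)
        thr = rednoise_threshold(x, alpha=0.05)
        spec = global_spectrum(x)
        short = spec.periods < 64
        # chi-square dof varies with scale, so allow mild variation
        assert thr[short].max() / thr[short].min() < 3.0

    def test_strong_tone_exceeds_threshold_only_near_its_period(self):
        x = gen_periodic_series([24], [1.0], 0.5, 4 * 168, 5)
        spec = global_spectrum(x, alpha=0.05)
        i24 = np.argmin(abs(spec.periods - 24))
        i5 = np.argmin(abs(spec.periods - 5))
        assert spec.power[i24] > spec.threshold[i24]
        assert spec.power[i5] <= spec.threshold[i5]

    def test_ar1_false_positive_rate_is_controlled(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(300 + s)
            n = 512
            x = np.zeros(n)
            e = r.normal(0, 1, n)
            for t in range(1, n):
                x[t] = 0.7 * x[t - 1] + e[t]
            spec = global_spectrum(x, alpha=0.05)
            i = np.argmin(abs(spec.periods - 24))
            hits += spec.power[i] > spec.threshold[i]
        assert hits / 20 <= 0.10


class TestDominantMode:
    @pytest.mark.parametrize("period,label", [(24, "24h"), (12, "12h"), (6, "6h")])
    def test_pure_tones_get_their_label(self, period, label):
        x = gen_periodic_series([period], [1.0], 0.05, 168, 2)
        assert dominant_mode(x).label == label

    def test_off_nominal_period_is_other(self):
        x = gen_periodic_series([17], [1.0], 0.05, 2 * 168, 2)
        assert dominant_mode(x).label == "other"

    def test_classifier_is_deterministic(self):
        x = gen_periodic_series([24], [1.0], 0.3, 168, 7)
        assert dominant_mode(x) == dominant_mode(x)


class TestProfileSeries:
    def test_small_gaps_interpolated(self, small_cohort):
        ds, _ = small_cohort
        traj = next(iter(ds))
        series = profile_series(traj)
        assert series is not None and not np.isnan(series).any()
        assert len(series) == 168

    def test_sparse_profile_skipped(self):
        import pandas as pd
        from mobstates.io import dataset_from_frame

        # a user seen only on Mondays: 144 consecutive missing slots
        df = pd.DataFrame(
            {
                "user_id": "sparse",
                "timestamp": [pd.Timestamp("2024-01-01 09:00") + pd.Timedelta(weeks=w)
                              for w in range(6)],
                "lat": 40.0,
                "lon": -75.0,
                "location_id": "x",
                "category": None,
            }
        )
        traj = dataset_from_frame(df).trajectories["sparse"]
        assert profile_series(traj) is None


class TestModeShares:
    def test_designed_share_recovery(self):
        ds, truth = gen_cohort(
            CohortSpec(
                n_users=40, weeks=20, seed=5, mode_fractions=(0.75, 0.20, 0.05),
                attendance=0.6,
            )
        )
        shares, labels = mode_shares(ds)
        assert abs(shares.get("24h", 0) - 0.75) <= 0.10
        assert abs(shares.get("12h", 0) - 0.20) <= 0.10
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_shares_invariant_under_user_reordering(self, small_cohort):
        ds, _ = small_cohort
        shares_a, _ = mode_shares(ds)
        reordered = Dataset(
            trajectories=dict(reversed(list(ds.trajectories.items()))),
            provenance=ds.provenance,
        )
        shares_b, _ = mode_shares(reordered)
        assert shares_a == shares_b
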