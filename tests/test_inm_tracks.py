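"""INM track statistics: classification, MSD, motion fits, speeds, fates."""

import math

import numpy as np
import pytest
from scipy import stats

from neurodiv import (
    ClassifierConfig,
    GeneratorSpec,
    NuclearTrack,
    TrackParams,
    classify_daughter,
    fit_motion_model,
    gen_tracks,
    mean_early_speed,
    msd_profile,
    pair_behavior,
    tabulate_fates,
)
from neurodiv.inm_tracks import ClassificationFailure


def make_track(positions, dt=5.0, nucleus_id="n0", pair_id="p0", fate="ND"):
    times = tuple(dt * i for i in range(len(positions)))
    return NuclearTrack(
        nucleus_id=nucleus_id,
        pair_id=pair_id,
        times=times,
        positions=tuple(float(x) for x in positions),
        fate_label=fate,
    )


def drift_track(v, dt=5.0, n_frames=13, **kw):
    return make_track([v * dt * i for i in range(n_frames)], dt=dt, **kw)


class TestClassifier:
    @pytest.mark.parametrize(
        "x20, expected",
        [
            (12.0, "Bs"),  # above threshold
            (5.0, "Ap"),
            (10.0, "Ap"),  # 'more than 10 um' read strictly: tie -> Ap
        ],
    )
    def test_threshold_rule(self, x20, expected):
        track = make_track([0, 2, 4, 6, x20, x20])
        assert classify_daughter(track) == expected

    def test_short_track_raises_classification_failure(self):
        track = make_track([0, 1, 2])  # ends at 10 min
        with pytest.raises(ClassificationFailure):
            classify_daughter(track)

    def test_relative_threshold_mode(self):
        cfg = ClassifierConfig(relative_fraction=0.1, apicobasal_length=60.0)
        track = make_track([0, 3, 5, 6, 7, 7])  # 7 um at 20 min > 6 um = 10% of 60
        assert classify_daughter(track, cfg) == "Bs"

    @pytest.mark.parametrize(
        "a, b, expected",
        [("Ap", "Ap", "Ap/Ap"), ("Bs", "Ap", "Ap/Bs"), ("Ap", "Bs", "Ap/Bs"), ("Bs", "Bs", "Bs/Bs")],
    )
    def test_pair_behavior_is_unordered(self, a, b, expected):
        assert pair_behavior(a, b) == expected

    def test_generated_mix_recovered_within_binomial_band(self):
        """A 50/50 Ap/Bs generated mix classifies back to ~50% Ap."""
        spec = GeneratorSpec(seed=2024)
        tracks = gen_tracks(spec, n_pairs=150)  # 300 daughters
        labels = [classify_daughter(t) for t in tracks]
        n = len(labels)
        ap_frac = labels.count("Ap") / n
        band = 1.96 * math.sqrt(0.25 / n)
        assert abs(ap_frac - 0.5) <= band + 0.02  # small classifier-error slack

    def test_regime_separation(self):
        """Diffusive daughters classify Ap, fast-drifting ones Bs."""
        ap_spec = GeneratorSpec(
            seed=7, track_params=TrackParams(bs_fraction=0.0, d_ap=0.5)
        )
        ap_tracks = gen_tracks(ap_spec, n_pairs=50)
        ap_rate = np.mean([classify_daughter(t) == "Ap" for t in ap_tracks])
        assert ap_rate >= 0.8

        bs_spec = GeneratorSpec(
            seed=8, track_params=TrackParams(bs_fraction=1.0, v_bs=0.8)
        )
        bs_tracks = gen_tracks(bs_spec, n_pairs=50)
        bs_rate = np.mean([classify_daughter(t) == "Bs" for t in bs_tracks])
        assert bs_rate >= 0.9


class TestMSD:
    def test_pure_drift_is_quadratic(self):
        track = drift_track(v=1.0, n_frames=13)  # 60 min at 5-min frames
        profile = msd_profile([track], max_lag=30.0, n_boot=10, seed=0)
        assert np.allclose(profile.msd, profile.lags**2)

    def test_stationary_track_is_zero(self):
        track = make_track([4.0] * 13)
        profile = msd_profile([track], max_lag=30.0, n_boot=10, seed=0)
        assert np.allclose(profile.msd, 0.0)

    def test_reflection_invariance(self):
        """MSD is unchanged when every track is mirrored about a plane."""
        rng = np.random.default_rng(5)
        tracks, mirrored = [], []
        for i in range(20):
            x = np.abs(np.cumsum(rng.normal(0, 1.5, size=13)))
            c = x.max() + 1.0
            tracks.append(make_track(x, nucleus_id=f"n{i}"))
            mirrored.append(make_track(c - x, nucleus_id=f"m{i}"))
        a = msd_profile(tracks, max_lag=30, n_boot=10, seed=1)
        b = msd_profile(mirrored, max_lag=30, n_boot=10, seed=1)
        assert np.allclose(a.msd, b.msd)

    def test_diffusion_slope_recovers_2d(self):
        """200 pure-diffusion tracks, D = 0.5: fitted slope within 10% of 2D.

        Tracks run away from the apical boundary (offset start), since
        reflection at the surface makes near-apical motion genuinely
        sub-diffusive rather than an estimator artefact.
        """
        d_true, dt = 0.5, 5.0
        rng = np.random.default_rng(31)
        tracks = []
        for i in range(200):
            steps = rng.normal(0, math.sqrt(2 * d_true * dt), size=12)
            x = 100.0 + np.concatenate([[0.0], np.cumsum(steps)])
            tracks.append(make_track(x, nucleus_id=f"n{i}", pair_id=f"p{i // 2}"))
        profile = msd_profile(tracks, max_lag=30.0, n_boot=200, seed=0)
        fit = fit_motion_model(profile)
        assert 2 * fit.d == pytest.approx(2 * d_true, rel=0.10)

    def test_lag_cap_at_half_shortest_track(self):
        track = drift_track(v=1.0, n_frames=13)  # 60 min
        profile = msd_profile([track], max_lag=60.0, n_boot=5, seed=0)
        assert profile.lags[-1] == pytest.approx(30.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            msd_profile([], max_lag=30)


class TestMotionFit:
    def test_exact_quadratic_selects_advective(self):
        profile = msd_profile([drift_track(v=1.0)], max_lag=30, n_boot=10, seed=0)
        fit = fit_motion_model(profile)
        assert fit.selected_model == "advective"
        assert fit.v == pytest.approx(1.0, abs=1e-6)
        assert fit.d == pytest.approx(0.0, abs=1e-6)

    def test_exact_linear_selects_diffusive(self):
        from neurodiv.inm_tracks import MSDProfile

        lags = 5.0 * np.arange(7)
        msd = 2 * 0.5 * lags
        profile = MSDProfile(
            lags=lags, msd=msd, ci_low=msd, ci_high=msd,
            n_contributing=np.full(7, 10),
        )
        fit = fit_motion_model(profile)
        assert fit.selected_model == "diffusive"
        assert fit.v == 0.0
        assert fit.d == pytest.approx(0.5)

    def test_all_zero_profile_returns_zero_diffusivity(self):
        profile = msd_profile([make_track([0.0] * 13)], max_lag=30, n_boot=5, seed=0)
        fit = fit_motion_model(profile)
        assert fit.selected_model == "diffusive"
        assert fit.d == 0.0

    @pytest.mark.parametrize("d_true", [0.1, 0.3, 0.6])
    @pytest.mark.parametrize("v_true", [0.4, 0.8, 1.2])
    def test_parameter_recovery_grid(self, d_true, v_true):
        """(D, v) recovered within 15% from 200 advective tracks."""
        spec = GeneratorSpec(
            seed=int(1000 * d_true + 100 * v_true),
            track_params=TrackParams(
                bs_fraction=1.0, d_bs=d_true, v_bs=v_true, duration=120.0
            ),
        )
        tracks = gen_tracks(spec, n_pairs=100)
        profile = msd_profile(tracks, max_lag=60.0, n_boot=300, seed=1)
        fit = fit_motion_model(profile)
        assert fit.selected_model == "advective"
        assert fit.v == pytest.approx(v_true, rel=0.15)
        assert fit.d == pytest.approx(d_true, rel=0.15)


class TestEarlySpeed:
    def test_uniform_drift(self):
        assert mean_early_speed(drift_track(v=1.0)) == pytest.approx(1.0)

    def test_stationary(self):
        assert mean_early_speed(make_track([3.0] * 13)) == pytest.approx(0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            mean_early_speed(make_track([0.0], dt=5.0))

    def test_net_variant_uses_endpoints(self):
        track = make_track([0, 10, 0, 10, 20])  # zig-zag then up, 20 min span
        assert mean_early_speed(track, method="per_frame") == pytest.approx(2.0)
        assert mean_early_speed(track, method="net") == pytest.approx(1.0)

    def test_matches_folded_normal_oracle(self):
        """Generated drift-diffusion frame speeds match the folded-normal
        mean E|X|, X ~ Normal(v*dt, 2*D*dt), computed independently."""
        v, d, dt = 1.1, 0.05, 5.0
        spec = GeneratorSpec(
            seed=99,
            track_params=TrackParams(bs_fraction=1.0, v_bs=v, d_bs=d),
        )
        tracks = gen_tracks(spec, n_pairs=50)  # 100 tracks
        speeds = [mean_early_speed(t) for t in tracks]
        mu, sd = v * dt, math.sqrt(2 * d * dt)
        expected = stats.foldnorm.mean(c=mu / sd, scale=sd) / dt
        assert np.mean(speeds) == pytest.approx(expected, rel=0.10)


class TestFateTable:
    def test_basal_counts_to_percentages(self):
        classified = (
            [("Bs", "S-phase")] * 9 + [("Bs", "LongG1")] * 7 + [("Bs", "ND")] * 60
        )
        table = tabulate_fates(classified)
        row = table[table.behavior == "Bs"].iloc[0]
        assert row.n_total == 76
        assert row.pct_s_phase == pytest.approx(11.8, abs=0.05)
        assert row.pct_longg1 == pytest.approx(9.2, abs=0.05)
        # 60/76 = 78.95; the conventional table prints 79.0
        assert row.pct_nd == pytest.approx(79.0, abs=0.1)

    def test_zero_class_percentages(self):
        classified = [("Bs", "S-phase")] * 40 + [("Bs", "ND")] * 107
        row = tabulate_fates(classified).iloc[0]
        assert round(row.pct_s_phase, 1) == 27.2
        assert row.pct_longg1 == 0.0
        assert round(row.pct_nd, 1) == 72.8

    def test_single_cell_is_hundred_percent(self):
        row = tabulate_fates([("Ap", "S-phase")]).iloc[0]
        assert row.pct_s_phase == 100.0

    def test_row_percentages_sum_to_hundred(self):
        classified = [("Ap", "S-phase"), ("Ap", "ND"), ("Bs", "LongG1"), ("Bs", "ND")]
        table = tabulate_fates(classified)
        sums = table[["pct_s_phase", "pct_longg1", "pct_nd"]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate_fates([])
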