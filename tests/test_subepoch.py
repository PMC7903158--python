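"""Sub-epoch extraction and the cued/uncued/neutral sub-sampling z procedure."""

import numpy as np
import pandas as pd
import pytest

import alpharhythm as ar
from alpharhythm import design
from alpharhythm.errors import DataError
from alpharhythm.subepoch import (
    SubsampleDistribution,
    subepoch_hemi_power,
    zscore_contrast,
)
from alpharhythm.subepoch import cued_lateralization as cued_lat


def _single_trial_schedule(cue_type, cued_position, side="left"):
    return pd.DataFrame(
        {
            "trial_id": [0],
            "cue_type": [cue_type],
            "cued_position": pd.array(
                [cued_position], dtype="Int64"
            ),
            "attended_side": [side],
            "probed_position": [3],
            "is_valid": pd.array(
                [True if cue_type == "instructive" else None], dtype="boolean"
            ),
        }
    )


class TestLabels:
    def test_instructive_cued_position_three(self):
        table = ar.subepoch_table(_single_trial_schedule("instructive", 3))
        assert list(table["label"]) == ["uncued", "cued", "uncued"]
        assert list(table["position"]) == [2, 3, 4]

    def test_neutral_trial_all_neutral(self):
        table = ar.subepoch_table(_single_trial_schedule("neutral", None))
        assert list(table["label"]) == ["neutral"] * 3

    def test_default_schedule_has_64_cued_subepochs(self, schedule160):
        table = ar.subepoch_table(schedule160)
        assert (table["label"] == "cued").sum() == 18 + 28 + 18
        # positions 1 and 5 never enter
        assert set(table["position"]) == {2, 3, 4}


class TestExtract:
    def test_subepochs_align_with_onsets(self, schedule160):
        fs = 100.0
        times = -2.0 + np.arange(int(12 * fs)) / fs
        # encode absolute time in the signal to verify alignment
        data = np.tile(times, (len(schedule160), 1, 1))
        subs = ar.extract_subepochs(data, times, fs, schedule160)
        assert subs.data.shape[0] == 3 * len(schedule160)
        for i, row in enumerate(subs.table.itertuples(index=False)):
            start = subs.data[i, 0, 0]
            assert start == pytest.approx(row.onset - 2.0, abs=1e-9)
        assert subs.times[0] == pytest.approx(-2.0)

    def test_window_exceeding_parent_epoch_raises(self, schedule160):
        fs = 100.0
        times = -2.0 + np.arange(int(12 * fs)) / fs
        data = np.zeros((len(schedule160), 1, times.size))
        with pytest.raises(DataError):
            ar.extract_subepochs(
                data, times, fs, schedule160, window=(-5.0, 3.25)
            )


def _toy_hemi_power(schedule, rng, effect=0.0):
    """Hemisphere power per sub-epoch: baseline noise + optional cued effect."""
    table = ar.subepoch_table(schedule)
    n, T = len(table), 30
    hemi = rng.uniform(0.9, 1.1, size=(n, 2, T))
    if effect:
        cued = (table["label"] == "cued").to_numpy()
        left_att = (table["attended_side"] == "left").to_numpy()
        # raise ipsilateral power on cued sub-epochs
        hemi[cued & left_att, 0] += effect
        hemi[cued & ~left_att, 1] += effect
    return hemi, table


class TestSubsampling:
    def test_matched_counts_are_respected(self, schedule160):
        rng = np.random.default_rng(0)
        hemi, table = _toy_hemi_power(schedule160, rng)
        dist = ar.subsampled_lateralization(hemi, table, "uncued", n_draws=50, seed=1)
        expected = {
            ("left", 2): 9, ("left", 3): 14, ("left", 4): 9,
            ("right", 2): 9, ("right", 3): 14, ("right", 4): 9,
        }
        assert dist.matched_counts == expected
        assert dist.draws.shape == (50, 30)

    def test_identity_pool_gives_degenerate_distribution(self, schedule160):
        rng = np.random.default_rng(1)
        hemi, table = _toy_hemi_power(schedule160, rng)
        dist = ar.subsampled_lateralization(hemi, table, "cued", n_draws=20, seed=2)
        cued_series = cued_lat(hemi, table)
        np.testing.assert_allclose(
            dist.draws, np.broadcast_to(cued_series, dist.draws.shape), atol=1e-12
        )

    def test_insufficient_cell_raises_naming_the_cell(self):
        schedule = pd.concat(
            [_single_trial_schedule("instructive", 3)], ignore_index=True
        )
        table = ar.subepoch_table(schedule)
        hemi = np.ones((len(table), 2, 5))
        with pytest.raises(DataError, match="position=3"):
            ar.subsampled_lateralization(hemi, table, "neutral", n_draws=5, seed=0)

    def test_homogeneous_pool_envelope_covers_cued_series(self, schedule160):
        """Null case: cued series falls inside the 2.5-97.5 percentile
        envelope for ~95% of time points."""
        rng = np.random.default_rng(3)
        hemi, table = _toy_hemi_power(schedule160, rng)
        dist = ar.subsampled_lateralization(
            hemi, table, "neutral", n_draws=800, seed=4
        )
        cued_series = cued_lat(hemi, table)
        lo = np.percentile(dist.draws, 2.5, axis=0)
        hi = np.percentile(dist.draws, 97.5, axis=0)
        coverage = np.mean((cued_series >= lo) & (cued_series <= hi))
        assert 0.80 <= coverage <= 1.0


class TestZScore:
    def _dist(self, draws):
        return SubsampleDistribution(
            draws=draws, times=np.arange(draws.shape[1], dtype=float),
            label="uncued", matched_counts={},
        )

    def test_cued_at_draw_mean_gives_zero(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(500, 8))
        z = zscore_contrast(draws.mean(axis=0), self._dist(draws))
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_percentile_matches_normal_quantile(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.0, 1.0, size=(20000, 1))
        cued = np.percentile(draws, 97.5, axis=0)
        z = zscore_contrast(cued, self._dist(draws))
        assert z[0] == pytest.approx(1.96, abs=0.08)

    def test_invariant_to_common_additive_constant(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(300, 6))
        cued = rng.normal(size=6)
        z0 = zscore_contrast(cued, self._dist(draws))
        z1 = zscore_contrast(cued + 5.0, self._dist(draws + 5.0))
        np.testing.assert_allclose(z0, z1, atol=1e-9)

    def test_zero_spread_flagged(self):
        draws = np.ones((10, 3))
        with pytest.warns(UserWarning, match="zero sub-sample spread"):
            z = zscore_contrast(np.array([1.0, 2.0, 1.0]), self._dist(draws))
        assert np.isnan(z).all()


class TestGroupInference:
    def test_all_zero_input_is_null(self):
        res = ar.group_inference(np.zeros((6, 5)), n_boot=200, n_perm=200, seed=0)
        np.testing.assert_allclose(res.p, 1.0)
        np.testing.assert_allclose(res.ci_low, 0.0)
        np.testing.assert_allclose(res.ci_high, 0.0)

    def test_shared_effect_p_matches_enumeration(self):
        z = np.zeros((5, 4))
        z[:, 2] = 2.0
        res = ar.group_inference(z, n_boot=200, n_perm=10000, seed=0)
        assert res.p[2] == pytest.approx(2 / 2**5)

    def test_null_flag_rate_is_calibrated(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((20, 400))
        res = ar.group_inference(z, n_boot=100, n_perm=1000, seed=1)
        rate = (res.p < 0.05).mean()
        assert abs(rate - 0.05) < 0.025


def test_planted_cued_boost_detected_in_z(schedule160, small_layout):
    """End-to-end: a cued power boost yields |z| well above the null around
    the cued onsets for a single synthetic participant."""
    params = ar.GeneratorParams(sampling_rate=100.0, seed=3)
    rec = ar.simulate_meg(schedule160, small_layout, params)
    tfd = ar.stft_decompose(
        rec.epochs, 100.0, rec.time_axis, freqs=(8, 9, 10, 11, 12),
        channel_names=small_layout.channel_names,
    )
    from alpharhythm.timefreq import trial_alpha_power

    power = trial_alpha_power(tfd, small_layout)
    hemi, rel_times, table = subepoch_hemi_power(
        power, tfd.times, small_layout, rec.schedule
    )
    cued_series = cued_lat(hemi, table)
    dist = ar.subsampled_lateralization(hemi, table, "uncued", n_draws=400, seed=9)
    z = zscore_contrast(cued_series, dist)
    near = (rel_times >= 0.0) & (rel_times <= 1.25)
    assert np.nanmax(np.abs(z[near])) > 3.0
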