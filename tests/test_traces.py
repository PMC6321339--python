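"""Localization-trace analytics: binarization, gap merging, dwell times,
subsets, active-site counting and box statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintkinetics import (
    SubsetScheme,
    binarize,
    boxplot_stats,
    bright_dark_times,
    count_active_sites,
    merge_single_frame_gaps,
    occupation_from_times,
    occupation_probability,
    rate_from_frame_counts,
    render_localization_table,
    split_subsets,
    subset_kinetics,
)
from paintkinetics.traces import bright_dark_frame_counts


def table_from_frames(frames, group=0, site=0):
    f = np.asarray(frames, dtype=np.int64)
    return pd.DataFrame(
        {
            "frame": f,
            "x": np.zeros(f.size),
            "y": np.zeros(f.size),
            "photons": np.ones(f.size),
            "group": np.full(f.size, group, dtype=np.int64),
            "site": np.full(f.size, site, dtype=np.int64),
        }
    )


class TestBinarize:
    def test_frames_to_trace(self):
        t = binarize(table_from_frames([2, 3, 7]), 0, 0, n_frames=11)
        expected = np.zeros(11, dtype=bool)
        expected[[2, 3, 7]] = True
        np.testing.assert_array_equal(t, expected)

    def test_duplicate_rows_count_once(self):
        t = binarize(table_from_frames([4, 4, 4]), 0, 0, n_frames=6)
        assert t.sum() == 1

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            binarize(table_from_frames([1]), 5, 9, n_frames=10)


class TestGapMerge:
    def test_single_gap_filled(self):
        np.testing.assert_array_equal(
            merge_single_frame_gaps(np.array([1, 0, 1], bool)), np.ones(3, bool)
        )

    def test_double_gap_untouched(self):
        t = np.array([1, 0, 0, 1], bool)
        np.testing.assert_array_equal(merge_single_frame_gaps(t), t)

    def test_all_dark_unchanged(self):
        t = np.zeros(8, bool)
        np.testing.assert_array_equal(merge_single_frame_gaps(t), t)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=0, max_size=40))
    def test_idempotent_and_monotone(self, bits):
        t = np.array(bits, dtype=bool)
        once = merge_single_frame_gaps(t)
        twice = merge_single_frame_gaps(once)
        np.testing.assert_array_equal(once, twice)
        # merging only adds bright frames; the difference is the merged gaps
        assert once.sum() >= t.sum()
        added = int(once.sum() - t.sum())
        gaps = sum(
            1
            for i in range(1, t.size - 1)
            if not t[i] and t[i - 1] and t[i + 1]
        )
        assert added == gaps


class TestDwellTimes:
    def test_stated_convention(self):
        """0,1,1,0,0,0,1,0 at 0.2 s: tauB = {0.4, 0.2}; interior tauD = {0.6};
        leading/trailing dark runs are censored."""
        trace = np.array([0, 1, 1, 0, 0, 0, 1, 0], dtype=bool)
        times = bright_dark_times(trace, exposure=0.2)
        np.testing.assert_allclose(sorted(times.bright), [0.2, 0.4])
        np.testing.assert_allclose(times.dark, [0.6])

    def test_all_bright(self):
        times_b, times_d = bright_dark_frame_counts(np.ones(5, bool))
        assert list(times_b) == [5]
        assert times_d.size == 0

    def test_occupation_identity_on_simulation(self, small_ensemble):
        """delta=0 ensemble: rho from dwell times matches the closed form
        within 3 standard errors."""
        cfg = small_ensemble.config
        table = render_localization_table(small_ensemble)
        brights, darks = [], []
        for _, rows in table.groupby(["group", "site"]):
            trace = np.zeros(cfg.n_frames, dtype=bool)
            trace[rows["frame"].to_numpy()] = True
            trace = merge_single_frame_gaps(trace)
            b, d = bright_dark_frame_counts(trace)
            brights.append(b)
            darks.append(d)
        b = np.concatenate(brights) * cfg.exposure
        d = np.concatenate(darks) * cfg.exposure
        from paintkinetics import BrightDarkTimes

        rho_obs = occupation_from_times(BrightDarkTimes(bright=b, dark=d))
        rho_true = occupation_probability(cfg.rates, cfg.concentration)
        # delta-method SE of the ratio estimator
        se = rho_obs * np.sqrt(
            (b.std() / b.mean()) ** 2 / b.size + (d.std() / d.mean()) ** 2 / d.size
        ) * (1 - rho_obs)
        assert abs(rho_obs - rho_true) < max(3 * se, 0.01)

    def test_rate_correction_removes_discretization_bias(self, rng):
        """Exponential dwells observed through 0.5-overlap framing: the
        geometric correction recovers the rate, the naive inverse mean does
        not."""
        k, dt, n = 0.3, 0.2, 40_000
        durations = rng.exponential(1 / k, n)
        phases = rng.uniform(0, dt, n)
        counts = np.floor((durations + phases) / dt).astype(int)
        counts = counts[counts >= 1]
        rate, se = rate_from_frame_counts(counts, dt)
        assert abs(rate - k) < 3 * se
        naive = 1.0 / (np.mean(counts) * dt)
        assert abs(naive - k) > 3 * se


class TestSubsets:
    def test_partition(self):
        scheme = SubsetScheme(frames_per_subset=5000, n_frames=25000)
        assert scheme.n_subsets == 5
        table = table_from_frames(np.arange(0, 25000, 7))
        subs = split_subsets(table, scheme)
        assert len(subs) == 5
        assert sum(len(s) for s in subs) == len(table)
        assert subs[0]["frame"].max() < 5000 <= subs[1]["frame"].min()

    def test_wide_scheme_single_subset(self):
        scheme = SubsetScheme(frames_per_subset=100, n_frames=50)
        assert scheme.n_subsets == 1


class TestActiveSites:
    def test_threshold_rule(self):
        """Counts (5,4,2,0,0) across five subsets with 'more than 3' -> active
        pattern (1,1,0,0,0)."""
        frames = np.concatenate(
            [np.arange(5), 5000 + np.arange(4), 10000 + np.arange(2)]
        )
        table = table_from_frames(frames)
        scheme = SubsetScheme(5000, 25000)
        out = count_active_sites(table, scheme, n_origami=1, threshold=3)
        assert list(out["n_active"]) == [1, 1, 0, 0, 0]

    def test_mean_per_origami_uses_all_picked(self):
        parts = [table_from_frames(np.arange(10), group=g, site=s) for g in range(2) for s in range(7)]
        table = pd.concat(parts[:13], ignore_index=True)  # 13 active sites
        out = count_active_sites(table, SubsetScheme(5000, 5000), n_origami=2)
        assert out.loc[0, "mean_active_per_origami"] == pytest.approx(6.5)

    def test_monotone_in_threshold(self, small_ensemble):
        table = render_localization_table(small_ensemble)
        scheme = SubsetScheme(1000, small_ensemble.config.n_frames)
        prev = None
        for thr in (0, 3, 10, 30):
            out = count_active_sites(table, scheme, n_origami=20, threshold=thr)
            if prev is not None:
                assert np.all(out["n_active"].to_numpy() <= prev)
            prev = out["n_active"].to_numpy()

    def test_zero_origami_rejected(self):
        with pytest.raises(ValueError):
            count_active_sites(table_from_frames([1]), SubsetScheme(10, 10), n_origami=0)

    def test_depleting_ensemble_activity_decays(self, depleting_ensemble):
        """Active-site count declines across subsets roughly as the
        site-survival law exp(-delta*rho*t) evaluated at subset midpoints."""
        from paintkinetics import occupation_probability

        cfg = depleting_ensemble.config
        table = render_localization_table(depleting_ensemble)
        scheme = SubsetScheme(cfg.n_frames // 4, cfg.n_frames)
        out = count_active_sites(table, scheme, n_origami=cfg.n_origami)
        n = out["n_active"].to_numpy().astype(float)
        assert n[0] > n[-1]  # depletion visible
        rho = occupation_probability(cfg.rates, cfg.concentration)
        mid = (np.arange(4) + 0.5) * (cfg.n_frames // 4) * cfg.exposure
        expected_ratio = np.exp(-cfg.delta * rho * (mid[-1] - mid[0]))
        assert n[-1] / n[0] == pytest.approx(expected_ratio, rel=0.25)


class TestBoxStats:
    def test_quartiles(self):
        bs = boxplot_stats(np.arange(1.0, 10.0))
        assert (bs.q25, bs.median, bs.q75) == (3.0, 5.0, 7.0)

    def test_constant_values(self):
        bs = boxplot_stats(np.full(10, 2.5))
        assert bs.q25 == bs.median == bs.q75 == 2.5
        assert bs.outliers.size == 0

    def test_exponential_median(self, rng):
        sample = rng.exponential(1 / 0.3, 10_000)
        bs = boxplot_stats(sample)
        assert bs.median == pytest.approx(np.log(2) / 0.3, rel=0.05)
        assert bs.whisker_high <= bs.q75 + 1.5 * (bs.q75 - bs.q25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats(np.empty(0))


class TestSubsetKinetics:
    def test_stationary_medians_flat(self, small_ensemble):
        cfg = small_ensemble.config
        table = render_localization_table(small_ensemble)
        scheme = SubsetScheme(cfg.n_frames // 5, cfg.n_frames)
        out = subset_kinetics(table, scheme, cfg.exposure)
        med = out["tauD_median"].to_numpy()
        assert np.nanmax(med) / np.nanmin(med) < 1.5  # no systematic drift

    def test_depleting_dark_time_rises(self):
        """As docking sites are depleted on 12-site origami, the dark gaps
        between binding events on a structure lengthen (per-site traces show
        the loss only as censored darkness, so the signature is read at the
        origami level)."""
        from paintkinetics import BindingRates, SimulationConfig, simulate_ensemble
        from paintkinetics.units import nM

        cfg = SimulationConfig(
            rates=BindingRates(1.5e6, 0.3),
            concentration=nM(30),
            delta=1.5e-3,
            n_origami=40,
            sites_per_origami=12,
            exposure=0.2,
            n_frames=25500,
            seed=404,
        )
        table = render_localization_table(simulate_ensemble(cfg))
        scheme = SubsetScheme(5100, 25500)
        out = subset_kinetics(table, scheme, 0.2, per_origami=True)
        med = out["tauD_median"].to_numpy()
        assert med[-1] > med[0]
        # overall upward trend across subsets
        assert np.polyfit(np.arange(med.size), med, 1)[0] > 0

    def test_origami_level_merging_inflates_bright_time(self):
        """Fig-A6-type artifact: binarizing at the origami level merges
        simultaneous events, so 12-site origami show longer apparent bright
        times than 4-site origami."""
        from paintkinetics import SimulationConfig, BindingRates, simulate_ensemble
        from paintkinetics.units import nM

        meds = {}
        for b in (12, 4):
            cfg = SimulationConfig(
                rates=BindingRates(1.5e6, 0.3),
                concentration=nM(30),
                n_origami=40,
                sites_per_origami=b,
                exposure=0.2,
                n_frames=5100,
                seed=77,
            )
            table = render_localization_table(simulate_ensemble(cfg))
            scheme = SubsetScheme(5100, 5100)
            out = subset_kinetics(table, scheme, 0.2, per_origami=True)
            meds[b] = out.loc[0, "tauB_mean"]
        assert meds[12] > meds[4]
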