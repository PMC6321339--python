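"""Stochastic simulator: distributions, conservation laws, determinism."""

import numpy as np
import pytest
from scipy import stats

from paintkinetics import (
    BindingRates,
    SimulationConfig,
    copasi_reference_preset,
    occupation_probability,
    render_localization_table,
    render_movie,
    render_roi_traces,
    simulate_ensemble,
    simulate_site,
)
from paintkinetics.simulate import SiteEventList, _site_rng, occupancy_per_frame
from paintkinetics.units import nM

RATES = BindingRates(ka=1.5e6, kd=0.3)


def _long_config(**kw):
    base = dict(
        rates=RATES,
        concentration=nM(100),
        n_origami=1,
        sites_per_origami=1,
        exposure=0.1,
        n_frames=100_000,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateSite:
    def test_zero_concentration_gives_empty_history(self):
        cfg = _long_config(concentration=0.0)
        site = simulate_site(cfg, _site_rng(1, 1))
        assert site.n_events == 0

    def test_mean_bright_time_is_inverse_kd(self):
        cfg = _long_config()
        brights = []
        for i in range(20):
            site = simulate_site(cfg, _site_rng(7, i))
            ends_ok = np.array([c == "unbind" for c in site.causes])
            brights.append((site.ends - site.starts)[ends_ok])
        b = np.concatenate(brights)
        se = b.std(ddof=1) / np.sqrt(b.size)
        assert abs(b.mean() - 1 / RATES.kd) < 3 * se

    def test_dwell_distributions_are_exponential(self):
        """KS at alpha=0.01: dark ~ Exp(ka<A>), bright ~ Exp(kd+delta+bleach)."""
        cfg = _long_config(delta=0.0, bleach_rate=0.1, n_frames=400_000)
        darks, brights = [], []
        i = 0
        while sum(x.size for x in brights) < 10_000:
            site = simulate_site(cfg, _site_rng(13, i))
            starts, ends = site.starts, site.ends
            brights.append(ends[:-1] - starts[:-1])  # last may be censored
            darks.append(starts[1:] - ends[:-1])
            i += 1
        darks = np.concatenate(darks)[:10_000]
        brights = np.concatenate(brights)[:10_000]
        kon = RATES.ka * cfg.concentration
        assert stats.kstest(darks, "expon", args=(0, 1 / kon)).pvalue > 0.01
        assert stats.kstest(brights, "expon", args=(0, 1 / (RATES.kd + 0.1))).pvalue > 0.01

    def test_depletion_survival_matches_closed_form(self):
        """Wall-clock survival of sites ~ exp(-delta*rho*t) (Eq.-4-type law),
        within binomial error on >= 2000 sites."""
        delta = 1e-3
        conc = nM(200)  # rho ~ 0.5 at the reference rates
        rho = occupation_probability(RATES, conc)
        t_half = np.log(2) / (delta * rho)
        cfg = SimulationConfig(
            rates=RATES,
            concentration=conc,
            delta=delta,
            n_origami=2000,
            sites_per_origami=1,
            exposure=1.0,
            n_frames=int(t_half) + 1,
            seed=3,
        )
        ens = simulate_ensemble(cfg)
        survived = sum(1 for s in ens.sites if s.depleted_at is None or s.depleted_at > t_half)
        p = survived / 2000
        se = np.sqrt(0.5 * 0.5 / 2000)
        assert abs(p - 0.5) < 3 * se
        # pointwise band at a few earlier times
        times = np.array([0.25, 0.5, 0.75]) * t_half
        for t in times:
            frac = sum(
                1 for s in ens.sites if s.depleted_at is None or s.depleted_at > t
            ) / 2000
            expected = np.exp(-delta * rho * t)
            band = 3 * np.sqrt(expected * (1 - expected) / 2000)
            assert abs(frac - expected) < band

    def test_depletion_requires_occupation(self):
        """Sites that never bind are never depleted; depletion ends the history."""
        cfg = _long_config(delta=0.05, n_frames=50_000)
        for i in range(50):
            site = simulate_site(cfg, _site_rng(5, i))
            if site.n_events == 0:
                assert site.depleted_at is None
            if site.depleted_at is not None:
                assert site.causes[-1] == "deplete"
                assert site.depleted_at == site.ends[-1]
                # no binding activity after the damage instant
                assert np.all(site.ends <= site.depleted_at + 1e-12)

    def test_event_list_invariants_rejected(self):
        with pytest.raises(ValueError):
            SiteEventList(0, 0, starts=[1.0, 2.0], ends=[3.0, 4.0], causes=("unbind", "unbind"))


class TestEnsemble:
    def test_determinism(self):
        cfg = _long_config(n_origami=4, sites_per_origami=3, n_frames=10_000)
        a = simulate_ensemble(cfg)
        b = simulate_ensemble(cfg)
        for sa, sb in zip(a.sites, b.sites):
            np.testing.assert_array_equal(sa.starts, sb.starts)
            np.testing.assert_array_equal(sa.ends, sb.ends)
            assert sa.causes == sb.causes

    def test_occupied_fraction_matches_equilibrium(self):
        cfg = _long_config(n_origami=50, sites_per_origami=12, n_frames=20_000)
        ens = simulate_ensemble(cfg)
        total_occ = sum(s.occupied_time for s in ens.sites)
        frac = total_occ / (len(ens.sites) * cfg.duration)
        rho = occupation_probability(RATES, cfg.concentration)
        assert frac == pytest.approx(rho, rel=0.02)

    def test_incorporation_probability(self):
        cfg = _long_config(
            n_origami=400, sites_per_origami=12, incorporation_probability=0.8, n_frames=100
        )
        ens = simulate_ensemble(cfg)
        mean_sites = ens.n_sites / 400
        assert mean_sites == pytest.approx(9.6, abs=3 * np.sqrt(12 * 0.8 * 0.2 / 400))

    def test_single_site_reduces_to_simulate_site(self):
        cfg = _long_config(n_frames=10_000)
        ens = simulate_ensemble(cfg)
        direct = simulate_site(cfg, _site_rng(cfg.seed, 1))
        np.testing.assert_array_equal(ens.sites[0].starts, direct.starts)


class TestRenderers:
    def test_occupancy_conserves_occupied_time(self, small_ensemble):
        cfg = small_ensemble.config
        for site in small_ensemble.sites[:20]:
            occ = occupancy_per_frame(site, cfg.n_frames, cfg.exposure)
            assert occ.sum() * cfg.exposure == pytest.approx(site.occupied_time, rel=1e-9)

    def test_exact_frame_occupation(self):
        site = SiteEventList(0, 0, starts=[10 * 0.2], ends=[20 * 0.2], causes=("unbind",))
        occ = occupancy_per_frame(site, 30, 0.2)
        np.testing.assert_allclose(occ[10:20], 1.0, atol=1e-9)
        np.testing.assert_allclose(occ[:10], 0.0, atol=1e-9)
        np.testing.assert_allclose(occ[20:], 0.0, atol=1e-9)

    def test_roi_trace_background_only(self):
        cfg = _long_config(concentration=0.0, n_frames=100)
        ens = simulate_ensemble(cfg)
        df = render_roi_traces(ens, n_rois=1, background=10.0)
        assert np.all(df["roi_000"] == 10.0)

    def test_localization_rule_thresholds(self):
        dt = 0.2
        # event fully covering frames 5..9
        full = SiteEventList(0, 0, starts=[5 * dt], ends=[10 * dt], causes=("unbind",))
        # event covering 40% of frame 0
        partial = SiteEventList(1, 0, starts=[0.0], ends=[0.4 * dt], causes=("unbind",))
        cfg = SimulationConfig(
            rates=RATES, concentration=nM(10), n_origami=1, sites_per_origami=2,
            exposure=dt, n_frames=12, seed=0,
        )
        from paintkinetics.simulate import EnsembleRealization

        ens = EnsembleRealization(
            config=cfg,
            sites=(full, partial),
            origami_xy=np.array([[5.0, 5.0]]),
            site_offsets=np.zeros((2, 2)),
        )
        table = render_localization_table(ens, min_overlap_fraction=0.5)
        assert sorted(table[table["site"] == 0]["frame"]) == [5, 6, 7, 8, 9]
        assert (table["site"] == 1).sum() == 0

    def test_localization_rate_matches_occupancy(self, small_ensemble):
        """Over a long stationary acquisition the per-frame localization
        probability approaches the occupation probability."""
        cfg = small_ensemble.config
        table = render_localization_table(small_ensemble)
        rho = occupation_probability(cfg.rates, cfg.concentration)
        per_site = len(table) / (small_ensemble.n_sites * cfg.n_frames)
        assert per_site == pytest.approx(rho, rel=0.05)

    def test_movie_conserves_intensity_and_matches_traces(self):
        cfg = _long_config(n_origami=4, sites_per_origami=2, n_frames=500, exposure=0.2)
        ens = simulate_ensemble(cfg)
        # place origami inside a small frame
        object.__setattr__(ens, "origami_xy", np.array([[8.0, 8.0], [24.0, 8.0], [8.0, 24.0], [24.0, 24.0]]))
        stack = render_movie(ens, frame_shape=(32, 32), psf_sigma=1.0, background=0.0)
        df = render_roi_traces(ens, n_rois=1, background=0.0)
        per_frame_stack = stack.sum(axis=(1, 2)).astype(float)
        per_frame_trace = df["roi_000"].to_numpy()
        # integer quantization: within 0.5 count per involved pixel
        assert np.allclose(per_frame_stack, per_frame_trace, atol=30.0)
        assert stats.pearsonr(per_frame_stack, per_frame_trace).statistic > 0.999

    def test_movie_outside_frame_rejected(self):
        cfg = _long_config(n_frames=10)
        ens = simulate_ensemble(cfg)
        object.__setattr__(ens, "origami_xy", np.array([[100.0, 5.0]]))
        with pytest.raises(ValueError):
            render_movie(ens, frame_shape=(32, 32))


class TestPreset:
    def test_reference_parameter_set(self):
        cfg = copasi_reference_preset()
        assert cfg.exposure == 0.2
        assert cfg.concentration == pytest.approx(nM(10))
        assert cfg.rates.kd == 0.3
        assert cfg.rates.ka == 1.5e6
        assert cfg.sites_per_origami == 12
        assert cfg.n_frames * cfg.exposure == pytest.approx(17 * 60)
        assert cfg.delta == 0.0 and cfg.bleach_rate == 0.0

    def test_gap_merge_free_bright_times_recover_kd(self):
        """Frame-discretized bright runs from the reference preset give the
        generative kd after the geometric-count correction."""
        from paintkinetics import estimate_kd_from_paint

        out = estimate_kd_from_paint(n_origami=60, seed=9)
        assert abs(out["kd"] - 0.3) < 3 * out["se"]
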