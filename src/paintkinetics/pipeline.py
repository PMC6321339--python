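"""End-to-end workflows binding simulation, correlation and inference.

Two experiments structure the package, mirrored here as single functions:

* ``run_titration`` — the SI-FCS titration: simulate ensembles at several
  imager concentrations, detrend each ROI trace (Eq.-1-style trend),
  autocorrelate with the multiple-tau scheme, fit exponential decays, and
  fit the decay-time-versus-concentration relation for (ka, kd).
* ``run_depletion`` — the depletion experiment: simulate depleting
  ensembles across occupancies, extract the effective decay rate kappa of
  each ensemble trace from the trend fit, and regress kappa on the
  occupation probability through the origin for delta.
* ``estimate_kd_from_paint`` — the localization-based route: simulate the
  mass-action reference conditions, binarize per-site traces, and estimate
  kd from discretization-corrected bright times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correlate import multi_tau_acf, traces_from_frame
from .kinetics import BindingRates, ConfocalModel, confocal_acf, occupation_probability
from .models import (
    ConfocalDiffusionModel,
    DepletionRegression,
    DepletionResults,
    TitrationModel,
    TitrationResults,
    aggregate_rois,
    fit_acf,
    fit_detrend,
)
from .simulate import (
    SimulationConfig,
    render_localization_table,
    render_roi_traces,
    simulate_ensemble,
)
from .traces import bright_dark_frame_counts, merge_single_frame_gaps, rate_from_frame_counts
from .units import nM

__all__ = [
    "titration_tau_points",
    "run_titration",
    "run_depletion",
    "estimate_kd_from_paint",
    "confocal_roundtrip",
    "PAPER_CONCENTRATIONS_NM",
]

#: the five titration concentrations in nM used throughout
PAPER_CONCENTRATIONS_NM = (10.0, 30.0, 100.0, 300.0, 600.0)


def titration_tau_points(
    rates: BindingRates,
    concentrations: np.ndarray,
    *,
    n_rois: int = 64,
    origami_per_roi: int = 8,
    n_frames: int = 200_000,
    exposure: float = 0.01,
    seed: int = 1,
    delta: float = 0.0,
    bleach_rate: float = 0.0,
    brightness: float = 100.0,
    background: float = 10.0,
    noise: str = "none",
    m: int = 16,
    bi_exp_above: float = nM(100),
) -> pd.DataFrame:
    """Simulate + correlate one titration series; one row per concentration.

    Each concentration is an independent ensemble (seed offset by index)
    rendered into ``n_rois`` ROI traces; every trace is detrended, then
    autocorrelated, then fitted by a single exponential with offset — or a
    double exponential above ``bi_exp_above``, where the slow depletion
    component contaminates the curve and the fast component is the binding
    decay.  ROIs whose detrend fit fails to converge are excluded and
    reported in ``n_excluded``.
    """
    rows = []
    for i, conc in enumerate(np.asarray(concentrations, dtype=float)):
        cfg = SimulationConfig(
            rates=rates,
            concentration=float(conc),
            delta=delta,
            bleach_rate=bleach_rate,
            n_origami=n_rois * origami_per_roi,
            sites_per_origami=12,
            exposure=exposure,
            n_frames=n_frames,
            seed=seed * 1000 + i,
        )
        realization = simulate_ensemble(cfg)
        df = render_roi_traces(
            realization,
            n_rois=n_rois,
            brightness=brightness,
            background=background,
            noise=noise,
        )
        components = 2 if conc > bi_exp_above else 1
        fits, n_excluded = [], 0
        for trace in traces_from_frame(df):
            det = fit_detrend(trace)
            if not det.converged:
                n_excluded += 1
                continue
            curve = multi_tau_acf(det.detrended(), m=m)
            fits.append(fit_acf(curve, components=components))
        tau_mean, tau_sd, n_used = aggregate_rois(fits)
        rows.append(
            {
                "concentration_M": float(conc),
                "tau_c_s": tau_mean,
                "tau_c_sd_s": tau_sd,
                "n_rois": n_used,
                "n_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows)


def run_titration(
    rates: BindingRates,
    concentrations=None,
    **kwargs,
) -> tuple[TitrationResults, pd.DataFrame]:
    """Full SI-FCS titration recovery; returns (fit results, per-concentration points)."""
    if concentrations is None:
        concentrations = [nM(c) for c in PAPER_CONCENTRATIONS_NM]
    points = titration_tau_points(rates, concentrations, **kwargs)
    results = TitrationModel.from_dataframe(points).fit()
    return results, points


def run_depletion(
    rates: BindingRates,
    delta: float,
    concentrations=None,
    *,
    n_sites: int = 2000,
    n_groups: int = 8,
    duration: float = 18000.0,
    exposure: float = 2.0,
    seed: int = 1,
    brightness: float = 100.0,
    background: float = 5.0,
) -> tuple[DepletionResults, pd.DataFrame]:
    """Depletion-rate recovery across occupancies.

    Per concentration, ``n_sites`` docking sites are simulated with the
    occupied-gated damage clock and split into ``n_groups`` independent
    ensemble traces; each group trace is fitted by the monoexponential
    trend, giving kappa mean and SD per occupancy; the through-origin
    regression of kappa on rho yields delta.  The occupation probability is
    computed from the concentration and the generative rate constants.
    """
    if concentrations is None:
        concentrations = [nM(c) for c in PAPER_CONCENTRATIONS_NM]
    n_frames = int(round(duration / exposure))
    sites_per_group = max(1, n_sites // n_groups)
    rows = []
    for i, conc in enumerate(np.asarray(concentrations, dtype=float)):
        kappas = []
        for g in range(n_groups):
            cfg = SimulationConfig(
                rates=rates,
                concentration=float(conc),
                delta=delta,
                n_origami=sites_per_group,
                sites_per_origami=1,
                exposure=exposure,
                n_frames=n_frames,
                seed=seed * 100_000 + i * 100 + g,
            )
            realization = simulate_ensemble(cfg)
            df = render_roi_traces(
                realization, n_rois=1, brightness=brightness, background=background
            )
            trace = traces_from_frame(df)[0]
            det = fit_detrend(trace)
            if det.converged:
                kappas.append(det.kappa)
        kappas = np.asarray(kappas)
        rows.append(
            {
                "concentration_M": float(conc),
                "rho": occupation_probability(rates, float(conc)),
                "kappa_mean": float(np.mean(kappas)),
                "kappa_sd": float(np.std(kappas, ddof=1)),
                "n_groups": int(kappas.size),
            }
        )
    points = pd.DataFrame(rows)
    regression = DepletionRegression(
        points["rho"].to_numpy(),
        points["kappa_mean"].to_numpy(),
        points["kappa_sd"].to_numpy(),
    )
    return regression.fit(), points


def estimate_kd_from_paint(
    n_origami: int = 500,
    seed: int = 1,
    config: SimulationConfig | None = None,
    merge_gaps: bool = False,
) -> dict:
    """kd from discretization-corrected bright times of simulated PAINT traces.

    Simulates the mass-action reference conditions (10 nM, 0.2 s frames,
    17-min segment, 12 sites per origami) for ``n_origami`` structures,
    renders a localization table, collects per-site bright-run frame counts
    (gap merging off by default so raw dwell statistics are geometric), and
    inverts the mean via the geometric-count correction.
    """
    from .simulate import copasi_reference_preset

    if config is None:
        config = copasi_reference_preset(n_origami=n_origami, seed=seed)
    realization = simulate_ensemble(config)
    table = render_localization_table(realization)
    counts = []
    for _, site_rows in table.groupby(["group", "site"]):
        trace = np.zeros(config.n_frames, dtype=bool)
        trace[site_rows["frame"].to_numpy()] = True
        if merge_gaps:
            trace = merge_single_frame_gaps(trace)
        b, _ = bright_dark_frame_counts(trace)
        counts.append(b)
    counts = np.concatenate(counts)
    kd, se = rate_from_frame_counts(counts, config.exposure)
    return {"kd": kd, "se": se, "n_events": int(counts.size), "mean_bright_s": float(np.mean(counts)) * config.exposure}


def confocal_roundtrip(
    d_true: float,
    *,
    wxy: float = 0.2,
    s: float = 5.0,
    n_particles: float = 2.0,
    n_lags: int = 200,
) -> "object":
    """Generate a noiseless confocal 3D-diffusion curve at ``d_true`` and refit it.

    Returns the ConfocalResults; ``results.diffusion_coefficient`` recovers
    ``d_true`` to numerical precision on the noiseless curve.
    """
    tau_diff = wxy**2 / (4.0 * d_true)
    lags = np.logspace(np.log10(tau_diff / 100), np.log10(tau_diff * 1000), n_lags)
    g = confocal_acf(lags, ConfocalModel(n_particles, tau_diff, s, wxy=wxy))
    return ConfocalDiffusionModel(lags, g, wxy=wxy).fit()
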