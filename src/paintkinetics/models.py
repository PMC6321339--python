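"""Model/Results classes for every inference stage of the analysis.

Each stage is a small model object built from data whose ``fit()`` returns a
results object carrying point estimates, 95% confidence bounds (Student-t
with residual degrees of freedom) and a ``summary()`` table:

``DetrendModel``
    monoexponential intensity trend I(t) = I0 exp(-kappa t) + Iinf, used to
    bleach/depletion-correct SI-FCS traces before correlation.
``AcfDecayModel``
    single or double exponential decay with offset fitted to an
    autocorrelation curve; the fast component is the binding decay.
``TitrationModel``
    decay time versus imager concentration, tau_c = 1/(ka <A> + kd),
    yielding the association/dissociation rate constants and Kd.
``DepletionRegression``
    effective depletion rate versus occupation probability, kappa =
    delta * rho, a weighted regression through the origin.
``ConfocalDiffusionModel``
    3D free-diffusion FCS model for calibration measurements in solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .correlate import AcfCurve, RoiTrace
from .kinetics import (
    BindingRates,
    ConfocalModel,
    DetrendParams,
    confocal_acf,
    detrend_model,
)
from .units import to_nM

__all__ = [
    "DetrendModel",
    "DetrendResults",
    "AcfDecayModel",
    "AcfDecayResults",
    "TitrationModel",
    "TitrationResults",
    "DepletionRegression",
    "DepletionResults",
    "ConfocalDiffusionModel",
    "ConfocalResults",
    "aggregate_rois",
    "fit_detrend",
    "detrend",
    "fit_acf",
    "fit_titration",
    "fit_depletion",
]


def _tcrit(df_resid: int, level: float = 0.95) -> float:
    if df_resid <= 0:
        return np.inf
    return float(stats.t.ppf(0.5 + level / 2.0, df_resid))


@dataclass
class _ResultsBase:
    """Common plumbing: named params, standard errors, t-based 95% bounds."""

    param_names: tuple
    params: np.ndarray
    bse: np.ndarray
    df_resid: int
    converged: bool = True
    message: str = ""

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        half = _tcrit(self.df_resid, level) * self.bse
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half},
            index=list(self.param_names),
        )

    def _summary(self, title: str, extra: list[str] | None = None) -> str:
        ci = self.conf_int()
        lines = [title, "=" * len(title)]
        lines.append(f"{'parameter':<14}{'estimate':>14}{'std err':>12}{'[0.025':>14}{'0.975]':>14}")
        for i, name in enumerate(self.param_names):
            lines.append(
                f"{name:<14}{self.params[i]:>14.6g}{self.bse[i]:>12.3g}"
                f"{ci['lower'].iloc[i]:>14.6g}{ci['upper'].iloc[i]:>14.6g}"
            )
        lines.append(f"df_resid = {self.df_resid}, converged = {self.converged}")
        if extra:
            lines.extend(extra)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Eq-1 style detrending
# ---------------------------------------------------------------------------


class DetrendModel:
    """Monoexponential trend model for an ROI intensity trace."""

    def __init__(self, trace: RoiTrace):
        if trace.values.size < 10:
            raise ValueError("trace must have length >= 10 for detrending")
        self.trace = trace

    def _start_values(self) -> tuple[float, float, float]:
        y = self.trace.values
        t = self.trace.times
        n = y.size
        head = float(np.mean(y[: max(1, n // 10)]))
        tail = float(np.mean(y[-max(1, n // 10):]))
        i_inf0 = max(tail, 0.0)
        i00 = max(head - tail, 1e-12 * max(abs(head), 1.0))
        # log-linear envelope fit for the rate (deterministic, derivative-free)
        resid = y - i_inf0
        mask = resid > 0.05 * i00
        if np.count_nonzero(mask) >= 2 and head > tail:
            slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
            kappa0 = max(-slope, 1.0 / (100 * t[-1]))
        else:
            kappa0 = 1.0 / t[-1]
        return i00, kappa0, i_inf0

    def fit(self) -> "DetrendResults":
        y = self.trace.values
        t = self.trace.times
        mean = float(np.mean(y))
        scale = max(abs(mean), 1e-30)
        if np.std(y) < 1e-12 * scale:
            # constant trace: no trend to remove
            return DetrendResults(
                param_names=("i0", "kappa", "i_inf"),
                params=np.array([0.0, 0.0, mean]),
                bse=np.zeros(3),
                df_resid=y.size - 3,
                converged=True,
                message="constant trace; kappa fixed at 0",
                trace=self.trace,
            )
        p0 = self._start_values()

        def model(tt, i0, kappa, i_inf):
            return i0 * np.exp(-kappa * tt) + i_inf

        try:
            popt, pcov = optimize.curve_fit(
                model,
                t,
                y,
                p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            bse = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
            return DetrendResults(
                param_names=("i0", "kappa", "i_inf"),
                params=popt,
                bse=bse,
                df_resid=y.size - 3,
                converged=True,
                trace=self.trace,
            )
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"detrend fit did not converge ({err}); falling back to kappa=0")
            return DetrendResults(
                param_names=("i0", "kappa", "i_inf"),
                params=np.array([0.0, 0.0, mean]),
                bse=np.full(3, np.nan),
                df_resid=y.size - 3,
                converged=False,
                message=str(err),
                trace=self.trace,
            )


@dataclass
class DetrendResults(_ResultsBase):
    trace: RoiTrace | None = None

    @property
    def detrend_params(self) -> DetrendParams:
        i0, kappa, i_inf = self.params
        return DetrendParams(i0=float(i0), kappa=float(kappa), i_inf=float(i_inf))

    @property
    def kappa(self) -> float:
        return float(self.params[1])

    def model_values(self) -> np.ndarray:
        return detrend_model(self.trace.times, self.detrend_params)

    def detrended(self) -> RoiTrace:
        return detrend(self.trace, self.detrend_params)

    def summary(self) -> str:
        return self._summary("Monoexponential detrend  I(t) = I0 exp(-kappa t) + Iinf")


def fit_detrend(trace: RoiTrace) -> DetrendResults:
    """Fit the monoexponential trend to an ROI trace."""
    return DetrendModel(trace).fit()


def detrend(trace: RoiTrace, params: DetrendParams) -> RoiTrace:
    """Divide a trace pointwise by its fitted trend (result fluctuates about 1)."""
    model = detrend_model(trace.times, params)
    if np.any(model <= 0):
        raise ValueError("trend model non-positive somewhere; cannot divide")
    return RoiTrace(
        trace.values / model,
        trace.exposure,
        roi_id=trace.roi_id,
        origin={**trace.origin, "detrended": True},
    )


# ---------------------------------------------------------------------------
# ACF decay fits
# ---------------------------------------------------------------------------


class AcfDecayModel:
    """Exponential-decay model for an autocorrelation curve.

    ``components=1`` fits amplitude*exp(-tau/tau_c)+offset; ``components=2``
    adds a slower second exponential (as needed when docking-site depletion
    contributes a slow correlation component at high imager concentration).
    """

    def __init__(self, curve: AcfCurve, components: int = 1):
        if curve.lags.size < 8:
            raise ValueError("need >= 8 lag points")
        if components not in (1, 2):
            raise ValueError("components must be 1 or 2")
        self.curve = curve
        self.components = components

    def _start_values(self) -> tuple[float, float, float]:
        lags, g = self.curve.lags, self.curve.values
        offset0 = float(np.mean(g[-max(1, g.size // 8):]))
        amp0 = max(float(g[0] - offset0), 1e-12)
        below = np.nonzero(g - offset0 < amp0 / np.e)[0]
        tau0 = float(lags[below[0]]) if below.size else float(lags[lags.size // 2])
        return amp0, tau0, offset0

    def fit(self) -> "AcfDecayResults":
        lags, g = self.curve.lags, self.curve.values
        amp0, tau0, offset0 = self._start_values()

        if self.components == 1:
            def model(tau, a, tc, c):
                return a * np.exp(-tau / tc) + c

            p0s = [(amp0, tau0, offset0), (amp0, 10 * tau0, offset0), (amp0, tau0 / 10, offset0)]
            names = ("amplitude", "tau_c", "offset")
            lower = [0.0, 1e-12, -np.inf]
            upper = [np.inf, np.inf, np.inf]
        else:
            def model(tau, a1, t1, a2, t2, c):
                return a1 * np.exp(-tau / t1) + a2 * np.exp(-tau / t2) + c

            p0s = [
                (amp0, tau0, 0.1 * amp0, 30 * tau0, offset0),
                (0.7 * amp0, tau0, 0.3 * amp0, 100 * tau0, offset0),
            ]
            names = ("amplitude", "tau_c", "amplitude2", "tau_c2", "offset")
            lower = [0.0, 1e-12, 0.0, 1e-12, -np.inf]
            upper = [np.inf, np.inf, np.inf, np.inf, np.inf]

        last_err: Exception | None = None
        for p0 in p0s:
            try:
                popt, pcov = optimize.curve_fit(
                    model, lags, g, p0=p0, bounds=(lower, upper), maxfev=40000
                )
                bse = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                if self.components == 2 and popt[1] > popt[3]:
                    # report the faster component as the binding decay
                    popt = np.array([popt[2], popt[3], popt[0], popt[1], popt[4]])
                    bse = np.array([bse[2], bse[3], bse[0], bse[1], bse[4]])
                resid = g - model(lags, *popt)
                return AcfDecayResults(
                    param_names=names,
                    params=popt,
                    bse=bse,
                    df_resid=g.size - len(popt),
                    converged=True,
                    curve=self.curve,
                    components=self.components,
                    residual_norm=float(np.linalg.norm(resid)),
                )
            except (RuntimeError, ValueError) as err:
                last_err = err
        warnings.warn(f"ACF fit did not converge ({last_err})")
        nan = np.full(len(names), np.nan)
        return AcfDecayResults(
            param_names=names,
            params=nan,
            bse=nan,
            df_resid=g.size - len(names),
            converged=False,
            message=str(last_err),
            curve=self.curve,
            components=self.components,
            residual_norm=np.nan,
        )


@dataclass
class AcfDecayResults(_ResultsBase):
    curve: AcfCurve | None = None
    components: int = 1
    residual_norm: float = np.nan

    @property
    def tau_c(self) -> float:
        """Decay time of the (fast) binding component, seconds."""
        return float(self.params[1])

    @property
    def amplitude(self) -> float:
        return float(self.params[0])

    @property
    def offset(self) -> float:
        return float(self.params[-1])

    @property
    def second_component(self) -> tuple[float, float] | None:
        if self.components == 2:
            return float(self.params[2]), float(self.params[3])
        return None

    def summary(self) -> str:
        kind = "single" if self.components == 1 else "double"
        return self._summary(f"ACF {kind}-exponential decay fit")


def fit_acf(curve: AcfCurve, components: int = 1) -> AcfDecayResults:
    """Fit a (bi-)exponential decay with offset to an ACF curve."""
    return AcfDecayModel(curve, components=components).fit()


def aggregate_rois(fits: list[AcfDecayResults]) -> tuple[float, float, int]:
    """Mean and sample SD of per-ROI decay times, excluding unconverged fits.

    Returns ``(tau_c_mean, tau_c_sd, n_used)``.
    """
    taus = [f.tau_c for f in fits if f.converged and np.isfinite(f.tau_c)]
    if len(taus) < 2:
        raise ValueError("need >= 2 converged fits to aggregate")
    return float(np.mean(taus)), float(np.std(taus, ddof=1)), len(taus)


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------


class TitrationModel:
    """Decay time versus imager concentration, tau_c = 1/(ka <A> + kd).

    Points are (concentration [M], tau_c mean [s]) with optional per-point
    SDs used as weights (1/sd^2).
    """

    def __init__(
        self,
        concentrations: np.ndarray,
        tau_c_mean: np.ndarray,
        tau_c_sd: np.ndarray | None = None,
        n_rois: np.ndarray | None = None,
    ):
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.tau_c_mean = np.asarray(tau_c_mean, dtype=float)
        self.tau_c_sd = None if tau_c_sd is None else np.asarray(tau_c_sd, dtype=float)
        self.n_rois = n_rois
        if np.unique(self.concentrations).size < 2:
            raise ValueError("need >= 2 distinct concentrations")
        if np.any(self.tau_c_mean <= 0):
            raise ValueError("decay times must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TitrationModel":
        """Build from a frame with columns concentration_M, tau_c_s, optionally tau_c_sd_s, n_rois."""
        return cls(
            df["concentration_M"].to_numpy(),
            df["tau_c_s"].to_numpy(),
            df["tau_c_sd_s"].to_numpy() if "tau_c_sd_s" in df else None,
            df["n_rois"].to_numpy() if "n_rois" in df else None,
        )

    def fit(self) -> "TitrationResults":
        conc, tau = self.concentrations, self.tau_c_mean
        # linearization 1/tau = ka*<A> + kd gives the start values
        slope, intercept = np.polyfit(conc, 1.0 / tau, 1)
        p0 = (max(slope, 1e3), max(intercept, 1e-3))

        def model(a, ka, kd):
            return 1.0 / (ka * a + kd)

        popt, pcov = optimize.curve_fit(
            model,
            conc,
            tau,
            p0=p0,
            sigma=self.tau_c_sd,
            absolute_sigma=False,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        bse = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        return TitrationResults(
            param_names=("ka", "kd"),
            params=popt,
            bse=bse,
            df_resid=conc.size - 2,
            converged=True,
            model=self,
        )


@dataclass
class TitrationResults(_ResultsBase):
    model: TitrationModel | None = None

    @property
    def rates(self) -> BindingRates:
        return BindingRates(ka=float(self.params[0]), kd=float(self.params[1]))

    @property
    def ka(self) -> float:
        return float(self.params[0])

    @property
    def kd(self) -> float:
        return float(self.params[1])

    @property
    def kd_affinity(self) -> float:
        """Equilibrium dissociation constant kd/ka, molar."""
        return self.kd / self.ka

    def kd_affinity_conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """Approximate CI for Kd by relative-error propagation."""
        rel = np.hypot(self.bse[0] / self.ka, self.bse[1] / self.kd)
        half = _tcrit(self.df_resid, level) * rel * self.kd_affinity
        return self.kd_affinity - half, self.kd_affinity + half

    def predict(self, concentrations) -> np.ndarray:
        a = np.asarray(concentrations, dtype=float)
        return 1.0 / (self.ka * a + self.kd)

    def summary(self) -> str:
        lo, hi = self.kd_affinity_conf_int()
        return self._summary(
            "Titration fit  tau_c = 1/(ka <A> + kd)",
            extra=[
                f"Kd = kd/ka = {to_nM(self.kd_affinity):.4g} nM "
                f"(95% CI {to_nM(lo):.3g} – {to_nM(hi):.3g} nM)"
            ],
        )


def fit_titration(points: pd.DataFrame | TitrationModel) -> TitrationResults:
    """Weighted fit of the titration relation; accepts a points frame or model."""
    model = points if isinstance(points, TitrationModel) else TitrationModel.from_dataframe(points)
    return model.fit()


# ---------------------------------------------------------------------------
# depletion regression
# ---------------------------------------------------------------------------


class DepletionRegression:
    """kappa = delta * rho: weighted regression through the origin.

    The model has no intercept (an unoccupied population is not depleted);
    an intercept mode exists for diagnostics only.
    """

    def __init__(
        self,
        rho: np.ndarray,
        kappa_mean: np.ndarray,
        kappa_sd: np.ndarray | None = None,
        intercept: bool = False,
    ):
        self.rho = np.asarray(rho, dtype=float)
        self.kappa_mean = np.asarray(kappa_mean, dtype=float)
        self.kappa_sd = None if kappa_sd is None else np.asarray(kappa_sd, dtype=float)
        self.intercept = intercept
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("rho values must lie in [0, 1]")
        if np.unique(self.rho).size < 2:
            raise ValueError("need >= 2 distinct rho values")
        if np.all(self.rho == 0):
            raise ValueError("all rho are zero: slope undefined")

    def fit(self) -> "DepletionResults":
        rho, kappa = self.rho, self.kappa_mean
        w = np.ones_like(rho) if self.kappa_sd is None else 1.0 / self.kappa_sd**2
        if self.intercept:
            X = np.stack([rho, np.ones_like(rho)], axis=1)
        else:
            X = rho[:, None]
        WX = X * w[:, None]
        xtx = X.T @ WX
        beta = np.linalg.solve(xtx, WX.T @ kappa)
        resid = kappa - X @ beta
        df_resid = rho.size - X.shape[1]
        s2 = float(resid @ (w * resid)) / max(df_resid, 1)
        cov = s2 * np.linalg.inv(xtx)
        names = ("delta", "intercept") if self.intercept else ("delta",)
        return DepletionResults(
            param_names=names,
            params=beta,
            bse=np.sqrt(np.diag(cov)),
            df_resid=df_resid,
            converged=True,
            model=self,
        )


@dataclass
class DepletionResults(_ResultsBase):
    model: DepletionRegression | None = None

    @property
    def delta(self) -> float:
        """Per-occupied-site depletion rate constant, s^-1."""
        return float(self.params[0])

    def predict(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        out = self.delta * rho
        if self.model is not None and self.model.intercept:
            out = out + self.params[1]
        return out

    def summary(self) -> str:
        return self._summary(
            "Depletion regression  kappa = delta * rho (through origin)",
            extra=[f"delta = {self.delta / 1e-6:.4g} x 1e-6 s^-1"],
        )


def fit_depletion(points: pd.DataFrame | DepletionRegression, intercept: bool = False) -> DepletionResults:
    """Through-origin regression of kappa on rho; accepts a points frame or model."""
    if isinstance(points, DepletionRegression):
        model = points
    else:
        model = DepletionRegression(
            points["rho"].to_numpy(),
            points["kappa_mean"].to_numpy(),
            points["kappa_sd"].to_numpy() if "kappa_sd" in points else None,
            intercept=intercept,
        )
    return model.fit()


# ---------------------------------------------------------------------------
# confocal calibration
# ---------------------------------------------------------------------------


class ConfocalDiffusionModel:
    """3D free-diffusion FCS model fitted to a confocal autocorrelation curve."""

    def __init__(self, lags: np.ndarray, g: np.ndarray, wxy: float = 0.2):
        self.lags = np.asarray(lags, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.wxy = float(wxy)
        if self.lags.size < 8:
            raise ValueError("need >= 8 lag points")
        if self.wxy <= 0:
            raise ValueError("wxy must be positive")

    def fit(self, s_fixed: float | None = None) -> "ConfocalResults":
        amp0 = float(self.g[0])
        n0 = 1.0 / max(amp0, 1e-12)
        half = np.nonzero(self.g < amp0 / 2)[0]
        tau0 = float(self.lags[half[0]]) if half.size else float(np.median(self.lags))

        if s_fixed is None:
            def model(tau, n, tau_d, s):
                return confocal_acf(tau, ConfocalModel(n, tau_d, s, wxy=self.wxy))

            p0, names = (n0, tau0, 5.0), ("n_particles", "tau_diff", "s")
            bounds = ([1e-12, 1e-12, 0.5], [np.inf, np.inf, 100.0])
        else:
            def model(tau, n, tau_d):
                return confocal_acf(tau, ConfocalModel(n, tau_d, s_fixed, wxy=self.wxy))

            p0, names = (n0, tau0), ("n_particles", "tau_diff")
            bounds = ([1e-12, 1e-12], [np.inf, np.inf])

        popt, pcov = optimize.curve_fit(model, self.lags, self.g, p0=p0, bounds=bounds, maxfev=40000)
        return ConfocalResults(
            param_names=names,
            params=popt,
            bse=np.sqrt(np.clip(np.diag(pcov), 0, np.inf)),
            df_resid=self.g.size - len(popt),
            converged=True,
            wxy=self.wxy,
            s_fixed=s_fixed,
        )


@dataclass
class ConfocalResults(_ResultsBase):
    wxy: float = 0.2
    s_fixed: float | None = None

    @property
    def n_particles(self) -> float:
        return float(self.params[0])

    @property
    def tau_diff(self) -> float:
        return float(self.params[1])

    @property
    def s(self) -> float:
        return float(self.params[2]) if self.s_fixed is None else float(self.s_fixed)

    @property
    def diffusion_coefficient(self) -> float:
        """D = wxy^2/(4 tau_diff), µm²/s."""
        return self.wxy**2 / (4.0 * self.tau_diff)

    def concentration(self) -> float:
        """Solution concentration from the amplitude, molar."""
        from .kinetics import concentration_from_amplitude

        return concentration_from_amplitude(
            ConfocalModel(self.n_particles, self.tau_diff, self.s, wxy=self.wxy)
        )

    def summary(self) -> str:
        return self._summary(
            "Confocal 3D diffusion fit",
            extra=[
                f"D = {self.diffusion_coefficient:.4g} µm²/s, "
                f"c = {to_nM(self.concentration()):.4g} nM"
            ],
        )
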