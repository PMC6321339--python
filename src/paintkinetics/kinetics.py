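"""Closed-form kinetics of reversible imager/docking-strand hybridization.

DNA-PAINT generates blinking by transient hybridization of a dye-labelled
imager strand (solution concentration ``<A>``) to a surface-attached docking
strand.  A single docking site is a two-state telegraph process: dark dwell
times are exponential with rate ``ka*<A>`` and bright dwell times exponential
with rate ``kd``.  Everything downstream — the SI-FCS autocorrelation decay,
the titration relation, the occupation probability and the effective
photo-depletion rate — follows from these two rate constants.  This module
collects those closed forms; they are pure functions consumed by the
simulator, the fitting models and the pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingRates",
    "DepletionKinetics",
    "DetrendParams",
    "BrightDarkTimes",
    "ConfocalModel",
    "characteristic_decay_time",
    "occupation_probability",
    "occupation_from_times",
    "effective_depletion_rate",
    "equilibrium_kd",
    "acf_model",
    "detrend_model",
    "confocal_acf",
    "concentration_from_amplitude",
    "diffusion_at_temperature",
    "water_viscosity",
]


@dataclass(frozen=True)
class BindingRates:
    """Association/dissociation rate constants of imager–docking hybridization.

    Parameters
    ----------
    ka : float
        Association rate constant, M^-1 s^-1.
    kd : float
        Dissociation rate constant, s^-1.
    """

    ka: float
    kd: float

    def __post_init__(self) -> None:
        if not (self.ka > 0 and np.isfinite(self.ka)):
            raise ValueError(f"ka must be positive and finite, got {self.ka}")
        if not (self.kd > 0 and np.isfinite(self.kd)):
            raise ValueError(f"kd must be positive and finite, got {self.kd}")

    @property
    def affinity(self) -> float:
        """Equilibrium dissociation constant Kd = kd/ka, in molar."""
        return self.kd / self.ka


@dataclass(frozen=True)
class DepletionKinetics:
    """Photo-induced depletion parameters of a docking-site population.

    ``delta`` is the depletion rate constant per *occupied* site (only the
    hybridized duplex is damaged); ``rho`` the equilibrium occupation
    probability.  The observable ensemble decay rate is ``kappa = delta*rho``.
    """

    delta: float
    rho: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")

    @property
    def kappa(self) -> float:
        return self.delta * self.rho


@dataclass(frozen=True)
class DetrendParams:
    """Parameters of the monoexponential intensity trend I(t) = I0 exp(-kappa t) + Iinf."""

    i0: float
    kappa: float
    i_inf: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.i_inf < 0:
            raise ValueError("i_inf must be >= 0")


@dataclass(frozen=True)
class BrightDarkTimes:
    """Observed bright-time (bound) and dark-time (unbound) durations, seconds."""

    bright: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bright", np.asarray(self.bright, dtype=float))
        object.__setattr__(self, "dark", np.asarray(self.dark, dtype=float))
        if np.any(self.bright <= 0) or np.any(self.dark <= 0):
            raise ValueError("all durations must be positive")

    @property
    def mean_bright(self) -> float:
        return float(np.mean(self.bright)) if self.bright.size else float("nan")

    @property
    def mean_dark(self) -> float:
        return float(np.mean(self.dark)) if self.dark.size else float("nan")


@dataclass(frozen=True)
class ConfocalModel:
    """Parameters of the 3D free-diffusion confocal FCS model.

    ``n_particles`` is the mean number of fluorophores in the detection
    volume, ``tau_diff`` the lateral diffusion time wxy^2/(4D), ``s`` the
    structure parameter (axial/lateral aspect ratio), ``wxy`` the lateral
    1/e^2 waist in micrometers.
    """

    n_particles: float
    tau_diff: float
    s: float
    wxy: float = 0.2
    temperature: float = 296.15

    def __post_init__(self) -> None:
        for name in ("n_particles", "tau_diff", "s", "wxy", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def diffusion_coefficient(self) -> float:
        """D = wxy^2 / (4 tau_diff), in µm²/s."""
        return self.wxy**2 / (4.0 * self.tau_diff)


# ---------------------------------------------------------------------------
# binding / titration closed forms
# ---------------------------------------------------------------------------


def characteristic_decay_time(rates: BindingRates, concentration: float) -> float:
    """SI-FCS autocorrelation decay time, tau_c = 1 / (ka*<A> + kd).

    The relaxation rate of a two-state telegraph site is the sum of the
    binding and unbinding rates, so tau_c decreases monotonically with the
    imager concentration (this is the titration relation).

    Parameters
    ----------
    rates : BindingRates
    concentration : float
        Imager concentration ``<A>`` in molar.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return 1.0 / (rates.ka * concentration + rates.kd)


def occupation_probability(rates: BindingRates, concentration) -> float:
    """Equilibrium probability that a docking site is occupied.

    rho = 1 / (1 + kd/(ka*<A>)); returns 0 at zero concentration (the
    continuous limit of the expression).  Accepts scalars or arrays.
    """
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    kon = rates.ka * conc
    out = np.where(kon > 0, kon / (kon + rates.kd), 0.0)
    return float(out) if np.isscalar(concentration) else out


def occupation_from_times(times: BrightDarkTimes) -> float:
    """Occupation probability from dwell times: mean(tauB)/(mean(tauB)+mean(tauD)).

    Equivalent to `occupation_probability` when tauB = 1/kd and
    tauD = 1/(ka*<A>).
    """
    if times.bright.size == 0 or times.dark.size == 0:
        raise ValueError("bright and dark sequences must be non-empty")
    tb, td = times.mean_bright, times.mean_dark
    return tb / (tb + td)


def effective_depletion_rate(kinetics: DepletionKinetics) -> float:
    """Ensemble-observable depletion rate kappa = delta * rho.

    Damage only accrues while a site is hybridized, so the per-site rate
    ``delta`` is diluted by the occupation probability.
    """
    return kinetics.kappa


def equilibrium_kd(rates: BindingRates) -> float:
    """Equilibrium dissociation constant Kd = kd/ka, molar."""
    return rates.affinity


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------


def acf_model(lag, tau_c: float, amplitude: float = 1.0, offset: float = 0.0):
    """Single-exponential SI-FCS autocorrelation, amplitude*exp(-lag/tau_c)+offset."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return amplitude * np.exp(-np.asarray(lag, dtype=float) / tau_c) + offset


def detrend_model(t, params: DetrendParams):
    """Monoexponential intensity trend I(t) = I0 exp(-kappa t) + Iinf."""
    return params.i0 * np.exp(-params.kappa * np.asarray(t, dtype=float)) + params.i_inf


def confocal_acf(lag, model: ConfocalModel):
    """3D free-diffusion confocal autocorrelation.

    G(tau) = N^-1 (1 + tau/tauD)^-1 (1 + tau/(S^2 tauD))^-1/2, amplitude 1/N.
    """
    tau = np.asarray(lag, dtype=float)
    x = tau / model.tau_diff
    return (1.0 / model.n_particles) / (1.0 + x) / np.sqrt(1.0 + x / model.s**2)


def concentration_from_amplitude(model: ConfocalModel) -> float:
    """Solution concentration from the FCS amplitude, in molar.

    c = N / (pi^(3/2) wxy^3 S) is a number density in molecules/µm³ for
    ``wxy`` in µm, converted to molar via 1 nM = 0.60221 molecules/µm³.
    """
    from .units import per_um3_to_molar

    density = model.n_particles / (np.pi**1.5 * model.wxy**3 * model.s)
    return per_um3_to_molar(density)


# ---------------------------------------------------------------------------
# temperature scaling of diffusion
# ---------------------------------------------------------------------------

#: Vogel–Fulcher–Tammann coefficients for liquid water viscosity,
#: eta(T) = _VFT_A * exp(_VFT_B / (T - _VFT_C)) in mPa·s, valid 273–373 K
#: (accurate to <1% over that range).
_VFT_A = 0.02939  # mPa s
_VFT_B = 507.88  # K
_VFT_C = 149.3  # K


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of liquid water in mPa·s (VFT correlation)."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t < 273.0) or np.any(t > 373.0):
        raise ValueError("temperature outside liquid-water range 273–373 K")
    out = _VFT_A * np.exp(_VFT_B / (t - _VFT_C))
    return float(out) if np.isscalar(temperature) else out


def diffusion_at_temperature(d_ref: float, t_ref: float, t: float) -> float:
    """Stokes–Einstein rescaling D(T) = D_ref * (T/T_ref) * eta(T_ref)/eta(T).

    Both temperatures in kelvin and restricted to the liquid-water range.
    Used to transfer a calibration-dye diffusion coefficient measured at one
    temperature to the measurement temperature.
    """
    eta_ref = water_viscosity(t_ref)
    eta_t = water_viscosity(t)
    return d_ref * (t / t_ref) * (eta_ref / eta_t)
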