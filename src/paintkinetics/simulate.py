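"""Stochastic simulation of DNA-PAINT binding with photo-induced depletion.

Each docking site is an independent continuous-time two-state process: dark
dwells are exponential with rate ``ka*<A>``, bright dwells exponential with
rate ``kd + bleach_rate`` (unbinding competes with bleaching of the bound
dye).  Photo-induced damage accrues only while the site is occupied, at rate
``delta`` per occupied second; the total occupied time a site survives is
therefore exponential with mean ``1/delta``, which is how depletion is drawn
here (an occupied-time budget, equivalent to a competing exponential channel
during every bright interval).  Bleaching ends the fluorescent event but
leaves the site intact; depletion terminates the site permanently.

Renderers turn event histories into the observables the analysis stages
consume: ROI-integrated intensity traces (SI-FCS input), localization tables
(DNA-PAINT input), and TIFF-writable image stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import BindingRates
from .units import nM

__all__ = [
    "SimulationConfig",
    "SiteEventList",
    "EnsembleRealization",
    "simulate_site",
    "simulate_ensemble",
    "render_roi_traces",
    "render_localization_table",
    "render_movie",
    "copasi_reference_preset",
    "occupancy_per_frame",
]

#: event end causes
UNBIND, BLEACH, DEPLETE, CENSORED = "unbind", "bleach", "deplete", "censored"
_CAUSE_CODES = {0: UNBIND, 1: BLEACH, 2: DEPLETE, 3: CENSORED}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Defaults mirror typical DNA-PAINT origami experiments: 12 docking sites
    per origami on a 3x4 grid with 20 nm pitch, conventional-imager rates,
    and camera discretization set via ``exposure``/``n_frames``.
    """

    rates: BindingRates = field(default_factory=lambda: BindingRates(ka=1.5e6, kd=0.3))
    concentration: float = nM(10)
    delta: float = 0.0
    bleach_rate: float = 0.0
    n_origami: int = 1
    sites_per_origami: int = 12
    incorporation_probability: float = 1.0
    exposure: float = 0.2
    n_frames: int = 5100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.delta < 0 or self.bleach_rate < 0:
            raise ValueError("rates and concentration must be >= 0")
        if self.n_origami < 1 or self.sites_per_origami < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.incorporation_probability <= 1.0:
            raise ValueError("incorporation_probability must lie in [0, 1]")
        if self.exposure <= 0 or self.n_frames < 1:
            raise ValueError("exposure must be > 0 and n_frames >= 1")

    @property
    def duration(self) -> float:
        """Total simulated wall-clock time, seconds."""
        return self.exposure * self.n_frames


@dataclass(frozen=True)
class SiteEventList:
    """Binding-event history of one docking site.

    ``starts``/``ends`` are event boundaries in seconds, ``causes`` the cause
    ending each event (unbind/bleach/deplete/censored; censored = the
    acquisition ended mid-event).  ``depleted_at`` is the damage instant, or
    None if the site survived.
    """

    site_id: int
    origami_id: int
    starts: np.ndarray
    ends: np.ndarray
    causes: tuple
    depleted_at: float | None = None

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.size:
            if np.any(ends < starts):
                raise ValueError("events must have end >= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("events must be non-overlapping and ordered")
        if self.depleted_at is not None:
            if not starts.size or self.causes[-1] != DEPLETE:
                raise ValueError("a depleted site must end with a deplete event")

    @property
    def n_events(self) -> int:
        return int(self.starts.size)

    @property
    def occupied_time(self) -> float:
        return float(np.sum(self.ends - self.starts))


@dataclass(frozen=True)
class EnsembleRealization:
    """A simulated field of origami: per-site event lists plus geometry.

    ``origami_xy`` holds per-origami pixel positions, ``site_offsets`` the
    3x4-grid offsets (20 nm pitch) of each designed site in pixels.
    """

    config: SimulationConfig
    sites: tuple
    origami_xy: np.ndarray
    site_offsets: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    """Counter-based substream: reproducible independent of iteration order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(site_index,)))


def simulate_site(
    config: SimulationConfig,
    rng: np.random.Generator,
    site_id: int = 0,
    origami_id: int = 0,
) -> SiteEventList:
    """Simulate one docking site over ``config.duration`` seconds.

    Dark dwells ~ Exp(ka*<A>); bright dwells ~ Exp(kd + bleach_rate) with the
    cause drawn proportionally to the two rates; the site's occupied-time
    budget to depletion ~ Exp(delta).  Dwells are drawn in growing batches so
    the whole history is vectorized.
    """
    kon = config.rates.ka * config.concentration
    t_max = config.duration
    empty = SiteEventList(site_id, origami_id, np.empty(0), np.empty(0), ())
    if kon == 0.0:
        return empty

    k_off = config.rates.kd + config.bleach_rate
    budget = rng.exponential(1.0 / config.delta) if config.delta > 0 else np.inf

    mean_cycle = 1.0 / kon + 1.0 / k_off
    n_guess = max(16, int(1.5 * t_max / mean_cycle) + 10)
    darks = np.empty(0)
    brights = np.empty(0)
    bleach_flags = np.empty(0, dtype=bool)
    while True:
        n_new = n_guess - darks.size
        darks = np.concatenate([darks, rng.exponential(1.0 / kon, n_new)])
        brights = np.concatenate([brights, rng.exponential(1.0 / k_off, n_new)])
        if config.bleach_rate > 0:
            bleach_flags = np.concatenate(
                [bleach_flags, rng.random(n_new) < config.bleach_rate / k_off]
            )
        else:
            bleach_flags = np.zeros(n_guess, dtype=bool)
        total_time = np.sum(darks) + np.sum(brights)
        if total_time >= t_max or np.sum(brights) >= budget:
            break
        n_guess *= 2

    starts = np.cumsum(darks) + np.concatenate([[0.0], np.cumsum(brights)[:-1]])
    ends = starts + brights
    causes = np.where(bleach_flags, 1, 0)

    # apply the occupied-time depletion budget
    depleted_at = None
    cum_bright = np.cumsum(brights)
    if np.isfinite(budget) and cum_bright[-1] >= budget:
        i = int(np.searchsorted(cum_bright, budget))
        prior = cum_bright[i - 1] if i > 0 else 0.0
        ends = ends[: i + 1].copy()
        starts = starts[: i + 1]
        causes = causes[: i + 1].copy()
        ends[i] = starts[i] + (budget - prior)
        causes[i] = 2
        depleted_at = float(ends[i])

    # clip to the acquisition window
    keep = starts < t_max
    starts, ends, causes = starts[keep], ends[keep], causes[keep]
    if starts.size == 0:
        return empty
    if ends[-1] > t_max:
        ends = ends.copy()
        ends[-1] = t_max
        causes = causes.copy()
        causes[-1] = 3
        depleted_at = None
    if depleted_at is not None and depleted_at > t_max:
        depleted_at = None

    return SiteEventList(
        site_id,
        origami_id,
        starts,
        ends,
        tuple(_CAUSE_CODES[c] for c in causes),
        depleted_at,
    )


def simulate_ensemble(config: SimulationConfig) -> EnsembleRealization:
    """Simulate all (incorporated) sites of ``config.n_origami`` origami.

    Site substreams are counter-based on the master seed, so the realization
    is bit-identical for a given config regardless of evaluation order.
    Incorporation is Bernoulli per designed site; missing sites are skipped
    entirely (no events, no geometry entry).
    """
    geom_rng = _site_rng(config.seed, 0xFFFF_FFFF)
    n_ori, n_per = config.n_origami, config.sites_per_origami
    # origami scattered on a loose grid; positions in pixels (130 nm pixels)
    grid = int(np.ceil(np.sqrt(n_ori)))
    gx, gy = np.meshgrid(np.arange(grid), np.arange(grid))
    origami_xy = np.stack([gx.ravel()[:n_ori], gy.ravel()[:n_ori]], axis=1) * 4.0 + 2.0
    origami_xy = origami_xy + geom_rng.uniform(-0.5, 0.5, size=origami_xy.shape)

    # 3x4 site grid with 20 nm pitch, in 130 nm pixels, centred on the origami
    pitch = 20.0 / 130.0
    sx, sy = np.meshgrid(np.arange(3) - 1.0, np.arange(4) - 1.5)
    full_offsets = np.stack([sx.ravel(), sy.ravel()], axis=1) * pitch

    incorporated = (
        geom_rng.random((n_ori, n_per)) < config.incorporation_probability
        if config.incorporation_probability < 1.0
        else np.ones((n_ori, n_per), dtype=bool)
    )

    sites = []
    site_offsets = []
    for ori in range(n_ori):
        for s in range(n_per):
            if not incorporated[ori, s]:
                continue
            idx = ori * n_per + s
            ev = simulate_site(config, _site_rng(config.seed, idx + 1), site_id=s, origami_id=ori)
            sites.append(ev)
            site_offsets.append(full_offsets[s % 12])
    return EnsembleRealization(
        config=config,
        sites=tuple(sites),
        origami_xy=origami_xy,
        site_offsets=np.asarray(site_offsets, dtype=float).reshape(len(sites), 2),
    )


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------


def _pooled_occupancy(starts: np.ndarray, ends: np.ndarray, n_frames: int, exposure: float) -> np.ndarray:
    """Summed fractional occupancy per frame for a pool of events.

    Exact: evaluates the integrated indicator C(t) = sum_e |[s_e,e_e) ∩ [0,t)|
    at all frame boundaries via sorted cumulative sums, then differences.
    O((n_events + n_frames) log n_events), independent of event lengths.
    """
    bounds = np.arange(n_frames + 1) * exposure
    occ = np.zeros(n_frames)
    if starts.size == 0:
        return occ

    def cum_min_sum(a: np.ndarray) -> np.ndarray:
        # sum_i min(a_i, t) for each boundary t
        a = np.sort(a)
        csum = np.concatenate([[0.0], np.cumsum(a)])
        idx = np.searchsorted(a, bounds, side="right")
        return csum[idx] + bounds * (a.size - idx)

    c = cum_min_sum(ends) - cum_min_sum(starts)
    return np.diff(c) / exposure


def occupancy_per_frame(site: SiteEventList, n_frames: int, exposure: float) -> np.ndarray:
    """Fractional occupancy of one site in each frame (exact overlap)."""
    return _pooled_occupancy(site.starts, site.ends, n_frames, exposure)


def render_roi_traces(
    realization: EnsembleRealization,
    n_rois: int = 1,
    brightness: float = 100.0,
    background: float = 10.0,
    noise: str = "none",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Integrated ROI intensity traces from an ensemble realization.

    Origami are assigned to ``n_rois`` ROIs round-robin; a frame's intensity
    is ``background + brightness * (summed fractional occupancy of the ROI's
    sites)``.  ``noise='poisson'`` applies shot noise to each frame value.

    Returns a DataFrame with a ``time_s`` column and one column per ROI
    (``roi_000`` ...); the exposure is stored in ``df.attrs['exposure']``.
    """
    cfg = realization.config
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    if noise == "poisson" and rng is None:
        rng = _site_rng(cfg.seed, 0xFFFF_FFFE)

    out = {}
    for roi in range(n_rois):
        members = [s for s in realization.sites if s.origami_id % n_rois == roi]
        starts = np.concatenate([s.starts for s in members]) if members else np.empty(0)
        ends = np.concatenate([s.ends for s in members]) if members else np.empty(0)
        occ = _pooled_occupancy(starts, ends, cfg.n_frames, cfg.exposure)
        trace = background + brightness * occ
        if noise == "poisson":
            trace = rng.poisson(trace).astype(float)
        out[f"roi_{roi:03d}"] = trace
    df = pd.DataFrame({"time_s": np.arange(cfg.n_frames) * cfg.exposure, **out})
    df.attrs["exposure"] = cfg.exposure
    return df


def render_localization_table(
    realization: EnsembleRealization,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Emit one localization row per (site, frame) with occupied fraction >= threshold.

    Mimics the picked-localization tables produced by SMLM software: columns
    frame (0-based), x, y (pixels), photons, group (origami id), site.
    ``df.attrs`` carries ``exposure`` and ``n_frames``.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must lie in (0, 1]")
    cfg = realization.config
    dt = cfg.exposure
    frames_out, groups, sites_out, xs, ys, photons = [], [], [], [], [], []
    for k, site in enumerate(realization.sites):
        if site.n_events == 0:
            continue
        f0 = np.floor(site.starts / dt).astype(int)
        f1 = np.minimum(np.ceil(site.ends / dt).astype(int) - 1, cfg.n_frames - 1)
        counts = f1 - f0 + 1
        ev_idx = np.repeat(np.arange(site.n_events), counts)
        frames = np.concatenate([np.arange(a, b + 1) for a, b in zip(f0, f1)])
        lo = np.maximum(site.starts[ev_idx], frames * dt)
        hi = np.minimum(site.ends[ev_idx], (frames + 1) * dt)
        frac = (hi - lo) / dt
        frames = frames[frac >= min_overlap_fraction]
        frac = frac[frac >= min_overlap_fraction]
        # duplicate frames (two events touching one frame) count once
        frames, uniq_idx = np.unique(frames, return_index=True)
        frac = frac[uniq_idx]
        if frames.size == 0:
            continue
        xy = realization.origami_xy[site.origami_id] + realization.site_offsets[k]
        frames_out.append(frames)
        groups.append(np.full(frames.size, site.origami_id))
        sites_out.append(np.full(frames.size, site.site_id))
        xs.append(np.full(frames.size, xy[0]))
        ys.append(np.full(frames.size, xy[1]))
        photons.append(1000.0 * frac)

    if frames_out:
        df = pd.DataFrame(
            {
                "frame": np.concatenate(frames_out).astype(np.int64),
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
                "photons": np.concatenate(photons),
                "group": np.concatenate(groups).astype(np.int64),
                "site": np.concatenate(sites_out).astype(np.int64),
            }
        )
        df = df.sort_values(["group", "site", "frame"], kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(
            {
                "frame": np.empty(0, np.int64),
                "x": np.empty(0),
                "y": np.empty(0),
                "photons": np.empty(0),
                "group": np.empty(0, np.int64),
                "site": np.empty(0, np.int64),
            }
        )
    df.attrs["exposure"] = cfg.exposure
    df.attrs["n_frames"] = cfg.n_frames
    df.attrs["n_origami"] = cfg.n_origami
    return df


def render_movie(
    realization: EnsembleRealization,
    frame_shape: tuple = (64, 64),
    psf_sigma: float = 1.0,
    brightness: float = 100.0,
    background: float = 10.0,
) -> np.ndarray:
    """Rasterize an ensemble into a uint16 image stack (frames, h, w).

    Each origami's per-frame intensity (brightness x summed site occupancy)
    is deposited as a normalized Gaussian kernel at its pixel position;
    counts are integer-quantized.  Raises if an origami lies outside the
    frame.
    """
    cfg = realization.config
    h, w = frame_shape
    if np.any(realization.origami_xy[:, 0] >= w) or np.any(realization.origami_xy[:, 1] >= h):
        raise ValueError("origami position outside frame")

    stack = np.full((cfg.n_frames, h, w), float(background))
    half = max(1, int(np.ceil(3 * psf_sigma)))
    for ori in range(cfg.n_origami):
        members = [s for s in realization.sites if s.origami_id == ori]
        if not members:
            continue
        starts = np.concatenate([s.starts for s in members])
        ends = np.concatenate([s.ends for s in members])
        occ = _pooled_occupancy(starts, ends, cfg.n_frames, cfg.exposure)
        if not np.any(occ):
            continue
        x, y = realization.origami_xy[ori]
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        kern = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2))
        kern /= kern.sum()
        stack[:, y0:y1, x0:x1] += brightness * occ[:, None, None] * kern[None, :, :]
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16)


def copasi_reference_preset(**overrides) -> SimulationConfig:
    """The mass-action simulation parameter set used for bright/dark-time studies.

    ka = 1.5e6 M^-1 s^-1, kd = 0.3 s^-1, <A> = 10 nM, 12 sites per origami,
    0.2 s frame interval, one 17-min (5100-frame) segment, no depletion or
    bleaching.  Keyword overrides replace individual fields.
    """
    cfg = SimulationConfig(
        rates=BindingRates(ka=1.5e6, kd=0.3),
        concentration=nM(10),
        delta=0.0,
        bleach_rate=0.0,
        n_origami=1,
        sites_per_origami=12,
        exposure=0.2,
        n_frames=5100,
        seed=0,
    )
    return replace(cfg, **overrides) if overrides else cfg
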