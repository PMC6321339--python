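"""ROI binning and multiple-tau autocorrelation for camera-based FCS.

Surface-integrated FCS (SI-FCS) correlates the integrated intensity of
camera ROIs instead of a confocal spot: software-bin the image stack,
detrend each ROI trace, and autocorrelate it on a quasi-logarithmic lag
grid.  The multiple-tau scheme keeps ``m`` lag points per octave and doubles
the averaging bin width after each block, so five decades of lag cost only
O(n log n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RoiTrace", "AcfCurve", "bin_stack", "multi_tau_acf", "traces_from_frame"]


@dataclass(frozen=True)
class RoiTrace:
    """Per-frame integrated intensity of one region of interest."""

    values: np.ndarray
    exposure: float
    roi_id: str = "roi"
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size < 2:
            raise ValueError("trace must have length >= 2")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.exposure


@dataclass(frozen=True)
class AcfCurve:
    """Autocorrelation estimate on a multiple-tau lag grid.

    ``lags`` in seconds (first lag equals the exposure), ``values`` the
    normalized fluctuation autocorrelation G(tau), ``m`` the points per
    octave of the lag grid.
    """

    lags: np.ndarray
    values: np.ndarray
    m: int = 16
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.size != values.size:
            raise ValueError("lags and values must have equal length")
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "g": self.values})


def traces_from_frame(df: pd.DataFrame, exposure: float | None = None) -> list[RoiTrace]:
    """Convert a wide trace table (``time_s`` + one column per ROI) to RoiTraces."""
    if exposure is None:
        exposure = df.attrs.get("exposure")
    if exposure is None:
        t = df["time_s"].to_numpy()
        exposure = float(t[1] - t[0])
    cols = [c for c in df.columns if c != "time_s"]
    return [RoiTrace(df[c].to_numpy(), exposure, roi_id=c) for c in cols]


def bin_stack(stack: np.ndarray, bin_factor: int, exposure: float = 0.01) -> list[RoiTrace]:
    """Software-bin an image stack into per-ROI integrated intensity traces.

    Each ``bin_factor x bin_factor`` pixel window is summed per frame; a
    64x64 stack with factor 8 yields 64 traces.  Trailing rows/columns that
    do not fill a window are cropped (a deterministic, explicit choice).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, h, w) array")
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    n, h, w = stack.shape
    hb, wb = h // bin_factor, w // bin_factor
    if hb == 0 or wb == 0:
        raise ValueError("bin_factor larger than frame")
    cropped = stack[:, : hb * bin_factor, : wb * bin_factor].astype(float)
    binned = cropped.reshape(n, hb, bin_factor, wb, bin_factor).sum(axis=(2, 4))
    out = []
    for i in range(hb):
        for j in range(wb):
            out.append(
                RoiTrace(
                    binned[:, i, j],
                    exposure,
                    roi_id=f"roi_{i:02d}_{j:02d}",
                    origin={"bin_factor": bin_factor, "window": (i, j)},
                )
            )
    return out


def _mt_lag_grid(n: int, m: int) -> list[tuple[int, int]]:
    """Multiple-tau lag plan: (lag index in base units, octave level).

    Block 0 holds lags 1..m at base spacing; each later block holds m lags
    with doubled spacing, continuing from the previous block's largest lag.
    Lags are kept while they do not exceed a quarter of the trace length.
    """
    plan = []
    start, spacing, level = 0, 1, 0
    limit = n // 4
    while True:
        block = [start + j * spacing for j in range(1, m + 1) if start + j * spacing <= limit]
        if not block:
            break
        plan.extend((lag, level) for lag in block)
        if len(block) < m:
            break
        start += m * spacing
        spacing *= 2
        level += 1
        # align the next block on the doubled bin width so every lag is an
        # integer number of binned samples
        start = -(-start // spacing) * spacing
    return plan


def multi_tau_acf(trace: RoiTrace, m: int = 16) -> AcfCurve:
    """Normalized fluctuation autocorrelation on a multiple-tau lag grid.

    G(tau) = <I(t) I(t+tau)> / (<I(t)> <I(t+tau)>) - 1, with the two means
    taken over the same overlap window as the product (symmetric
    normalization; robust against residual slow trends).  At octave level L
    the trace is block-averaged by 2^L and the same estimator applied, so
    base-resolution lags coincide exactly with the direct estimator on the
    unbinned trace.
    """
    x = trace.values
    n = x.size
    if n < 4 * m:
        raise ValueError(f"trace length {n} < 4*m = {4 * m}")
    if np.mean(x) == 0:
        raise ValueError("zero-mean trace: normalization undefined")

    plan = _mt_lag_grid(n, m)
    binned = {0: x}
    lags, values = [], []
    for lag, level in plan:
        if level not in binned:
            prev = binned[level - 1]
            nb = prev.size // 2
            binned[level] = prev[: 2 * nb].reshape(nb, 2).mean(axis=1)
        b = binned[level]
        k = lag >> level  # lag in units of the binned sampling interval
        if k >= b.size:
            continue
        left, right = b[: b.size - k], b[k:]
        denom = left.mean() * right.mean()
        if denom == 0:
            continue
        lags.append(lag * trace.exposure)
        values.append(float(np.mean(left * right) / denom - 1.0))
    return AcfCurve(np.asarray(lags), np.asarray(values), m=m, roi_id=trace.roi_id)
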