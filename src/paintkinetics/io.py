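"""File formats, run configuration and provenance.

Localization tables follow the picked-localization convention of SMLM
software: an HDF5 dataset named ``locs`` with fields frame (0-based
integer), x, y (pixels), photons, group (origami id) and site (docking-site
id, -1 = unassigned), or a CSV file with identical column headers.  ROI
traces and ACF curves are plain CSV with units in the headers.  Run
configuration is YAML validated against the dataclass fields (unknown keys
rejected), and every result bundle carries the config hash, seed and
package version.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .kinetics import BindingRates
from .simulate import SimulationConfig
from .units import nM

__all__ = [
    "LOC_COLUMNS",
    "read_localizations",
    "write_localizations",
    "write_roi_traces",
    "read_roi_traces",
    "write_acf",
    "write_movie",
    "read_movie",
    "RunConfig",
    "load_config",
    "ResultBundle",
    "write_results",
]

LOC_COLUMNS = ("frame", "x", "y", "photons", "group", "site")
_LOC_DTYPE = np.dtype(
    [("frame", "u4"), ("x", "f4"), ("y", "f4"), ("photons", "f4"), ("group", "i4"), ("site", "i4")]
)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table to HDF5 (``locs`` dataset) or CSV by extension."""
    path = Path(path)
    missing = [c for c in LOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if path.suffix in (".h5", ".hdf5"):
        rec = np.empty(len(table), dtype=_LOC_DTYPE)
        for name in LOC_COLUMNS:
            rec[name] = table[name].to_numpy()
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("locs", data=rec)
            for key in ("exposure", "n_frames", "n_origami"):
                if key in table.attrs:
                    ds.attrs[key] = table.attrs[key]
    else:
        table.loc[:, list(LOC_COLUMNS)].to_csv(path, index=False)


def read_localizations(
    path: str | Path,
    exposure: float | None = None,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Read a localization table from HDF5 or CSV.

    Frames are validated (0-based, < n_frames when declared) and rows are
    re-sorted by frame within each (group, site).  For CSV, ``exposure``
    and ``n_frames`` must be supplied by the caller when needed downstream;
    HDF5 carries them as dataset attributes.
    """
    path = Path(path)
    attrs: dict = {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise ValueError("missing 'locs' dataset")
            ds = f["locs"]
            rec = ds[()]
            attrs = {k: ds.attrs[k] for k in ds.attrs}
        df = pd.DataFrame({name: rec[name] for name in rec.dtype.names})
    else:
        df = pd.read_csv(path)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df.astype({"frame": np.int64, "group": np.int64, "site": np.int64})
    if exposure is not None:
        attrs["exposure"] = exposure
    if n_frames is not None:
        attrs["n_frames"] = n_frames
    if np.any(df["frame"] < 0):
        raise ValueError("negative frame index")
    if "n_frames" in attrs and np.any(df["frame"] >= int(attrs["n_frames"])):
        raise ValueError("frame index >= declared n_frames")
    df = df.sort_values(["group", "site", "frame"], kind="stable").reset_index(drop=True)
    for k, v in attrs.items():
        df.attrs[k] = float(v) if k == "exposure" else int(v) if k in ("n_frames", "n_origami") else v
    return df


def write_roi_traces(df: pd.DataFrame, path: str | Path) -> None:
    """Write a wide ROI trace table (time_s + roi_* columns) to CSV."""
    df.to_csv(path, index=False)


def read_roi_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("missing 'time_s' column")
    t = df["time_s"].to_numpy()
    if t.size >= 2:
        df.attrs["exposure"] = float(t[1] - t[0])
    return df


def write_acf(curves, path: str | Path) -> None:
    """Write ACF curves to CSV: lag_s plus one g column per ROI."""
    curves = list(curves)
    out = pd.DataFrame({"lag_s": curves[0].lags})
    for c in curves:
        out[f"g_{c.roi_id}"] = c.values
    out.to_csv(path, index=False)


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    """Write a uint16 grayscale stack as an uncompressed multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_movie(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated YAML run configuration (unknown keys rejected).

    ``simulation`` holds SimulationConfig fields with concentrations in nM
    at this boundary; ``analysis`` the stage parameters; ``io`` paths.
    """

    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    seed: int = 1
    log_level: str = "INFO"

    _SIM_KEYS = {
        "ka_per_M_s",
        "kd_per_s",
        "concentration_nM",
        "delta_per_s",
        "bleach_rate_per_s",
        "n_origami",
        "sites_per_origami",
        "incorporation_probability",
        "exposure_s",
        "n_frames",
    }
    _ANALYSIS_KEYS = {
        "bin_factor",
        "m",
        "frames_per_subset",
        "threshold",
        "bi_exp_above_nM",
        "n_rois",
        "min_overlap_fraction",
        "brightness",
        "background",
        "noise",
    }
    _IO_KEYS = {"out_dir", "movie_path", "locs_path", "traces_path"}

    def __post_init__(self) -> None:
        for block, allowed in (
            (self.simulation, self._SIM_KEYS),
            (self.analysis, self._ANALYSIS_KEYS),
            (self.io, self._IO_KEYS),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            rates=BindingRates(
                ka=float(s.get("ka_per_M_s", 1.5e6)), kd=float(s.get("kd_per_s", 0.3))
            ),
            concentration=nM(float(s.get("concentration_nM", 10.0))),
            delta=float(s.get("delta_per_s", 0.0)),
            bleach_rate=float(s.get("bleach_rate_per_s", 0.0)),
            n_origami=int(s.get("n_origami", 1)),
            sites_per_origami=int(s.get("sites_per_origami", 12)),
            incorporation_probability=float(s.get("incorporation_probability", 1.0)),
            exposure=float(s.get("exposure_s", 0.2)),
            n_frames=int(s.get("n_frames", 5100)),
            seed=int(self.seed if seed is None else seed),
        )

    def digest(self) -> str:
        canon = json.dumps(
            {"simulation": self.simulation, "analysis": self.analysis, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    allowed_top = {"simulation", "analysis", "io", "seed", "log_level"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# results + provenance
# ---------------------------------------------------------------------------


@dataclass
class ResultBundle:
    """Stage outputs plus provenance (config hash, seed, version, timestamp)."""

    results: dict
    config: RunConfig | None = None
    seed: int | None = None

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config_hash": self.config.digest() if self.config else None,
            "seed": self.seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }


def write_results(bundle: ResultBundle, path: str | Path, force: bool = False) -> None:
    """Write a result bundle as JSON with a provenance sidecar.

    Refuses to overwrite an existing file unless ``force``.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(bundle.results, f, indent=2, default=float)
    side = path.with_suffix(path.suffix + ".provenance.json")
    with open(side, "w") as f:
        json.dump(bundle.provenance(), f, indent=2)
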