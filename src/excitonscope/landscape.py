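"""Site-energy landscape statistics.

Per-pigment Q_y excitation-energy trajectories are summarized by their mean
and sample standard deviation; the pooled distribution (density of states)
is a histogram on a fixed bin width, smoothed with a natural cubic spline
and normalized to unit integral.  Environment-on/off shift analysis compares
excitation energies with and without the protein point-charge environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .constants import DEFAULT_BIN_WIDTH_EV


@dataclass(frozen=True)
class SiteEnergyTrajectory:
    """Per-frame Q_y (S1) site energies of one pigment, in eV."""

    pigment_id: str
    energies: np.ndarray
    frame_stride_ps: float = 10.0  # metadata only

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("energies must be a non-empty 1-D sequence")
        if not (np.isfinite(e).all() and (e > 0).all()):
            raise ValueError(f"energies for {self.pigment_id!r} must be finite and > 0")
        object.__setattr__(self, "energies", e)

    def __len__(self) -> int:
        return self.energies.size


@dataclass(frozen=True)
class DensityOfStates:
    """Smoothed site-energy distribution on an energy grid (eV)."""

    energy: np.ndarray
    density: np.ndarray
    bin_width: float
    normalized: bool = True

    @property
    def mode(self) -> float:
        return float(self.energy[np.argmax(self.density)])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.energy))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"energy_eV": self.energy, "density": self.density}).to_csv(
            path, index=False
        )


def summarize(traj: SiteEnergyTrajectory) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a trajectory, in eV."""
    e = traj.energies
    if e.size < 2:
        raise ValueError("standard deviation undefined for fewer than 2 frames")
    return float(e.mean()), float(e.std(ddof=1))


def density_of_states(
    trajs: Iterable[SiteEnergyTrajectory] | SiteEnergyTrajectory,
    bin_width: float = DEFAULT_BIN_WIDTH_EV,
    smooth: bool = True,
    refine: int = 10,
) -> DensityOfStates:
    """Pooled, spline-smoothed, unit-normalized density of states.

    The pooled samples are histogrammed on bins of ``bin_width`` spanning
    [min, max]; a natural cubic spline through the bin centres is evaluated
    on a ``refine``-times finer grid, clipped at zero and renormalized.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(trajs, SiteEnergyTrajectory):
        trajs = [trajs]
    samples = np.concatenate([t.energies for t in trajs])
    if samples.size < 10:
        raise ValueError("need at least 10 pooled samples for a density of states")

    lo, hi = samples.min(), samples.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (samples.size * bin_width)

    if smooth and centers.size >= 4:
        grid = np.linspace(centers[0], centers[-1], centers.size * refine)
        vals = CubicSpline(centers, dens, bc_type="natural")(grid)
        vals = np.clip(vals, 0.0, None)
    else:
        grid, vals = centers, dens

    norm = np.trapezoid(vals, grid)
    if norm > 0:
        vals = vals / norm
    return DensityOfStates(grid, vals, bin_width)


def environmental_shift(e_env: float, e_gas: float) -> float:
    """Environment-induced site-energy shift e_env - e_gas, reported to 3 decimals."""
    if not (np.isfinite(e_env) and np.isfinite(e_gas)):
        raise ValueError("energies must be finite")
    return round(e_env - e_gas, 3)


def classify_shift(shift: float) -> str:
    """Sign convention: positive = blue shift, negative = red shift."""
    if shift > 0:
        return "blue"
    if shift < 0:
        return "red"
    return "neutral"


def shift_table(records: Sequence[tuple[str, float, float]]) -> pd.DataFrame:
    """Shift table for (pigment_id, e_env, e_gas) records.

    Returns one row per pigment with the 3-decimal shift and its sign
    classification (blue / red / neutral).
    """
    if len(records) < 1:
        raise ValueError("at least one record required")
    rows = []
    for pid, e_env, e_gas in records:
        s = environmental_shift(e_env, e_gas)
        rows.append(
            {"pigment_id": pid, "e_env_eV": e_env, "e_gas_eV": e_gas,
             "shift_eV": s, "classification": classify_shift(s)}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# trajectory I/O: long-format CSV or HDF5 with columns (frame, pigment_id, energy_eV)


def load_trajectories(path: str | Path, frame_stride_ps: float = 10.0) -> list[SiteEnergyTrajectory]:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        import h5py

        out = []
        with h5py.File(path, "r") as fh:
            for pid in fh:
                out.append(
                    SiteEnergyTrajectory(str(pid), np.asarray(fh[pid][...], float),
                                         frame_stride_ps)
                )
        return out
    df = pd.read_csv(path)
    return [
        SiteEnergyTrajectory(str(pid), grp.sort_values("frame")["energy_eV"].to_numpy(float),
                             frame_stride_ps)
        for pid, grp in df.groupby("pigment_id", sort=False)
    ]


def save_trajectories(path: str | Path, trajs: Sequence[SiteEnergyTrajectory]) -> None:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            for t in trajs:
                fh.create_dataset(t.pigment_id, data=t.energies)
        return
    frames = [
        pd.DataFrame({"frame": np.arange(len(t)), "pigment_id": t.pigment_id,
                      "energy_eV": t.energies})
        for t in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
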