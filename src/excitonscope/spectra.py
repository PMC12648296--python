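"""Absorption spectra from a second-order cumulant lineshape.

The linear absorption of the exciton manifold is computed from the exciton
energies and transition dipoles together with a bath spectral density J(ω).
Each exciton k carries a lineshape function

    g_k(t) = p_k * g(t),        p_k = Σ_m c_mk^4   (participation ratio),

where g(t) is the standard second-order cumulant built from J with the
detailed-balance thermal factor (site fluctuations assumed uncorrelated and
diagonal; off-diagonal fluctuations are neglected):

    g(t) = (1/π) ∫_0^∞ dω J(ω)/ω² [ coth(ω/2k_BT)(1-cos ωt) + i(sin ωt - ωt) ]

(ħ = 1; ω, k_BT and J all as angular frequencies).  The spectrum is the
half-Fourier transform

    I(ω) = (1/π) Σ_k |μ_k|² Re ∫_0^∞ dt e^{i(ω-ω_k)t - g_k(t)} dt,

so the integrated intensity obeys the dipole-strength sum rule Σ_k |μ_k|².
No static disorder is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, EV_TO_CM, KB_CM, TWO_PI_C
from .hamiltonian import ExcitonStates


@dataclass(frozen=True)
class SpectralDensity:
    """Bath spectral density on an ascending non-negative grid (cm^-1)."""

    freq_cm: np.ndarray
    values: np.ndarray  # same energy units as freq_cm

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_cm, dtype=float)
        j = np.asarray(self.values, dtype=float)
        if f.ndim != 1 or f.shape != j.shape:
            raise ValueError("frequency grid and J values must be matching 1-D arrays")
        if (f < 0).any() or (np.diff(f) <= 0).any():
            raise ValueError("frequency grid must be non-negative and strictly ascending")
        if not np.isfinite(j).all() or (j < 0).any():
            raise ValueError("spectral density must be finite and non-negative")
        object.__setattr__(self, "freq_cm", f)
        object.__setattr__(self, "values", j)

    def reorganization_energy(self) -> float:
        """λ = (1/π) ∫ J(ω)/ω dω, in cm^-1."""
        mask = self.freq_cm > 0
        return float(
            np.trapezoid(self.values[mask] / self.freq_cm[mask], self.freq_cm[mask]) / np.pi
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDensity":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_cm-1": self.freq_cm, "J_cm-1": self.values}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Intensity (arbitrary units) on a wavenumber grid (cm^-1)."""

    freq_cm: np.ndarray
    intensity: np.ndarray
    applied_shift_cm: float = 0.0

    @property
    def peak_cm(self) -> float:
        if np.ptp(self.intensity) == 0:
            raise ValueError("flat spectrum has no peak")
        return float(self.freq_cm[np.argmax(self.intensity)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_cm-1": self.freq_cm, "intensity": self.intensity}).to_csv(
            path, index=False
        )


def lineshape_g(
    J: SpectralDensity, temperature_k: float, t_ps: np.ndarray
) -> np.ndarray:
    """Second-order cumulant lineshape g(t) on a uniform time grid (ps).

    Satisfies g(0) = 0 and dg/dt(0) = 0 for any J.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    t = np.asarray(t_ps, dtype=float)
    if t.size > 2 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-8):
        raise ValueError("time grid must be uniform")

    mask = J.freq_cm > 0
    w = J.freq_cm[mask] * TWO_PI_C        # rad/ps
    jw = J.values[mask] * TWO_PI_C        # rad/ps (energy in hbar=1 units)
    if w.size == 0:
        return np.zeros(t.shape, dtype=complex)
    kt = KB_CM * temperature_k * TWO_PI_C
    coth = 1.0 / np.tanh(w / (2.0 * kt))

    wt = np.outer(t, w)  # (n_t, n_w)
    re = (jw / w**2 * coth) * (1.0 - np.cos(wt))
    im = (jw / w**2) * (np.sin(wt) - wt)
    return (np.trapezoid(re, w, axis=1) + 1j * np.trapezoid(im, w, axis=1)) / np.pi


def absorption_spectrum(
    states: ExcitonStates,
    J: SpectralDensity | None,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    freq_cm: np.ndarray | None = None,
    t_max_ps: float = 2.0,
    n_t: int = 4096,
    damping_floor: float = 1e-8,
) -> AbsorptionSpectrum:
    """Linear absorption of the exciton manifold (see module docstring).

    A mild exponential damping is applied so the time integrand has decayed
    to ``damping_floor`` at ``t_max_ps``; with J = None (or zero) each
    exciton therefore appears as a narrow line at its eigenvalue.
    Numerically negative intensities from the truncated half-Fourier
    transform are clipped to zero.
    """
    if states.eigenvalues.size == 0:
        raise ValueError("empty exciton state list")
    w_k = states.eigenvalues * EV_TO_CM * TWO_PI_C  # rad/ps
    strengths = states.dipole_strengths

    if freq_cm is None:
        margin = 1500.0
        lo = states.eigenvalues.min() * EV_TO_CM - margin
        hi = states.eigenvalues.max() * EV_TO_CM + margin
        freq_cm = np.linspace(lo, hi, 4000)
    w_grid = np.asarray(freq_cm, float) * TWO_PI_C

    t = np.linspace(0.0, t_max_ps, n_t)
    eta = -np.log(damping_floor) / t_max_ps
    if J is None:
        g = np.zeros(n_t, dtype=complex)
    else:
        g = lineshape_g(J, temperature_k, t)

    # participation ratios scale the common g(t) per exciton
    p = np.sum(states.eigenvectors**4, axis=0)

    # dipole-weighted time-domain response summed over excitons, then one
    # half-Fourier transform to the frequency grid
    resp = np.exp(
        -1j * np.outer(w_k, t) - np.outer(p, np.ones_like(t)) * g - eta * t
    )
    total = (strengths @ resp) * _trap_weights(t)
    intensity = np.real(np.exp(1j * np.outer(w_grid, t)) @ total)
    intensity = np.clip(intensity / np.pi, 0.0, None)
    return AbsorptionSpectrum(np.asarray(freq_cm, float), intensity)


def _trap_weights(t: np.ndarray) -> np.ndarray:
    dt = t[1] - t[0]
    w = np.full(t.size, dt)
    w[0] = w[-1] = 0.5 * dt
    return w


def align_to_experiment(
    spec: AbsorptionSpectrum, exp_peak_nm: float
) -> tuple[AbsorptionSpectrum, float]:
    """Rigidly shift the spectrum so its maximum lands on the experimental peak.

    shift (cm^-1) = 10^7 / exp_peak_nm - computed_peak; the full grid is
    translated by the shift.  Returns (shifted spectrum, shift).
    """
    peak = spec.peak_cm  # raises on flat input
    shift = 1.0e7 / exp_peak_nm - peak
    return (
        AbsorptionSpectrum(spec.freq_cm + shift, spec.intensity, spec.applied_shift_cm + shift),
        shift,
    )
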