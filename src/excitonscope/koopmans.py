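"""Koopmans-condition diagnostics for range-separated functional tuning.

The range-separation parameter ω of a long-range corrected functional is
optimally tuned when the HOMO eigenvalue matches the negative vertical
ionization potential (and optionally the LUMO the negative electron
affinity), computed from total-energy differences of the n-, (n-1)- and
(n+1)-electron species:

    IP(n) = E(n-1) - E(n),   EA(n) = E(n) - E(n+1)

    J(ω) = |ε_HOMO + IP|  [+ |ε_LUMO + EA|]

The default objective uses the IP term only; ties are broken toward the
smaller ω.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class TuningRecord:
    """One ω point of a tuning scan for one species (all energies in eV)."""

    omega: float                       # a0^-1
    eps_homo: float
    eps_lumo: float | None = None
    ip: float | None = None            # may be given directly ...
    ea: float | None = None
    e_n: float | None = None           # ... or derived from total energies
    e_n_minus_1: float | None = None
    e_n_plus_1: float | None = None
    species: str = ""

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        for v in (self.eps_homo, self.eps_lumo, self.ip, self.ea,
                  self.e_n, self.e_n_minus_1, self.e_n_plus_1):
            if v is not None and not math.isfinite(v):
                raise ValueError("energies must be finite")

    def get_ip(self) -> float:
        if self.ip is not None:
            return self.ip
        if self.e_n is not None and self.e_n_minus_1 is not None:
            return ionization_potential(self.e_n_minus_1, self.e_n)
        raise ValueError(f"record (omega={self.omega}) lacks IP information")

    def get_ea(self) -> float:
        if self.ea is not None:
            return self.ea
        if self.e_n is not None and self.e_n_plus_1 is not None:
            return electron_affinity(self.e_n, self.e_n_plus_1)
        raise ValueError(f"record (omega={self.omega}) lacks EA information")


def ionization_potential(e_n_minus_1: float, e_n: float) -> float:
    """IP(n) = E(n-1) - E(n), in eV."""
    return e_n_minus_1 - e_n


def electron_affinity(e_n: float, e_n_plus_1: float) -> float:
    """EA(n) = E(n) - E(n+1), in eV."""
    return e_n - e_n_plus_1


def koopmans_objective(rec: TuningRecord, include_ea: bool = False) -> float:
    """J(ω) = |ε_HOMO + IP| (+ |ε_LUMO + EA| when include_ea), in eV."""
    j = abs(rec.eps_homo + rec.get_ip())
    if include_ea:
        if rec.eps_lumo is None:
            raise ValueError("record lacks eps_lumo for the EA term")
        j += abs(rec.eps_lumo + rec.get_ea())
    return j


def select_omega(records: Sequence[TuningRecord], include_ea: bool = False) -> float:
    """The ω minimizing the Koopmans objective; ties go to the smaller ω."""
    if len(records) == 0:
        raise ValueError("empty tuning-record list")
    if len(records) < 2:
        raise ValueError("need at least 2 records to select an omega")
    best = min(records, key=lambda r: (koopmans_objective(r, include_ea), r.omega))
    return best.omega


def load_scan(path: str | Path) -> list[TuningRecord]:
    """Read a scan CSV with columns (omega, eps_homo, eps_lumo, ip, ea[, species])."""
    df = pd.read_csv(path)

    def opt(row, col):
        return None if col not in row or pd.isna(row[col]) else float(row[col])

    return [
        TuningRecord(
            omega=float(row["omega"]), eps_homo=float(row["eps_homo"]),
            eps_lumo=opt(row, "eps_lumo"), ip=opt(row, "ip"), ea=opt(row, "ea"),
            species=str(row.get("species", "")),
        )
        for _, row in df.iterrows()
    ]
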