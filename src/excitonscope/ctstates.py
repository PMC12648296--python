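"""Charge-transfer state identification and directionality analysis.

Excited states of pigment pairs/clusters are classified from natural
transition orbital (NTO) descriptors into pure charge-transfer (CT),
mixed CT/excitonic, mixed excitation (ME) and locally excited (LE) states.
A pure CT state is dominated by a single hole-particle pair (weight
n >= 0.94) on different fragments and is optically dark (f <= 0.01).

Density-difference grids Δρ = ρ_excited - ρ_ground resolve the hole and
electron spatially: Δρ > 0 marks electron gain, Δρ < 0 hole formation.
Integrating Δρ over nearest-atom (Voronoi) fragment regions yields the
per-fragment electron gain Δq in e, so a full one-electron transfer from
donor D to acceptor A gives Δq_D = -1, Δq_A = +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import CT_NTO_MIN, CT_OSC_MAX, MIXED_NTO_MIN
from .cube import DensityGrid

CLASSES = ("pure_CT", "mixed", "ME", "LE", "unassigned")


def _as_fragset(frag) -> frozenset[str]:
    """Normalize a fragment label: 'A', 'A/B', 'A+B' or an iterable of labels."""
    if isinstance(frag, frozenset):
        return frag
    if isinstance(frag, str):
        for sep in ("/", "+"):
            if sep in frag:
                return frozenset(p.strip() for p in frag.split(sep))
        return frozenset([frag.strip()])
    return frozenset(str(f) for f in frag)


@dataclass(frozen=True)
class NTOComponent:
    """One hole-particle pair: weight n and the fragments the orbitals live on."""

    weight: float
    hole: frozenset[str]
    particle: frozenset[str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("NTO weight must lie in [0, 1]")
        object.__setattr__(self, "hole", _as_fragset(self.hole))
        object.__setattr__(self, "particle", _as_fragset(self.particle))


@dataclass
class ExcitedStateRecord:
    """One excited state of a snapshot: energy, oscillator strength, NTOs."""

    snapshot_id: str
    energy_ev: float
    osc_strength: float
    nto_components: list[NTOComponent]
    state_index: int | None = None  # 1-based (S1..S10); None when not printed
    assigned_class: str = "unassigned"
    ct_direction: str | None = None  # "D->A" for pure CT

    def __post_init__(self) -> None:
        if self.osc_strength < 0:
            raise ValueError("oscillator strength must be >= 0")
        if self.state_index is not None and self.state_index < 1:
            raise ValueError("state_index is 1-based")

    @property
    def dominant(self) -> NTOComponent:
        if not self.nto_components:
            raise ValueError("record has no NTO components")
        return max(self.nto_components, key=lambda c: c.weight)


def classify_state(
    rec: ExcitedStateRecord,
    ct_nto_min: float = CT_NTO_MIN,
    ct_osc_max: float = CT_OSC_MAX,
    mixed_nto_min: float = MIXED_NTO_MIN,
) -> str:
    """Assign exactly one class to a state (deterministic and total).

    Precedence pure_CT > mixed > ME > LE:

    * dominant NTO has single-fragment hole and particle on *different*
      fragments (CT character): ``pure_CT`` if n >= ct_nto_min and
      f <= ct_osc_max, else ``mixed`` (CT/excitonic);
    * dominant NTO delocalized over >= 2 fragments: ``ME``;
    * otherwise (hole and particle coincide on one fragment per component,
      possibly different fragments across components): ``LE``.

    The classification is written back onto the record (and a CT direction
    label "D->A" for pure CT) and returned.
    """
    dom = rec.dominant  # raises on empty NTO list
    span = dom.hole | dom.particle
    if len(dom.hole) == 1 and len(dom.particle) == 1 and dom.hole != dom.particle:
        if dom.weight >= ct_nto_min and rec.osc_strength <= ct_osc_max:
            cls = "pure_CT"
            rec.ct_direction = f"{next(iter(dom.hole))}->{next(iter(dom.particle))}"
        elif dom.weight > mixed_nto_min and rec.osc_strength > ct_osc_max:
            cls = "mixed"
        else:
            cls = "mixed"
    elif len(span) >= 2:
        cls = "ME"
    else:
        cls = "LE"
    rec.assigned_class = cls
    return cls


def classify_table(records: Iterable[ExcitedStateRecord], **thresholds) -> list[str]:
    return [classify_state(r, **thresholds) for r in records]


# --------------------------------------------------------------------------
# density grids


def density_difference(rho_exc: DensityGrid, rho_gnd: DensityGrid) -> DensityGrid:
    """Δρ = ρ_excited − ρ_ground, voxelwise, on identical grid geometry."""
    if not rho_exc.same_geometry(rho_gnd):
        raise ValueError("grids differ in shape, origin or voxel vectors")
    return DensityGrid(
        rho_exc.origin, rho_exc.axes, rho_exc.values - rho_gnd.values,
        rho_exc.atom_numbers, rho_exc.atom_coords,
    )


def density_difference_from_orbitals(
    occupied: Sequence[DensityGrid],
    virtual: Sequence[DensityGrid],
    coefficients: Sequence[float],
) -> DensityGrid:
    """Orbital-based approximation Δρ ≈ Σ_ia c_ia (|ψ_a|² − |ψ_i|²)."""
    if len(coefficients) == 0:
        raise ValueError("no coefficient entries")
    if not (len(occupied) == len(virtual) == len(coefficients)):
        raise ValueError("occupied, virtual and coefficient lists must align")
    ref = occupied[0]
    total = np.zeros(ref.shape)
    for psi_i, psi_a, c in zip(occupied, virtual, coefficients):
        if not (psi_i.same_geometry(ref) and psi_a.same_geometry(ref)):
            raise ValueError("all orbitals must share one grid geometry")
        if not np.isfinite(c):
            raise ValueError("coefficients must be finite")
        total += c * (psi_a.values**2 - psi_i.values**2)
    return DensityGrid(ref.origin, ref.axes, total, ref.atom_numbers, ref.atom_coords)


@dataclass(frozen=True)
class FragmentPartition:
    """Atom -> fragment map; voxels are assigned to the nearest atom (Voronoi).

    ``atom_fragments`` aligns with the grid's atom list; distance ties go to
    the lower fragment id (guaranteed by stable nearest-neighbour ordering).
    """

    atom_fragments: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.atom_fragments)) < 2:
            raise ValueError("CT analysis needs at least 2 fragments")

    @property
    def fragments(self) -> list[str]:
        return sorted(set(self.atom_fragments))


def fragment_charges(delta: DensityGrid, part: FragmentPartition) -> dict[str, float]:
    """Per-fragment electron gain Δq_F = Σ_{voxels→F} Δρ · dV, in e.

    The fragment sums partition the total grid integral exactly: every voxel
    is assigned to exactly one fragment via its nearest atom.
    """
    if delta.atom_coords is None or len(delta.atom_numbers) == 0:
        raise ValueError("grid carries no atoms to partition against")
    if len(part.atom_fragments) != len(delta.atom_numbers):
        raise ValueError("partition does not cover the grid's atom list")
    centers = delta.voxel_centers()
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    inside = ((delta.atom_coords >= lo - 1e-9) & (delta.atom_coords <= hi + 1e-9)).all(axis=1)
    if not inside.any():
        raise ValueError("grid does not cover any fragment atom")
    _, nearest = cKDTree(delta.atom_coords).query(centers)
    frag_ids = np.array([part.fragments.index(f) for f in part.atom_fragments])
    voxel_frag = frag_ids[nearest]
    dv = delta.voxel_volume
    flat = delta.values.ravel()
    return {
        frag: float(flat[voxel_frag == i].sum() * dv)
        for i, frag in enumerate(part.fragments)
    }


def homo_lumo_overlap(
    homo: DensityGrid, lumo: DensityGrid, part: FragmentPartition
) -> tuple[dict[str, float], dict[str, float], float]:
    """Frontier-orbital fragment populations and spatial-overlap diagnostic.

    Returns (|HOMO|² populations per fragment, |LUMO|² populations per
    fragment, product norm ∫|ψ_HOMO ψ_LUMO| dV).  A vanishing product norm
    signals spatially separated hole and electron, i.e. strong CT character.
    """
    if not homo.same_geometry(lumo):
        raise ValueError("HOMO and LUMO grids differ in geometry")
    pop_h = fragment_charges(
        DensityGrid(homo.origin, homo.axes, homo.values**2, homo.atom_numbers, homo.atom_coords),
        part,
    )
    pop_l = fragment_charges(
        DensityGrid(lumo.origin, lumo.axes, lumo.values**2, lumo.atom_numbers, lumo.atom_coords),
        part,
    )
    product_norm = float(np.abs(homo.values * lumo.values).sum() * homo.voxel_volume)
    return pop_h, pop_l, product_norm


# --------------------------------------------------------------------------
# CT assignments across snapshots


@dataclass(frozen=True)
class CTAssignment:
    """A pure CT state resolved on a donor/acceptor fragment pair."""

    snapshot_id: str
    energy_ev: float
    donor: str
    acceptor: str
    delta_q: dict[str, float] = field(default_factory=dict)
    nto_weight: float | None = None
    osc_strength: float | None = None

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")
        if self.delta_q:
            if not (self.delta_q.get(self.donor, -1.0) < 0 < self.delta_q.get(self.acceptor, 1.0)):
                raise ValueError("expected Δq_donor < 0 < Δq_acceptor (Δρ>0 = electron gain)")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.donor, self.acceptor})


def ct_direction_series(
    assignments: Sequence[CTAssignment], pair_order: tuple[str, str] | None = None
) -> tuple[list[int], int]:
    """Signed direction per snapshot and the number of adjacent sign flips.

    Sign convention: +1 when the hole sits on the first-listed fragment of
    the pair (i.e. that fragment is the donor), -1 otherwise.
    """
    if len(assignments) < 1:
        raise ValueError("need at least one assignment")
    pairs = {a.pair for a in assignments}
    if len(pairs) != 1:
        raise ValueError("assignments span more than one fragment pair")
    if pair_order is None:
        first = assignments[0]
        pair_order = (first.donor, first.acceptor)
    signs = [1 if a.donor == pair_order[0] else -1 for a in assignments]
    flips = int(np.sum(np.array(signs[1:]) != np.array(signs[:-1]))) if len(signs) > 1 else 0
    return signs, flips


@dataclass(frozen=True)
class CTSummary:
    """Pure-CT energy summary for one fragment pair across snapshots."""

    pair: str
    per_snapshot_min_ev: dict[str, float]
    min_ev: float | None
    max_ev: float | None
    state_indices: tuple[int, ...]
    snapshots_without_ct: tuple[str, ...]


def ct_summary(
    records: Sequence[ExcitedStateRecord],
    pair: str,
    classify_first: bool = True,
    n_states: int = 10,
) -> CTSummary:
    """Summarize pure-CT energies per snapshot for one pigment pair.

    Snapshots in which none of the ``n_states`` lowest states is a pure CT
    state are flagged rather than erroring; min/max are then taken over the
    snapshots that do show CT.
    """
    if classify_first:
        for r in records:
            if r.assigned_class == "unassigned":
                classify_state(r)
    snapshots: dict[str, list[ExcitedStateRecord]] = {}
    for r in records:
        snapshots.setdefault(r.snapshot_id, []).append(r)

    per_snap: dict[str, float] = {}
    no_ct: list[str] = []
    indices: set[int] = set()
    for snap, recs in snapshots.items():
        cts = [
            r for r in recs
            if r.assigned_class == "pure_CT"
            and (r.state_index is None or r.state_index <= n_states)
        ]
        if not cts:
            no_ct.append(snap)
            continue
        lowest = min(cts, key=lambda r: r.energy_ev)
        per_snap[snap] = lowest.energy_ev
        indices.update(r.state_index for r in cts if r.state_index is not None)

    energies = list(per_snap.values())
    return CTSummary(
        pair,
        per_snap,
        min(energies) if energies else None,
        max(energies) if energies else None,
        tuple(sorted(indices)),
        tuple(no_ct),
    )


# --------------------------------------------------------------------------
# state-table I/O: CSV with one row per (snapshot, state, NTO component)


def load_state_table(path: str | Path) -> dict[str, list[ExcitedStateRecord]]:
    """Read state records grouped by pair label.

    Columns: pair, snapshot, state_index (may be empty), energy_eV, f,
    nto_weight, hole_fragment, particle_fragment.  Rows sharing
    (pair, snapshot, energy_eV) are merged into one record with several
    NTO components.
    """
    df = pd.read_csv(path)
    out: dict[str, list[ExcitedStateRecord]] = {}
    for (pair, snap, energy), grp in df.groupby(
        ["pair", "snapshot", "energy_eV"], sort=False
    ):
        comps = [
            NTOComponent(row.nto_weight, row.hole_fragment, row.particle_fragment)
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        idx = first["state_index"]
        rec = ExcitedStateRecord(
            snapshot_id=str(snap),
            energy_ev=float(energy),
            osc_strength=float(first["f"]),
            nto_components=comps,
            state_index=None if pd.isna(idx) else int(idx),
        )
        out.setdefault(str(pair), []).append(rec)
    return out


def save_state_table(path: str | Path, tables: dict[str, list[ExcitedStateRecord]]) -> None:
    rows = []
    for pair, recs in tables.items():
        for r in recs:
            for c in r.nto_components:
                rows.append({
                    "pair": pair, "snapshot": r.snapshot_id,
                    "state_index": r.state_index, "energy_eV": r.energy_ev,
                    "f": r.osc_strength, "nto_weight": c.weight,
                    "hole_fragment": "/".join(sorted(c.hole)),
                    "particle_fragment": "/".join(sorted(c.particle)),
                })
    pd.DataFrame(rows).to_csv(path, index=False)
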