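"""Pigment geometries, transition-charge sets and complex assembly.

A pigment-protein complex is represented as an ordered list of pigments
(the order defines the row order of the exciton Hamiltonian), each paired
with a per-atom set of transition charges.  Transition charges are atom-
centred monopoles fitted to the transition electrostatic potential (TrESP);
multiplied by the atomic positions they yield the transition dipole, and
scaled uniformly they can be matched to an experimental dipole magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import EANG_TO_DEBYE


@dataclass(frozen=True)
class PigmentGeometry:
    """One pigment: element symbols, coordinates (Å) and a fragment id."""

    pigment_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    fragment_id: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError(f"pigment {self.pigment_id!r} has no atoms")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords lengths differ")
        if not np.isfinite(coords).all():
            raise ValueError(f"non-finite coordinates in pigment {self.pigment_id!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class TransitionChargeSet:
    """Per-atom transition charges (e), aligned 1:1 with a pigment's atoms."""

    pigment_id: str
    charges: np.ndarray  # (n_atoms,), e
    scale_applied: float = 1.0

    def __post_init__(self) -> None:
        q = np.asarray(self.charges, dtype=float)
        if q.ndim != 1:
            raise ValueError("charges must be one-dimensional")
        if not np.isfinite(q).all():
            raise ValueError("non-finite transition charges")
        if not self.scale_applied > 0:
            raise ValueError("scale_applied must be positive")
        object.__setattr__(self, "charges", q)

    def __len__(self) -> int:
        return self.charges.size


@dataclass
class ComplexAssembly:
    """Ordered pigments plus matching charge sets; order fixes Hamiltonian rows."""

    pigments: list[PigmentGeometry]
    charge_sets: list[TransitionChargeSet] = field(default_factory=list)
    ring_members: tuple[int, ...] = ()
    rc_members: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        ids = [p.pigment_id for p in self.pigments]
        if len(set(ids)) != len(ids):
            raise ValueError("pigment_id values must be unique within a complex")
        if set(self.ring_members) & set(self.rc_members):
            raise ValueError("ring_members and rc_members overlap")
        if self.charge_sets:
            if len(self.charge_sets) != len(self.pigments):
                raise ValueError("one charge set per pigment required")
            for p, q in zip(self.pigments, self.charge_sets):
                if len(q) != p.n_atoms:
                    raise ValueError(
                        f"charge set for {p.pigment_id!r} has {len(q)} charges "
                        f"but the pigment has {p.n_atoms} atoms"
                    )

    def __len__(self) -> int:
        return len(self.pigments)

    @property
    def labels(self) -> list[str]:
        return [p.pigment_id for p in self.pigments]

    def charge_set_for(self, pigment_id: str) -> TransitionChargeSet:
        for p, q in zip(self.pigments, self.charge_sets):
            if p.pigment_id == pigment_id:
                return q
        raise KeyError(pigment_id)


# --------------------------------------------------------------------------
# loading


def load_pigments(
    structure_file: str | Path,
    selection_map: Mapping[str, Mapping[str, object]],
    ring_ids: Sequence[str] = (),
    rc_ids: Sequence[str] = (),
) -> ComplexAssembly:
    """Load a :class:`ComplexAssembly` from a PDB file.

    ``selection_map`` maps pigment_id -> selector dict with keys
    ``resname`` (str), and optionally ``resid`` (int) and ``chain`` (str).
    Pigments appear in the assembly in ``selection_map`` order.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # synthetic PDBs trigger benign parser warnings
        structure = PDBParser(QUIET=True).get_structure("complex", str(structure_file))

    pigments: list[PigmentGeometry] = []
    for frag_id, (pigment_id, sel) in enumerate(selection_map.items()):
        resname = sel.get("resname")
        resid = sel.get("resid")
        chain_id = sel.get("chain")
        elements: list[str] = []
        coords: list[np.ndarray] = []
        for model in structure:
            for chain in model:
                if chain_id is not None and chain.id != chain_id:
                    continue
                for residue in chain:
                    if resname is not None and residue.get_resname().strip() != resname:
                        continue
                    if resid is not None and residue.id[1] != int(resid):
                        continue
                    for atom in residue:
                        elem = (atom.element or atom.get_name()[:1]).strip() or "X"
                        elements.append(elem)
                        coords.append(atom.get_coord().astype(float))
            break  # first model only
        if not coords:
            raise ValueError(
                f"empty selection: selector for pigment {pigment_id!r} matched no atoms"
            )
        pigments.append(
            PigmentGeometry(pigment_id, tuple(elements), np.array(coords), frag_id)
        )

    order = {pid: i for i, pid in enumerate(selection_map)}
    return ComplexAssembly(
        pigments,
        ring_members=tuple(order[i] for i in ring_ids),
        rc_members=tuple(order[i] for i in rc_ids),
    )


def load_charge_table(path: str | Path) -> dict[str, TransitionChargeSet]:
    """Read a CSV with columns (pigment_id, atom_index, atom_name, q_e)."""
    df = pd.read_csv(path)
    out: dict[str, TransitionChargeSet] = {}
    for pid, grp in df.groupby("pigment_id", sort=False):
        grp = grp.sort_values("atom_index")
        out[str(pid)] = TransitionChargeSet(str(pid), grp["q_e"].to_numpy(float))
    return out


def write_charge_table(path: str | Path, sets: Mapping[str, TransitionChargeSet]) -> None:
    rows = []
    for pid, qset in sets.items():
        for i, q in enumerate(qset.charges):
            rows.append({"pigment_id": pid, "atom_index": i, "atom_name": f"A{i}", "q_e": q})
    # full float precision so write/read round-trips to <1e-12
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# dipoles and scaling


def transition_dipole(geom: PigmentGeometry, q: TransitionChargeSet) -> np.ndarray:
    """Transition dipole Σ_I q_I r_I in e·Å (multiply by 4.80321 for Debye)."""
    if len(q) != geom.n_atoms:
        raise ValueError(
            f"charge set length {len(q)} does not match atom count {geom.n_atoms}"
        )
    return q.charges @ geom.coords


def dipole_debye(geom: PigmentGeometry, q: TransitionChargeSet) -> np.ndarray:
    return transition_dipole(geom, q) * EANG_TO_DEBYE


def scale_charges(
    q: TransitionChargeSet,
    *,
    factor: float | None = None,
    target_dipole_debye: float | None = None,
    geom: PigmentGeometry | None = None,
) -> TransitionChargeSet:
    """Uniformly rescale a transition-charge set.

    Either give ``factor`` directly (e.g. the 0.724 applied to match the
    experimental dipole of BChl), or give ``target_dipole_debye`` together
    with the geometry, in which case the factor is target/current magnitude.
    """
    if (factor is None) == (target_dipole_debye is None):
        raise ValueError("give exactly one of factor or target_dipole_debye")
    if factor is None:
        if geom is None:
            raise ValueError("geometry required for target-dipole scaling")
        current = float(np.linalg.norm(dipole_debye(geom, q)))
        if current <= 0.0:
            raise ValueError("current transition dipole is zero; cannot scale to target")
        factor = target_dipole_debye / current
    return replace(
        q, charges=q.charges * factor, scale_applied=q.scale_applied * factor
    )
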