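"""Volumetric scalar fields in the Gaussian cube convention.

Lengths are in bohr, values in e/bohr^3 (for densities) or bohr^-3/2 (for
orbitals); the value loop order is z-fastest.  The reader is strict: it
supports orthogonal or skewed voxel vectors but rejects the Angstrom variant
(negative voxel counts) to keep the unit convention unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import BOHR_TO_ANG


@dataclass(frozen=True)
class DensityGrid:
    """Scalar field on a regular grid with cube-file geometry (bohr)."""

    origin: np.ndarray          # (3,)
    axes: np.ndarray            # (3, 3): rows are the three voxel vectors
    values: np.ndarray          # (nx, ny, nz)
    atom_numbers: tuple[int, ...] = ()
    atom_coords: np.ndarray | None = None  # (n_atoms, 3), bohr

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, float)
        axes = np.asarray(self.axes, float)
        values = np.asarray(self.values, float)
        if origin.shape != (3,) or axes.shape != (3, 3) or values.ndim != 3:
            raise ValueError("bad grid geometry")
        if not np.isfinite(values).all():
            raise ValueError("grid values must be finite")
        if abs(np.linalg.det(axes)) <= 0.0:
            raise ValueError("voxel volume must be positive")
        coords = self.atom_coords
        if coords is not None:
            coords = np.asarray(coords, float)
            if coords.shape != (len(self.atom_numbers), 3):
                raise ValueError("atom list inconsistent")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "atom_coords", coords)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in bohr^3."""
        return float(abs(np.linalg.det(self.axes)))

    def integral(self) -> float:
        """∫ values dV over the whole grid."""
        return float(self.values.sum() * self.voxel_volume)

    def voxel_centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) voxel positions in bohr, z-fastest order."""
        nx, ny, nz = self.shape
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1)
        return self.origin + idx @ self.axes

    def same_geometry(self, other: "DensityGrid", atol: float = 1e-8) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )

    def atom_coords_ang(self) -> np.ndarray:
        if self.atom_coords is None:
            raise ValueError("grid carries no atoms")
        return self.atom_coords * BOHR_TO_ANG


def write_cube(path: str | Path, grid: DensityGrid, comment: str = "excitonscope") -> None:
    nx, ny, nz = grid.shape
    n_atoms = len(grid.atom_numbers)
    lines = [comment, "scalar field (bohr, z-fastest)"]
    lines.append(f"{n_atoms:5d} {grid.origin[0]:12.6f} {grid.origin[1]:12.6f} {grid.origin[2]:12.6f}")
    for n, ax in zip((nx, ny, nz), grid.axes):
        lines.append(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    for num, xyz in zip(grid.atom_numbers, grid.atom_coords if grid.atom_coords is not None else []):
        lines.append(
            f"{num:5d} {float(num):12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}"
        )
    flat = grid.values.reshape(nx * ny, nz)
    for row in flat:
        for start in range(0, nz, 6):
            lines.append("".join(f"{v:14.6e}" for v in row[start:start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> DensityGrid:
    tokens_lines = Path(path).read_text().splitlines()
    header = tokens_lines[2].split()
    n_atoms = int(header[0])
    if n_atoms < 0:
        raise ValueError("cube files with orbital/Angstrom header variant not supported")
    origin = np.array(header[1:4], float)
    counts, axes = [], []
    for line in tokens_lines[3:6]:
        parts = line.split()
        n = int(parts[0])
        if n <= 0:
            raise ValueError("voxel counts must be positive (bohr convention)")
        counts.append(n)
        axes.append([float(x) for x in parts[1:4]])
    numbers, coords = [], []
    for line in tokens_lines[6:6 + n_atoms]:
        parts = line.split()
        numbers.append(int(parts[0]))
        coords.append([float(x) for x in parts[2:5]])
    data = np.array(" ".join(tokens_lines[6 + n_atoms:]).split(), dtype=float)
    nx, ny, nz = counts
    if data.size != nx * ny * nz:
        raise ValueError("cube value count does not match the declared grid shape")
    return DensityGrid(
        origin,
        np.array(axes),
        data.reshape(nx, ny, nz),
        tuple(numbers),
        np.array(coords) if numbers else None,
    )
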