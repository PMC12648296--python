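"""Synthetic inputs with known ground truth.

Generates every input class the analysis consumes: an elliptical ring of
32 pigments around a C2-symmetric 6-pigment reaction-centre cluster with
transition-charge sets tuned to a target dipole, mean-reverting (OU)
site-energy trajectories with Gaussian stationary statistics, excited-state
descriptor tables with known CT/LE/ME labels, ground/excited density-grid
pairs with known donor/acceptor charge separation, and a parametric
Drude-Lorentz (plus optional vibrational-mode) spectral density.

The pigments are pseudo-molecules of six point charges — enough structure
for TrESP couplings and grid partitioning, not chemically realistic.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctstates import ExcitedStateRecord, FragmentPartition, NTOComponent
from .cube import DensityGrid
from .landscape import SiteEnergyTrajectory
from .spectra import SpectralDensity
from .structures import (
    ComplexAssembly,
    PigmentGeometry,
    TransitionChargeSet,
    scale_charges,
)

RC_LABELS = ("P_L", "P_M", "B_L", "B_M", "H_L", "H_M")

# default per-pigment site-energy means for the RC cluster (eV), in the
# range seen for BChl/BPh pigments embedded in the protein
RC_SITE_MEANS = {
    "P_L": 1.912, "P_M": 1.833, "B_L": 1.869,
    "B_M": 1.826, "H_L": 2.035, "H_M": 1.900,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generators (defaults = study conditions)."""

    seed: int = 0
    n_ring_pairs: int = 16          # -> 32 ring pigments
    rc_pigments: int = 6
    ring_mean_ev: float = 1.877     # LH1 ring mean Q_y site energy
    ring_sigma_ev: float = 0.05
    rc_means_ev: dict = field(default_factory=lambda: dict(RC_SITE_MEANS))
    rc_sigma_ev: float = 0.05
    n_frames: int = 20000
    ou_tau_frames: float = 50.0     # OU correlation time
    frame_stride_ps: float = 10.0
    dipole_target_debye: float = 6.3   # Q_y transition dipole of BChl a
    ring_semi_axes_ang: tuple = (47.0, 41.0)  # elliptical LH1 ring
    grid_spacing_bohr: float = 0.5
    grid_shape: tuple = (64, 32, 32)
    lobe_sigma_bohr: float = 1.5
    fragment_sep_bohr: float = 12.0
    label_mix: dict = field(
        default_factory=lambda: {"pure_CT": 0.4, "LE": 0.3, "ME": 0.2, "mixed": 0.1}
    )

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# --------------------------------------------------------------------------
# geometry + charges


def _pseudo_pigment(
    pigment_id: str,
    center: np.ndarray,
    direction: np.ndarray,
    fragment_id: int,
    target_debye: float,
    rng: np.random.Generator,
    half_span_ang: float = 1.5,
) -> tuple[PigmentGeometry, TransitionChargeSet]:
    """Six point charges whose dipole matches the target magnitude.

    Two charges of opposite sign sit along the transition-dipole axis; the
    remaining four carry small zero-sum charges so the set is not a bare
    dipole.  The whole set is rescaled to the target dipole magnitude.
    """
    u = direction / np.linalg.norm(direction)
    # orthonormal frame around u
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    d = half_span_ang
    coords = center + np.array(
        [d * u, -d * u, d * v, -d * v, d * w, -d * w]
    )
    q_main = 0.5
    q_small = rng.uniform(0.01, 0.05)
    charges = np.array([q_main, -q_main, q_small, -q_small, 0.0, 0.0])
    geom = PigmentGeometry(pigment_id, ("C",) * 6, coords, fragment_id)
    qset = scale_charges(
        TransitionChargeSet(pigment_id, charges),
        target_dipole_debye=target_debye, geom=geom,
    )
    return geom, qset


def make_complex(cfg: GeneratorConfig) -> ComplexAssembly:
    """Elliptical pigment ring plus an inner C2-symmetric RC cluster."""
    rng = cfg.rng(1)
    a, b = cfg.ring_semi_axes_ang
    pigments: list[PigmentGeometry] = []
    charge_sets: list[TransitionChargeSet] = []

    # 2*n_ring_pairs pigments at consecutive angles with tangential,
    # same-sense transition dipoles: the head-to-tail arrangement makes
    # nearest-neighbour couplings negative and the low-energy exciton
    # superradiant (J-aggregate-like red shift), as in the real antenna ring
    n_ring = 2 * cfg.n_ring_pairs
    for j in range(n_ring):
        theta = 2.0 * np.pi * j / max(n_ring, 1)
        tangent = np.array([-a * np.sin(theta), b * np.cos(theta), 0.0])
        sub, radial = ("alpha", 0.0) if j % 2 == 0 else ("beta", 2.0)
        center = np.array(
            [(a + radial) * np.cos(theta), (b + radial) * np.sin(theta), 0.0]
        )
        pid = f"{sub}_BChl_{j // 2 + 1:02d}"
        geom, qset = _pseudo_pigment(
            pid, center, tangent, len(pigments), cfg.dipole_target_debye, rng
        )
        pigments.append(geom)
        charge_sets.append(qset)

    # RC cluster: C2-symmetric L/M pairs around the origin
    rc_positions = {
        "P_L": np.array([4.0, 1.0, 0.0]), "P_M": np.array([-4.0, 1.0, 0.0]),
        "B_L": np.array([11.0, -5.0, 2.0]), "B_M": np.array([-11.0, -5.0, 2.0]),
        "H_L": np.array([18.0, -11.0, 4.0]), "H_M": np.array([-18.0, -11.0, 4.0]),
    }
    rc_dirs = {
        "P_L": np.array([1.0, 1.0, 0.2]), "P_M": np.array([-1.0, 1.0, 0.2]),
        "B_L": np.array([1.0, -1.0, 0.3]), "B_M": np.array([-1.0, -1.0, 0.3]),
        "H_L": np.array([0.5, -1.0, 0.1]), "H_M": np.array([-0.5, -1.0, 0.1]),
    }
    for lab in RC_LABELS[: cfg.rc_pigments]:
        geom, qset = _pseudo_pigment(
            lab, rc_positions[lab], rc_dirs[lab], len(pigments),
            cfg.dipole_target_debye, rng,
        )
        pigments.append(geom)
        charge_sets.append(qset)

    n_rc = min(cfg.rc_pigments, len(RC_LABELS))
    return ComplexAssembly(
        pigments, charge_sets,
        ring_members=tuple(range(n_ring)),
        rc_members=tuple(range(n_ring, n_ring + n_rc)),
    )


def write_pdb(assembly: ComplexAssembly, path: str | Path) -> None:
    """Write the assembly as a minimal PDB (one residue per pigment)."""
    lines = []
    serial = 1
    for resid, pig in enumerate(assembly.pigments, start=1):
        for j, (el, xyz) in enumerate(zip(pig.elements, pig.coords)):
            name = f"{el}{j + 1}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} BCL A{resid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {el:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def selection_map(assembly: ComplexAssembly) -> dict[str, dict]:
    """Selector map matching :func:`write_pdb` output, for load_pigments."""
    return {
        pig.pigment_id: {"resname": "BCL", "resid": i + 1, "chain": "A"}
        for i, pig in enumerate(assembly.pigments)
    }


# --------------------------------------------------------------------------
# site-energy trajectories


def make_site_energy_trajectories(
    cfg: GeneratorConfig, labels: list[str] | None = None
) -> list[SiteEnergyTrajectory]:
    """Per-pigment OU series with stationary mean/SD set by the config.

    Exact OU discretization: x_{t+1} = μ + φ(x_t − μ) + σ√(1−φ²) ε with
    φ = exp(−1/τ), so the stationary distribution is N(μ, σ²) and the
    autocorrelation decays as exp(−lag/τ).
    """
    if cfg.ring_sigma_ev <= 0 or cfg.rc_sigma_ev <= 0:
        raise ValueError("site-energy sigma must be positive")
    rng = cfg.rng(2)
    if labels is None:
        labels = [f"alpha_BChl_{i + 1:02d}" for i in range(cfg.n_ring_pairs)]
        labels += [f"beta_BChl_{i + 1:02d}" for i in range(cfg.n_ring_pairs)]
        labels += list(RC_LABELS[: cfg.rc_pigments])

    phi = np.exp(-1.0 / cfg.ou_tau_frames)
    out = []
    for lab in labels:
        if lab in cfg.rc_means_ev:
            mu, sigma = cfg.rc_means_ev[lab], cfg.rc_sigma_ev
        else:
            mu, sigma = cfg.ring_mean_ev, cfg.ring_sigma_ev
        eps = rng.standard_normal(cfg.n_frames)
        x = np.empty(cfg.n_frames)
        x[0] = mu + sigma * eps[0]
        innov = sigma * np.sqrt(1.0 - phi**2)
        for t in range(1, cfg.n_frames):
            x[t] = mu + phi * (x[t - 1] - mu) + innov * eps[t]
        out.append(SiteEnergyTrajectory(lab, x, cfg.frame_stride_ps))
    return out


# --------------------------------------------------------------------------
# excited-state descriptor tables


def make_state_table(
    cfg: GeneratorConfig, n_records: int = 50, fragments: tuple[str, str] = ("A", "B")
) -> list[tuple[ExcitedStateRecord, str]]:
    """State records whose descriptors satisfy the class definitions by
    construction; returns (record, truth_label) pairs."""
    mix = cfg.label_mix
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("label mix must sum to 1")
    rng = cfg.rng(3)
    fa, fb = fragments
    classes = list(mix.keys())
    probs = np.array([mix[c] for c in classes])
    out: list[tuple[ExcitedStateRecord, str]] = []
    for i in range(n_records):
        cls = classes[rng.choice(len(classes), p=probs)]
        energy = rng.uniform(1.7, 2.6)
        hole, particle = (fa, fb) if rng.random() < 0.5 else (fb, fa)
        if cls == "pure_CT":
            n = rng.uniform(0.94, 1.0)
            f = rng.uniform(0.0, 0.01)
            comps = [NTOComponent(n, hole, particle)]
        elif cls == "mixed":
            n = rng.uniform(0.905, 1.0)
            f = rng.uniform(0.02, 0.7)
            comps = [NTOComponent(n, hole, particle)]
        elif cls == "ME":
            n = rng.uniform(0.85, 0.95)
            f = rng.uniform(0.1, 0.8)
            both = frozenset({fa, fb})
            comps = [NTOComponent(n, both, both)]
        else:  # LE
            f = rng.uniform(0.05, 0.8)
            w1 = rng.uniform(0.5, 0.8)
            comps = [NTOComponent(w1, hole, hole)]
            if rng.random() < 0.5:  # two local components on different pigments
                comps.append(NTOComponent(rng.uniform(0.1, w1 - 0.05), particle, particle))
        rec = ExcitedStateRecord(
            snapshot_id=f"snap_{i:03d}", energy_ev=energy, osc_strength=f,
            nto_components=comps, state_index=int(rng.integers(1, 11)),
        )
        out.append((rec, cls))
    return out


# --------------------------------------------------------------------------
# density-grid pairs


def _gaussian_lobe(centers: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((centers - mu) ** 2).sum(axis=1)
    return np.exp(-0.5 * d2 / sigma**2) / (sigma * np.sqrt(2.0 * np.pi)) ** 3


def make_density_pair(
    cfg: GeneratorConfig,
    character: str = "pure_CT",
    direction: tuple[str, str] = ("A", "B"),
) -> tuple[DensityGrid, DensityGrid, FragmentPartition, dict[str, float]]:
    """Ground/excited density pair with known fragment charge transfer.

    Two fragments sit at ±fragment_sep/2 along x; unit-normalized Gaussian
    lobes realize a full one-electron transfer (pure_CT: Δq = ∓1 e), a local
    reshaping (LE: Δq ≈ 0) or a half transfer (ME: Δq = ∓0.5 e).  Returns
    (ρ_ground, ρ_excited, partition, truth Δq per fragment); Δρ integrates
    to zero by construction.
    """
    if character not in {"pure_CT", "LE", "ME"}:
        raise ValueError(f"unknown character {character!r}")
    nx, ny, nz = cfg.grid_shape
    h = cfg.grid_spacing_bohr
    origin = -0.5 * h * np.array([nx - 1, ny - 1, nz - 1])
    axes = h * np.eye(3)
    half = 0.5 * cfg.fragment_sep_bohr
    frag_pos = {"A": np.array([-half, 0.0, 0.0]), "B": np.array([half, 0.0, 0.0])}
    donor, acceptor = direction
    if donor not in frag_pos or acceptor not in frag_pos or donor == acceptor:
        raise ValueError("direction must name two distinct fragments A/B")
    for p in frag_pos.values():
        if (np.abs(p) > np.abs(origin)).any():
            raise ValueError("fragments fall outside the grid")

    atoms = np.array([frag_pos["A"], frag_pos["B"]])
    grid_kw = dict(atom_numbers=(12, 12), atom_coords=atoms)
    tmp = DensityGrid(origin, axes, np.zeros(cfg.grid_shape), **grid_kw)
    centers = tmp.voxel_centers()
    s = cfg.lobe_sigma_bohr
    dv = tmp.voxel_volume

    def lobe(pos, sigma):
        g = _gaussian_lobe(centers, pos, sigma)
        return g / (g.sum() * dv)  # exactly 1 e on the discrete grid

    g_d = lobe(frag_pos[donor], s)
    g_a = lobe(frag_pos[acceptor], s)
    g_a2 = lobe(frag_pos[acceptor], 1.3 * s)
    g_d2 = lobe(frag_pos[donor], 1.3 * s)

    ground = g_d + g_a  # one electron on each fragment
    if character == "pure_CT":
        excited = g_a + g_a2
        truth = {donor: -1.0, acceptor: +1.0}
    elif character == "ME":
        excited = 0.5 * g_d + g_a + 0.5 * g_a2
        truth = {donor: -0.5, acceptor: +0.5}
    else:  # LE: reshape on the donor fragment only
        excited = g_d2 + g_a
        truth = {donor: 0.0, acceptor: 0.0}

    shape = cfg.grid_shape
    rho_gnd = DensityGrid(origin, axes, ground.reshape(shape), **grid_kw)
    rho_exc = DensityGrid(origin, axes, excited.reshape(shape), **grid_kw)
    part = FragmentPartition(("A", "B"))
    return rho_gnd, rho_exc, part, truth


# --------------------------------------------------------------------------
# spectral density


def make_spectral_density(
    lambda_cm: float = 35.0,
    gamma_cm: float = 50.0,
    modes: list[tuple[float, float, float]] | None = None,
    freq_max_cm: float = 2000.0,
    n_points: int = 2001,
) -> SpectralDensity:
    """Drude-Lorentz J(ω) = 2λωγ/(ω²+γ²) plus optional underdamped
    vibrational modes (λ_j, ω_j, γ_j); deterministic analytic form."""
    if lambda_cm < 0 or gamma_cm <= 0:
        raise ValueError("need lambda >= 0 and gamma > 0")
    w = np.linspace(0.0, freq_max_cm, n_points)
    j = 2.0 * lambda_cm * w * gamma_cm / (w**2 + gamma_cm**2)
    for lam_j, w_j, g_j in modes or []:
        j += 2.0 * lam_j * w_j**2 * g_j * w / ((w**2 - w_j**2) ** 2 + (g_j * w) ** 2)
    return SpectralDensity(w, j)
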