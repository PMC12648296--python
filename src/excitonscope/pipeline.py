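"""Config-driven orchestration of the analysis stages.

Stages run in dependency order: simulate -> dos -> couplings -> hamiltonian
-> spectrum -> classify -> ctscan -> tune.  Each stage writes its artifacts
into the run directory; a manifest records the package version, seed,
thresholds, stage status and a SHA-256 hash of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, constants, hamiltonian as ham_mod, landscape, spectra, synthetic, tables
from .ctstates import ct_direction_series, ct_summary, CTAssignment
from .koopmans import load_scan, select_omega

log = logging.getLogger("excitonscope")

ALL_STAGES = (
    "simulate", "dos", "couplings", "hamiltonian",
    "spectrum", "classify", "ctscan", "tune",
)


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the study conditions."""

    seed: int = 0
    out_dir: str = "excitonscope_run"
    stages: tuple = ALL_STAGES
    n_frames: int = 2000
    bin_width_ev: float = constants.DEFAULT_BIN_WIDTH_EV
    screening_factor: float = constants.DEFAULT_SCREENING
    charge_scale: float = constants.DEFAULT_CHARGE_SCALE
    temperature_k: float = constants.DEFAULT_TEMPERATURE_K
    align_nm: float = constants.DEFAULT_ALIGN_NM
    ct_nto_min: float = constants.CT_NTO_MIN
    ct_osc_max: float = constants.CT_OSC_MAX
    lambda_cm: float = 35.0
    gamma_cm: float = 50.0
    state_table: str | None = None   # None -> packaged RC pair table
    tuning_table: str | None = None  # None -> packaged tuning scan

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Empty list iff the configuration is valid."""
    v: list[str] = []
    if cfg.bin_width_ev <= 0:
        v.append("bin_width_ev: must be positive")
    if not 0.0 <= cfg.screening_factor <= 1.0:
        v.append("screening_factor: must lie in [0, 1]")
    if cfg.charge_scale <= 0:
        v.append("charge_scale: must be positive")
    if cfg.temperature_k <= 0:
        v.append("temperature_k: must be positive")
    if cfg.align_nm <= 0:
        v.append("align_nm: must be positive")
    if not 0.0 <= cfg.ct_nto_min <= 1.0:
        v.append("ct_nto_min: must lie in [0, 1]")
    if cfg.ct_osc_max < 0:
        v.append("ct_osc_max: must be >= 0")
    if cfg.n_frames < 2:
        v.append("n_frames: need at least 2 frames")
    for s in cfg.stages:
        if s not in ALL_STAGES:
            v.append(f"stages: unknown stage {s!r}")
    for key in ("state_table", "tuning_table"):
        path = getattr(cfg, key)
        if path is not None and not Path(path).exists():
            v.append(f"{key}: path {path!r} does not exist")
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest dict."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "screening_factor": cfg.screening_factor,
            "charge_scale": cfg.charge_scale,
            "bin_width_ev": cfg.bin_width_ev,
            "temperature_k": cfg.temperature_k,
            "align_nm": cfg.align_nm,
            "ct_nto_min": cfg.ct_nto_min,
            "ct_osc_max": cfg.ct_osc_max,
        },
        "stages": {},
        "outputs": {},
    }

    gen = synthetic.GeneratorConfig(seed=cfg.seed, n_frames=cfg.n_frames)
    state: dict = {}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = "completed"
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
        log.info("stage %s completed (%d outputs)", stage, len(files))

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            manifest["stages"][stage] = "skipped"
            continue
        try:
            files = _run_stage(stage, cfg, gen, state, out)
        except Exception:
            manifest["stages"][stage] = "failed"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.exception("stage %s failed", stage)
            raise
        record(stage, files)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(
    stage: str, cfg: PipelineConfig, gen: synthetic.GeneratorConfig,
    state: dict, out: Path,
) -> list[Path]:
    if stage == "simulate":
        assembly = synthetic.make_complex(gen)
        trajs = synthetic.make_site_energy_trajectories(gen)
        state["assembly"], state["trajs"] = assembly, trajs
        pdb = out / "complex.pdb"
        synthetic.write_pdb(assembly, pdb)
        from .structures import write_charge_table

        charges = out / "transition_charges.csv"
        write_charge_table(charges, {p.pigment_id: q for p, q in
                                     zip(assembly.pigments, assembly.charge_sets)})
        traj_csv = out / "site_energies.csv"
        landscape.save_trajectories(traj_csv, trajs)
        return [pdb, charges, traj_csv]

    if stage == "dos":
        trajs = state.get("trajs") or landscape.load_trajectories(out / "site_energies.csv")
        dos = landscape.density_of_states(trajs, bin_width=cfg.bin_width_ev)
        f = out / "dos.csv"
        dos.to_csv(f)
        return [f]

    if stage == "couplings":
        assembly = state["assembly"]
        ham = ham_mod.build_hamiltonian(
            {p.pigment_id: 2.0 for p in assembly.pigments},  # placeholder diagonal
            couplings=None, assembly=assembly, screening_f=cfg.screening_factor,
        )
        state["couplings"] = ham.matrix - np.diag(np.diag(ham.matrix))
        f = out / "couplings.csv"
        ham_mod.export_couplings_csv(f, ham)
        return [f]

    if stage == "hamiltonian":
        assembly, trajs = state["assembly"], state["trajs"]
        energies = {t.pigment_id: float(t.energies.mean()) for t in trajs}
        ham = ham_mod.build_hamiltonian(
            {p.pigment_id: energies[p.pigment_id] for p in assembly.pigments},
            couplings=state["couplings"],
        )
        state["hamiltonian"] = ham
        f = out / "hamiltonian.txt"
        ham.to_text(f)
        return [f]

    if stage == "spectrum":
        assembly, ham = state["assembly"], state["hamiltonian"]
        states_ = ham_mod.diagonalize(ham, ham_mod.site_dipoles(assembly))
        J = synthetic.make_spectral_density(cfg.lambda_cm, cfg.gamma_cm)
        spec = spectra.absorption_spectrum(states_, J, cfg.temperature_k)
        aligned, shift = spectra.align_to_experiment(spec, cfg.align_nm)
        f1, f2 = out / "spectrum.csv", out / "spectrum_aligned.csv"
        spec.to_csv(f1)
        aligned.to_csv(f2)
        (out / "spectrum_shift.json").write_text(
            json.dumps({"applied_shift_cm-1": shift, "align_nm": cfg.align_nm})
        )
        return [f1, f2, out / "spectrum_shift.json"]

    if stage == "classify":
        from .ctstates import classify_state, save_state_table, load_state_table

        pairs = (load_state_table(cfg.state_table) if cfg.state_table
                 else tables.rc_pair_states())
        rows = []
        for pair, recs in pairs.items():
            for r in recs:
                cls = classify_state(r, cfg.ct_nto_min, cfg.ct_osc_max)
                rows.append({"pair": pair, "snapshot": r.snapshot_id,
                             "energy_eV": r.energy_ev, "class": cls,
                             "ct_direction": r.ct_direction})
        state["classified"] = pairs
        import pandas as pd

        f1 = out / "classification.csv"
        pd.DataFrame(rows).to_csv(f1, index=False)
        f2 = out / "classification.json"
        f2.write_text(json.dumps(rows, indent=2))
        return [f1, f2]

    if stage == "ctscan":
        pairs = state.get("classified") or tables.rc_pair_states()
        report = {}
        for pair, recs in pairs.items():
            summ = ct_summary(recs, pair)
            entry = {
                "min_eV": summ.min_ev, "max_eV": summ.max_ev,
                "state_indices": list(summ.state_indices),
                "snapshots_without_ct": list(summ.snapshots_without_ct),
                "per_snapshot_min_eV": summ.per_snapshot_min_ev,
            }
            assigns = [
                CTAssignment(r.snapshot_id, r.energy_ev,
                             r.ct_direction.split("->")[0], r.ct_direction.split("->")[1])
                for r in recs if r.assigned_class == "pure_CT"
            ]
            if assigns and len({a.pair for a in assigns}) == 1:
                first = sorted(pair.split("/"))
                order = tuple(pair.split("/")) if "/" in pair else (first[0], first[1])
                signs, flips = ct_direction_series(assigns, pair_order=order)
                entry["direction_signs"] = signs
                entry["direction_flips"] = flips
            report[pair] = entry
        f = out / "ct_summary.json"
        f.write_text(json.dumps(report, indent=2))
        return [f]

    if stage == "tune":
        recs = (load_scan(cfg.tuning_table) if cfg.tuning_table
                else tables.tuning_scan("BChl"))
        best = select_omega(recs)
        f = out / "tuning.json"
        f.write_text(json.dumps({"selected_omega": best,
                                 "n_records": len(recs)}, indent=2))
        return [f]

    raise ValueError(f"unknown stage {stage!r}")


def config_to_yaml(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["stages"] = list(d["stages"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
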