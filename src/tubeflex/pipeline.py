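"""End-to-end pipeline orchestration with a single seeded config.

A run config is one JSON document with a root seed, the list of enabled
stages, and per-stage parameter blocks mirroring the module options.  Stages
execute in dependency order (synth -> relax -> assemble -> bend -> map); all
randomness derives from the root seed through fixed per-stage offsets, so a
rerun with the same config is bit-identical for every deterministic stage.
Each run writes a manifest recording the config, package versions, and a
SHA-256 hash of every output file.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import assembly as asm
from . import bent, density, io, relaxation, synthetic

__all__ = ["RunConfig", "DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger("tubeflex")

STAGES = ("synth", "relax", "assemble", "bend", "map")

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "tubeflex_run",
    "stages": list(STAGES),
    "synth": {
        "n_atoms": 48, "extent": 28.0,
        "n_residues": 10, "k_ex": 2000.0, "noise_sigma": 0.05,
        "amplitude": 1.0, "r1": 0.5,
    },
    "relax": {"n_mc": 250, "n_rate_mc": 200},
    # the tube's optimised helical symmetry
    "symmetry": {"c_sym": 6, "rise": 38.46, "twist": 21.89},
    "assembly": {"n_rings": 2},
    "restraints": {"upper_bound": 7.0},
    "bend": {"curvature_radius": 655.0, "tube_diameter": 63.3,
             "inner_spacing": 38.5, "n_rings": 10, "n_pairs": 400,
             "tolerance": 0.5},
    "map": {"voxel": 2.0, "atom_sigma": 2.5, "threshold": 0.162,
            "n_members": 8, "n_boot": 50, "jitter": 1.5,
            "lowpass": 8.0, "smooth_sigma": 2.0, "fsc_criterion": 0.143},
}


@dataclass
class RunConfig:
    """A validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    seed: int = 1
    outdir: str = "tubeflex_run"
    stages: list = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = copy.deepcopy(d)
        return cls(seed=d.pop("seed", 1), outdir=d.pop("outdir", "tubeflex_run"),
                   stages=d.pop("stages", list(STAGES)), params=d)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "outdir": self.outdir,
               "stages": list(self.stages)}
        out.update(copy.deepcopy(self.params))
        return out

    @classmethod
    def default(cls) -> "RunConfig":
        return cls.from_dict(DEFAULT_CONFIG)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path):
        io.write_json(self.to_dict(), path)

    def block(self, stage: str) -> dict:
        merged = copy.deepcopy(DEFAULT_CONFIG.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    def stage_seed(self, stage: str) -> int:
        # deterministic per-stage seed derived from the root seed
        return (self.seed * 1000003 + STAGES.index(stage) + 1) % (2**31)


def validate_config(config) -> list:
    """Return a list of violations (empty = valid).  Never mutates config."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    problems = []
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        problems.append("RunConfig.seed: must be a non-negative integer")
    for stage in cfg.stages:
        if stage not in STAGES:
            problems.append(f"RunConfig.stages: unknown stage {stage!r}")
    sym = cfg.block("symmetry")
    if sym["rise"] <= 0:
        problems.append("SymmetryParams.rise: must be positive")
    if sym["c_sym"] < 1:
        problems.append("SymmetryParams.c_sym: must be at least 1")
    syn = cfg.block("synth")
    if syn["n_atoms"] < 4:
        problems.append("synth.n_atoms: must be at least 4")
    if syn["k_ex"] <= 0:
        problems.append("synth.k_ex: must be positive")
    if syn["noise_sigma"] < 0:
        problems.append("NoiseSpec.sigma: must be non-negative")
    bd = cfg.block("bend")
    if bd["curvature_radius"] <= bd["tube_diameter"] / 2:
        problems.append("BentGeometry.curvature_radius: must exceed the tube "
                        "radius")
    if bd["inner_spacing"] <= 0:
        problems.append("BentGeometry.inner_spacing: must be positive")
    mp = cfg.block("map")
    if mp["voxel"] <= 0:
        problems.append("DensityMap.voxel_size: must be positive")
    if mp["n_boot"] < 2:
        problems.append("map.n_boot: must be at least 2")
    if not 0 < mp["fsc_criterion"] < 1:
        problems.append("map.fsc_criterion: must be in (0, 1)")
    rx = cfg.block("relax")
    if rx["n_mc"] < 2:
        problems.append("relax.n_mc: must be at least 2")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    results: dict = {}

    def emit(name):
        outputs.append(outdir / name)
        return outdir / name

    state: dict = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, state, results, emit)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": cfg.to_dict(),
        "versions": {"tubeflex": __version__, "numpy": np.__version__},
        "results": results,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _stage_synth(cfg, state, results, emit):
    p = cfg.block("synth")
    seed = cfg.stage_seed("synth")
    monomer = synthetic.make_monomer(p["n_atoms"], p["extent"], seed)
    state["monomer"] = monomer
    io.write_structure(emit("monomer.pdb"), monomer)

    rng = np.random.default_rng(seed + 1)
    residues = [f"res{i}" for i in range(p["n_residues"])]
    rates = {r: p["r1"] * (0.5 + rng.uniform()) for r in residues}
    decays = synthetic.make_decay_table(
        rates, amplitude=p["amplitude"],
        noise=synthetic.NoiseSpec(p["noise_sigma"] * p["amplitude"], seed + 2))
    io.decays_to_frame(decays).to_csv(emit("decays.csv"), index=False)
    state["decays"] = decays

    phi = {r: float(2e7 * (0.5 + rng.uniform())) for r in residues}
    r0 = {r: float(8.0 + 10.0 * rng.uniform()) for r in residues}
    sigma = p["noise_sigma"] * np.mean(list(r0.values()))
    ds = synthetic.make_dispersion_dataset(
        p["k_ex"], phi, r0, noise=synthetic.NoiseSpec(sigma, seed + 3))
    io.profiles_to_frame(ds.profiles).to_csv(emit("profiles.csv"), index=False)
    io.write_json({"k_ex": ds.k_ex, "phi_ex": ds.phi_ex, "r1rho0": ds.r1rho0,
                   "sigma": ds.sigma, "rates": rates},
                  emit("synth_params.json"))
    state["dispersion"] = ds
    results["synth"] = {"n_atoms": monomer.n_atoms,
                        "n_residues": len(residues)}


def _stage_relax(cfg, state, results, emit):
    p = cfg.block("relax")
    seed = cfg.stage_seed("relax")
    decays = state.get("decays")
    if decays is None:
        raise ValueError("relax stage needs the synth stage (or input tables)")
    rates = relaxation.estimate_rate_errors(decays, n_repeats=p["n_rate_mc"],
                                            seed=seed)
    import pandas as pd

    pd.DataFrame([{"residue": r.residue, "rate": r.rate,
                   "rate_err": r.rate_err, "kind": r.kind,
                   "converged": r.converged} for r in rates]
                 ).to_csv(emit("rates.csv"), index=False)

    fit = relaxation.fit_dispersion_global(state["dispersion"].profiles)
    fit = relaxation.monte_carlo_errors(fit, state["dispersion"].profiles,
                                        n_repeats=p["n_mc"], seed=seed + 1)
    io.write_json(io.dispersion_results_to_dict(fit), emit("dispersion_fit.json"))
    results["relax"] = {"k_ex": fit.k_ex, "k_ex_err": fit.k_ex_err,
                        "chi2": fit.chi2}


def _stage_assemble(cfg, state, results, emit):
    sym = cfg.block("symmetry")
    p = cfg.block("assembly")
    monomer = state.get("monomer") or synthetic.make_monomer(
        cfg.block("synth")["n_atoms"], cfg.block("synth")["extent"],
        cfg.stage_seed("synth"))
    params = asm.SymmetryParams(sym["c_sym"], sym["rise"], sym["twist"])
    assembly = asm.build_assembly(monomer, params, p["n_rings"])
    state["assembly"] = assembly
    io.write_structure(emit("assembly.pdb"), monomer, assembly)

    bound = cfg.block("restraints")["upper_bound"]
    restraint = asm.expand_restraint(monomer.labels[0], monomer.labels[-1],
                                     assembly, upper_bound=bound)
    report = asm.check_violations([restraint], assembly)
    results["assemble"] = {
        "n_subunits": assembly.n_subunits,
        "n_candidates": len(restraint.candidates),
        "effective_distance": asm.effective_distance(restraint, assembly),
        "n_violated": report.n_violated,
    }


def _stage_bend(cfg, state, results, emit):
    p = cfg.block("bend")
    seed = cfg.stage_seed("bend")
    geometry = bent.compute_bend_geometry(p["curvature_radius"],
                                          p["tube_diameter"],
                                          p["inner_spacing"])
    assembly = state.get("assembly")
    if assembly is None:
        raise ValueError("bend stage needs the assemble stage")
    one_ring = asm.build_assembly(assembly.monomer, assembly.params, 1)
    ring = bent.ring_from_assembly(one_ring)
    # centre the ring radially so it fits inside the arc
    ring.positions = ring.positions - ring.positions.mean(axis=0)
    straight = bent.build_straight_tube(ring, p["inner_spacing"], p["n_rings"])
    bent_model = bent.build_bent_tube(ring, geometry, p["n_rings"])
    network = bent.make_restraint_network(straight, p["n_pairs"], seed)
    scores = bent.score_restraint_fulfilment(bent_model, network,
                                             tolerance=p["tolerance"])
    scores.to_csv(emit("fulfilment.csv"), header=True)
    results["bend"] = {
        "bend_angle_deg": geometry.bend_angle_deg,
        "inner_radius": geometry.inner_radius,
        "outer_radius": geometry.outer_radius,
        "outer_spacing_arc": geometry.outer_spacing,
        "mean_fulfilment": float(scores.dropna().mean()),
    }


def _stage_map(cfg, state, results, emit):
    p = cfg.block("map")
    seed = cfg.stage_seed("map")
    monomer = state.get("monomer") or synthetic.make_monomer(
        cfg.block("synth")["n_atoms"], cfg.block("synth")["extent"],
        cfg.stage_seed("synth"))
    halves = synthetic.make_half_maps(monomer, p["voxel"],
                                      noise_sigma=0.02, n_replicates=2,
                                      seed=seed, atom_sigma=p["atom_sigma"])
    curve = density.compute_fsc(*halves)
    curve.to_frame().to_csv(emit("fsc.csv"), index=False)
    fit = density.fit_fsc_sigmoid(curve)
    try:
        res = density.resolution_at(fit, p["fsc_criterion"])
    except ValueError:
        res = None

    n = monomer.n_atoms
    members = synthetic.make_half_maps(
        monomer, p["voxel"], noise_sigma=0.0, jitter=p["jitter"],
        n_replicates=p["n_members"], seed=seed + 1,
        jitter_selection=np.arange(max(n // 4, 1)),
        atom_sigma=p["atom_sigma"])
    boots = density.bootstrap_replicates(members, n_boot=p["n_boot"],
                                         seed=seed + 2)
    var = density.isosurface_variance(boots, threshold=p["threshold"],
                                      lowpass=p["lowpass"],
                                      smooth_sigma=p["smooth_sigma"])
    density.write_mrc(var, emit("isosurface_variance.mrc"))
    results["map"] = {
        "fsc_fit": {"A": fit.A, "B": fit.B, "C": fit.C},
        "resolution_A": res,
        "variance_max": float(var.grid.max()),
    }


_STAGE_FUNCS = {"synth": _stage_synth, "relax": _stage_relax,
                "assemble": _stage_assemble, "bend": _stage_bend,
                "map": _stage_map}
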