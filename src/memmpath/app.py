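"""Pipeline driver, configuration, serialization and format adapters.

The end-to-end stage order mirrors how a conformational-transition study is
analyzed: simulate/ingest trajectories -> featurize -> TICA -> k-means
microstates -> TRAM -> PCCA+ macrostates -> kinetics (optionally with
bootstrap error bars) -> dynamic-network residue scoring, plus a band (NEB)
optimization stage on the energy model.  Every stage reads only the
serialized outputs of its upstream stages inside the run directory, so each
is runnable standalone (that is what the CLI subcommands do); a manifest
records the config hash, per-stage output checksums and timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import featspace, kinetics, macro, memm, microstates, netscore, pathopt, toysim

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "read_trajectory",
    "write_reports",
    "save_trajectory_set",
    "load_trajectory_set",
    "demo_config",
    "STAGES",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Strict):
    potential: str = "tilted_double_well_1d"
    params: dict = Field(default_factory=dict)
    kT: float = 1.0
    diffusion: float = 1.0
    dt: float = 0.005
    save_stride: int = 10
    n_unbiased: int = 2
    unbiased_steps: int = 50_000
    umbrella_centers: list[float] = Field(
        default_factory=lambda: [round(x, 3) for x in
                                 np.linspace(-1.3, 1.3, 8)]
    )
    umbrella_force_constant: float = 15.0
    umbrella_steps: int = 50_000


class FeaturizeBlock(_Strict):
    lag: int = 10
    n_components: int = 1
    reg: float = 1e-10


class MicrostatesBlock(_Strict):
    k: int = 30
    max_iter: int = 300
    tol: float = 1e-8


class MemmBlock(_Strict):
    lag: int = 10
    tol: float = 1e-8
    max_iter: int = 100_000
    fes_bins: int = 40


class MacroBlock(_Strict):
    m: int = 2


class KineticsBlock(_Strict):
    frame_time: float = 1.0     # physical time per saved frame
    units: str = "steps"
    bootstrap_samples: int = 0
    percentiles: tuple[float, float] = (5.0, 95.0)


class NetscoreBlock(_Strict):
    enabled: bool = True
    n_nodes: int = 40
    n_frames: int = 2000
    noise: float = 0.5
    contact_cutoff: float = 5.0
    persistence_threshold: float = 0.75
    dilation: float = 1.0
    max_paths: int = 150_000
    top_k: int = 16


class PathoptBlock(_Strict):
    enabled: bool = True
    n_replicas: int = 16
    cycles: int = 3
    stage_steps: int = 150
    dt: float = 2e-4
    convergence_threshold: float = 0.3


class PipelineConfig(_Strict):
    """Per-stage parameter blocks plus a mandatory global seed."""

    seed: int
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    featurize: FeaturizeBlock = Field(default_factory=FeaturizeBlock)
    microstates: MicrostatesBlock = Field(default_factory=MicrostatesBlock)
    memm: MemmBlock = Field(default_factory=MemmBlock)
    macro: MacroBlock = Field(default_factory=MacroBlock)
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    netscore: NetscoreBlock = Field(default_factory=NetscoreBlock)
    pathopt: PathoptBlock = Field(default_factory=PathoptBlock)

    @classmethod
    def from_json(cls, path):
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path=None):
        text = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def demo_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Small double-well demo configuration (runs in about a minute)."""
    return PipelineConfig(seed=seed).model_copy(update=overrides)


class RunManifest(BaseModel):
    config_hash: str
    version: str
    stages: dict = Field(default_factory=dict)
    warnings: list = Field(default_factory=list)

    def record(self, stage, files, t0, **extra):
        checks = {}
        for f in files:
            p = Path(f)
            checks[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages[stage] = {
            "outputs": checks,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            **extra,
        }


# ---------------------------------------------------------------------------
# Serialization / adapters
# ---------------------------------------------------------------------------

def _write_npz(path, meta: dict, **arrays):
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _read_npz(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    return meta, arrays


def save_trajectory_set(ts: toysim.TrajectorySet, path):
    """Portable array container (.npz) with a JSON metadata block."""
    meta = {"trajectories": [], "biases": []}
    arrays = {}
    for i, tr in enumerate(ts.trajectories):
        arrays[f"traj_{i}"] = tr.frames
        meta["trajectories"].append({
            "ensemble": int(tr.ensemble), "dt": float(tr.dt),
            "seed": None if tr.seed is None else int(tr.seed),
        })
    for b in ts.biases:
        meta["biases"].append({
            "kind": b.kind, "center": float(b.center),
            "force_constant": float(b.force_constant),
        })
    _write_npz(path, meta, **arrays)


def load_trajectory_set(path) -> toysim.TrajectorySet:
    meta, arrays = _read_npz(path)
    trajs = [
        toysim.Trajectory(arrays[f"traj_{i}"], ensemble=tm["ensemble"],
                          dt=tm["dt"], seed=tm["seed"])
        for i, tm in enumerate(meta["trajectories"])
    ]
    biases = [
        toysim.BiasSpec(b["kind"], center=b["center"],
                        force_constant=b["force_constant"])
        for b in meta["biases"]
    ]
    return toysim.TrajectorySet(trajs, biases)


def export_trajectory_csv(ts: toysim.TrajectorySet, path):
    rows = []
    for i, tr in enumerate(ts.trajectories):
        for t, x in enumerate(tr.frames):
            rows.append([i, tr.ensemble, t, *x])
    d = ts.trajectories[0].frames.shape[1]
    cols = ["trajectory", "ensemble", "frame"] + [f"x{j}" for j in range(d)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_trajectory(path, topology_path=None) -> toysim.TrajectorySet:
    """Load trajectories from the native container or an MD format.

    Standard MD formats (multi-model PDB, DCD, XTC, ...) go through mdtraj;
    coordinates are reduced to one representative point per residue
    (backbone phosphorus for nucleotides, C-alpha for amino acids) and
    returned as a single-ensemble TrajectorySet in Angstrom.
    """
    path = Path(path)
    if path.suffix == ".npz":
        return load_trajectory_set(path)
    import mdtraj

    if topology_path is not None:
        top = mdtraj.load_topology(str(topology_path))
        traj = mdtraj.load(str(path), top=str(topology_path))
        if traj.n_atoms != top.n_atoms:
            raise ValueError(
                f"trajectory has {traj.n_atoms} atoms, topology {top.n_atoms}"
            )
    else:
        traj = mdtraj.load(str(path))
    idx = []
    for res in traj.topology.residues:
        sel = [a.index for a in res.atoms if a.name == "P"]
        if not sel:
            sel = [a.index for a in res.atoms if a.name == "CA"]
        if sel:
            idx.append(sel[0])
    coords = traj.xyz[:, idx, :] * 10.0        # nm -> Angstrom
    flat = coords.reshape(len(coords), -1)
    tr = toysim.Trajectory(flat, ensemble=0, dt=1.0)
    return toysim.TrajectorySet([tr], [toysim.NULL_BIAS])


def write_reports(outdir, fes=None, kinetic_model=None, scores=None,
                  float_fmt: str = "%.6g"):
    """Stable-schema CSV/TSV exports of the main stage outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    if fes is not None:
        tab = fes.to_table()
        df = pd.DataFrame(tab if len(tab) else None,
                          columns=["ic1", "ic2", "delta_g"])
        f = outdir / "free_energy_surface.csv"
        df.to_csv(f, index=False, float_format=float_fmt)
        files.append(f)
    if kinetic_model is not None:
        df = pd.DataFrame(kinetic_model.to_records(),
                          columns=["source", "target", "mfpt", "lo", "hi",
                                   "units"])
        f = outdir / "kinetic_model.tsv"
        df.to_csv(f, sep="\t", index=False, float_format=float_fmt)
        files.append(f)
    if scores is not None:
        f = outdir / "residue_scores.tsv"
        scores.to_csv(f, sep="\t", index=False, float_format=float_fmt)
        files.append(f)
    return files


# ---------------------------------------------------------------------------
# Stages (each reads upstream artifacts from the run directory)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path):
    sb = cfg.simulate
    pot = toysim.make_potential(sb.potential, **sb.params)
    unb = toysim.simulate_langevin_batch(
        pot, [toysim.NULL_BIAS] * sb.n_unbiased,
        np.tile(np.asarray(pot.minima[0], dtype=float), (sb.n_unbiased, 1)),
        sb.unbiased_steps, sb.dt, sb.kT, sb.diffusion, cfg.seed,
        save_stride=sb.save_stride, ensembles=[0] * sb.n_unbiased,
    )
    umb = toysim.generate_umbrella_ensembles(
        pot, sb.umbrella_centers, sb.umbrella_force_constant,
        sb.umbrella_steps, sb.dt, sb.kT, cfg.seed + 1,
        diffusion=sb.diffusion, save_stride=sb.save_stride,
    )
    ts = unb.extend(umb)
    f = outdir / "trajectories.npz"
    save_trajectory_set(ts, f)
    return [f]


def stage_featurize(cfg: PipelineConfig, outdir: Path):
    """Feature extraction; for scalar toy coordinates the features are the
    coordinates themselves, for multi-point systems inter-point distances."""
    ts = load_trajectory_set(outdir / "trajectories.npz")
    arrays = {}
    meta = {"ensembles": [tr.ensemble for tr in ts.trajectories]}
    for i, tr in enumerate(ts.trajectories):
        arrays[f"feat_{i}"] = tr.frames
    f = outdir / "features.npz"
    _write_npz(f, meta, **arrays)
    return [f]


def stage_tica(cfg: PipelineConfig, outdir: Path):
    meta, arrays = _read_npz(outdir / "features.npz")
    feats = [arrays[f"feat_{i}"] for i in range(len(meta["ensembles"]))]
    fb = cfg.featurize
    model = featspace.estimate_tica(feats, lag=fb.lag,
                                    n_components=fb.n_components, reg=fb.reg)
    ics = featspace.project(feats, model)
    f = outdir / "ics.npz"
    _write_npz(f, {
        "ensembles": meta["ensembles"], "lag": fb.lag,
        "eigenvalues": [float(v) for v in model.eigenvalues],
    }, mean=model.mean, components=model.components,
        **{f"ic_{i}": x for i, x in enumerate(ics)})
    return [f]


def stage_cluster(cfg: PipelineConfig, outdir: Path):
    meta, arrays = _read_npz(outdir / "ics.npz")
    ics = [arrays[f"ic_{i}"] for i in range(len(meta["ensembles"]))]
    kb = cfg.microstates
    pooled = np.concatenate(ics)
    n_distinct = len(np.unique(pooled, axis=0))
    if kb.k > n_distinct:
        raise ValueError(
            f"microstates.k = {kb.k} exceeds {n_distinct} distinct frames"
        )
    disc = microstates.kmeans_cluster(ics, kb.k, seed=cfg.seed,
                                      max_iter=kb.max_iter, tol=kb.tol)
    f = outdir / "discretization.npz"
    _write_npz(f, {
        "ensembles": meta["ensembles"], "k": kb.k, "seed": cfg.seed,
        "inertia": disc.inertia,
    }, centers=disc.centers,
        **{f"dtraj_{i}": d for i, d in enumerate(disc.dtrajs)})
    return [f]


def stage_tram(cfg: PipelineConfig, outdir: Path):
    ts = load_trajectory_set(outdir / "trajectories.npz")
    meta, arrays = _read_npz(outdir / "discretization.npz")
    dts = toysim.DiscreteTrajectorySet(
        [arrays[f"dtraj_{i}"] for i in range(len(meta["ensembles"]))],
        meta["ensembles"], meta["k"],
    )
    mb = cfg.memm
    cnt = microstates.count_transitions(dts, mb.lag)
    bias_tab = memm.evaluate_bias_energies(ts, kT=cfg.simulate.kT)
    model = memm.estimate_tram(cnt, dts, bias_tab, tol=mb.tol,
                               max_iter=mb.max_iter)
    sub, T0 = model.unbiased_transition_matrix()
    f = outdir / "memm.npz"
    _write_npz(f, {
        "lag": mb.lag, "converged": bool(model.converged),
        "n_iter": int(model.n_iter), "residual": float(model.residual),
    }, active_set=model.active_set, f=model.f, f_k=model.f_k,
        sub0=sub, T0=T0,
        **{f"logmu_{i}": lm for i, lm in enumerate(model.log_mu)})
    # free-energy surface over the IC coordinates
    _, ic_arrays = _read_npz(outdir / "ics.npz")
    ics = np.concatenate([
        ic_arrays[f"ic_{i}"] for i in range(len(meta["ensembles"]))
    ])
    weights = np.concatenate(model.frame_weights())
    fes = memm.free_energy_surface(ics, weights, bins=mb.fes_bins,
                                   kT=cfg.simulate.kT)
    files = write_reports(outdir, fes=fes)
    return [f] + files


def _load_memm_kinetics(outdir):
    meta, arrays = _read_npz(outdir / "memm.npz")
    f = arrays["f"]
    pi_full = np.exp(-f)
    pi_full /= pi_full.sum()
    sub, T0 = arrays["sub0"], arrays["T0"]
    pi = pi_full[sub] / pi_full[sub].sum()
    return meta, arrays, T0, pi, sub


def stage_pcca(cfg: PipelineConfig, outdir: Path):
    meta, arrays, T0, pi, sub = _load_memm_kinetics(outdir)
    mac = macro.pcca(T0, pi, cfg.macro.m)
    f = outdir / "macrostates.npz"
    _write_npz(f, {
        "m": cfg.macro.m,
        "populations": [float(p) for p in mac.populations],
    }, memberships=mac.memberships, labels=mac.labels,
        populations=mac.populations)
    return [f]


def stage_kinetics(cfg: PipelineConfig, outdir: Path):
    meta, arrays, T0, pi, sub = _load_memm_kinetics(outdir)
    mmeta, marrays = _read_npz(outdir / "macrostates.npz")
    mac = macro.MacrostateModel(
        memberships=marrays["memberships"], labels=marrays["labels"],
        populations=marrays["populations"], m=mmeta["m"],
    )
    kb = cfg.kinetics
    lag_time = kb.frame_time * meta["lag"]
    pairs, vals = kinetics.macrostate_mfpts(T0, pi, mac.labels, mac.m,
                                            lag_time)
    km = kinetics.KineticModel(pairs=pairs, mfpts=vals, units=kb.units,
                               macrostates=mac)
    if kb.bootstrap_samples >= 2:
        ts = load_trajectory_set(outdir / "trajectories.npz")
        dmeta, darrays = _read_npz(outdir / "discretization.npz")
        dts = toysim.DiscreteTrajectorySet(
            [darrays[f"dtraj_{i}"] for i in range(len(dmeta["ensembles"]))],
            dmeta["ensembles"], dmeta["k"],
        )
        bias_tab = memm.evaluate_bias_energies(ts, kT=cfg.simulate.kT)
        unb_ids = [i for i, tr in enumerate(ts.trajectories)
                   if ts.biases[tr.ensemble].kind == "none"]
        bia_ids = [i for i in range(len(ts.trajectories))
                   if i not in unb_ids]
        g = kinetics.mean_statistical_inefficiency(
            dts, ensembles={dts.ensembles[i] for i in bia_ids} or None
        )
        res = kinetics.bootstrap_kinetics(
            dts, bias_tab.tables, unb_ids, bia_ids,
            kinetics.EstimatorConfig(lag=meta["lag"], lag_time=lag_time,
                                     n_macrostates=cfg.macro.m),
            kinetics.BootstrapSpec(kb.bootstrap_samples,
                                   min_block_length=max(1.0, g),
                                   percentiles=kb.percentiles,
                                   seed=cfg.seed + 2),
        )
        km.lo = np.array([
            res["quantities"].get(p, {}).get("lo", np.nan) for p in pairs
        ])
        km.hi = np.array([
            res["quantities"].get(p, {}).get("hi", np.nan) for p in pairs
        ])
    return write_reports(outdir, kinetic_model=km)


def stage_netscore(cfg: PipelineConfig, outdir: Path):
    nb = cfg.netscore
    n_bb = max(4, nb.n_nodes // 6)
    comm = np.zeros(nb.n_nodes, dtype=int)
    rest = np.arange(n_bb, nb.n_nodes)
    comm[rest] = 1 + (rest - n_bb) % 2
    fx = toysim.generate_network_fixture(
        nb.n_nodes, comm, list(range(n_bb)), nb.noise, nb.n_frames,
        cfg.seed + 3, contact_cutoff=nb.contact_cutoff,
    )
    g = netscore.build_network(fx.frames, nb.contact_cutoff,
                               nb.persistence_threshold)
    ps = netscore.suboptimal_paths(g, fx.source, fx.sink, nb.dilation,
                                   nb.max_paths)
    usage = netscore.node_usage([ps], nodes=range(nb.n_nodes))
    pers = netscore.contact_persistence(
        [fx.frames], list(range(nb.n_nodes)), list(range(n_bb)),
        nb.contact_cutoff,
    )
    scores = netscore.combined_score(usage, fx.conservation, pers,
                                     top_k=nb.top_k)
    return write_reports(outdir, scores=scores)


def stage_neb(cfg: PipelineConfig, outdir: Path):
    pb = cfg.pathopt
    pot = toysim.make_potential(cfg.simulate.potential, **cfg.simulate.params)
    start = np.asarray(pot.minima[0], dtype=float)
    end = np.asarray(pot.minima[-1], dtype=float)
    band = pathopt.initialize_band(start, end, pb.n_replicas)
    band = pathopt.optimize_band(
        band, pot, pathopt.default_schedule(pb.stage_steps),
        dt=pb.dt, seed=cfg.seed + 4, n_cycles=pb.cycles,
    )
    df = pd.DataFrame(band.replicas,
                      columns=[f"x{j}" for j in range(band.replicas.shape[1])])
    df.insert(0, "replica", np.arange(len(df)))
    df["energy"] = band.energies
    f = outdir / "band.csv"
    df.to_csv(f, index=False)
    hist = outdir / "band_history.json"
    hist.write_text(json.dumps(band.history, indent=2))
    return [f, hist]


STAGES = [
    ("simulate", stage_simulate),
    ("featurize", stage_featurize),
    ("tica", stage_tica),
    ("cluster", stage_cluster),
    ("tram", stage_tram),
    ("pcca", stage_pcca),
    ("kinetics", stage_kinetics),
    ("netscore", stage_netscore),
    ("neb", stage_neb),
]


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute all configured stages in dependency order.

    A stage failure aborts with the stage name attached; the partial
    manifest written so far stays on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.to_json(outdir / "config.json")
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=_version(),
    )
    for name, fn in STAGES:
        if name == "netscore" and not config.netscore.enabled:
            continue
        if name == "neb" and not config.pathopt.enabled:
            continue
        t0 = time.perf_counter()
        try:
            files = fn(config, outdir)
        except Exception as err:
            (outdir / "manifest.json").write_text(
                manifest.model_dump_json(indent=2)
            )
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest.record(name, files, t0)
        (outdir / "manifest.json").write_text(
            manifest.model_dump_json(indent=2)
        )
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("memmpath")
    except Exception:
        return "unknown"
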