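"""Enumerate and execute a full rigid-residue scan, then aggregate reports.

A scan is: one unperturbed simulation per state plus one simulation per
(state, residue) pair with that residue held rigid — ``states × residues``
perturbed runs in total.  The manifest records durations in ns (the study
design: 210 ns unperturbed, 30 ns per perturbed run, 4 ns equilibration
discarded), a per-run seed derived deterministically from one master seed,
and stable run ids.  ``run_scan`` executes the manifest against the built-in
elastic-network simulator at a configurable frames-per-run scale (frame
counts proportional to nominal durations), storing each run as a frame
archive plus JSON metadata so a scan is resumable and auditable.

``aggregate_report`` materializes the downstream analysis stack over a run
store: dual-reference 2D RMSD landscape, k-means clustering with occupancy /
representatives / state-dominance groups, per-residue perturbation-effect
classification, whole-protein and per-residue configurational entropies with
relative tables, and PCA/KDE projections.  Every artifact is stamped with the
manifest hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import correlation_entropy as ce
from . import landscape_clustering as lc
from . import pca_projection as pca
from . import superposition as sup
from .errors import ConfigError, InputError, StabilityError
from .model_io import Ensemble, read_trajectory, write_trajectory
from .synthetic_data import ElasticNetworkModel, RigidConstraint, simulate_langevin

__all__ = [
    "RunSpec",
    "ScanManifest",
    "RunStore",
    "ReportBundle",
    "build_manifest",
    "total_production_time",
    "run_scan",
    "aggregate_report",
]


@dataclass(frozen=True)
class RunSpec:
    """One manifest entry: a single production simulation."""

    run_id: str
    state: str
    perturbation: int | None  # rigid residue id, or None for unperturbed
    duration_ns: float  # production time (equilibration excluded)
    equilibration_ns: float
    seed: int


@dataclass(frozen=True)
class ScanManifest:
    """Deterministic enumeration of every run in a rigid-residue scan."""

    states: tuple[str, ...]
    residues: tuple[int, ...]
    unperturbed_ns: float
    rrs_ns: float
    equilibration_ns: float
    master_seed: int
    runs: tuple[RunSpec, ...]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def hash(self) -> str:
        payload = json.dumps(
            [asdict(r) for r in self.runs], sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def build_manifest(config: Mapping) -> ScanManifest:
    """Build a scan manifest from a config mapping.

    Keys: ``states`` (list of labels), ``residues`` (list of ids or
    ``[first, last]`` range via ``residue_range``), ``unperturbed_ns``
    (default 210), ``rrs_ns`` (default 30), ``equilibration_ns`` (default 4),
    ``seed`` (default 0).  Per-run seeds derive from the master seed through
    a spawned seed sequence.
    """
    states = tuple(config.get("states", ("synthetic-A", "synthetic-B")))
    if "residues" in config:
        residues = tuple(int(r) for r in config["residues"])
    elif "residue_range" in config:
        first, last = config["residue_range"]
        residues = tuple(range(int(first), int(last) + 1))
    else:
        raise ConfigError("config must define 'residues' or 'residue_range'")
    unperturbed_ns = float(config.get("unperturbed_ns", 210.0))
    rrs_ns = float(config.get("rrs_ns", 30.0))
    equil_ns = float(config.get("equilibration_ns", 4.0))
    master_seed = int(config.get("seed", 0))
    if not states or len(set(states)) != len(states):
        raise ConfigError("states must be non-empty and unique")
    if len(set(residues)) != len(residues):
        raise ConfigError("duplicate residues produce overlapping run ids")
    if unperturbed_ns <= 0 or rrs_ns <= 0:
        raise ConfigError("durations must be positive")
    if equil_ns < 0 or equil_ns >= min(unperturbed_ns, rrs_ns):
        raise ConfigError("equilibration must be ≥ 0 and shorter than every run")

    entries: list[tuple[str, int | None, float]] = []
    for state in states:
        entries.append((state, None, unperturbed_ns))
    for state in states:
        for res in residues:
            entries.append((state, res, rrs_ns))
    children = np.random.SeedSequence(master_seed).spawn(len(entries))
    runs = []
    for (state, pert, dur), child in zip(entries, children):
        seed = int(child.generate_state(1)[0] % 2**31)
        run_id = (
            f"{state}-unperturbed" if pert is None else f"{state}-rigid{pert:03d}"
        )
        runs.append(
            RunSpec(
                run_id=run_id,
                state=state,
                perturbation=pert,
                duration_ns=dur,
                equilibration_ns=equil_ns,
                seed=seed,
            )
        )
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ConfigError("overlapping run ids in manifest")
    return ScanManifest(
        states=states,
        residues=residues,
        unperturbed_ns=unperturbed_ns,
        rrs_ns=rrs_ns,
        equilibration_ns=equil_ns,
        master_seed=master_seed,
        runs=tuple(runs),
    )


def total_production_time(manifest: ScanManifest) -> float:
    """Total production simulation time over the manifest, ns."""
    return float(sum(r.duration_ns for r in manifest.runs))


class RunStore:
    """Completed runs of a scan: ensembles plus per-run metadata.

    With a directory, each run lives in ``<dir>/<run_id>/`` as a frame
    archive plus ``meta.json``; without one, runs are held in memory.
    """

    def __init__(self, directory: str | Path | None = None, topology=None):
        self.directory = Path(directory) if directory is not None else None
        self._topology = topology
        self._ensembles: dict[str, Ensemble] = {}
        self.metadata: dict[str, dict] = {}
        self.failures: dict[str, str] = {}
        self.manifest: ScanManifest | None = None

    def add(self, run: RunSpec, ensemble: Ensemble, extra: dict | None = None) -> None:
        meta = {**asdict(run), "n_frames": ensemble.n_frames, **(extra or {})}
        self._ensembles[run.run_id] = ensemble
        self.metadata[run.run_id] = meta
        if self.directory is not None:
            rd = self.directory / run.run_id
            rd.mkdir(parents=True, exist_ok=True)
            write_trajectory(ensemble, rd / "frames.traj")
            (rd / "meta.json").write_text(json.dumps(meta, indent=1))

    def has(self, run_id: str) -> bool:
        if run_id in self._ensembles:
            return True
        if self.directory is not None:
            rd = self.directory / run_id
            return (rd / "frames.traj").exists() and (rd / "meta.json").exists()
        return False

    def ensemble(self, run_id: str) -> Ensemble:
        if run_id not in self._ensembles and self.directory is not None:
            rd = self.directory / run_id
            meta = json.loads((rd / "meta.json").read_text())
            self.metadata[run_id] = meta
            self._ensembles[run_id] = read_trajectory(
                rd / "frames.traj",
                topology=self._topology,
                state_label=meta["state"],
                perturbation=meta["perturbation"],
                run_id=run_id,
            )
        return self._ensembles[run_id]

    def ensembles(self) -> dict[str, Ensemble]:
        return {rid: self.ensemble(rid) for rid in sorted(self.metadata)}

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.metadata)


def run_scan(
    manifest: ScanManifest,
    model: ElasticNetworkModel,
    frames_per_run: int = 1000,
    save_every: int = 50,
    store_dir: str | Path | None = None,
    resume: bool = True,
) -> RunStore:
    """Execute every manifest entry with the elastic-network simulator.

    ``frames_per_run`` is the frame count of a perturbed run; other durations
    scale proportionally (an unperturbed run of 210 ns at ``rrs_ns=30`` gets
    7× the frames).  Equilibration steps, in the manifest's ns proportion,
    are simulated and discarded before the first saved frame.  Unstable runs
    are recorded as failures and the scan continues.
    """
    missing = [r for r in manifest.residues if r not in model.topology.residue_ids]
    if missing:
        raise ConfigError(f"model lacks manifest residues {missing}")
    store = RunStore(store_dir)
    store._topology = model.topology
    for run in manifest.runs:
        if resume and store.has(run.run_id):
            store.ensemble(run.run_id)  # load for completeness
            continue
        frames = int(round(frames_per_run * run.duration_ns / manifest.rrs_ns))
        n_steps = frames * save_every
        n_equil = int(round(n_steps * run.equilibration_ns / run.duration_ns))
        constraint = (
            None if run.perturbation is None else RigidConstraint(run.perturbation)
        )
        try:
            ens = simulate_langevin(
                model,
                state=run.state,
                n_steps=n_steps,
                save_every=save_every,
                constraint=constraint,
                seed=run.seed,
                n_equil_steps=n_equil,
                run_id=run.run_id,
            )
        except StabilityError as exc:
            warnings.warn(f"run {run.run_id} failed: {exc}", stacklevel=2)
            store.failures[run.run_id] = str(exc)
            continue
        store.add(run, ens, extra={"n_steps": n_steps, "n_equil_steps": n_equil})
    store.manifest = manifest
    return store


@dataclass
class ReportBundle:
    """Aggregated analysis artifacts of one scan."""

    manifest_hash: str
    master_seed: int
    landscape: sup.RMSDLandscape
    cluster_model: lc.ClusterModel | None
    occupancy: pd.DataFrame | None
    cluster_groups: pd.Series | None
    representatives: list[dict] | None
    effect: lc.EffectClassification | None
    entropy_reports: dict[str, ce.EntropyReport]
    entropy_tables: dict[str, pd.DataFrame]
    pc_models: dict[str, pca.PCModel]
    pc1_overlap: float | None
    projections: dict[str, np.ndarray]
    densities: dict[str, pca.ProjectionDensity]
    notes: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        """Write the tabular artifacts as CSV/JSON under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.landscape.table.to_csv(out / "rmsd2d.csv", index=False)
        if self.occupancy is not None:
            self.occupancy.to_csv(out / "occupancy.csv")
        if self.cluster_groups is not None:
            self.cluster_groups.to_csv(out / "cluster_groups.csv")
        if self.effect is not None:
            self.effect.table.to_csv(out / "effect_classification.csv", index=False)
        for name, tab in self.entropy_tables.items():
            tab.to_csv(out / f"entropy_{name}.csv")
        proj = pd.DataFrame({k: pd.Series(v) for k, v in self.projections.items()})
        proj.to_csv(out / "pc_projections.csv", index=False)
        stamp = {
            "manifest_hash": self.manifest_hash,
            "master_seed": self.master_seed,
            "pc1_overlap": self.pc1_overlap,
            "notes": self.notes,
        }
        (out / "report.json").write_text(json.dumps(stamp, indent=1))
        return out


def aggregate_report(
    store: RunStore,
    model: ElasticNetworkModel,
    analyses: Mapping | None = None,
) -> ReportBundle:
    """Run the full analysis stack over a completed (possibly partial) scan."""
    cfg = dict(analyses or {})
    k = int(cfg.get("k_clusters", 6))
    cluster_seed = int(cfg.get("cluster_seed", 0))
    effect_threshold = float(cfg.get("effect_threshold", 1.0))
    dominance = float(cfg.get("dominance_threshold", 0.8))
    component = int(cfg.get("pca_component", 1))
    temperature = float(cfg.get("temperature", model.temperature))
    notes: list[str] = []
    if store.failures:
        notes.append(f"missing runs (failed): {sorted(store.failures)}")

    manifest: ScanManifest = store.manifest
    states = list(manifest.states)
    if len(states) != 2:
        raise InputError("aggregate_report expects a two-state scan")
    ref_a = model.reference_coords[states[0]]
    ref_b = model.reference_coords[states[1]]
    ensembles = store.ensembles()
    runs = [store.metadata[rid] for rid in store.run_ids]

    # --- 2D RMSD landscape over every completed run -----------------------
    landscape = sup.rmsd_landscape_2d(
        [ensembles[rid] for rid in store.run_ids], ref_a, ref_b,
        ref_labels=(states[0], states[1]),
    )

    # --- clustering, occupancy, groups, representatives -------------------
    cluster_model = occupancy = groups = representatives = None
    if landscape.n_points >= k:
        cluster_model = lc.fit_clusters(landscape, k=k, seed=cluster_seed)
        occupancy = lc.occupancy_table(cluster_model, landscape)
        run_states = {m["run_id"]: m["state"] for m in runs}
        groups = lc.assign_cluster_groups(occupancy, run_states, dominance)
        representatives = lc.representative_frames(cluster_model, landscape, ensembles)

    # --- perturbation-effect classification -------------------------------
    sub = landscape.table
    unpert = {
        s: sub[sub["run_id"] == f"{s}-unperturbed"][["rmsd_A", "rmsd_B"]].to_numpy()
        for s in states
        if f"{s}-unperturbed" in store.run_ids
    }
    pert = {
        (m["state"], m["perturbation"]): sub[sub["run_id"] == m["run_id"]][
            ["rmsd_A", "rmsd_B"]
        ].to_numpy()
        for m in runs
        if m["perturbation"] is not None
    }
    effect = None
    complete_res = [
        r
        for r in manifest.residues
        if all((s, r) in pert for s in states)
    ]
    if len(unpert) == 2 and complete_res:
        effect = lc.classify_perturbation_effect(
            unpert,
            {key: v for key, v in pert.items() if key[1] in complete_res},
            threshold=effect_threshold,
        )
    else:
        notes.append("effect classification skipped: missing unperturbed or perturbed runs")

    # --- configurational entropy ------------------------------------------
    # equal-length windows: every compared run is truncated to the shortest
    window = min(ensembles[rid].n_frames for rid in store.run_ids)
    reports: dict[str, ce.EntropyReport] = {}
    for rid in store.run_ids:
        ens = ensembles[rid]
        windowed = Ensemble(
            topology=ens.topology,
            frames=ens.frames[:window],
            frame_interval=ens.frame_interval,
            state_label=ens.state_label,
            perturbation=ens.perturbation,
            run_id=ens.run_id,
        )
        ref = model.reference_coords[ens.state_label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports[rid] = ce.entropy_report(windowed, reference=ref, temperature=temperature)
    ref_run = f"{states[0]}-unperturbed"
    per_state_ref = {s: f"{s}-unperturbed" for s in states}
    entropy_tables: dict[str, pd.DataFrame] = {}
    if ref_run in reports and all(v in reports for v in per_state_ref.values()):
        entropy_tables = ce.relative_entropy_table(reports, ref_run, per_state_ref)
        norm = pd.DataFrame(
            {rid: rep.normalized for rid, rep in reports.items()},
        )
        norm.index = pd.RangeIndex(1, len(norm) + 1, name="residue")
        entropy_tables["per_residue_normalized"] = norm
    else:
        notes.append("relative entropy tables skipped: unperturbed reference missing")

    # --- PCA / projections / KDE ------------------------------------------
    # study convention: each unperturbed run is fit against the OTHER state's
    # reference; projections use PC1 of the second (extended) state's run
    pc_models: dict[str, pca.PCModel] = {}
    ca = model.topology.is_alpha_carbon
    for s, other in ((states[0], states[1]), (states[1], states[0])):
        rid = f"{s}-unperturbed"
        if rid in ensembles:
            with warnings.catch_warnings():
                # superposed data always has ~6 zero-variance directions
                warnings.simplefilter("ignore")
                pc_models[rid] = pca.fit_pca(
                    ensembles[rid],
                    reference=model.reference_coords[other][ca],
                    reference_label=f"{other}-reference",
                )
    overlap = None
    ids = [f"{s}-unperturbed" for s in states]
    if all(i in pc_models for i in ids):
        overlap = pca.pc_overlap(
            pc_models[ids[0]].components[0], pc_models[ids[1]].components[0]
        )
    projections: dict[str, np.ndarray] = {}
    densities: dict[str, pca.ProjectionDensity] = {}
    proj_model = pc_models.get(ids[1]) or next(iter(pc_models.values()), None)
    if proj_model is not None:
        for rid in store.run_ids:
            series = pca.project_trajectory(ensembles[rid], proj_model, component)
            projections[rid] = series
            densities[rid] = pca.kde_density(series)
    else:
        notes.append("PCA skipped: no unperturbed run available")

    return ReportBundle(
        manifest_hash=manifest.hash(),
        master_seed=manifest.master_seed,
        landscape=landscape,
        cluster_model=cluster_model,
        occupancy=occupancy,
        cluster_groups=groups,
        representatives=representatives,
        effect=effect,
        entropy_reports=reports,
        entropy_tables=entropy_tables,
        pc_models=pc_models,
        pc1_overlap=overlap,
        projections=projections,
        densities=densities,
        notes=notes,
    )
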