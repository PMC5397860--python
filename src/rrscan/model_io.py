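"""Structure/trajectory IO and atom/residue bookkeeping.

The two containers every downstream stage consumes live here:

* :class:`Topology` — per-atom names, masses, residue membership and
  α-carbon flags, with 1-based contiguous residue ids.
* :class:`Ensemble` — an ordered stack of Cartesian frames (Å) for one
  simulation, tagged with its state label and (optional) rigid-residue
  perturbation.

PDB structures are read through Biopython (altloc duplicates resolved to the
highest-occupancy copy, masses inferred from the element); DCD/XTC frames are
read through MDAnalysis' standalone coordinate readers.  A self-describing
plain-text frame archive (``.traj``) is provided so ensembles round-trip
without any binary codec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    FormatError,
    MassAssignmentError,
    RangeError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Topology",
    "Ensemble",
    "read_structure",
    "renumber_residues",
    "renumber_ensemble",
    "residue_atom_mask",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
]

FRAME_ARCHIVE_MAGIC = "# rrscan frame archive 1"


@dataclass(frozen=True)
class Topology:
    """Atom-level bookkeeping shared by all frames of an ensemble.

    Residue ids are 1-based and contiguous; ``residue_index[a]`` gives the
    residue id of atom ``a``.  ``source_numbering`` maps original residue ids
    to renumbered ones when :func:`renumber_residues` has been applied.
    """

    atom_names: tuple[str, ...]
    masses: np.ndarray  # amu, (n_atoms,)
    residue_index: np.ndarray  # int, (n_atoms,), 1-based
    residue_names: tuple[str, ...]
    is_alpha_carbon: np.ndarray  # bool, (n_atoms,)
    source_numbering: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        resix = np.asarray(self.residue_index, dtype=int)
        ca = np.asarray(self.is_alpha_carbon, dtype=bool)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "residue_index", resix)
        object.__setattr__(self, "is_alpha_carbon", ca)
        n = len(self.atom_names)
        if not (masses.shape == resix.shape == ca.shape == (n,)):
            raise TopologyError("per-atom arrays must all have length n_atoms")
        if n and not np.all(masses > 0):
            raise TopologyError("atomic masses must be strictly positive")
        if n and np.any(np.diff(resix) < 0):
            raise TopologyError("residue_index must be non-decreasing")
        if n:
            ids = np.unique(resix)
            if ids[0] != 1 or ids[-1] != len(ids):
                raise TopologyError("residue ids must be 1-based and contiguous")
            if len(self.residue_names) != len(ids):
                raise TopologyError("one residue name per residue required")
            if ca.any():
                per_res = np.bincount(resix[ca], minlength=len(ids) + 1)[1:]
                if np.any(per_res > 1):
                    raise TopologyError("more than one α-carbon flagged in a residue")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(1, self.n_residues + 1)

    def atoms_of_residue(self, residue: int) -> np.ndarray:
        """Indices of the atoms belonging to 1-based residue ``residue``."""
        return np.nonzero(self.residue_index == residue)[0]

    def residue_atom_counts(self) -> np.ndarray:
        return np.bincount(self.residue_index, minlength=self.n_residues + 1)[1:]

    def subset(self, atom_indices: np.ndarray) -> "Topology":
        """Topology restricted to ``atom_indices`` (residues re-compacted)."""
        atom_indices = np.asarray(atom_indices, dtype=int)
        old_res = self.residue_index[atom_indices]
        kept_res, new_res = np.unique(old_res, return_inverse=True)
        return Topology(
            atom_names=tuple(self.atom_names[i] for i in atom_indices),
            masses=self.masses[atom_indices],
            residue_index=new_res + 1,
            residue_names=tuple(self.residue_names[r - 1] for r in kept_res),
            is_alpha_carbon=self.is_alpha_carbon[atom_indices],
            source_numbering={int(r): int(i + 1) for i, r in enumerate(kept_res)},
        )


@dataclass
class Ensemble:
    """Ordered Cartesian frames of one simulation.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å.  ``perturbation`` is
    ``None`` for unperturbed runs or the 1-based id of the residue held rigid.
    """

    topology: Topology
    frames: np.ndarray
    frame_interval: float = 1.0  # time units (ps for the toy simulator) per saved frame
    state_label: str = "synthetic-A"
    perturbation: int | None = None
    run_id: str = "run-0"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.size == 0:
            frames = frames.reshape(0, self.topology.n_atoms, 3)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {frames.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(frames)):
            raise TopologyError("non-finite coordinates in ensemble")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "PDB") -> tuple[Topology, np.ndarray]:
    """Read a PDB structure into a :class:`Topology` plus one coordinate frame.

    Altloc duplicates keep the highest-occupancy copy; masses come from the
    element inferred by the parser.  Residues are numbered 1..n in file order.
    """
    if format.upper() != "PDB":
        raise FormatError(f"unsupported structure format: {format}")
    path = Path(path)
    models = _parse_pdb_models(path)
    if not models:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    topology, coords = models[0]
    return topology, coords


def _parse_pdb_models(path: Path) -> list[tuple[Topology, np.ndarray]]:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # message names the offending line
        raise FormatError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: malformed PDB record ({exc})") from exc

    out: list[tuple[Topology, np.ndarray]] = []
    for model in structure:
        names: list[str] = []
        masses: list[float] = []
        resix: list[int] = []
        resnames: list[str] = []
        ca: list[bool] = []
        coords: list[np.ndarray] = []
        rid = 0
        for chain in model:
            for residue in chain:
                rid += 1
                resnames.append(residue.get_resname().strip())
                for atom in residue:  # DisorderedAtom yields highest occupancy
                    name = atom.get_name().strip()
                    mass = float(atom.mass)
                    if not np.isfinite(mass) or mass <= 0:
                        raise MassAssignmentError(
                            f"{path}: cannot assign a mass to atom "
                            f"'{name}' in residue {resnames[-1]} {rid}"
                        )
                    names.append(name)
                    masses.append(mass)
                    resix.append(rid)
                    ca.append(name == "CA")
                    coords.append(np.asarray(atom.coord, dtype=float))
        if not names:
            continue
        topo = Topology(
            atom_names=tuple(names),
            masses=np.array(masses),
            residue_index=np.array(resix),
            residue_names=tuple(resnames),
            is_alpha_carbon=np.array(ca),
        )
        out.append((topo, np.array(coords)))
    return out


# ---------------------------------------------------------------------------
# Residue renumbering
# ---------------------------------------------------------------------------

def residue_atom_mask(topology: Topology, first_kept: int, last_kept: int) -> np.ndarray:
    """Boolean atom mask of residues with ids in [first_kept, last_kept]."""
    return (topology.residue_index >= first_kept) & (topology.residue_index <= last_kept)


def renumber_residues(topology: Topology, first_kept: int, last_kept: int) -> Topology:
    """Drop residues outside [first_kept, last_kept] and renumber 1..n.

    The mapping original→new id is recorded in ``source_numbering``; use
    :func:`residue_atom_mask` (or :func:`renumber_ensemble`) to trim the
    matching coordinate arrays.
    """
    if first_kept > last_kept:
        raise RangeError("first_kept must be ≤ last_kept")
    present = set(np.unique(topology.residue_index).tolist())
    if first_kept not in present or last_kept not in present:
        raise RangeError(
            f"residue range {first_kept}..{last_kept} not present "
            f"(topology spans {min(present, default='-')}..{max(present, default='-')})"
        )
    mask = residue_atom_mask(topology, first_kept, last_kept)
    sub = topology.subset(np.nonzero(mask)[0])
    # subset() already renumbered contiguously and stored original→new ids
    return sub


def renumber_ensemble(ensemble: Ensemble, first_kept: int, last_kept: int) -> Ensemble:
    """Apply :func:`renumber_residues` to an ensemble, trimming all frames."""
    mask = residue_atom_mask(ensemble.topology, first_kept, last_kept)
    topo = renumber_residues(ensemble.topology, first_kept, last_kept)
    return replace(ensemble, topology=topo, frames=ensemble.frames[:, mask, :])


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    frame_interval: float | None = None,
    state_label: str | None = None,
    perturbation: int | None = None,
    run_id: str | None = None,
) -> Ensemble:
    """Read a trajectory file into an :class:`Ensemble`.

    ``format`` defaults from the extension: ``.dcd``/``.xtc`` (MDAnalysis
    readers), ``.pdb`` (multi-model), ``.traj`` (frame archive).  Metadata in
    a frame archive is overridden by explicit arguments.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("dcd", "xtc"):
        frames = _read_mdanalysis_frames(path, fmt)
        meta: dict = {}
    elif fmt == "pdb":
        models = _parse_pdb_models(path)
        frames = np.array([c for _, c in models]).reshape(len(models), -1, 3)
        meta = {}
    elif fmt == "traj":
        frames, meta = _read_frame_archive(path)
    else:
        raise FormatError(f"unsupported trajectory format: {fmt}")

    if frames.size and frames.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"{path}: trajectory has {frames.shape[1]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    return Ensemble(
        topology=topology,
        frames=frames.reshape(-1, topology.n_atoms, 3),
        frame_interval=frame_interval
        if frame_interval is not None
        else float(meta.get("frame_interval", 1.0)),
        state_label=state_label
        if state_label is not None
        else str(meta.get("state_label", "synthetic-A")),
        perturbation=perturbation if perturbation is not None else meta.get("perturbation"),
        run_id=run_id if run_id is not None else str(meta.get("run_id", path.stem)),
    )


def _read_mdanalysis_frames(path: Path, fmt: str) -> np.ndarray:
    if fmt == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    frames = []
    try:
        with Reader(str(path)) as reader:
            for ts in reader:
                frames.append(np.array(ts.positions, dtype=float))
    except OSError as exc:
        raise FormatError(
            f"{path}: truncated or unreadable {fmt.upper()} after frame "
            f"{len(frames) - 1}: {exc}"
        ) from exc
    return np.array(frames)


def _read_frame_archive(path: Path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != FRAME_ARCHIVE_MAGIC:
            raise FormatError(f"{path}: not a frame archive (bad header '{first}')")
        meta: dict = {}
        natoms: int | None = None
        frames: list[np.ndarray] = []
        current: list[list[float]] = []
        in_header = True
        lineno = 1
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line == "frame":
                in_header = False
                if current:
                    _close_frame(current, natoms, frames, path)
                    current = []
                continue
            if in_header:
                key, _, value = line.partition(" ")
                if key == "natoms":
                    natoms = int(value)
                elif key == "frame_interval":
                    meta["frame_interval"] = float(value)
                elif key == "perturbation":
                    meta["perturbation"] = None if value == "none" else int(value)
                elif key in ("state_label", "run_id"):
                    meta[key] = value
                else:
                    raise FormatError(f"{path}:{lineno}: unknown archive key '{key}'")
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 coordinates")
            current.append([float(p) for p in parts])
        if current:
            _close_frame(current, natoms, frames, path)
    if natoms is None:
        raise FormatError(f"{path}: missing natoms header")
    return np.array(frames).reshape(len(frames), natoms, 3), meta


def _close_frame(
    current: list[list[float]], natoms: int | None, frames: list[np.ndarray], path: Path
) -> None:
    if natoms is not None and len(current) != natoms:
        raise FormatError(
            f"{path}: truncated frame (got {len(current)} of {natoms} atoms); "
            f"last complete frame index is {len(frames) - 1}"
        )
    frames.append(np.array(current))


def write_trajectory(ensemble: Ensemble, path: str | Path, format: str | None = None) -> Path:
    """Write an ensemble as a frame archive (``.traj``) or multi-model PDB."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "traj":
        _write_frame_archive(ensemble, path)
    elif fmt == "pdb":
        _write_multimodel_pdb(ensemble, path)
    else:
        raise FormatError(f"unsupported trajectory output format: {fmt}")
    return path


def _write_frame_archive(ensemble: Ensemble, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(FRAME_ARCHIVE_MAGIC + "\n")
        fh.write(f"natoms {ensemble.n_atoms}\n")
        fh.write(f"frame_interval {ensemble.frame_interval!r}\n")
        fh.write(f"state_label {ensemble.state_label}\n")
        pert = "none" if ensemble.perturbation is None else str(ensemble.perturbation)
        fh.write(f"perturbation {pert}\n")
        fh.write(f"run_id {ensemble.run_id}\n")
        for frame in ensemble.frames:
            fh.write("frame\n")
            np.savetxt(fh, frame, fmt="%.10g")


def _write_multimodel_pdb(ensemble: Ensemble, path: Path) -> None:
    topo = ensemble.topology
    with open(path, "w") as fh:
        for m, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a in range(topo.n_atoms):
                name = topo.atom_names[a][:4]
                res = topo.residue_index[a]
                resname = topo.residue_names[res - 1][:3]
                x, y, z = frame[a]
                fh.write(
                    f"ATOM  {a + 1:5d} {name:^4s} {resname:>3s} A{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(ensemble: Ensemble, selector: str | Iterable[int]) -> Ensemble:
    """Reduce an ensemble to a selection, preserving frame order.

    ``selector`` is ``"all"``, ``"alpha_carbons"``, or an iterable of 1-based
    residue ids.
    """
    topo = ensemble.topology
    if isinstance(selector, str):
        if selector == "all":
            return ensemble
        if selector == "alpha_carbons":
            idx = np.nonzero(topo.is_alpha_carbon)[0]
        else:
            raise SelectionError(f"unknown selector '{selector}'")
    else:
        residues = set(int(r) for r in selector)
        idx = np.nonzero(np.isin(topo.residue_index, list(residues)))[0]
    if idx.size == 0:
        raise SelectionError(f"selection '{selector}' resolves to no atoms")
    return replace(
        ensemble, topology=topo.subset(idx), frames=ensemble.frames[:, idx, :]
    )
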