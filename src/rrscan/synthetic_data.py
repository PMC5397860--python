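"""Synthetic ensembles with known statistical structure.

Two generators back the test architecture:

* **Gaussian ensembles** drawn from a user-specified mean and 3n × 3n
  covariance.  Because the quasi-harmonic entropy is a closed-form functional
  of the covariance, :func:`analytic_entropy` evaluates the exact entropy of
  the specification through the same mode construction the trajectory
  estimator uses — an oracle for sampled estimates.

* A **two-state coarse-grained elastic network** integrated with overdamped
  (Brownian) Langevin dynamics.  The two reference geometries share one bead
  topology: state A packs an N-terminal arm against a compact globular core,
  state B lifts and extends it — the compact-vs-extended asymmetry of a
  photoreceptor's Dark and Light conformations — and the arm is internally
  soft (softer still in state B), so the extended state is floppier and the
  arm's excess fluctuation lives in exactly the degrees of freedom a
  rigid-body constraint removes.  That constraint reproduces
  the rigid-residue-scan perturbation: each step, the constrained residue's
  proposed displacement is replaced by its closest mass-weighted rigid-body
  motion, conserving all intra-residue distances to machine precision while
  leaving the interaction terms untouched.

Units follow the package convention: Å, amu, ps, kcal/mol, K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .constants import KB_AKMA, KCAL_MOL_TO_AKMA
from .correlation_entropy import (
    CovarianceResult,
    configurational_entropy,
    quasiharmonic_modes,
)
from .errors import SpecError, StabilityError
from .model_io import Ensemble, Topology

__all__ = [
    "GaussianEnsembleSpec",
    "ElasticNetworkModel",
    "RigidConstraint",
    "sample_gaussian_ensemble",
    "analytic_entropy",
    "build_two_state_toy",
    "simulate_langevin",
    "rigid_body_project",
]


# ---------------------------------------------------------------------------
# Gaussian ensembles with analytic entropy
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Multivariate-normal ensemble specification with known covariance."""

    mean: np.ndarray  # (n_atoms, 3) Å
    covariance: np.ndarray  # (3n, 3n) Å², symmetric PSD
    masses: np.ndarray  # amu
    temperature: float = 300.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1, 3)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n3 = 3 * self.mean.shape[0]
        if self.covariance.shape != (n3, n3):
            raise SpecError(f"covariance must be ({n3}, {n3})")
        if self.masses.shape != (self.mean.shape[0],):
            raise SpecError("one mass per atom required")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise SpecError("covariance must be symmetric")
        lam = np.linalg.eigvalsh(0.5 * (self.covariance + self.covariance.T))
        tol = 1e-10 * max(lam.max(), np.finfo(float).tiny)
        if lam.min() < -tol:
            raise SpecError(
                f"covariance not positive-semidefinite (min eigenvalue {lam.min():.3e})"
            )
        if self.n_frames < 1:
            raise SpecError("n_frames must be ≥ 1")

    @property
    def n_atoms(self) -> int:
        return self.mean.shape[0]


def _bead_topology(masses: np.ndarray, beads_per_residue: int = 1) -> Topology:
    n = len(masses)
    if n % beads_per_residue:
        raise SpecError("atom count not divisible by beads_per_residue")
    resix = np.repeat(np.arange(1, n // beads_per_residue + 1), beads_per_residue)
    names = tuple(
        "CA" if a % beads_per_residue == 0 else f"B{a % beads_per_residue + 1}"
        for a in range(n)
    )
    return Topology(
        atom_names=names,
        masses=np.asarray(masses, dtype=float),
        residue_index=resix,
        residue_names=tuple("BEA" for _ in range(n // beads_per_residue)),
        is_alpha_carbon=np.array([name == "CA" for name in names]),
    )


def sample_gaussian_ensemble(spec: GaussianEnsembleSpec, run_id: str = "gaussian") -> Ensemble:
    """Draw i.i.d. frames from the specified multivariate normal."""
    rng = np.random.default_rng(spec.seed)
    flat = rng.multivariate_normal(
        spec.mean.ravel(),
        spec.covariance,
        size=spec.n_frames,
        method="eigh",
        check_valid="ignore",  # PSD already validated with a tighter tolerance
    )
    return Ensemble(
        topology=_bead_topology(spec.masses),
        frames=flat.reshape(spec.n_frames, spec.n_atoms, 3),
        state_label="synthetic-A",
        run_id=run_id,
    )


def analytic_entropy(spec: GaussianEnsembleSpec, mode_cutoff: float = 1e-3) -> float:
    """Exact quasi-harmonic entropy of the specification, kcal/mol·K.

    Shares the mode construction and quantum-oscillator formula with the
    trajectory estimator; the only difference is that the covariance is the
    spec's true covariance rather than a sampled one.  Modes below
    ``mode_cutoff`` (rad/ps) are excluded, mirroring the estimator's cutoff
    policy on full-rank covariances.
    """
    cov = CovarianceResult(
        mean=spec.mean,
        covariance=spec.covariance,
        n_frames=0,
        topology=None,
        superposed=False,
    )
    spectrum = quasiharmonic_modes(
        cov,
        masses=spec.masses,
        temperature=spec.temperature,
        zero_mode_policy="cutoff",
        freq_cutoff=mode_cutoff,
    )
    return configurational_entropy(spectrum)


# ---------------------------------------------------------------------------
# Two-state elastic network
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetworkModel:
    """Coarse-grained harmonic bead network with two reference states.

    Spring pairs are the union of contacts in both reference geometries; each
    state stores its own rest lengths (measured on its own reference) and
    force constants (kcal/mol/Å²), so that every reference geometry is a
    force-free minimum of its state's potential.
    """

    topology: Topology
    reference_coords: Mapping[str, np.ndarray]  # state label → (n_atoms, 3) Å
    spring_i: np.ndarray  # (n_springs,) atom indices
    spring_j: np.ndarray
    rest_lengths: Mapping[str, np.ndarray]  # state label → (n_springs,) Å
    force_constants: Mapping[str, np.ndarray]  # state label → (n_springs,)
    friction: float = 2.0  # 1/ps
    temperature: float = 300.0  # K
    timestep: float = 0.002  # ps

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for state, fc in self.force_constants.items():
            if np.any(np.asarray(fc) <= 0):
                raise SpecError(f"non-positive force constant in state '{state}'")
        graph = coo_matrix(
            (np.ones(len(self.spring_i)), (self.spring_i, self.spring_j)),
            shape=(n, n),
        )
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp != 1:
            raise SpecError(f"spring graph has {n_comp} components; must be connected")

    @property
    def states(self) -> list[str]:
        return list(self.reference_coords)


@dataclass(frozen=True)
class RigidConstraint:
    """Residue whose beads move only as a rigid body during simulation."""

    residue: int


def build_two_state_toy(
    n_residues: int = 20,
    beads_per_residue: int = 4,
    arm_length: int = 5,
    seed: int = 0,
    contact_cutoff: float = 7.0,
    k_intra: float = 5.0,
    k_inter: float = 2.0,
    arm_flexibility: float = 0.05,
    bead_mass: float = 12.0,
    temperature: float = 300.0,
    friction: float = 2.0,
    timestep: float = 0.002,
    state_labels: tuple[str, str] = ("synthetic-A", "synthetic-B"),
) -> ElasticNetworkModel:
    """Build the two-state toy protein.

    The core (residues ``arm_length+1 .. n_residues``) is a compact globule:
    residue centers on a spherical spiral of radius 5.5 Å, densely
    cross-linked so its collective modes are stiff and decorrelate quickly.
    The N-terminal arm (residues ``1 .. arm_length``) is packed against the
    globule surface in state A and extends radially outward in state B.
    Each residue is a cluster of ``beads_per_residue`` beads held by
    intra-residue springs; inter-residue springs connect bead pairs within
    ``contact_cutoff`` in either reference geometry (union of contacts), with
    rest lengths per state so each reference is force-free.

    ``arm_flexibility`` (< 1) scales the arm residues' intra-residue force
    constants in both states: the arm is intrinsically floppy *internally*,
    so most of its fluctuation amplitude lives in exactly the degrees of
    freedom a rigid-residue constraint removes.  The extended state B arm
    additionally loses its packing contacts, so state B fluctuates more than
    state A overall.
    """
    if n_residues < 10:
        raise SpecError("n_residues must be ≥ 10")
    if beads_per_residue < 3:
        raise SpecError("beads_per_residue must be ≥ 3")
    if not 1 <= arm_length < n_residues:
        raise SpecError("arm_length must be in [1, n_residues)")

    rng = np.random.default_rng(seed)
    label_a, label_b = state_labels
    n_core = n_residues - arm_length
    r_core = 5.5

    # core: spherical (fibonacci) spiral — compact, densely contacted
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k_idx = np.arange(n_core)
    z = 1.0 - 2.0 * (k_idx + 0.5) / n_core
    rho = np.sqrt(1.0 - z * z)
    phi = golden * k_idx
    core = r_core * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    # arm attachment: the first core residue (top of the sphere)
    anchor = core[0]
    out_dir = anchor / np.linalg.norm(anchor)
    # state A: arm wrapped along the globule surface at slightly larger radius
    tangent = np.cross(out_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(tangent) < 1e-6:
        tangent = np.cross(out_dir, [0.0, 1.0, 0.0])
    tangent /= np.linalg.norm(tangent)
    arm_a = []
    arm_b = []
    for i in range(1, arm_length + 1):
        angle = 0.55 * (arm_length + 1 - i)  # rad along a great circle
        direction = np.cos(angle) * out_dir + np.sin(angle) * tangent
        arm_a.append((r_core + 2.5) * direction)
        # state B: the arm lifts off the surface and partially unwinds —
        # extended and detached, yet still tethered enough not to swing freely
        angle_b = 0.75 * (arm_length + 1 - i)
        dir_b = np.cos(angle_b) * out_dir + np.sin(angle_b) * tangent
        arm_b.append((r_core + 5.5) * dir_b)
    centers_a = np.vstack([arm_a, core])
    centers_b = np.vstack([arm_b, core])

    # identical internal bead geometry in both states (same per-residue offsets)
    base = np.array([[0.9, 0.0, 0.0], [-0.45, 0.78, 0.0], [-0.45, -0.78, 0.0]])
    offsets = []
    for _ in range(n_residues):
        local = base.copy()
        if beads_per_residue > 3:
            extra = rng.normal(size=(beads_per_residue - 3, 3))
            extra *= 0.9 / np.linalg.norm(extra, axis=1, keepdims=True)
            local = np.vstack([local, extra])
        # random proper rotation for geometric variety
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        offsets.append(local @ q.T)

    coords_a = np.concatenate(
        [centers_a[r] + offsets[r] for r in range(n_residues)]
    )
    coords_b = np.concatenate(
        [centers_b[r] + offsets[r] for r in range(n_residues)]
    )
    n_atoms = n_residues * beads_per_residue
    masses = np.full(n_atoms, bead_mass)
    topo = _bead_topology(masses, beads_per_residue)

    resix = topo.residue_index
    arm_atoms = resix <= arm_length

    pairs_i: list[int] = []
    pairs_j: list[int] = []
    # stiff intra-residue springs: all bead pairs within each residue
    for r in range(1, n_residues + 1):
        idx = np.nonzero(resix == r)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pairs_i.append(idx[a])
                pairs_j.append(idx[b])
    n_intra = len(pairs_i)

    # inter-residue springs: union of contacts over both references.  Arm
    # residues anchor to their surroundings through two designated beads
    # only; the arm backbone bead and remaining side bead carry no
    # inter-residue springs, so their fluctuation is purely internal —
    # exactly the motion a rigid-residue constraint removes (and, for the
    # backbone bead, motion visible to α-carbon essential-dynamics PCA).
    da = np.linalg.norm(coords_a[:, None] - coords_a[None], axis=-1)
    db = np.linalg.norm(coords_b[:, None] - coords_b[None], axis=-1)
    close = (da < contact_cutoff) | (db < contact_cutoff)
    bead_rank = np.arange(n_atoms) % beads_per_residue
    arm_free = arm_atoms & ~np.isin(bead_rank, (1, 2))
    iu, ju = np.triu_indices(n_atoms, k=1)
    inter = (
        close[iu, ju]
        & (resix[iu] != resix[ju])
        & ~arm_free[iu]
        & ~arm_free[ju]
    )
    pairs_i.extend(iu[inter].tolist())
    pairs_j.extend(ju[inter].tolist())
    # arm backbone chain: consecutive backbone beads of residues 1..arm+1
    # linked by soft springs — one dominant collective arm mode at the
    # α-carbon level, suppressed wherever a residue is held rigid
    ca_index = np.nonzero(topo.is_alpha_carbon)[0]
    chain_pairs = []
    for i in range(arm_length):
        chain_pairs.append(len(pairs_i))
        pairs_i.append(int(ca_index[i]))
        pairs_j.append(int(ca_index[i + 1]))

    si = np.array(pairs_i)
    sj = np.array(pairs_j)
    rest_a = np.linalg.norm(coords_a[si] - coords_a[sj], axis=1)
    rest_b = np.linalg.norm(coords_b[si] - coords_b[sj], axis=1)
    intra_mask = np.arange(len(si)) < n_intra
    touches_arm = arm_atoms[si] | arm_atoms[sj]
    arm_intra = intra_mask & touches_arm
    k_a = np.where(intra_mask, k_intra, k_inter)
    k_a = np.where(arm_intra, k_intra * arm_flexibility, k_a)
    chain_idx = np.array(chain_pairs, dtype=int)
    k_a[chain_idx] = 0.5 * k_inter * np.sqrt(arm_flexibility / 0.05)
    arm_soft = arm_intra.copy()
    arm_soft[chain_idx] = True
    k_b = k_a.copy()
    # the extended state's arm is internally softer still: the activated
    # state fluctuates more, and monotonically so in this factor
    k_b[arm_soft] *= 0.5

    return ElasticNetworkModel(
        topology=topo,
        reference_coords={label_a: coords_a, label_b: coords_b},
        spring_i=si,
        spring_j=sj,
        rest_lengths={label_a: rest_a, label_b: rest_b},
        force_constants={label_a: k_a, label_b: k_b},
        friction=friction,
        temperature=temperature,
        timestep=timestep,
    )


# ---------------------------------------------------------------------------
# Rigid-body projection and Brownian dynamics
# ---------------------------------------------------------------------------

def rigid_body_project(
    displacement: np.ndarray, coords: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Closest mass-weighted rigid-body motion to a proposed displacement.

    Finds the exact rotation + translation of ``coords`` that best fits
    ``coords + displacement`` in the mass-weighted least-squares sense
    (weighted Kabsch), and returns the corresponding displacement.  The map
    is a projection: applying it to its own output returns the same motion to
    machine precision.  Degenerate geometries (<3 beads or collinear) fall
    back to the mass-weighted mean translation, with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    w = np.asarray(masses, dtype=float)
    target = coords + displacement
    wsum = w.sum()
    com = (w[:, None] * coords).sum(0) / wsum
    com_t = (w[:, None] * target).sum(0) / wsum
    x = coords - com
    y = target - com_t
    if coords.shape[0] >= 3:
        h = (w[:, None] * x).T @ y
        u, s, vt = np.linalg.svd(h)
        if s[1] > 1e-10 * max(s[0], np.finfo(float).tiny):
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            return x @ rot.T + com_t - coords
    warnings.warn(
        "degenerate residue geometry: rigid constraint degrades to "
        "translation-only",
        stacklevel=2,
    )
    return np.broadcast_to(com_t - com, coords.shape).copy()


def simulate_langevin(
    model: ElasticNetworkModel,
    state: str,
    n_steps: int,
    save_every: int = 50,
    constraint: RigidConstraint | None = None,
    seed: int = 0,
    n_equil_steps: int = 0,
    run_id: str | None = None,
    coordinate_bound: float = 1e4,
) -> Ensemble:
    """Overdamped Langevin (Euler–Maruyama) trajectory about one state.

    Each step ``x += F dt/(mγ) + √(2 k_B T dt/(mγ)) ξ`` with harmonic spring
    forces from the state's rest lengths.  With ``constraint`` set, the
    constrained residue's displacement is replaced every step by its exact
    rigid-body equivalent, conserving intra-residue distances.  Frames are
    saved every ``save_every`` steps after the first ``n_equil_steps``
    (discarded as equilibration).
    """
    if state not in model.reference_coords:
        raise SpecError(f"model has no state '{state}'")
    x = np.array(model.reference_coords[state], dtype=float)
    si, sj = model.spring_i, model.spring_j
    l0 = np.asarray(model.rest_lengths[state], dtype=float)
    k = np.asarray(model.force_constants[state], dtype=float)
    m = model.topology.masses
    dt, gamma, temp = model.timestep, model.friction, model.temperature
    mob = dt * KCAL_MOL_TO_AKMA / (m * gamma)  # Å² mol/kcal per step
    sigma = np.sqrt(2.0 * KB_AKMA * temp * dt / (m * gamma))
    n_atoms = x.shape[0]

    res_idx = None
    if constraint is not None:
        res_idx = model.topology.atoms_of_residue(constraint.residue)
        if res_idx.size == 0:
            raise SpecError(f"constraint residue {constraint.residue} not in topology")
        m_res = m[res_idx]

    rng = np.random.default_rng(seed)
    frames = []
    total = n_equil_steps + n_steps
    block = 1000
    step = 0
    while step < total:
        nb = min(block, total - step)
        noise = rng.standard_normal((nb, n_atoms, 3))
        for b in range(nb):
            d = x[si] - x[sj]
            r = np.sqrt((d * d).sum(1))
            coef = -k * (r - l0) / r
            fp = coef[:, None] * d
            force = np.empty_like(x)
            for c in range(3):
                force[:, c] = np.bincount(si, weights=fp[:, c], minlength=n_atoms)
                force[:, c] -= np.bincount(sj, weights=fp[:, c], minlength=n_atoms)
            dx = force * mob[:, None] + sigma[:, None] * noise[b]
            if res_idx is not None:
                dx[res_idx] = rigid_body_project(dx[res_idx], x[res_idx], m_res)
            x = x + dx
            step += 1
            if step > n_equil_steps and (step - n_equil_steps) % save_every == 0:
                frames.append(x.copy())
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > coordinate_bound:
            raise StabilityError(
                f"trajectory diverged at step {step}; reduce the timestep "
                f"(currently {dt} ps)"
            )
    return Ensemble(
        topology=model.topology,
        frames=np.array(frames).reshape(len(frames), n_atoms, 3),
        frame_interval=save_every * dt,
        state_label=state,
        perturbation=None if constraint is None else constraint.residue,
        run_id=run_id
        or (
            f"{state}-rigid{constraint.residue}"
            if constraint is not None
            else f"{state}-unperturbed"
        ),
    )
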