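"""Covariance, cross-correlation and quasi-harmonic configurational entropy.

The quasi-harmonic picture models equilibrium fluctuations as an effective
harmonic well whose force-constant matrix is

    F = k_B T Σ⁻¹,

with Σ the (unnormalized, mass-unweighted) 3n × 3n coordinate covariance of
the superposed trajectory.  The secular equation F u = ω² M u is solved via
the equivalent symmetric eigenproblem of M^{1/2} Σ M^{1/2}: each eigenvalue λ
(amu·Å²) gives a mode frequency

    ω = √(k_B T / λ)   [rad/ps],

so large-variance collective motions are the low-frequency modes.  The
configurational entropy in the harmonic limit is the quantum
harmonic-oscillator sum over retained modes

    S = k_B Σ_i [ α_i/(e^{α_i} − 1) − ln(1 − e^{−α_i}) ],   α_i = ħω_i/(k_B T),

reported in kcal/mol·K.  Translation/rotation is removed by least-squares
superposition before the covariance is accumulated; the six rigid-body
remnants then carry near-zero variance (very high ω, vanishing entropy) and
are dropped by the default zero-mode policy.

Per-residue entropies use the residue's own 3m × 3m covariance sub-block,
extracted after whole-protein superposition, with no rigid-body exclusion
inside the block: the block keeps the residue's translation/rotation relative
to the protein frame, and cross-residue correlation is deliberately excluded,
so residue entropies do not sum to the whole-protein value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import HBAR_KCAL_PS_MOL, KB_AKMA, KB_KCAL_MOL_K
from .errors import (
    ConditioningError,
    EmptySpectrumError,
    InsufficientDataError,
    MissingReferenceError,
    ParameterError,
)
from .model_io import Ensemble, Topology
from .superposition import superpose

__all__ = [
    "CovarianceResult",
    "QuasiHarmonicSpectrum",
    "EntropyReport",
    "covariance_matrix",
    "cross_correlation",
    "quasiharmonic_modes",
    "configurational_entropy",
    "residue_entropy",
    "entropy_report",
    "normalized_residue_entropy",
    "relative_entropy_table",
]

#: relative eigenvalue floor for rank-deficient covariances
EIGENVALUE_FLOOR_REL = 1e-12
#: default low-frequency cutoff, rad/ps (guards against unremoved drift)
DEFAULT_FREQ_CUTOFF = 1e-3


@dataclass
class CovarianceResult:
    """Second moments of a superposed ensemble."""

    mean: np.ndarray  # (n, 3) Å
    covariance: np.ndarray  # (3n, 3n) Å²
    n_frames: int
    topology: Topology | None = None
    superposed: bool = True

    @property
    def n_atoms(self) -> int:
        return self.mean.shape[0]


@dataclass
class QuasiHarmonicSpectrum:
    """Mode frequencies (ascending, rad/ps) with mass-metric-orthonormal modes."""

    frequencies: np.ndarray  # (n_modes,)
    modes: np.ndarray  # (3n, n_modes), uᵀ M u = I
    n_excluded: int
    temperature: float  # K


@dataclass
class EntropyReport:
    """Whole-protein and per-residue configurational entropies for one run."""

    run_id: str
    state_label: str
    perturbation: int | None
    total: float  # kcal/mol·K
    per_residue: np.ndarray  # kcal/mol·K, indexed by residue id − 1
    normalized: np.ndarray  # per-residue entropy / residue atom count
    temperature: float


def covariance_matrix(
    ensemble: Ensemble,
    reference: np.ndarray | None = None,
    weights: np.ndarray | str | None = "masses",
    superpose_frames: bool = True,
    max_mean_iterations: int = 10,
) -> CovarianceResult:
    """Coordinate covariance of an ensemble after best-fit superposition.

    ``reference=None`` iteratively aligns to the running mean; otherwise every
    frame is fit to the fixed reference.  ``weights`` steer the fit only — the
    covariance itself is the plain coordinate covariance in Å².
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("covariance requires at least 2 frames")
    w = ensemble.topology.masses if isinstance(weights, str) else weights
    frames = ensemble.frames
    if superpose_frames:
        if reference is not None:
            ref = np.asarray(reference, dtype=float)
            frames = np.array([superpose(f, ref, w) for f in frames])
        else:
            ref = frames[0]
            for _ in range(max_mean_iterations):
                frames = np.array([superpose(f, ref, w) for f in ensemble.frames])
                new_ref = frames.mean(axis=0)
                if np.max(np.abs(new_ref - ref)) < 1e-10:
                    ref = new_ref
                    break
                ref = new_ref
    flat = frames.reshape(ensemble.n_frames, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (ensemble.n_frames - 1)
    return CovarianceResult(
        mean=mean.reshape(-1, 3),
        covariance=0.5 * (cov + cov.T),
        n_frames=ensemble.n_frames,
        topology=ensemble.topology,
        superposed=superpose_frames,
    )


def cross_correlation(cov: CovarianceResult) -> np.ndarray:
    """Normalized atom-pair cross-correlation C_ij = c_ij / √(c_ii c_jj).

    ``c_ij`` is the trace of the 3×3 displacement-covariance block of atoms
    i and j.  Zero-variance atoms (e.g. frozen beads) yield NaN rows/columns,
    flagged with a warning rather than silently set to 0.
    """
    n = cov.n_atoms
    blocks = cov.covariance.reshape(n, 3, n, 3)
    c = np.einsum("icjc->ij", blocks)
    var = np.diag(c).copy()
    dead = var <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} atoms have zero positional variance; their "
            "cross-correlation entries are undefined (NaN)",
            stacklevel=2,
        )
        var[dead] = np.nan
    denom = np.sqrt(np.outer(var, var))
    corr = c / denom
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, np.where(dead, np.nan, 1.0))
    return np.clip(corr, -1.0, 1.0, out=corr)


def quasiharmonic_modes(
    cov: CovarianceResult,
    masses: np.ndarray | None = None,
    temperature: float = 300.0,
    zero_mode_policy: str = "rigid_body",
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    n_rigid_modes: int = 6,
) -> QuasiHarmonicSpectrum:
    """Quasi-harmonic mode spectrum of a coordinate covariance.

    ``zero_mode_policy``:

    * ``"rigid_body"`` — drop the ``n_rigid_modes`` smallest-variance modes
      (the rigid-body remnants left by superposition) plus any mode with
      ω < ``freq_cutoff``.  Default for superposed protein trajectories.
    * ``"cutoff"`` — drop only modes with ω < ``freq_cutoff``.
    * ``"none"`` — keep every mode.  Used for full-rank synthetic covariances
      and residue sub-blocks.
    """
    if masses is None:
        if cov.topology is None:
            raise ParameterError("masses required when covariance has no topology")
        masses = cov.topology.masses
    masses = np.asarray(masses, dtype=float)
    n3 = cov.covariance.shape[0]
    if masses.size * 3 != n3:
        raise ParameterError("mass vector does not match covariance dimension")
    if zero_mode_policy not in ("rigid_body", "cutoff", "none"):
        raise ParameterError(f"unknown zero_mode_policy '{zero_mode_policy}'")
    if cov.n_frames and cov.n_frames < n3:
        warnings.warn(
            f"covariance from {cov.n_frames} frames is rank-deficient for "
            f"{n3} coordinates; spectrum will contain floored modes",
            stacklevel=2,
        )
    msqrt = np.sqrt(np.repeat(masses, 3))
    a = cov.covariance * np.outer(msqrt, msqrt)
    lam, vec = np.linalg.eigh(0.5 * (a + a.T))
    scale = max(np.trace(a) / n3, np.finfo(float).tiny)
    if np.any(lam < -1e-8 * scale):
        raise ConditioningError(
            f"covariance has significant negative eigenvalues "
            f"(min {lam.min():.3e}); numerical rank "
            f"{int(np.sum(lam > 1e-12 * scale))} of {n3}"
        )
    floor = max(EIGENVALUE_FLOOR_REL * scale, 1e-30)
    if np.any(lam < floor):
        warnings.warn(
            f"{int(np.sum(lam < floor))} covariance eigenvalues floored at "
            f"{floor:.3e} amu·Å² (rank-deficient or constrained modes)",
            stacklevel=2,
        )
        lam = np.maximum(lam, floor)
    # λ ascending = ω descending; modes in ascending-frequency order:
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    n_excluded = 0
    if zero_mode_policy == "rigid_body":
        if n3 <= n_rigid_modes:
            raise ParameterError(
                f"cannot drop {n_rigid_modes} rigid-body modes from a "
                f"{n3}-coordinate system"
            )
        lam = lam[:-n_rigid_modes]
        vec = vec[:, :-n_rigid_modes]
        n_excluded += n_rigid_modes
    omega = np.sqrt(KB_AKMA * temperature / lam)
    keep = omega >= freq_cutoff if zero_mode_policy != "none" else np.ones_like(omega, bool)
    n_excluded += int((~keep).sum())
    omega = omega[keep]
    vec = vec[:, keep]
    if omega.size == 0:
        raise EmptySpectrumError("no quasi-harmonic mode survives the exclusion policy")
    modes = vec / msqrt[:, None]  # orthonormal in the mass metric
    return QuasiHarmonicSpectrum(
        frequencies=omega,
        modes=modes,
        n_excluded=n_excluded,
        temperature=float(temperature),
    )


def configurational_entropy(spectrum: QuasiHarmonicSpectrum) -> float:
    """Quantum harmonic-oscillator entropy over retained modes, kcal/mol·K."""
    alpha = (
        HBAR_KCAL_PS_MOL * spectrum.frequencies
        / (KB_KCAL_MOL_K * spectrum.temperature)
    )
    return float(KB_KCAL_MOL_K * mode_entropy_terms(alpha).sum())


def mode_entropy_terms(alpha: np.ndarray) -> np.ndarray:
    """Per-mode S/k_B terms α/(e^α − 1) − ln(1 − e^{−α}), overflow-safe."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    out = np.zeros_like(alpha)
    small = alpha < 50.0  # beyond this both terms underflow to 0
    a = alpha[small]
    out[small] = a / np.expm1(a) - np.log1p(-np.exp(-a))
    return out


def residue_entropy(
    ensemble_or_cov: Ensemble | CovarianceResult,
    residue: int,
    reference: np.ndarray | None = None,
    temperature: float = 300.0,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
) -> float:
    """Configurational entropy of one residue from its covariance sub-block.

    The block is cut from the whole-protein covariance (after whole-protein
    superposition); no rigid-body modes are excluded within the block.
    """
    cov = (
        ensemble_or_cov
        if isinstance(ensemble_or_cov, CovarianceResult)
        else covariance_matrix(ensemble_or_cov, reference=reference)
    )
    if cov.topology is None:
        raise ParameterError("residue entropy requires a covariance with topology")
    idx = cov.topology.atoms_of_residue(residue)
    if idx.size == 0:
        raise ParameterError(f"residue {residue} not in topology")
    coords = np.concatenate([3 * idx + c for c in range(3)])
    coords = np.sort(coords)
    sub = CovarianceResult(
        mean=cov.mean[idx],
        covariance=cov.covariance[np.ix_(coords, coords)],
        n_frames=cov.n_frames,
        topology=None,
        superposed=cov.superposed,
    )
    spec = quasiharmonic_modes(
        sub,
        masses=cov.topology.masses[idx],
        temperature=temperature,
        zero_mode_policy="none",
        freq_cutoff=freq_cutoff,
    )
    return configurational_entropy(spec)


def entropy_report(
    ensemble: Ensemble,
    reference: np.ndarray | None = None,
    temperature: float = 300.0,
    zero_mode_policy: str = "rigid_body",
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
) -> EntropyReport:
    """Whole-protein + per-residue entropies of one run, from one covariance."""
    cov = covariance_matrix(ensemble, reference=reference)
    spectrum = quasiharmonic_modes(
        cov,
        temperature=temperature,
        zero_mode_policy=zero_mode_policy,
        freq_cutoff=freq_cutoff,
    )
    total = configurational_entropy(spectrum)
    topo = ensemble.topology
    per_res = np.array(
        [
            residue_entropy(cov, rid, temperature=temperature, freq_cutoff=freq_cutoff)
            for rid in topo.residue_ids
        ]
    )
    return EntropyReport(
        run_id=ensemble.run_id,
        state_label=ensemble.state_label,
        perturbation=ensemble.perturbation,
        total=total,
        per_residue=per_res,
        normalized=normalized_residue_entropy(per_res, topo),
        temperature=float(temperature),
    )


def normalized_residue_entropy(
    per_residue: np.ndarray | EntropyReport, topology: Topology
) -> np.ndarray:
    """Per-residue entropy divided by the residue's atom count."""
    values = (
        per_residue.per_residue
        if isinstance(per_residue, EntropyReport)
        else np.asarray(per_residue, dtype=float)
    )
    return values / topology.residue_atom_counts()


def relative_entropy_table(
    reports: Mapping[str, EntropyReport],
    reference_run: str,
    per_state_reference: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Relative-entropy tables against unperturbed references.

    * ``"total"`` — whole-protein entropies of every run relative to the
      single ``reference_run`` (the unperturbed reference-state run).
    * ``"per_residue"`` — residue-by-run entropies relative to the same
      residue in the same state's unperturbed run (needs
      ``per_state_reference``).
    * ``"state_difference"`` — for each perturbation present in both states,
      the whole-protein entropy gap between the two states' runs.
    """
    if reference_run not in reports:
        raise MissingReferenceError(f"reference run '{reference_run}' missing")
    ref_total = reports[reference_run].total
    total = pd.DataFrame(
        {
            "run_id": list(reports),
            "state_label": [r.state_label for r in reports.values()],
            "perturbation": [r.perturbation for r in reports.values()],
            "total": [r.total for r in reports.values()],
            "relative": [r.total - ref_total for r in reports.values()],
        }
    )
    out: dict[str, pd.DataFrame] = {"total": total}

    if per_state_reference is not None:
        cols = {}
        for run_id, rep in reports.items():
            state_ref = per_state_reference.get(rep.state_label)
            if state_ref is None or state_ref not in reports:
                raise MissingReferenceError(
                    f"no unperturbed reference for state '{rep.state_label}'"
                )
            cols[run_id] = rep.per_residue - reports[state_ref].per_residue
        per_res = pd.DataFrame(cols)
        per_res.index = pd.RangeIndex(1, len(per_res) + 1, name="residue")
        out["per_residue"] = per_res

        by_state: dict[str, dict[int | None, float]] = {}
        for rep in reports.values():
            by_state.setdefault(rep.state_label, {})[rep.perturbation] = rep.total
        states = sorted(by_state)
        if len(states) == 2:
            a, b = states
            common = sorted(
                (p for p in by_state[a] if p in by_state[b] and p is not None)
            )
            out["state_difference"] = pd.DataFrame(
                {
                    "perturbation": common,
                    f"{b}_minus_{a}": [
                        by_state[b][p] - by_state[a][p] for p in common
                    ],
                }
            )
    return out
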