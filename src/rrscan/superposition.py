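"""Best-fit superposition and RMSD landscapes.

The weighted Kabsch algorithm computes the proper rotation ``U`` and
translation minimizing

    Σ_i w_i |U·(r_i − c_mob) + c_ref − r_i^ref|²

over rigid motions, with reflections excluded by correcting the sign of the
smallest singular value.  The mass-weighted RMSD after that fit,

    RMSD = √( Σ_i w_i |U·r_i − r_i^ref|² / Σ_i w_i ),

is the per-frame observable behind 1D traces and the dual-reference 2D
landscape (each frame scored against both reference conformations).

Weights default to atomic masses; pass ``weights=None`` explicitly where an
unweighted fit is wanted (e.g. α-carbon essential-dynamics work).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, ParameterError, TopologyError
from .model_io import Ensemble

__all__ = [
    "FitResult",
    "RMSDLandscape",
    "kabsch_fit",
    "apply_fit",
    "superpose",
    "rmsd",
    "rmsd_trace",
    "rmsd_landscape_2d",
    "landscape_histogram",
]


@dataclass(frozen=True)
class FitResult:
    """A proper rigid motion (rotation then translation) and its residual RMSD."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å


@dataclass
class RMSDLandscape:
    """Pooled per-frame (RMSD-to-ref-A, RMSD-to-ref-B) points with provenance.

    ``table`` columns: run_id, state_label, frame, rmsd_A, rmsd_B.
    """

    table: pd.DataFrame
    ref_labels: tuple[str, str] = ("A", "B")

    @property
    def points(self) -> np.ndarray:
        return self.table[["rmsd_A", "rmsd_B"]].to_numpy()

    @property
    def n_points(self) -> int:
        return len(self.table)

    def run_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["run_id"]))


def _checked(mobile: np.ndarray, reference: np.ndarray, weights) -> tuple:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise TopologyError("mobile and reference must both be (n_atoms, 3)")
    n = mobile.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise TopologyError("weights must have one entry per atom")
        if np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("weights must be non-negative with positive sum")
    return mobile, reference, w


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> FitResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``reference``.

    Raises :class:`DegenerateFitError` for <3 atoms or collinear geometry,
    where the optimal rotation is not unique.  Degenerate singular-value ties
    are resolved deterministically by LAPACK's fixed SVD ordering.
    """
    mobile, reference, w = _checked(mobile, reference, weights)
    if mobile.shape[0] < 3:
        raise DegenerateFitError("superposition requires at least 3 atoms")
    wsum = w.sum()
    c_mob = (w[:, None] * mobile).sum(0) / wsum
    c_ref = (w[:, None] * reference).sum(0) / wsum
    x = mobile - c_mob
    y = reference - c_ref
    # collinearity: centered weighted coordinates of rank < 2
    if np.linalg.matrix_rank(x * np.sqrt(w)[:, None], tol=1e-9 * max(1.0, np.abs(x).max())) < 2:
        raise DegenerateFitError("collinear atoms: rotation is not uniquely defined")
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    resid = x @ rot.T - y
    msd = float((w * (resid**2).sum(1)).sum() / wsum)
    return FitResult(
        rotation=rot,
        translation=c_ref - rot @ c_mob,
        rmsd=float(np.sqrt(max(msd, 0.0))),
    )


def apply_fit(fit: FitResult, coords: np.ndarray) -> np.ndarray:
    """Apply a fitted rigid motion to a coordinate set."""
    return np.asarray(coords, dtype=float) @ fit.rotation.T + fit.translation


def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """``mobile`` after best-fit superposition onto ``reference``."""
    return apply_fit(kabsch_fit(mobile, reference, weights), mobile)


def rmsd(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Mass-weighted best-fit RMSD between two conformations, in Å."""
    return kabsch_fit(mobile, reference, weights).rmsd


def rmsd_trace(
    ensemble: Ensemble,
    reference: np.ndarray,
    weights: np.ndarray | str | None = "masses",
) -> np.ndarray:
    """Per-frame best-fit RMSD against a fixed reference (frame order kept).

    ``weights="masses"`` uses the topology's atomic masses.
    """
    w = ensemble.topology.masses if isinstance(weights, str) else weights
    return np.array([rmsd(f, reference, w) for f in ensemble.frames])


def rmsd_landscape_2d(
    ensembles: Sequence[Ensemble],
    ref_A: np.ndarray,
    ref_B: np.ndarray,
    weights: np.ndarray | str | None = "masses",
    ref_labels: tuple[str, str] = ("A", "B"),
) -> RMSDLandscape:
    """Score every frame of every ensemble against both reference structures."""
    ref_A = np.asarray(ref_A, dtype=float)
    ref_B = np.asarray(ref_B, dtype=float)
    rows = []
    for ens in ensembles:
        if ref_A.shape != (ens.n_atoms, 3) or ref_B.shape != (ens.n_atoms, 3):
            raise TopologyError(
                f"reference atom count does not match ensemble '{ens.run_id}'"
            )
        ra = rmsd_trace(ens, ref_A, weights)
        rb = rmsd_trace(ens, ref_B, weights)
        rows.append(
            pd.DataFrame(
                {
                    "run_id": ens.run_id,
                    "state_label": ens.state_label,
                    "frame": np.arange(ens.n_frames),
                    "rmsd_A": ra,
                    "rmsd_B": rb,
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["run_id", "state_label", "frame", "rmsd_A", "rmsd_B"])
    )
    return RMSDLandscape(table=table, ref_labels=ref_labels)


def landscape_histogram(
    landscape: RMSDLandscape, bins: int | tuple[int, int] = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2D occupancy histogram (sums to 1) with bin edges."""
    if isinstance(bins, int):
        bins = (bins, bins)
    if bins[0] <= 0 or bins[1] <= 0:
        raise ParameterError("bin counts must be positive")
    pts = landscape.points
    if pts.shape[0] == 0:
        raise ParameterError("landscape has no points")
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    return hist / hist.sum(), xe, ye
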