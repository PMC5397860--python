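"""Essential-dynamics PCA of α-carbon fluctuations and KDE projections.

Frames are superposed (unweighted, matching the unweighted PCA convention)
onto a chosen reference structure, and the 3n × 3n coordinate covariance is
eigendecomposed.  Components are reported in descending-variance order with a
deterministic sign convention (largest-magnitude element positive), and all
3n components are retained so variance fractions sum exactly to one even for
degenerate covariances (trailing zero-variance components are kept as zeros).

Projections of any trajectory onto a component are scalar time series
(frame − mean)·v after superposition to the model's reference; their
distributions are summarized with a Gaussian kernel density estimate
(Scott's-rule bandwidth by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InputError, InsufficientDataError, ParameterError, TopologyError
from .model_io import Ensemble, select_atoms
from .superposition import superpose

__all__ = [
    "PCModel",
    "ProjectionDensity",
    "fit_pca",
    "variance_contributions",
    "pc_overlap",
    "project_trajectory",
    "kde_density",
]


@dataclass
class PCModel:
    """Principal components of superposed coordinate fluctuations."""

    reference_label: str
    reference: np.ndarray  # (n_sel, 3) Å — superposition target
    mean: np.ndarray  # (3n,) flattened mean structure
    components: np.ndarray  # (n_components, 3n), orthonormal rows
    variances: np.ndarray  # Å², non-increasing
    selection: str = "alpha_carbons"

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def fractions(self) -> np.ndarray:
        total = self.variances.sum()
        if total <= 0:
            return np.zeros_like(self.variances)
        return self.variances / total


@dataclass
class ProjectionDensity:
    """KDE of a projected coordinate series on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray  # ≥ 0, integrates to 1 on the grid
    bandwidth: float
    series: np.ndarray


def _superposed_flat(ensemble: Ensemble, reference: np.ndarray) -> np.ndarray:
    return np.array(
        [superpose(f, reference, weights=None) for f in ensemble.frames]
    ).reshape(ensemble.n_frames, -1)


def fit_pca(
    ensemble: Ensemble,
    reference: np.ndarray,
    selection: str = "alpha_carbons",
    reference_label: str = "reference",
) -> PCModel:
    """Fit PCA to an ensemble's fluctuations about a reference structure.

    ``reference`` must match the atom selection (e.g. α-carbon coordinates
    when ``selection="alpha_carbons"``).
    """
    ens = select_atoms(ensemble, selection)
    if ens.n_frames < 2:
        raise InsufficientDataError("PCA requires at least 2 frames")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ens.n_atoms, 3):
        raise TopologyError(
            f"reference shape {reference.shape} does not match selection "
            f"({ens.n_atoms} atoms)"
        )
    flat = _superposed_flat(ens, reference)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (ens.n_frames - 1)
    lam, vec = np.linalg.eigh(0.5 * (cov + cov.T))
    lam = lam[::-1]
    vec = vec[:, ::-1]
    if np.any(lam < -1e-10 * max(lam.max(), 1e-300)):
        warnings.warn("covariance has tiny negative eigenvalues; clipped to 0", stacklevel=2)
    lam = np.clip(lam, 0.0, None)
    if np.sum(lam > 0) < lam.size:
        warnings.warn(
            "degenerate covariance: trailing zero-variance components retained as zeros",
            stacklevel=2,
        )
    comps = vec.T
    # sign convention: largest-magnitude element of each component is positive
    signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    return PCModel(
        reference_label=reference_label,
        reference=reference,
        mean=mean,
        components=comps,
        variances=lam,
        selection=selection,
    )


def variance_contributions(model: PCModel, n: int) -> np.ndarray:
    """Cumulative variance fractions of the first ``n`` components."""
    if not 1 <= n <= model.n_components:
        raise ParameterError(f"n={n} out of range [1, {model.n_components}]")
    return np.cumsum(model.fractions[:n])


def pc_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """|a·b| between two unit-norm component vectors (sign-agnostic)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputError(f"component dimensions differ: {a.shape} vs {b.shape}")
    return float(abs(a @ b))


def project_trajectory(
    ensemble: Ensemble, model: PCModel, component: int = 1
) -> np.ndarray:
    """Scalar series of an ensemble projected onto one component (1-based)."""
    if not 1 <= component <= model.n_components:
        raise ParameterError(f"component {component} out of range")
    ens = select_atoms(ensemble, model.selection)
    if 3 * ens.n_atoms != model.mean.size:
        raise TopologyError("ensemble selection does not match the PCA model")
    flat = _superposed_flat(ens, model.reference)
    return (flat - model.mean) @ model.components[component - 1]


def kde_density(
    series: np.ndarray,
    grid: np.ndarray | tuple[float, float, int] | None = None,
    bandwidth: float | str = "scott",
) -> ProjectionDensity:
    """Gaussian-kernel density of a projected series, normalized on the grid."""
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 2:
        raise InsufficientDataError("KDE requires at least 2 samples")
    spread = series.std()
    if spread == 0:
        warnings.warn(
            "zero-spread series: returning a delta-like density", stacklevel=2
        )
        spread = max(1e-6, 1e-6 * max(abs(series[0]), 1.0))
    if grid is None:
        lo, hi = series.min() - 3 * spread, series.max() + 3 * spread
        grid = np.linspace(lo, hi, 512)
    elif isinstance(grid, tuple):
        grid = np.linspace(*grid)
    else:
        grid = np.asarray(grid, dtype=float)
    if series.std() == 0:
        density = np.exp(-0.5 * ((grid - series[0]) / spread) ** 2)
        bw = spread
    else:
        kde = gaussian_kde(series, bw_method=bandwidth)
        density = kde(grid)
        bw = float(np.sqrt(kde.covariance[0, 0]))
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ParameterError("density integrates to zero on the supplied grid")
    return ProjectionDensity(grid=grid, density=density / area, bandwidth=bw, series=series)
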