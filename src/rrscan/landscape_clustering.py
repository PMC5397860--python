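"""Clustering of 2D RMSD landscapes and perturbation-effect classification.

Pooled (RMSD-to-A, RMSD-to-B) points from many simulations are partitioned by
k-means (k-means++ init, many restarts, fixed seed; cluster ids 1..k assigned
by lexicographic center order so labels are stable across runs).  From the
fitted partition the module derives the per-simulation occupancy table
(percent of each run's frames in each cluster, columns summing to 100%),
representative frames (nearest point to each center), state-dominance cluster
groups, and a per-residue classification of how strongly each rigid-residue
perturbation displaced each state's landscape:

    shift score = |centroid_perturbed − centroid_unperturbed| / RMS spread
                  of the unperturbed cloud,

thresholded per state into {affects both, affects one state, negligible}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import InputError, ParameterError, ProvenanceError
from .model_io import Ensemble
from .superposition import RMSDLandscape

__all__ = [
    "ClusterModel",
    "EffectClassification",
    "fit_clusters",
    "occupancy_table",
    "representative_frames",
    "classify_perturbation_effect",
    "assign_cluster_groups",
]


@dataclass
class ClusterModel:
    """A fitted partition of landscape points into clusters 1..k."""

    k: int
    centers: np.ndarray  # (k, 2) Å, sorted lexicographically by (x, y)
    assignment: np.ndarray  # (n_points,), values in 1..k
    seed: int
    algorithm: str = "kmeans"


@dataclass
class EffectClassification:
    """Per-residue perturbation effect on each state's landscape.

    ``table`` columns: residue, score_<state> per state, effect_class.
    """

    table: pd.DataFrame
    threshold: float
    state_labels: tuple[str, str]


def fit_clusters(
    landscape: RMSDLandscape,
    k: int,
    seed: int = 0,
    algorithm: str = "kmeans",
    n_init: int = 50,
) -> ClusterModel:
    """Partition the pooled landscape points into ``k`` clusters."""
    pts = landscape.points
    if k < 1 or k > pts.shape[0]:
        raise ParameterError(f"k={k} must be in [1, n_points={pts.shape[0]}]")
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw_labels = km.fit_predict(pts)
        centers = km.cluster_centers_
    elif algorithm == "gmm":
        gm = GaussianMixture(n_components=k, n_init=max(1, n_init // 10), random_state=seed)
        raw_labels = gm.fit_predict(pts)
        centers = gm.means_
    else:
        raise ParameterError(f"unknown clustering algorithm '{algorithm}'")
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterModel(
        k=k,
        centers=centers[order],
        assignment=relabel[raw_labels],
        seed=seed,
        algorithm=algorithm,
    )


def occupancy_table(model: ClusterModel, landscape: RMSDLandscape) -> pd.DataFrame:
    """Percent of each simulation's frames in each cluster (columns sum to 100)."""
    if len(model.assignment) != landscape.n_points:
        raise ProvenanceError("cluster model was not fitted on this landscape")
    df = landscape.table.assign(cluster=model.assignment)
    counts = (
        df.groupby(["cluster", "run_id"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=range(1, model.k + 1), fill_value=0)
    )
    counts = counts[landscape.run_ids()]
    table = 100.0 * counts / counts.sum(axis=0)
    table.index.name = "cluster"
    return table


def representative_frames(
    model: ClusterModel,
    landscape: RMSDLandscape,
    ensembles: Mapping[str, Ensemble] | Sequence[Ensemble],
) -> list[dict]:
    """The frame whose 2D point lies nearest each cluster center.

    Ties break to the lowest run id, then frame index (guaranteed by stable
    ordering of the landscape table).  Returns one record per non-empty
    cluster with keys cluster, run_id, frame, coords, distance.
    """
    if not isinstance(ensembles, Mapping):
        ensembles = {e.run_id: e for e in ensembles}
    if len(model.assignment) != landscape.n_points:
        raise ProvenanceError("cluster model was not fitted on this landscape")
    pts = landscape.points
    table = landscape.table
    out: list[dict] = []
    for cid in range(1, model.k + 1):
        member = np.nonzero(model.assignment == cid)[0]
        if member.size == 0:
            warnings.warn(f"cluster {cid} is empty; skipped", stacklevel=2)
            continue
        dist = np.linalg.norm(pts[member] - model.centers[cid - 1], axis=1)
        best = member[int(np.argmin(dist))]
        row = table.iloc[best]
        run_id = str(row["run_id"])
        if run_id not in ensembles:
            raise ProvenanceError(f"landscape references unknown ensemble '{run_id}'")
        frame_idx = int(row["frame"])
        out.append(
            {
                "cluster": cid,
                "run_id": run_id,
                "frame": frame_idx,
                "coords": ensembles[run_id].frames[frame_idx],
                "distance": float(dist.min()),
            }
        )
    return out


def _centroid_and_spread(points: np.ndarray) -> tuple[np.ndarray, float]:
    centroid = points.mean(axis=0)
    spread = float(np.sqrt(((points - centroid) ** 2).sum(axis=1).mean()))
    return centroid, spread


def classify_perturbation_effect(
    unperturbed: Mapping[str, RMSDLandscape | np.ndarray],
    perturbed: Mapping[tuple[str, int], RMSDLandscape | np.ndarray],
    threshold: float = 1.0,
) -> EffectClassification:
    """Classify each rigid residue by how far it shifts each state's landscape.

    ``unperturbed`` maps state label → landscape (or raw (n, 2) points);
    ``perturbed`` maps (state label, residue id) → landscape.  The shift score
    for a state is the Euclidean distance between perturbed and unperturbed
    centroids divided by the unperturbed cloud's RMS spread; scores above
    ``threshold`` count as affecting that state.
    """
    def pts(obj) -> np.ndarray:
        return obj.points if isinstance(obj, RMSDLandscape) else np.asarray(obj, float)

    states = sorted(unperturbed)
    if len(states) != 2:
        raise InputError("exactly two states required")
    base = {s: _centroid_and_spread(pts(unperturbed[s])) for s in states}
    residues = sorted({r for (_, r) in perturbed})
    rows = []
    for res in residues:
        scores = {}
        for s in states:
            if (s, res) not in perturbed:
                raise InputError(f"missing perturbed landscape for state '{s}', residue {res}")
            centroid, _ = _centroid_and_spread(pts(perturbed[(s, res)]))
            c0, spread0 = base[s]
            scores[s] = float(np.linalg.norm(centroid - c0) / spread0)
        above = [s for s in states if scores[s] > threshold]
        if len(above) == 2:
            cls = "affects_both"
        elif len(above) == 1:
            cls = f"affects_{above[0]}"
        else:
            cls = "negligible"
        rows.append(
            {"residue": res, **{f"score_{s}": scores[s] for s in states}, "effect_class": cls}
        )
    return EffectClassification(
        table=pd.DataFrame(rows),
        threshold=threshold,
        state_labels=(states[0], states[1]),
    )


def assign_cluster_groups(
    table: pd.DataFrame,
    run_states: Mapping[str, str],
    dominance_threshold: float = 0.8,
) -> pd.Series:
    """Label each cluster by the state whose simulations dominate it.

    A cluster whose occupancy mass comes ≥ ``dominance_threshold`` from one
    state's runs gets that state's label; otherwise ``"shared"``.  Occupancy
    percentages are frame-share weighted assuming equal frame counts per run
    column (the orchestrator enforces this for compared runs).
    """
    missing = [c for c in table.columns if c not in run_states]
    if missing:
        raise ProvenanceError(f"no state labels for runs: {missing}")
    states = sorted(set(run_states[c] for c in table.columns))
    mass = {
        s: table[[c for c in table.columns if run_states[c] == s]].sum(axis=1)
        for s in states
    }
    total = sum(mass.values())
    groups = []
    for cid in table.index:
        if total[cid] <= 0:
            groups.append("shared")
            continue
        fractions = {s: mass[s][cid] / total[cid] for s in states}
        top = max(fractions, key=lambda s: fractions[s])
        groups.append(top if fractions[top] >= dominance_threshold else "shared")
    return pd.Series(groups, index=table.index, name="group")
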