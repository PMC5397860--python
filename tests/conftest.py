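"""Shared fixtures: tiny PDB text, toy models, and one session-scoped scan.

The session scan executes the full two-state rigid-residue design at desk
scale (20 residues × 4 beads, 42 runs) once; several integration tests share
it so the expensive simulation is not repeated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from rrscan.model_io import Ensemble, Topology
from rrscan.scan_orchestrator import aggregate_report, build_manifest, run_scan
from rrscan.synthetic_data import build_two_state_toy

#: master seed of the session scan — one fixed value for the whole suite
SCAN_SEED = 7

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.804   7.434  -6.604  1.00 10.00           C
ATOM      3  C   ALA A   1      13.247   7.264  -7.102  1.00 10.00           C
ATOM      4  N   GLY A   2      13.608   6.010  -7.372  1.00 10.00           N
ATOM      5  CA AGLY A   2      14.959   5.698  -7.852  0.35 10.00           C
ATOM      6  CA BGLY A   2      14.919   5.798  -7.852  0.65 10.00           C
ATOM      7  C   GLY A   2      15.219   6.261  -9.242  1.00 10.00           C
ATOM      8  N   SER A   3      16.462   6.112  -9.702  1.00 10.00           N
ATOM      9  CA  SER A   3      16.869   6.588 -11.022  1.00 10.00           C
ATOM     10  C   SER A   3      16.182   5.811 -12.142  1.00 10.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    """3-residue, 9-atom structure; one altloc pair (B has higher occupancy)."""
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def bead_ensemble():
    """Deterministic 4-bead / 2-residue ensemble with nontrivial motion."""
    rng = np.random.default_rng(42)
    topo = Topology(
        atom_names=("CA", "B2", "CA", "B2"),
        masses=np.array([12.0, 12.0, 12.0, 16.0]),
        residue_index=np.array([1, 1, 2, 2]),
        residue_names=("AAA", "BBB"),
        is_alpha_carbon=np.array([True, False, True, False]),
    )
    base = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 3.0, 0.0], [1.5, 3.0, 1.0]]
    )
    frames = base + 0.2 * rng.standard_normal((50, 4, 3))
    return Ensemble(topology=topo, frames=frames, run_id="bead-run")


@pytest.fixture(scope="session")
def toy_model():
    return build_two_state_toy(seed=SCAN_SEED)


@pytest.fixture(scope="session")
def toy_scan(toy_model):
    """Full 42-run rigid-residue scan of the toy model (session-scoped)."""
    manifest = build_manifest(
        {
            "states": list(toy_model.states),
            "residue_range": [1, toy_model.topology.n_residues],
            "seed": SCAN_SEED,
        }
    )
    store = run_scan(manifest, toy_model, frames_per_run=1000)
    return store


@pytest.fixture(scope="session")
def toy_report(toy_scan, toy_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate_report(toy_scan, toy_model, analyses={"k_clusters": 6})
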