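# rrscan

Rigid-residue-scan (RRS) perturbation analysis for protein dynamics.

An RRS probes allostery without mutations: a protein is re-simulated once
per residue with that residue held as a rigid body — its internal degrees of
freedom removed, its chemistry untouched — and the response of the *global*
dynamics is measured against the unperturbed baseline.  For a photoreceptor
with distinct Dark (compact) and Light (extended N-terminal arm) states,
this identifies residues whose internal flexibility selectively stabilizes
one state or the other.  `rrscan` is for computational structural biologists
who have (or want to generate) such ensembles and need the full analysis
stack behind the protocol:

* **Dual-reference 2D RMSD landscapes** — every frame scored by
  mass-weighted best-fit RMSD (weighted Kabsch superposition) against both
  state references; k-means clustering of the pooled landscape with
  per-simulation occupancy tables, representative structures, and
  state-dominance cluster groups.
* **Dynamic cross-correlation matrices** — C_ij = c_ij/√(c_ii c_jj) from
  the superposed coordinate covariance.
* **Quasi-harmonic configurational entropy** — effective force constants
  F = k_BT Σ⁻¹, mode frequencies ω = √(k_BT/λ) from the mass-weighted
  covariance spectrum, and the quantum harmonic-oscillator entropy
  S = k_B Σᵢ[αᵢ/(e^{αᵢ}−1) − ln(1−e^{−αᵢ})], αᵢ = ħωᵢ/k_BT — whole-protein
  and per-residue (covariance sub-blocks), absolute and relative to the
  unperturbed references.
* **Essential dynamics** — unweighted α-carbon PCA, variance contributions,
  inter-simulation PC overlaps, trajectory projections and their KDE
  densities.
* **A scan orchestrator** — enumerates the full design (one unperturbed run
  per state plus one run per state × residue), derives per-run seeds from a
  master seed, executes, stores, resumes, and aggregates every analysis into
  a stamped report bundle.
* **Synthetic data with oracles** — Gaussian ensembles whose exact
  quasi-harmonic entropy is known in closed form from the specified
  covariance, and a two-state coarse-grained elastic-network Langevin
  simulator with an exact per-residue rigid-body constraint, so the entire
  pipeline runs and is validated at desk scale.

Structures are read with Biopython, DCD/XTC trajectories with MDAnalysis,
clustering uses scikit-learn; see `docs/methods.md` for the models,
conventions and numerical choices.

## Worked example

Enumerate the classic scan design, then validate the entropy machinery
against the closed-form Gaussian oracle:

```python
import numpy as np
from rrscan.scan_orchestrator import build_manifest, total_production_time
from rrscan.synthetic_data import (
    GaussianEnsembleSpec, analytic_entropy, sample_gaussian_ensemble,
)
from rrscan.correlation_entropy import (
    covariance_matrix, quasiharmonic_modes, configurational_entropy,
)

manifest = build_manifest({"states": ["dark", "light"], "residue_range": [1, 148]})
print(f"runs: {manifest.n_runs}, total production: {total_production_time(manifest):.0f} ns")

rng = np.random.default_rng(0)
a = rng.standard_normal((30, 30))
spec = GaussianEnsembleSpec(
    mean=rng.standard_normal((10, 3)),
    covariance=a @ a.T / 30 * 0.2 + 0.05 * np.eye(30),
    masses=np.full(10, 12.0),
    n_frames=20_000,
    seed=1,
)
ens = sample_gaussian_ensemble(spec)
cov = covariance_matrix(ens, superpose_frames=False)
spectrum = quasiharmonic_modes(cov, temperature=300.0, zero_mode_policy="cutoff")
print(f"sampled entropy: {configurational_entropy(spectrum):.5f} kcal/mol·K")
print(f"analytic entropy: {analytic_entropy(spec):.5f} kcal/mol·K")
```

prints

```
runs: 298, total production: 9300 ns
sampled entropy: 0.13557 kcal/mol·K
analytic entropy: 0.13567 kcal/mol·K
```

— a two-state scan over 148 residues comprises 296 perturbed runs plus two
unperturbed ones, 9,300 ns of production time at the design durations
(210 ns unperturbed, 30 ns per perturbed run); and the trajectory entropy
estimator recovers the exact covariance-functional entropy of a 10-bead
Gaussian ensemble to 0.07% at 2×10⁴ frames.

A complete desk-scale scan of the built-in two-state toy (20 residues,
42 runs) with all downstream analyses:

```python
from rrscan.scan_orchestrator import aggregate_report, build_manifest, run_scan
from rrscan.synthetic_data import build_two_state_toy

model = build_two_state_toy(seed=7)
manifest = build_manifest(
    {"states": model.states, "residue_range": [1, 20], "seed": 7}
)
store = run_scan(manifest, model, frames_per_run=1000, store_dir="runs")
bundle = aggregate_report(store, model, analyses={"k_clusters": 6})
bundle.write("report")          # rmsd2d.csv, occupancy.csv, entropy_*.csv, …
```

The same is available from a shell: `rrscan scan --config scan.yaml --runs
runs/` then `rrscan report --config scan.yaml --runs runs/ --out report/`.

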