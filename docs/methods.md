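# Methods

`rrscan` implements the trajectory-analysis stack of a rigid-residue scan
(RRS): a perturbation protocol in which a protein is re-simulated once per
residue with that residue's internal degrees of freedom removed by a
rigid-body constraint, and the response of the global dynamics — the
conformational landscape, the correlation structure, and the configurational
entropy — is measured against the unperturbed two-state baseline.  This note
records the models, the numerical choices, and what the built-in synthetic
data can and cannot show.

## Superposition and RMSD

Structural comparison uses the weighted Kabsch algorithm: for mobile
coordinates r and reference r', the proper rotation U and translation
minimizing Σᵢ wᵢ|U·rᵢ + t − r'ᵢ|² are obtained from the SVD of the weighted
cross-covariance of centered coordinates, with the sign of the smallest
singular direction corrected so det U = +1 (reflections are never returned;
this is property-tested on random point sets).  The mass-weighted RMSD is

    RMSD = sqrt( Σᵢ wᵢ |U·rᵢ + t − r'ᵢ|² / Σᵢ wᵢ ),

with weights defaulting to atomic masses.  Fits with fewer than 3 atoms or
collinear geometry raise an error rather than returning an arbitrary member
of the degenerate optimum; ties among degenerate singular values resolve
through LAPACK's deterministic SVD ordering.  The 2D landscape scores every
frame of every simulation against both reference conformations, giving a
(RMSD-to-A, RMSD-to-B) point per frame; because best-fit RMSD is a metric,
all points obey |x − y| ≤ RMSD(A, B), a property the tests assert.

## Cross-correlation

After superposing all frames onto a fixed reference (removing translation
and rotation), the normalized cross-correlation of atoms i and j is

    C_ij = c_ij / sqrt(c_ii c_jj),

where c_ij is the trace of the 3×3 displacement-covariance block.  Entries
lie in [−1, 1] with unit diagonal.  Atoms with zero positional variance
(e.g. frozen beads) produce undefined entries; these are reported as NaN
with a warning, never silently zeroed.

## Quasi-harmonic configurational entropy

Equilibrium fluctuations are modeled as an effective harmonic well whose
force-constant matrix is F = k_B T Σ⁻¹, with Σ the unnormalized,
mass-unweighted coordinate covariance (Å²) of the superposed trajectory.
The normalized correlation matrix cannot play this role — it is
dimensionless, and F = k_B T C⁻¹ would be dimensionally inconsistent — so
the covariance interpretation is used, matching standard quasi-harmonic
practice.  The secular equation F u = ω² M u is solved through the
equivalent symmetric eigenproblem of M^{1/2} Σ M^{1/2}; each eigenvalue λ
(amu·Å²) yields ω = sqrt(k_B T / λ) in rad/ps.  The entropy in the harmonic
limit is the quantum harmonic-oscillator sum over retained modes
(Andricioaei–Karplus form):

    S = k_B Σᵢ [ αᵢ/(e^{αᵢ} − 1) − ln(1 − e^{−αᵢ}) ],  αᵢ = ħωᵢ/(k_B T),

in kcal/mol·K, with k_B = 1.9872041×10⁻³ kcal/mol/K and ħ converted to
kcal·ps/mol; all constants live in `rrscan.constants`.  The quantum form is
adopted (rather than the classical oscillator entropy) because it is the
standard choice in quasi-harmonic work and is finite for stiff modes; stiff
modes (α ≫ 1) contribute nothing, soft modes dominate.

**Zero-mode policy.**  Because superposition removes translation and
rotation, six linear combinations of coordinates carry near-zero variance.
Under ω = sqrt(k_B T/λ) these rigid-body remnants are the *highest*-frequency
(smallest-λ) modes and contribute essentially no entropy; the default policy
(`"rigid_body"`) drops the six smallest-variance modes explicitly, plus any
mode below a low-frequency cutoff (default 10⁻³ rad/ps) that would signal
unremoved drift.  Full-rank synthetic covariances use the `"cutoff"` or
`"none"` policies.  Rank-deficient covariances are regularized by flooring
eigenvalues at 10⁻¹² × trace/3n (with an absolute floor of 10⁻³⁰ amu·Å²),
with a warning; significantly negative eigenvalues raise an error reporting
the numerical rank.

**Gaussian entropy oracle.**  For an ensemble drawn from a known covariance,
the entropy is a closed-form functional of that covariance.
`synthetic_data.analytic_entropy` evaluates it through the *same* mode
construction and entropy formula as the trajectory path; only the covariance
source differs (true vs sampled).  This gives a ground truth against which
the sampled estimator is verified to within 2% at 2×10⁴ frames for a 10-bead
system.

**Per-residue entropy.**  A residue's entropy comes from its own 3m×3m
covariance sub-block, cut from the whole-protein covariance after
whole-protein superposition.  No rigid-body exclusion is applied within the
block: the block legitimately retains the residue's translation/rotation
relative to the protein frame.  Cross-residue correlation is deliberately
excluded, so residue entropies do not (and should not) sum to the
whole-protein value.  Normalized per-residue entropies divide by the
residue's atom count.  Relative-entropy tables reference every run's
whole-protein entropy to the single unperturbed compact-state run, and every
per-residue entropy to the same residue in the same state's unperturbed run.

**Entropy windows.**  When runs of unequal length are compared, every run is
truncated to the shortest frame count before covariance accumulation, so
entropy differences are not confounded by sampling-length effects.

## Essential-dynamics PCA and projections

PCA is unweighted and restricted to α-carbons (the mass-weighted variant of
the same eigenproblem is exactly the quasi-harmonic mode problem above).
Frames are superposed — unweighted, for consistency — onto a chosen
reference structure; the package supports both study conventions (each
state's trajectory against its own or the opposite state's optimized
reference; the orchestrator defaults to the opposite-reference convention).
All 3n components are retained, in descending variance order with a
deterministic sign convention (largest-magnitude element positive), so
variance fractions sum exactly to 1 even for degenerate covariances.
Overlaps between component vectors are reported as |a·b|, since PC signs are
arbitrary.  Projections are (frame − mean)·v after superposition; their
densities use a Gaussian KDE with Scott's-rule bandwidth by default
(config-overridable).  A zero-spread series yields a delta-like density with
a warning instead of a failure.

## Landscape clustering and perturbation classification

The pooled 2D RMSD point cloud is clustered with k-means (k-means++
initialization, 50 restarts, fixed seed; a Gaussian-mixture alternative is
available).  Raw points are clustered rather than binned densities.  Cluster
ids 1..k are assigned by lexicographic center order so labels are stable.
Occupancy tables report the percentage of each simulation's frames per
cluster; columns sum to 100% by construction.  Representatives are the
frames nearest each center, ties broken to the lowest run id then frame
index.  Clusters are grouped by state dominance: a cluster receiving ≥ 80%
(configurable) of its occupancy mass from one state's simulations is labeled
with that state; otherwise it is shared.

Perturbation effects are classified quantitatively: for each rigid residue
and each state, the shift score is the Euclidean distance between the
perturbed and unperturbed landscape centroids divided by the unperturbed
cloud's RMS spread.  Scores above a threshold (default 1.0) in one state, the
other, or both yield the classes `affects_<state>` / `affects_both` /
`negligible`.  The score is symmetric under state relabeling and monotone in
the visual displacement of the distributions.

## The synthetic two-state toy

Real RRS studies run all-atom explicit-solvent MD; this package instead
ships a coarse-grained elastic-network model integrated with overdamped
(Euler–Maruyama) Langevin dynamics, sufficient to generate equilibrium
ensembles of a harmonic network and to exercise every analysis above at desk
scale.  Design, with rationale:

* **Geometry.**  20 residues × 4 beads (12 amu each).  The core (residues
  6–20) sits on a spherical spiral of radius 5.5 Å — compact, densely
  cross-linked, hence stiff with fast-decorrelating collective modes.  The
  N-terminal arm (residues 1–5) is packed along the globule surface in state
  A ("compact"/dark-like) and lifts off, partially unwinding, in state B
  ("extended"/light-like).  This mirrors the compact-vs-extended N-terminal
  difference between a photoreceptor's dark and light conformations.
* **Springs.**  All intra-residue bead pairs are bonded (5 kcal/mol/Å² in
  the core).  Inter-residue springs connect bead pairs within 7 Å in either
  reference (union of contacts), at 2 kcal/mol/Å², with per-state rest
  lengths measured on each state's own reference so both references are
  force-free minima.
* **Differential flexibility.**  Arm residues' internal springs are softened
  by `arm_flexibility` (default 0.05), and halved again in state B.  Each
  arm residue anchors to its surroundings through two designated side beads
  only; its backbone (α-carbon) bead and remaining side bead carry no
  inter-residue contacts, so their fluctuation is *internal* — precisely the
  variance a rigid-body constraint removes, and (for the backbone bead)
  variance visible to α-carbon essential-dynamics analysis.  A soft chain of
  springs links consecutive arm backbone beads down to the first core
  residue, giving the arm one dominant collective backbone mode that a
  constraint on any single arm residue pins locally.  With four beads a
  residue has six internal modes against six rigid-body modes, so the
  entropy removed by the constraint dominates run-to-run sampling noise in
  the residue's tumbling.  Earlier design candidates placed the arm's
  floppiness in inter-residue hinges; a rigid residue constraint cannot
  remove hinge compliance, which made the expected arm-versus-core orderings
  fragile.  The final design makes them structural.
* **Integration.**  Overdamped dynamics, x ← x + F dt/(mγ) + √(2k_BT dt/(mγ)) ξ,
  with γ = 2 ps⁻¹, dt = 0.002 ps, T = 300 K.  These put the stiffest beads at
  a stability factor (relaxation rate × dt) ≲ 0.8 — a stable regime with
  modest discretization bias — while the softest collective modes decorrelate
  within a few ps, so 5×10⁴-step runs yield well-converged covariances.
  Inertial Langevin dynamics would add complexity without changing the
  equilibrium ensemble of a harmonic network.
* **Rigid constraint.**  Each step, the constrained residue's proposed
  displacement is replaced by the closest mass-weighted rigid-body motion,
  computed by a weighted Kabsch fit of the current residue geometry onto its
  proposed position (an exact rotation, not a linearization, so there is no
  accumulating drift; the projection is idempotent to machine precision).
  Intra-residue distances are conserved to ~10⁻¹² relative over 5×10⁴ steps.
  Residues with fewer than 3 beads or collinear geometry degrade to
  translation-only with a warning.
* **Seeding.**  One master seed per scan; per-run seeds derive from it
  through a spawned `numpy` seed sequence, making the full scan bit-for-bit
  reproducible.

### What the toy does and does not show

The toy is a single-basin harmonic network per state.  It reproduces the
*structural* signatures of the scan — the constrained residue's entropy
depletion (the diagonal signature in per-residue heat maps), arm-versus-core
ordering of landscape displacement, the extended state's larger spread — and
it exercises every pipeline stage end to end.  It cannot reproduce basin
hopping, the drastic cluster-switching effects, or any specific magnitude
from all-atom solvated simulations of a real photoreceptor: those phenomena
are anharmonic and chemistry-specific.  Passing tests therefore validate the
analysis machinery and the constraint mechanics, not biological conclusions.

## Scan orchestration and problem sizes

The manifest enumerates one unperturbed run per state plus one run per
(state, residue) pair; durations follow the study design this pipeline
targets (210 ns unperturbed, 30 ns per perturbed run, 4 ns equilibration
discarded), which the manifest records in ns for bookkeeping and arithmetic.
At desk scale each perturbed run is integrated for 5×10⁴ steps saving every
50 (1000 frames ≈ 100 ps), with unperturbed runs scaled proportionally
(7000 frames) and the equilibration fraction simulated and discarded before
the first saved frame; a full 42-run two-state scan completes in a few
minutes on one CPU.  Runs are stored as plain-text frame archives with JSON
metadata, keyed by run id, so scans resume after interruption and every
report is stamped with the manifest hash and master seed.  A failed (e.g.
numerically unstable) run is recorded and skipped; the report lists the gap
rather than aborting the scan.

## Known limitations

* The Euler–Maruyama integrator has O(dt) bias in stationary variances; at
  the default stability factor the bias on the stiffest (lowest-entropy)
  modes is a few percent.  Comparisons between runs use identical
  integration settings, so orderings are unaffected.
* Per-residue entropies include the residue's rigid-body motion relative to
  the protein frame; in systems where a constraint increases a residue's
  tumbling more than it removes internal fluctuation, the net per-residue
  entropy change can be positive.  The shipped toy is constructed so the
  internal share dominates.
* In a strictly harmonic model a perturbation changes fluctuation variances
  but not mean structures, so projected densities respond in width rather
  than position; the projection-level arm-versus-core comparison is
  therefore asserted on the suppression of the dominant mode's projection
  variance, where the landscape-level comparison can use centroids (mean
  RMSD is variance-sensitive).
* The frame archive stores coordinates in text at 10 significant digits;
  round-tripping through multi-model PDB loses precision below 10⁻³ Å.
* KDE densities are normalized on their evaluation grid; probability mass
  outside a user-supplied grid is renormalized away.
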