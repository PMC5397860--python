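"""Covariance estimation, cross-correlation bounds, quasi-harmonic modes and
configurational entropy, validated against closed forms and the Gaussian
analytic-entropy oracle."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rrscan.constants import HBAR_KCAL_PS_MOL, KB_AKMA, KB_KCAL_MOL_K
from rrscan.correlation_entropy import (
    CovarianceResult,
    configurational_entropy,
    covariance_matrix,
    cross_correlation,
    entropy_report,
    quasiharmonic_modes,
    relative_entropy_table,
    residue_entropy,
)
from rrscan.errors import InsufficientDataError, MissingReferenceError
from rrscan.model_io import Ensemble, Topology
from rrscan.synthetic_data import (
    GaussianEnsembleSpec,
    analytic_entropy,
    sample_gaussian_ensemble,
)


def random_psd_spec(n_atoms=10, n_frames=20_000, seed=7, scale=0.2):
    rng = np.random.default_rng(seed)
    n3 = 3 * n_atoms
    a = rng.standard_normal((n3, n3))
    cov = a @ a.T / n3 * scale + 0.05 * np.eye(n3)
    return GaussianEnsembleSpec(
        mean=rng.standard_normal((n_atoms, 3)),
        covariance=cov,
        masses=np.full(n_atoms, 12.0),
        n_frames=n_frames,
        seed=seed,
    )


def two_bead_ensemble(signs, n_frames=200):
    """Two beads driven by one scalar mode with given per-bead signs."""
    rng = np.random.default_rng(0)
    s = rng.standard_normal(n_frames)
    topo = Topology(
        atom_names=("CA", "CA"),
        masses=np.array([12.0, 12.0]),
        residue_index=np.array([1, 2]),
        residue_names=("AAA", "BBB"),
        is_alpha_carbon=np.array([True, True]),
    )
    base = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    frames = np.array(
        [base + np.outer(signs, [1.0, 0.5, -0.3]) * t for t in s]
    )
    return Ensemble(topology=topo, frames=frames, run_id="pair")


class TestCovarianceMatrix:
    def test_identical_frames_give_zero(self, bead_ensemble):
        ens = Ensemble(
            topology=bead_ensemble.topology,
            frames=np.repeat(bead_ensemble.frames[:1], 5, axis=0),
            run_id="same",
        )
        cov = covariance_matrix(ens, reference=ens.frames[0])
        assert np.abs(cov.covariance).max() <= 1e-18

    def test_single_frame_rejected(self, bead_ensemble):
        ens = Ensemble(
            topology=bead_ensemble.topology,
            frames=bead_ensemble.frames[:1],
            run_id="one",
        )
        with pytest.raises(InsufficientDataError):
            covariance_matrix(ens)

    def test_recovers_known_covariance(self):
        """Frobenius error < 5% against the generating covariance (pre-superposed
        Gaussian frames, 2×10⁴ draws, 10 beads)."""
        spec = random_psd_spec()
        ens = sample_gaussian_ensemble(spec)
        cov = covariance_matrix(ens, superpose_frames=False)
        err = np.linalg.norm(cov.covariance - spec.covariance) / np.linalg.norm(
            spec.covariance
        )
        assert err < 0.05


class TestCrossCorrelation:
    def test_common_motion_is_plus_one(self):
        cov = covariance_matrix(two_bead_ensemble([1.0, 1.0]), superpose_frames=False)
        corr = cross_correlation(cov)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_motion_is_minus_one(self):
        cov = covariance_matrix(two_bead_ensemble([1.0, -1.0]), superpose_frames=False)
        corr = cross_correlation(cov)
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_beads_near_zero(self):
        spec = random_psd_spec(n_atoms=2, seed=3, scale=0.0)  # diagonal-dominant
        ens = sample_gaussian_ensemble(spec)
        corr = cross_correlation(covariance_matrix(ens, superpose_frames=False))
        assert abs(corr[0, 1]) < 0.05

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounds_and_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        frames = rng.standard_normal((30, n, 3))
        topo = Topology(
            atom_names=tuple("CA" for _ in range(n)),
            masses=np.full(n, 12.0),
            residue_index=np.arange(1, n + 1),
            residue_names=tuple("AAA" for _ in range(n)),
            is_alpha_carbon=np.ones(n, dtype=bool),
        )
        ens = Ensemble(topology=topo, frames=frames, run_id="rnd")
        corr = cross_correlation(covariance_matrix(ens, superpose_frames=False))
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)
        assert np.nanmax(corr) <= 1.0 and np.nanmin(corr) >= -1.0
        np.testing.assert_array_equal(corr, corr.T)

    def test_frozen_bead_flagged_not_zeroed(self):
        rng = np.random.default_rng(1)
        frames = rng.standard_normal((40, 2, 3))
        frames[:, 1, :] = 7.0  # fully frozen bead
        topo = two_bead_ensemble([1, 1]).topology
        ens = Ensemble(topology=topo, frames=frames, run_id="frozen")
        with pytest.warns(UserWarning, match="zero positional variance"):
            corr = cross_correlation(covariance_matrix(ens, superpose_frames=False))
        assert np.isnan(corr[1, :]).all() and np.isnan(corr[:, 1]).all()


class TestQuasiHarmonicModes:
    def test_single_particle_closed_form(self):
        """ω = √(k_BT/(mσ²)) to 1e−8 relative."""
        m, sigma2, temp = 15.0, 0.42, 310.0
        cov = CovarianceResult(
            mean=np.zeros((1, 3)), covariance=sigma2 * np.eye(3), n_frames=0
        )
        spec = quasiharmonic_modes(
            cov, masses=np.array([m]), temperature=temp, zero_mode_policy="none"
        )
        expected = np.sqrt(KB_AKMA * temp / (m * sigma2))
        np.testing.assert_allclose(spec.frequencies, expected, rtol=1e-8)

    def test_isotropic_covariance_equal_masses_degenerate_spectrum(self):
        cov = CovarianceResult(
            mean=np.zeros((4, 3)), covariance=0.3 * np.eye(12), n_frames=0
        )
        spec = quasiharmonic_modes(
            cov, masses=np.full(4, 12.0), zero_mode_policy="none"
        )
        assert np.ptp(spec.frequencies) <= 1e-10 * spec.frequencies[0]

    def test_sampled_frequencies_recover_truth(self):
        """Frequencies from 2×10⁴ sampled frames within 3% of the true-Σ modes."""
        spec = random_psd_spec(seed=11)
        ens = sample_gaussian_ensemble(spec)
        sampled = quasiharmonic_modes(
            covariance_matrix(ens, superpose_frames=False),
            temperature=300.0,
            zero_mode_policy="cutoff",
        )
        true_cov = CovarianceResult(
            mean=spec.mean, covariance=spec.covariance, n_frames=0
        )
        truth = quasiharmonic_modes(
            true_cov, masses=spec.masses, temperature=300.0, zero_mode_policy="cutoff"
        )
        np.testing.assert_allclose(sampled.frequencies, truth.frequencies, rtol=0.03)

    def test_frequencies_scale_inverse_sqrt_mass(self):
        spec = random_psd_spec(n_atoms=4, seed=5)
        cov = CovarianceResult(mean=spec.mean, covariance=spec.covariance, n_frames=0)
        base = quasiharmonic_modes(cov, masses=spec.masses, zero_mode_policy="none")
        heavy = quasiharmonic_modes(
            cov, masses=4.0 * spec.masses, zero_mode_policy="none"
        )
        np.testing.assert_allclose(
            heavy.frequencies, base.frequencies / 2.0, rtol=1e-10
        )

    def test_rigid_body_policy_drops_six(self):
        spec = random_psd_spec(n_atoms=5, seed=6)
        cov = CovarianceResult(mean=spec.mean, covariance=spec.covariance, n_frames=0)
        all_modes = quasiharmonic_modes(cov, masses=spec.masses, zero_mode_policy="none")
        pruned = quasiharmonic_modes(
            cov, masses=spec.masses, zero_mode_policy="rigid_body"
        )
        assert pruned.n_excluded == 6
        assert pruned.frequencies.size == all_modes.frequencies.size - 6
        # the six dropped modes are the smallest-variance (highest-frequency) ones
        np.testing.assert_allclose(
            pruned.frequencies, all_modes.frequencies[:-6], rtol=1e-12
        )

    def test_modes_orthonormal_in_mass_metric(self):
        spec = random_psd_spec(n_atoms=4, seed=8)
        cov = CovarianceResult(mean=spec.mean, covariance=spec.covariance, n_frames=0)
        qh = quasiharmonic_modes(cov, masses=spec.masses, zero_mode_policy="none")
        m = np.repeat(spec.masses, 3)
        gram = qh.modes.T @ (m[:, None] * qh.modes)
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


class TestConfigurationalEntropy:
    def test_stiff_mode_contributes_nothing(self):
        from rrscan.correlation_entropy import QuasiHarmonicSpectrum

        spec = QuasiHarmonicSpectrum(
            frequencies=np.array([1e9]), modes=np.zeros((3, 1)), n_excluded=0,
            temperature=300.0,
        )
        assert configurational_entropy(spec) == pytest.approx(0.0, abs=1e-15)

    def test_strictly_decreasing_in_frequency(self):
        from rrscan.correlation_entropy import QuasiHarmonicSpectrum

        def s(omega):
            return configurational_entropy(
                QuasiHarmonicSpectrum(
                    frequencies=np.array([omega, 5.0]),
                    modes=np.zeros((6, 2)),
                    n_excluded=0,
                    temperature=300.0,
                )
            )

        values = [s(w) for w in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(values) < 0)

    def test_three_mode_toy_matches_scalar_sum(self):
        from rrscan.correlation_entropy import QuasiHarmonicSpectrum

        omegas = np.array([2.0, 7.0, 31.0])
        temp = 300.0
        expected = 0.0
        for w in omegas:  # independent scalar evaluation
            a = HBAR_KCAL_PS_MOL * w / (KB_KCAL_MOL_K * temp)
            expected += KB_KCAL_MOL_K * (
                a / (np.exp(a) - 1.0) - np.log(1.0 - np.exp(-a))
            )
        spec = QuasiHarmonicSpectrum(
            frequencies=omegas, modes=np.zeros((9, 3)), n_excluded=0, temperature=temp
        )
        assert configurational_entropy(spec) == pytest.approx(expected, rel=1e-12)

    def test_entropy_oracle_recovery(self):
        """Sampled-ensemble entropy within 2% of the analytic value (10 beads,
        2×10⁴ frames)."""
        spec = random_psd_spec()
        ens = sample_gaussian_ensemble(spec)
        cov = covariance_matrix(ens, superpose_frames=False)
        sampled = configurational_entropy(
            quasiharmonic_modes(cov, temperature=spec.temperature,
                                zero_mode_policy="cutoff")
        )
        truth = analytic_entropy(spec)
        assert sampled == pytest.approx(truth, rel=0.02)

    def test_invariant_under_global_rigid_motion(self):
        """Applying one rigid motion to every frame leaves the entropy fixed."""
        spec = random_psd_spec(n_atoms=6, n_frames=2000, seed=13)
        ens = sample_gaussian_ensemble(spec)
        rot = Rotation.from_euler("zyx", [0.7, -0.4, 1.1]).as_matrix()
        moved = Ensemble(
            topology=ens.topology,
            frames=ens.frames @ rot.T + np.array([3.0, -2.0, 5.0]),
            run_id="moved",
        )
        ref = ens.frames[0]

        def entropy(e):
            cov = covariance_matrix(e, reference=ref)
            return configurational_entropy(
                quasiharmonic_modes(cov, temperature=300.0, zero_mode_policy="rigid_body")
            )

        assert entropy(moved) == pytest.approx(entropy(ens), abs=1e-6)


class TestResidueEntropy:
    def test_sum_of_residues_differs_from_total(self):
        """Cross-residue correlation is excluded from residue blocks, so the
        residue sum need not reproduce the whole-protein entropy."""
        spec = random_psd_spec(n_atoms=6, n_frames=5000, seed=17)
        ens = sample_gaussian_ensemble(spec)  # one bead per residue, correlated
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = entropy_report(ens, reference=ens.frames[0], zero_mode_policy="cutoff")
        assert rep.per_residue.sum() != pytest.approx(rep.total, rel=1e-3)

    def test_duplicate_frames_degenerate(self, bead_ensemble):
        ens = Ensemble(
            topology=bead_ensemble.topology,
            frames=np.repeat(bead_ensemble.frames[:1], 4, axis=0),
            run_id="dup",
        )
        with pytest.warns(UserWarning):
            cov = covariance_matrix(ens, reference=ens.frames[0])
            s = residue_entropy(cov, 1)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_normalization_by_atom_count(self, bead_ensemble):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = entropy_report(
                bead_ensemble, reference=bead_ensemble.frames[0],
                zero_mode_policy="cutoff",
            )
        counts = bead_ensemble.topology.residue_atom_counts()
        np.testing.assert_allclose(rep.normalized, rep.per_residue / counts)
        assert np.all(rep.per_residue >= 0)

    def test_single_bead_residue_normalized_equals_raw(self):
        spec = random_psd_spec(n_atoms=3, n_frames=500, seed=19)
        ens = sample_gaussian_ensemble(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = entropy_report(ens, reference=ens.frames[0], zero_mode_policy="cutoff")
        np.testing.assert_allclose(rep.normalized, rep.per_residue)

    def test_duplicated_bead_halves_normalized_value(self):
        """A residue of two beads with identical statistics has ~the same raw
        entropy per bead, so the per-atom normalization halves."""
        rng = np.random.default_rng(23)
        s = rng.standard_normal((400, 3))
        frames1 = (np.zeros((400, 1, 3)) + s[:, None]) * 0.5
        topo1 = Topology(
            atom_names=("CA",), masses=np.array([12.0]),
            residue_index=np.array([1]), residue_names=("AAA",),
            is_alpha_carbon=np.array([True]),
        )
        # same residue built from two beads moving together (plus tiny jitter
        # to keep the covariance nonsingular)
        jitter = 1e-3 * rng.standard_normal((400, 2, 3))
        frames2 = np.stack([frames1[:, 0]] * 2, axis=1) + jitter
        frames2[:, 1, 0] += 2.0
        topo2 = Topology(
            atom_names=("CA", "B2"), masses=np.array([12.0, 12.0]),
            residue_index=np.array([1, 1]), residue_names=("AAA",),
            is_alpha_carbon=np.array([True, False]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = Ensemble(topology=topo1, frames=frames1, run_id="one")
            e2 = Ensemble(topology=topo2, frames=frames2, run_id="two")
            cov1 = covariance_matrix(e1, superpose_frames=False)
            cov2 = covariance_matrix(e2, superpose_frames=False)
            n1 = residue_entropy(cov1, 1) / 1
            n2 = residue_entropy(cov2, 1) / 2
        # duplicated-bead modes add little entropy: normalized value ~halves
        assert n2 < 0.65 * n1


class TestRelativeEntropyTable:
    def _reports(self):
        from rrscan.correlation_entropy import EntropyReport

        vals = {"A-unperturbed": 1.0, "B-unperturbed": 1.2, "A-rigid003": 1.05,
                "B-rigid003": 1.1}
        reports = {}
        for rid, total in vals.items():
            state = rid.split("-")[0]
            pert = None if "unperturbed" in rid else 3
            reports[rid] = EntropyReport(
                run_id=rid, state_label=state, perturbation=pert, total=total,
                per_residue=np.array([0.5, 0.5]) * total,
                normalized=np.array([0.5, 0.5]) * total, temperature=300.0,
            )
        return reports

    def test_reference_relative_to_itself_is_zero(self):
        reports = self._reports()
        tables = relative_entropy_table(
            reports, "A-unperturbed", {"A": "A-unperturbed", "B": "B-unperturbed"}
        )
        total = tables["total"].set_index("run_id")
        assert total.loc["A-unperturbed", "relative"] == 0.0
        assert len(total) == len(reports)

    def test_cells_are_raw_differences(self):
        reports = self._reports()
        tables = relative_entropy_table(
            reports, "A-unperturbed", {"A": "A-unperturbed", "B": "B-unperturbed"}
        )
        total = tables["total"].set_index("run_id")
        for rid, rep in reports.items():
            assert total.loc[rid, "relative"] == pytest.approx(
                rep.total - reports["A-unperturbed"].total
            )
        np.testing.assert_allclose(
            tables["per_residue"]["B-rigid003"],
            reports["B-rigid003"].per_residue - reports["B-unperturbed"].per_residue,
        )
        diff = tables["state_difference"]
        assert diff.loc[diff.perturbation == 3, "B_minus_A"].item() == pytest.approx(
            reports["B-rigid003"].total - reports["A-rigid003"].total
        )

    def test_missing_reference_raises(self):
        reports = self._reports()
        with pytest.raises(MissingReferenceError):
            relative_entropy_table(reports, "missing-run")
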