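"""Descriptor time series and windowed RMSF profiles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import coldadapt as ca
from coldadapt.core import Atom, Ensemble, StructureModel, ValidationError
from coldadapt.flexibility import FlexibilityProfile


def two_atom_structure(distance_nm):
    atoms = [
        Atom("CA", "C", 0, "ALA", "A", (0.0, 0.0, 0.0), True, False),
        Atom("CA", "C", 1, "ALA", "A", (distance_nm, 0.0, 0.0), True, False),
    ]
    return StructureModel(atoms=atoms,
                          residues=[(0, "ALA", "A"), (1, "ALA", "A")],
                          numbering_map={0: "1", 1: "2"})


def profile(values, labels=None, **kw):
    values = np.asarray(values, float)
    labels = labels or [str(i) for i in range(values.size)]
    defaults = dict(window_ns=1.0, n_windows=1)
    defaults.update(kw)
    return FlexibilityProfile(residue_labels=labels, rmsf_mean=values,
                              rmsf_sd=np.zeros_like(values), **defaults)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self):
        ref = ca.make_calpha_chain(6)
        ens = Ensemble(ref, np.tile(ref.coords, (4, 1, 1)), 0.02)
        ts = ca.rmsd_series(ens, selection="calpha")
        assert np.allclose(ts.values, 0.0, atol=1e-12)

    def test_uniform_translation_removed_by_fitting(self):
        ref = ca.make_calpha_chain(6)
        frames = np.stack([ref.coords, ref.coords + np.array([0.1, 0, 0])])
        ens = Ensemble(ref, frames, 0.02)
        ts = ca.rmsd_series(ens, ref.coords, selection="calpha")
        assert np.allclose(ts.values, 0.0, atol=1e-9)

    def test_matches_mdanalysis_oracle(self):
        from MDAnalysis.analysis import rms
        rng = np.random.default_rng(0)
        ref = ca.make_calpha_chain(4)
        frame = ref.coords + rng.normal(0, 0.1, (4, 3))
        ens = Ensemble(ref, np.stack([frame]), 0.02)
        got = ca.rmsd_series(ens, ref.coords, selection="calpha").values[0]
        expected = rms.rmsd(frame * 10, ref.coords * 10, center=True,
                            superposition=True) / 10
        assert got == pytest.approx(expected, rel=1e-6)

    def test_empty_selection_rejected(self):
        ref = ca.make_calpha_chain(4)
        ens = Ensemble(ref, np.stack([ref.coords]), 0.02)
        with pytest.raises(ValidationError):
            ca.rmsd_series(ens, selection=lambda a: False)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        top = StructureModel(
            atoms=[Atom("CA", "C", 0, "ALA", "A", (1.0, 2.0, 3.0), True, False)],
            residues=[(0, "ALA", "A")])
        ens = Ensemble(top, np.stack([top.coords]), 0.02)
        assert ca.radius_of_gyration_series(ens).values[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_one_nm_apart(self):
        top = two_atom_structure(1.0)
        ens = Ensemble(top, np.stack([top.coords]), 0.02)
        # closed form: sqrt(sum m r^2 / sum m) with both atoms 0.5 from COM
        assert ca.radius_of_gyration_series(ens).values[0] == pytest.approx(0.5)

    def test_translation_invariant(self):
        ref = ca.make_calpha_chain(7)
        frames = np.stack([ref.coords, ref.coords + 3.0])
        ens = Ensemble(ref, frames, 0.02)
        rg = ca.radius_of_gyration_series(ens).values
        assert rg[0] == pytest.approx(rg[1], rel=1e-12)


class TestDistanceMonitor:
    def test_constant_separation(self):
        top = two_atom_structure(0.21)
        ens = Ensemble(top, np.tile(top.coords, (3, 1, 1)), 0.02)
        ts = ca.distance_monitor(ens, "1/CA", "2/CA")
        assert np.allclose(ts.values, 0.21)

    def test_monotone_displacement(self):
        top = two_atom_structure(0.2)
        frames = np.tile(top.coords, (5, 1, 1))
        frames[:, 1, 0] = np.linspace(0.2, 0.4, 5)
        ens = Ensemble(top, frames, 0.02)
        ts = ca.distance_monitor(ens, "1/CA", "2/CA")
        assert np.all(np.diff(ts.values) > 0)
        assert ts.values[-1] == pytest.approx(0.4)

    def test_hand_computed_norms(self):
        top = two_atom_structure(0.3)
        frames = np.tile(top.coords, (2, 1, 1))
        frames[1, 1] = [0.3, 0.4, 0.0]
        ens = Ensemble(top, frames, 0.02)
        ts = ca.distance_monitor(ens, 0, 1)
        assert ts.values == pytest.approx([0.3, 0.5])

    def test_ambiguous_selector_lists_matches(self):
        top = two_atom_structure(0.3)
        ens = Ensemble(top, np.stack([top.coords]), 0.02)
        with pytest.raises(ValidationError, match="matched 2"):
            ca.distance_monitor(ens, "CA", "2/CA")


class TestWindowedRmsf:
    def test_constant_trajectory_is_zero(self):
        ref = ca.make_calpha_chain(5)
        ens = Ensemble(ref, np.tile(ref.coords, (30, 1, 1)), 0.1)
        prof = ca.windowed_rmsf(ens, window_ns=1.0, exclude_initial_ns=0.0)
        assert np.allclose(prof.rmsf_mean, 0.0, atol=1e-9)

    def test_window_arithmetic(self):
        # 110 ns, 10 ns windows, first 10 ns excluded -> 10 windows
        ref = ca.make_calpha_chain(4)
        ens = Ensemble(ref, np.tile(ref.coords, (110, 1, 1)), 1.0)
        prof = ca.windowed_rmsf(ens, window_ns=10.0, exclude_initial_ns=10.0)
        assert prof.n_windows == 10

    def test_too_short_trajectory_states_requirement(self):
        ref = ca.make_calpha_chain(4)
        ens = Ensemble(ref, np.tile(ref.coords, (15, 1, 1)), 1.0)
        with pytest.raises(ValidationError, match="ns"):
            ca.windowed_rmsf(ens, window_ns=10.0, exclude_initial_ns=10.0)

    def test_isotropic_noise_recovers_sigma_sqrt3(self):
        # closed form sigma*sqrt(3); 50 residues keeps the fitting
        # degrees-of-freedom loss well inside the 5% band
        ref = ca.make_calpha_chain(50)
        spec = ca.HarmonicSpec(reference=ref, isotropic_sigma=0.02,
                               n_frames=4000, seed=7)
        ens = ca.gen_harmonic_ensemble(spec, frame_interval=0.02)
        prof = ca.windowed_rmsf(ens, window_ns=80.0, exclude_initial_ns=0.0)
        assert prof.rmsf_mean.mean() == pytest.approx(0.02 * np.sqrt(3),
                                                      rel=0.05)

    def test_mode_amplitude_recovery(self):
        # internal mode orthogonal to rigid-body motions: RMSF_i ->
        # sqrt(a^2 sum_xyz |v_i|^2 + 3 sigma^2) per residue
        n_res = 10
        ref = ca.make_calpha_chain(n_res)
        coords = ref.coords
        centered = coords - coords.mean(axis=0)
        rigid = [np.tile(e, n_res) for e in np.eye(3)]       # translations
        for axis in np.eye(3):                               # rotations
            rigid.append(np.cross(centered, axis).reshape(-1))
        v = np.random.default_rng(8).standard_normal(3 * n_res)
        for r in rigid:
            v -= (v @ r) / (r @ r) * r
        v /= np.linalg.norm(v)
        amp, sigma = 0.15, 0.01
        spec = ca.HarmonicSpec(reference=ref, mode_vectors=v[None],
                               mode_amplitudes=[amp], isotropic_sigma=sigma,
                               n_frames=4000, seed=8)
        ens = ca.gen_harmonic_ensemble(spec, frame_interval=0.02)
        prof = ca.windowed_rmsf(ens, window_ns=80.0, exclude_initial_ns=0.0)
        per_res = (v.reshape(n_res, 3) ** 2).sum(axis=1)
        expected = np.sqrt(amp**2 * per_res + 3 * sigma**2)
        peak = int(np.argmax(expected))
        assert prof.rmsf_mean[peak] == pytest.approx(expected[peak], rel=0.05)
        assert np.corrcoef(prof.rmsf_mean, expected)[0, 1] > 0.99

    def test_global_rotation_invariance(self):
        ref = ca.make_calpha_chain(6)
        spec = ca.HarmonicSpec(reference=ref, isotropic_sigma=0.03,
                               n_frames=40, seed=2)
        ens = ca.gen_harmonic_ensemble(spec, frame_interval=1.0)
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        rotated = Ensemble(ref, ens.frames @ R.T + 2.0, 1.0)
        a = ca.windowed_rmsf(ens, 10.0, 0.0).rmsf_mean
        b = ca.windowed_rmsf(rotated, 10.0, 0.0).rmsf_mean
        assert np.allclose(a, b, atol=1e-9)


class TestAverageAndDifference:
    def test_single_profile_unchanged_with_zero_sd(self):
        p = profile([0.1, 0.2])
        avg = ca.average_profiles([p])
        assert np.allclose(avg.rmsf_mean, p.rmsf_mean)
        assert np.all(avg.rmsf_sd == 0) and avg.n_replicates == 1

    def test_two_replicates_mean_and_sample_sd(self):
        avg = ca.average_profiles([profile([0.1]), profile([0.3])])
        assert avg.rmsf_mean[0] == pytest.approx(0.2)
        # direct two-point sample sd
        assert avg.rmsf_sd[0] == pytest.approx(
            np.std([0.1, 0.3], ddof=1))

    def test_identical_replicates_have_zero_sd(self):
        avg = ca.average_profiles([profile([0.15, 0.25])] * 3)
        assert np.all(avg.rmsf_sd == 0) and avg.n_replicates == 3

    def test_label_mismatch_names_residue(self):
        with pytest.raises(ValidationError, match="12"):
            ca.average_profiles([profile([0.1], labels=["11"]),
                                 profile([0.1], labels=["12"])])

    def test_difference_zero_for_identical(self):
        p = profile([0.1, 0.2, 0.3])
        diff = ca.rmsf_difference(p, p)
        assert np.allclose(diff.delta, 0.0)
        assert diff.gaps_a == [] and diff.gaps_b == []

    def test_difference_sign_convention(self):
        a = profile([0.08], labels=["42"])
        b = profile([0.05], labels=["42"])
        diff = ca.rmsf_difference(a, b)
        assert diff.delta[0] == pytest.approx(0.03)

    def test_unmapped_insertion_reported_as_gap(self):
        a = profile([0.1, 0.2], labels=["52", "52A"])
        b = profile([0.1], labels=["52"])
        diff = ca.rmsf_difference(a, b)
        assert diff.gaps_a == ["52A"]
        assert len(diff.delta) == 1
        frame = diff.to_frame()
        assert (frame["residue_b"] == "-").sum() == 1


class TestCovarianceTrace:
    def test_constant_trajectory_is_zero(self):
        ref = ca.make_calpha_chain(5)
        ens = Ensemble(ref, np.tile(ref.coords, (10, 1, 1)), 0.02)
        assert ca.covariance_trace(ens) == pytest.approx(0.0, abs=1e-15)

    def test_single_frame_undefined(self):
        ref = ca.make_calpha_chain(5)
        ens = Ensemble(ref, np.stack([ref.coords]), 0.02)
        with pytest.raises(ValidationError, match="single frame"):
            ca.covariance_trace(ens)

    def test_isotropic_closed_form_3n_sigma_squared(self):
        ref = ca.make_calpha_chain(50)
        spec = ca.HarmonicSpec(reference=ref, isotropic_sigma=0.02,
                               n_frames=5000, seed=3)
        ens = ca.gen_harmonic_ensemble(spec)
        assert ca.covariance_trace(ens) == pytest.approx(
            3 * 50 * 0.02**2, rel=0.05)

    def test_equals_pca_eigenvalue_sum(self):
        ref = ca.make_calpha_chain(8)
        spec = ca.HarmonicSpec(reference=ref, isotropic_sigma=0.05,
                               n_frames=60, seed=4)
        ens = ca.superpose_frames(ca.gen_harmonic_ensemble(spec))
        trace = ca.covariance_trace(ens)
        eigsum = ca.pca_ensemble(ens).eigenvalues.sum()
        assert trace == pytest.approx(eigsum, rel=1e-9)
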