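"""Scattering amplitudes, buffer subtraction, and curve arithmetic."""

import numpy as np
import pytest

import shellsaxs as sx
from shellsaxs.envelope import Envelope
from shellsaxs.model_io import Atoms, ConfigurationEnsemble, FORM_FACTORS
from shellsaxs.saxs import (
    amplitudes,
    buffer_subtracted_intensity,
    difference_curve,
    generate_q_directions,
    measure_bulk_density,
    solvent_density_correction,
)

from oracles import debye_intensity, sphere_form_factor_sq


def _point_ensemble(xyz, electrons=1.0, box=60.0):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    atoms = Atoms(
        names=np.array([f"P{i}" for i in range(n)], dtype=object),
        elements=np.array(["POINT"] * n, dtype=object),
        electrons=np.full(n, float(electrons)),
        vdw_radius=np.ones(n),
        solute=np.ones(n, dtype=bool),
        mol_id=np.arange(n),
    )
    return ConfigurationEnsemble(
        atoms=atoms,
        frames=xyz[None, :, :],
        box=np.full(3, box),
        temperature=300.0,
    )


class TestDirections:
    def test_count_and_norms(self):
        vecs = generate_q_directions(150, 0.3)
        assert vecs.shape == (150, 3)
        assert np.allclose(np.linalg.norm(vecs, axis=1), 0.3, rtol=1e-12)

    def test_isotropy_of_direction_set(self):
        dirs = generate_q_directions(150, 1.0)
        outer = np.einsum("ni,nj->ij", dirs, dirs) / len(dirs)
        assert np.allclose(outer, np.eye(3) / 3.0, atol=1e-2)

    def test_deterministic(self):
        assert np.array_equal(
            generate_q_directions(50, 0.2), generate_q_directions(50, 0.2)
        )


class TestAmplitudes:
    def test_single_unit_scatterer_at_origin(self):
        ens = _point_ensemble([[30.0, 30.0, 30.0]])
        ens.frames[0, 0] = 0.0  # at the coordinate origin: all phases vanish
        A = amplitudes(ens, None, np.array([0.0, 0.5, 1.0]), 20)
        assert np.allclose(A.A, 1.0)

    def test_translation_phase_property(self):
        rng = np.random.default_rng(1)
        xyz = rng.random((10, 3)) * 5.0
        ens1 = _point_ensemble(xyz)
        ens2 = _point_ensemble(xyz + [3.0, -2.0, 1.0])
        q = np.array([0.2, 0.7])
        A1 = amplitudes(ens1, None, q, 30)
        A2 = amplitudes(ens2, None, q, 30)
        assert np.allclose(np.abs(A1.A), np.abs(A2.A), rtol=1e-10)

    def test_two_atom_interference_at_qd_pi(self):
        d = 4.0
        ens = _point_ensemble([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        q = np.array([np.pi / d])
        A = amplitudes(ens, None, q, 150)
        I = buffer_subtracted_intensity(A, None, n_bootstrap=0).I
        # orientational average: 2 (1 + sinc(qd)) = 2 at qd = pi
        assert I[0] == pytest.approx(2.0, rel=1e-3)

    def test_empty_envelope_raises(self, small_system):
        _, buffer = small_system
        far = Envelope(points=np.array([[1e5, 1e5, 1e5]]), distance=1.0)
        with pytest.raises(ValueError, match="no atoms inside"):
            amplitudes(buffer, far, np.array([0.1]), 10)


class TestDebyeEquivalence:
    def test_orientational_average_matches_debye_sum(self):
        """150-direction averages agree with the brute-force Debye double sum."""
        rng = np.random.default_rng(3)
        n = 40
        xyz = rng.random((n, 3)) * 6.0
        els = rng.choice(["C", "N", "O", "H"], n)
        atoms = Atoms.from_lists(
            [f"{e}{i}" for i, e in enumerate(els)], list(els), [True] * n
        )
        ens = ConfigurationEnsemble(
            atoms=atoms, frames=xyz[None] + 20.0, box=np.full(3, 50.0), temperature=300.0
        )
        q = np.linspace(0.05, 1.0, 20)
        A = amplitudes(ens, None, q, 150)
        I = buffer_subtracted_intensity(A, None, n_bootstrap=0).I
        I_ref = debye_intensity(xyz, lambda qk: [FORM_FACTORS(e, qk) for e in els], q)
        assert np.max(np.abs(I - I_ref) / I_ref) <= 1e-3

    def test_sphere_fixture_form_factor(self):
        sph = sx.make_uniform_sphere(10.0, 2000, seed=9, n_frames=12)
        q = np.array([1e-4, np.pi / 10.0])
        A = amplitudes(sph, None, q, 150)
        I = buffer_subtracted_intensity(A, None, n_bootstrap=0).I
        ratio = I[1] / I[0]
        expected = sphere_form_factor_sq(np.array([np.pi]))[0]  # (3/pi^2)^2
        assert ratio == pytest.approx(expected, rel=0.25)  # speckle-limited


class TestBufferSubtraction:
    def test_rigid_body_with_empty_buffer_is_debye(self):
        rng = np.random.default_rng(5)
        xyz = rng.random((12, 3)) * 4.0
        ens = _point_ensemble(xyz + 20.0)
        q = np.linspace(0.1, 0.8, 8)
        A = amplitudes(ens, None, q, 150)
        I = buffer_subtracted_intensity(A, None, n_bootstrap=0).I
        I_ref = debye_intensity(xyz, lambda qk: np.ones(12), q)
        assert np.allclose(I, I_ref, rtol=2e-3)

    def test_forward_intensity_is_total_electrons_squared(self):
        sph = sx.make_uniform_sphere(10.0, 500, electrons_per_point=2.0, seed=2)
        A = amplitudes(sph, None, np.array([0.0]), 10)
        I = buffer_subtracted_intensity(A, None, n_bootstrap=0).I
        assert I[0] == pytest.approx((500 * 2.0) ** 2, rel=1e-12)

    def test_null_contrast(self, toy_solute):
        """Statistically identical sample/buffer: I(q) = 0 within 3 SE."""
        box = np.full(3, 26.0)
        s1 = sx.ShellSpec(epsilon=0.0, shell_width=3.0, seed=31)
        s2 = sx.ShellSpec(epsilon=0.0, shell_width=3.0, seed=877)
        _, bufA = sx.make_solvated_system(toy_solute, box, s1, n_frames=40)
        _, bufB = sx.make_solvated_system(toy_solute, box, s2, n_frames=40)
        env = Envelope(points=box[None, :] / 2.0, distance=8.0)
        q = np.linspace(0.0, 0.3, 7)
        A = amplitudes(bufA, env, q, 80)
        B = amplitudes(bufB, env, q, 80)
        curve = buffer_subtracted_intensity(A, B, seed=4)
        assert np.all(np.abs(curve.I) <= 3 * curve.sigma)

    def test_mismatched_grids_rejected(self, small_system):
        sample, buffer = small_system
        env = sx.build_envelope(sample, 8.0)
        A = amplitudes(sample, env, np.array([0.1]), 10)
        B = amplitudes(buffer, env, np.array([0.2]), 10)
        with pytest.raises(ValueError, match="differ"):
            buffer_subtracted_intensity(A, B)


class TestDensityCorrection:
    def test_measured_density_matches_generator(self, small_system):
        _, buffer = small_system
        rho = measure_bulk_density(buffer)
        # generator truncates to a common per-frame count; allow 5%
        assert rho == pytest.approx(0.334, rel=0.05)

    def test_identity_when_target_equals_measured(self, small_system):
        _, buffer = small_system
        rho = measure_bulk_density(buffer) * 1000.0
        assert solvent_density_correction(buffer, rho) == pytest.approx(1.0, rel=1e-12)

    def test_scale_is_simple_ratio(self, small_system):
        _, buffer = small_system
        rho = measure_bulk_density(buffer) * 1000.0
        scale = solvent_density_correction(buffer, rho * 334.0 / 330.0)
        assert scale == pytest.approx(334.0 / 330.0, rel=1e-12)

    def test_scaled_amplitudes_scale_solvent_only(self, small_system):
        sample, _ = small_system
        env = sx.build_envelope(sample, 8.0)
        q = np.array([0.0])
        A1 = amplitudes(sample, env, q, 5, solvent_scale=1.0)
        A2 = amplitudes(sample, env, q, 5, solvent_scale=2.0)
        at = sample.atoms
        solute_e = at.electrons[at.solute].sum()
        # at q=0 amplitude is real: solute part fixed, solvent part doubled
        solvent_part = A1.A[0, 0, 0].real - solute_e
        assert A2.A[0, 0, 0].real == pytest.approx(solute_e + 2 * solvent_part, rel=1e-10)


class TestDifferenceCurve:
    def _curve(self, I, sigma=None):
        q = np.linspace(0.01, 0.5, len(I))
        return sx.SaxsCurve(q=q, I=np.asarray(I, dtype=float), sigma=sigma)

    def test_self_difference_vanishes(self):
        c = self._curve([3.0, 2.0, 1.0, 0.5])
        assert np.allclose(difference_curve(c, c).I, 0.0)

    def test_antisymmetric(self):
        a = self._curve([3.0, 2.0, 1.0, 0.5])
        b = self._curve([1.0, 1.0, 1.0, 1.0])
        assert np.allclose(difference_curve(a, b).I, -difference_curve(b, a).I)

    def test_constant_offset_recovered(self):
        a = self._curve([3.0, 2.0, 1.0, 0.5])
        b = self._curve(np.asarray([3.0, 2.0, 1.0, 0.5]) + 2.5)
        assert np.allclose(difference_curve(b, a).I, 2.5)

    def test_sigma_in_quadrature(self):
        a = self._curve([1.0, 1.0], sigma=np.array([0.3, 0.4]))
        b = self._curve([2.0, 2.0], sigma=np.array([0.4, 0.3]))
        assert np.allclose(difference_curve(a, b).sigma, 0.5)

    def test_grid_mismatch_rejected(self):
        a = self._curve([1.0, 2.0, 3.0])
        b = sx.SaxsCurve(q=np.array([0.1, 0.2]), I=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            difference_curve(a, b)
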