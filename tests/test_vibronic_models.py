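"""AH / VH / VG surface construction and geometry RMSD."""

import numpy as np
import pytest

from vibronic2pa import (
    MolecularSystem,
    SyntheticSpec,
    build_AH,
    build_VG,
    build_VH,
    compute_normal_modes,
    generate_model_system,
    rmsd_geometries,
)
from vibronic2pa.constants import BOHR_TO_ANGSTROM


def test_vg_zero_gradient_is_undisplaced(gen_default, gen_basis):
    m = build_VG(gen_default.ground, gen_basis, np.zeros(3 * 4), 0.12)
    assert np.allclose(m.shift_K, 0.0)
    assert np.allclose(m.duschinsky_J, np.eye(m.n_modes))
    assert m.adiabatic_gap == pytest.approx(0.12)


def test_vg_single_mode_closed_form(gen_default, gen_basis):
    """Shifted-parabola minimum: |K| = |g|/omega^2, reorganization energy
    g^2/(2 omega^2), K oriented so Q' = Q + K vanishes at the minimum."""
    w = gen_basis.frequencies
    sqm = np.sqrt(gen_default.ground.masses_au)
    g_mode = 1.5e-4
    grad_cart = sqm * gen_basis.mode_vectors[:, 0] * g_mode
    m = build_VG(gen_default.ground, gen_basis, grad_cart, 0.12)
    assert m.shift_K[0] == pytest.approx(g_mode / w[0] ** 2, rel=1e-10)
    assert np.max(np.abs(m.shift_K[1:])) < 1e-15
    reorg = g_mode**2 / (2 * w[0] ** 2)
    assert m.reorganization_energy == pytest.approx(reorg, rel=1e-10)
    assert m.adiabatic_gap == pytest.approx(0.12 - reorg, rel=1e-10)


def test_vg_near_zero_frequency_rejected(gen_default, gen_basis):
    from vibronic2pa.normal_modes import NormalModeBasis

    freqs = gen_basis.frequencies.copy()
    freqs[0] = 1e-10
    bad = NormalModeBasis(freqs, gen_basis.mode_vectors)
    with pytest.raises(ValueError, match="ill-conditioned"):
        build_VG(gen_default.ground, bad, np.zeros(12), 0.12)


def test_vh_reduces_to_vg_for_identical_hessians(gen_default, gen_basis):
    gen = gen_default
    grad = gen.es_gradient_at_gs
    vh = build_VH(gen.ground, gen_basis, gen.ground.hessian, grad, 0.12)
    vg = build_VG(gen.ground, gen_basis, grad, 0.12)
    assert np.allclose(vh.final_frequencies, vg.final_frequencies, atol=1e-10)
    assert np.allclose(vh.duschinsky_J, np.eye(vh.n_modes), atol=1e-8)
    assert np.allclose(vh.shift_K, vg.shift_K, atol=1e-10)


def test_vh_imaginary_frequency_made_positive(gen_default, gen_basis):
    """A negative ES Hessian eigenvalue -omega^2 must come out as +omega."""
    gen = gen_default
    sqm = np.sqrt(gen.ground.masses_au)
    lv = gen_basis.mode_vectors
    w2 = gen_basis.frequencies**2
    w2_mod = w2.copy()
    w2_mod[0] = -w2[0]
    h = (sqm[:, None] * lv) @ np.diag(w2_mod) @ (lv.T * sqm[None, :])
    vh = build_VH(
        gen.ground, gen_basis, 0.5 * (h + h.T), np.zeros(12), 0.12
    )
    assert np.all(vh.final_frequencies > 0)
    assert np.min(np.abs(vh.final_frequencies - gen_basis.frequencies[0])) < 1e-9
    assert any("imaginary" in w for w in vh.warnings)


def test_vh_recovers_constructed_duschinsky_rotation(gen_default, gen_basis):
    """30 deg mixing of the two lowest modes must reappear in J."""
    gen = gen_default
    theta = np.deg2rad(30.0)
    r = np.eye(gen_basis.n_modes)
    r[:2, :2] = [
        [np.cos(theta), -np.sin(theta)],
        [np.sin(theta), np.cos(theta)],
    ]
    sqm = np.sqrt(gen.ground.masses_au)
    lv = gen_basis.mode_vectors
    w2 = np.diag(gen_basis.frequencies**2)
    h = (sqm[:, None] * lv) @ r.T @ w2 @ r @ (lv.T * sqm[None, :])
    vh = build_VH(gen.ground, gen_basis, 0.5 * (h + h.T), np.zeros(12), 0.12)
    j = vh.duschinsky_J.copy()
    # mode-sign gauge may flip rows; normalize diagonals positive
    for i in range(j.shape[0]):
        if j[i, i] < 0:
            j[i, :] = -j[i, :]
    assert np.allclose(j, r, atol=1e-8)


def test_ah_identity_case(gen_default, gen_basis):
    gen = gen_default
    es_same = MolecularSystem(
        masses=gen.ground.masses,
        coordinates=gen.ground.coordinates,
        hessian=gen.ground.hessian,
        gradient=np.zeros(12),
        energy=0.1,
    )
    m = build_AH(gen.ground, gen_basis, es_same, 0.1)
    assert np.allclose(m.duschinsky_J, np.eye(m.n_modes), atol=1e-10)
    assert np.allclose(m.shift_K, 0.0, atol=1e-10)


def test_ah_rigid_shift_formula(gen_default, gen_basis):
    gen = gen_default
    dx = np.array([0.02, -0.01, 0.005])
    es = MolecularSystem(
        masses=gen.ground.masses,
        coordinates=gen.ground.coordinates + dx,
        hessian=gen.ground.hessian,
        gradient=np.zeros(12),
        energy=0.1,
    )
    m = build_AH(gen.ground, gen_basis, es, 0.1)
    # a rigid translation lies in the projected-out space: J = I, K = 0
    assert np.allclose(m.duschinsky_J, np.eye(m.n_modes), atol=1e-8)
    assert np.allclose(m.shift_K, 0.0, atol=1e-8)


def test_ah_vibrational_shift_formula(gen_default, gen_basis):
    gen = gen_default
    sqm = np.sqrt(gen.ground.masses_au)
    q_shift = 3.0
    dx = (gen_basis.mode_vectors[:, 1] / sqm * q_shift).reshape(-1, 3)
    es = MolecularSystem(
        masses=gen.ground.masses,
        coordinates=gen.ground.coordinates - dx,
        hessian=gen.ground.hessian,
        gradient=np.zeros(12),
        energy=0.1,
    )
    m = build_AH(gen.ground, gen_basis, es, 0.1)
    expected = gen_basis.mode_vectors.T @ (
        sqm * (gen.ground.coordinates - es.coordinates).ravel()
    )
    assert np.allclose(m.shift_K, expected, atol=1e-10)
    assert m.shift_K[1] == pytest.approx(q_shift, rel=1e-8)
    assert np.allclose(
        m.duschinsky_J.T @ m.duschinsky_J, np.eye(m.n_modes), atol=1e-8
    )


def test_ah_rejects_non_minimum(gen_default, gen_basis):
    gen = gen_default
    es = MolecularSystem(
        masses=gen.ground.masses,
        coordinates=gen.ground.coordinates,
        hessian=gen.ground.hessian,
        gradient=np.full(12, 1e-2),
    )
    with pytest.raises(ValueError, match="not a minimum"):
        build_AH(gen.ground, gen_basis, es, 0.1)


@pytest.mark.parametrize("seed", [2, 9])
def test_exact_harmonic_pair_gives_identical_ah_vh(seed):
    """Exactly harmonic surfaces: AH and VH must agree to numerical noise
    (with frequency changes and Duschinsky mixing present)."""
    gen = generate_model_system(SyntheticSpec(seed=seed))
    basis = compute_normal_modes(gen.ground)
    ah = build_AH(gen.ground, basis, gen.excited, gen.adiabatic_gap)
    vh = build_VH(
        gen.ground, basis, gen.excited.hessian, gen.es_gradient_at_gs,
        gen.vertical_gap,
    )
    assert np.allclose(ah.duschinsky_J, vh.duschinsky_J, atol=1e-8)
    assert np.allclose(ah.shift_K, vh.shift_K, atol=1e-8)
    assert np.allclose(ah.final_frequencies, vh.final_frequencies, atol=1e-8)
    assert ah.adiabatic_gap == pytest.approx(vh.adiabatic_gap, abs=1e-10)
    # ... and both recover the construction's ground truth
    assert np.allclose(ah.duschinsky_J, gen.truth_model.duschinsky_J, atol=1e-8)
    assert np.allclose(ah.shift_K, gen.truth_model.shift_K, atol=1e-8)


def test_vg_reorganization_ties_vertical_and_adiabatic_gaps(gen_default, gen_basis):
    gen = gen_default
    vg = build_VG(gen.ground, gen_basis, gen.es_gradient_at_gs, gen.vertical_gap)
    assert vg.energy_gap - vg.adiabatic_gap == pytest.approx(
        vg.reorganization_energy, abs=1e-10
    )


class TestRMSD:
    def test_identical_is_zero(self, gen_default):
        assert rmsd_geometries(gen_default.ground, gen_default.ground) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_translation_removed(self, gen_default):
        a = gen_default.ground
        b = MolecularSystem(masses=a.masses, coordinates=a.coordinates + [1.0, -2.0, 0.5])
        assert rmsd_geometries(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_removed(self, gen_default, rng):
        from conftest import random_rotation

        a = gen_default.ground
        rot = random_rotation(rng)
        b = MolecularSystem(masses=a.masses, coordinates=a.coordinates @ rot.T)
        assert rmsd_geometries(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_two_displaced_atoms_closed_form(self, rng):
        """Two of ten atoms moved 0.1 A along the axis through them: no net
        rotation or translation, so RMSD = sqrt(2*0.01/10)."""
        d_bohr = 0.1 / BOHR_TO_ANGSTROM
        coords = rng.normal(scale=3.0, size=(10, 3))
        coords[0] = [6.0, 0.0, 0.0]
        coords[1] = [-6.0, 0.0, 0.0]
        a = MolecularSystem(masses=np.ones(10), coordinates=coords)
        moved = coords.copy()
        moved[0, 0] += d_bohr
        moved[1, 0] -= d_bohr
        b = MolecularSystem(masses=np.ones(10), coordinates=moved)
        assert rmsd_geometries(a, b) == pytest.approx(
            np.sqrt(2 * 0.01 / 10), rel=1e-6
        )

    def test_atom_count_mismatch(self, gen_default):
        small = MolecularSystem(masses=[1.0], coordinates=[[0, 0, 0]])
        with pytest.raises(ValueError, match="atom counts"):
            rmsd_geometries(gen_default.ground, small)
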