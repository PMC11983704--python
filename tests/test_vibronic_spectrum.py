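"""Franck-Condon / Herzberg-Teller stick spectra and broadening."""

import itertools
import math

import numpy as np
import pytest

from vibronic2pa import (
    CrossSectionConvention,
    DuschinskyEngine,
    EnumerationCaps,
    HTExpansion,
    LineshapeSpec,
    PolarizationWeights,
    QuadratureEngine,
    Rank2TransitionTensor,
    SyntheticSpec,
    VibronicModel,
    broaden,
    compute_normal_modes,
    compute_stick_spectrum,
    decompose_intensity,
    fc_overlap,
    generate_model_system,
    ht_matrix_element,
    quadrature_oracle,
    rotational_average,
)
from vibronic2pa.constants import cm1_to_hartree
from vibronic2pa.pipeline import build_vibronic_model
from vibronic2pa.synthetic import random_expansion, random_vibronic_model

from conftest import random_rotation

W1500 = float(cm1_to_hartree(1500.0))


def one_mode_model(dimensionless_shift=0.0, w=W1500, wf=None):
    wf = w if wf is None else wf
    k = dimensionless_shift / np.sqrt(w)
    return VibronicModel(
        "VG", [w], [wf], [[1.0]], [k], 0.12, "vertical",
        0.12 - 0.5 * wf**2 * k**2,
    )


def xx_expansion(s0_xx, b_xx, n_modes=1):
    s0 = np.zeros((3, 3))
    s0[0, 0] = s0_xx
    bs = []
    for v in range(n_modes):
        b = np.zeros((3, 3))
        b[0, 0] = b_xx if v == 0 else 0.0
        bs.append(Rank2TransitionTensor(b))
    return HTExpansion(Rank2TransitionTensor(s0), tuple(bs))


class TestOverlaps:
    def test_orthonormality_for_identical_surfaces(self):
        m = one_mode_model(0.0)
        assert fc_overlap(m, [0], [0]) == pytest.approx(1.0, abs=1e-12)
        for n in range(1, 5):
            assert abs(fc_overlap(m, [0], [n])) < 1e-12

    def test_displaced_oscillator_poisson_progression(self):
        d = 1.3
        m = one_mode_model(d)
        s_hr = d**2 / 2
        for n in range(8):
            exact = math.exp(-s_hr) * s_hr**n / math.factorial(n)
            assert fc_overlap(m, [0], [n]) ** 2 == pytest.approx(exact, abs=1e-12)

    def test_two_mode_duschinsky_against_quadrature(self, rng):
        theta = np.deg2rad(20.0)
        w = np.array([W1500 * 0.8, W1500 * 1.1])
        j = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        k = np.array([0.8, -0.5]) / np.sqrt(w)
        m = VibronicModel("VH", w, w * 1.05, j, k, 0.12, "vertical", 0.1)
        de = DuschinskyEngine(m)
        qe = QuadratureEngine(m)
        for quanta in itertools.product(range(4), repeat=2):
            assert de.overlap((0, 0), quanta) == pytest.approx(
                qe.overlap((0, 0), quanta), abs=1e-6
            )

    def test_nonzero_initial_quanta_supported(self):
        m = one_mode_model(0.9)
        qe = QuadratureEngine(m)
        for mi, n in itertools.product(range(3), range(4)):
            assert fc_overlap(m, [mi], [n]) == pytest.approx(
                qe.overlap((mi,), (n,)), abs=1e-8
            )

    def test_invalid_quanta_rejected(self):
        m = one_mode_model(0.0)
        with pytest.raises(ValueError, match="non-negative"):
            fc_overlap(m, [-1], [0])
        with pytest.raises(ValueError, match="mode count"):
            fc_overlap(m, [0, 0], [0])


class TestHTMatrixElements:
    def test_ladder_identity_for_identical_surfaces(self):
        m = one_mode_model(0.0)
        assert ht_matrix_element(m, 0, [1]) == pytest.approx(
            1.0 / np.sqrt(2 * W1500), rel=1e-12
        )
        assert ht_matrix_element(m, 0, [0]) == pytest.approx(0.0, abs=1e-14)
        assert ht_matrix_element(m, 0, [2]) == pytest.approx(0.0, abs=1e-14)

    def test_closure_sums(self, rng):
        """sum_n <0|n><0|Q_v|n> = 0 and sum_n <0|Q_v|n>^2 = 1/(2 omega_v)."""
        m = random_vibronic_model(rng, 2)
        eng = DuschinskyEngine(m)
        cross = 0.0
        square = 0.0
        for quanta in itertools.product(range(22), repeat=2):
            ov = eng.overlap((0, 0), quanta)
            q0 = eng.q_matrix_element(0, quanta)
            cross += ov * q0
            square += q0 * q0
        assert cross == pytest.approx(0.0, abs=1e-8)
        assert square == pytest.approx(
            1.0 / (2 * m.initial_frequencies[0]), rel=1e-8
        )

    def test_displaced_case_against_quadrature(self):
        m = one_mode_model(1.1)
        qe = QuadratureEngine(m)
        for n in range(5):
            assert ht_matrix_element(m, 0, [n]) == pytest.approx(
                qe.q_matrix_element(0, (n,)), abs=1e-8
            )


class TestStickSpectrum:
    def test_undisplaced_fc_is_single_00_line(self):
        m = one_mode_model(0.0)
        exp = xx_expansion(5.0, 0.7)
        stick = compute_stick_spectrum(m, exp, mode_label="FC")
        assert len(stick.lines) == 1
        assert stick.lines[0].quanta == (0,)
        assert stick.lines[0].delta_au == pytest.approx(
            rotational_average(exp.S0).delta_2PA, rel=1e-12
        )

    def test_poisson_relative_strengths(self):
        """Dimensionless shift 1.0 -> Huang-Rhys 0.5 -> 1 : 0.5 : 0.125."""
        m = one_mode_model(1.0)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="FC")
        by_quanta = {l.quanta[0]: l.delta_au for l in stick.lines}
        assert by_quanta[1] / by_quanta[0] == pytest.approx(0.5, rel=1e-10)
        assert by_quanta[2] / by_quanta[0] == pytest.approx(0.125, rel=1e-10)

    def test_ht_pure_with_zero_b_is_empty(self):
        m = one_mode_model(0.7)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="HT_pure")
        assert stick.lines == ()

    def test_energies_start_at_00_line_and_strengths_positive(self, rng):
        m = random_vibronic_model(rng, 2)
        exp = random_expansion(rng, 2)
        stick = compute_stick_spectrum(m, exp, mode_label="FC_HT")
        energies = stick.energies_ev()
        e00 = min(energies)
        assert np.all(energies >= e00 - 1e-12)
        assert np.all(stick.strengths() >= 0)

    def test_mode_count_mismatch_rejected(self):
        m = one_mode_model(0.0)
        with pytest.raises(ValueError, match="mode count"):
            compute_stick_spectrum(m, xx_expansion(5.0, 0.1, n_modes=2))

    def test_completeness_warning(self):
        m = one_mode_model(2.5)  # Huang-Rhys ~3: slow progression
        caps = EnumerationCaps(max_quanta_per_mode=1)
        with pytest.warns(RuntimeWarning, match="captured"):
            compute_stick_spectrum(
                m, xx_expansion(5.0, 0.0), mode_label="FC", caps=caps,
                completeness_warning=0.999,
            )


class TestSumRules:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_eq7_sum_rule_and_mode_additivity(self, seed):
        rng = np.random.default_rng(seed)
        n = 3
        m = random_vibronic_model(rng, n, shift_scale=0.5)
        exp = random_expansion(rng, n)
        caps = EnumerationCaps(max_quanta_per_mode=9, max_excited_modes=3)
        d = decompose_intensity(m, exp)
        totals = {}
        for label in ("FC", "FC_HT", "HT_pure"):
            totals[label] = compute_stick_spectrum(
                m, exp, mode_label=label, caps=caps
            ).total_delta
        closure = d.delta_FC + d.delta_HT
        assert totals["FC_HT"] == pytest.approx(closure, rel=1e-6)
        assert totals["FC"] + totals["HT_pure"] == pytest.approx(
            totals["FC_HT"], rel=1e-6
        )

    def test_interference_shows_line_by_line(self, rng):
        """FC_HT differs from FC + HT_pure per line, but not in total."""
        m = random_vibronic_model(rng, 2, shift_scale=0.6)
        exp = random_expansion(rng, 2)
        caps = EnumerationCaps(max_quanta_per_mode=10, max_excited_modes=2)
        spectra = {
            label: compute_stick_spectrum(m, exp, mode_label=label, caps=caps)
            for label in ("FC", "FC_HT", "HT_pure")
        }
        fc = {l.quanta: l.delta_au for l in spectra["FC"].lines}
        ht = {l.quanta: l.delta_au for l in spectra["HT_pure"].lines}
        mixed = {l.quanta: l.delta_au for l in spectra["FC_HT"].lines}
        diffs = [
            abs(mixed[q] - fc.get(q, 0.0) - ht.get(q, 0.0))
            for q in mixed
        ]
        assert max(diffs) > 1e-8  # interference present line-by-line
        assert spectra["FC_HT"].total_delta == pytest.approx(
            spectra["FC"].total_delta + spectra["HT_pure"].total_delta, rel=1e-6
        )


class TestDecomposition:
    def test_zero_b_gives_zero_ht(self):
        d = decompose_intensity(one_mode_model(0.3), xx_expansion(5.0, 0.0))
        assert d.delta_HT == 0.0
        assert d.percent_HT == 0.0

    def test_zero_s0_gives_full_ht(self):
        d = decompose_intensity(one_mode_model(0.3), xx_expansion(0.0, 0.4))
        assert d.delta_FC == 0.0
        assert d.percent_HT == 100.0

    def test_one_mode_xx_closed_form_and_state_sum(self):
        s, b = 4.0, 0.6
        m = one_mode_model(0.8)
        w = m.initial_frequencies[0]
        d = decompose_intensity(m, xx_expansion(s, b))
        expected = 100.0 * (b**2 / (2 * w)) / (s**2 + b**2 / (2 * w))
        assert d.percent_HT == pytest.approx(expected, rel=1e-12)
        # explicit converged state-sum oracle
        total = compute_stick_spectrum(
            m, xx_expansion(s, b), mode_label="FC_HT",
            caps=EnumerationCaps(max_quanta_per_mode=25, max_excited_modes=1),
        ).total_delta
        assert total == pytest.approx(d.delta_FC + d.delta_HT, rel=1e-9)


class TestInvariances:
    def test_spectrum_invariant_under_common_rotation(self, rng):
        m = random_vibronic_model(rng, 2)
        exp = random_expansion(rng, 2)
        rot = random_rotation(rng)
        caps = EnumerationCaps(max_quanta_per_mode=6, max_excited_modes=2)
        a = compute_stick_spectrum(m, exp, mode_label="FC_HT", caps=caps)
        b = compute_stick_spectrum(m, exp.rotated(rot), mode_label="FC_HT", caps=caps)
        sa = {l.quanta: l.delta_au for l in a.lines}
        sb = {l.quanta: l.delta_au for l in b.lines}
        assert set(sa) == set(sb)
        for q in sa:
            assert sa[q] == pytest.approx(sb[q], rel=1e-8, abs=1e-12)

    def test_ah_vh_vg_spectra_coincide_for_frequency_preserving_pair(self):
        gen = generate_model_system(
            SyntheticSpec(seed=21, duschinsky_angle_scale=0.0,
                          frequency_change_scale=0.0)
        )
        basis = compute_normal_modes(gen.ground)
        caps = EnumerationCaps(max_quanta_per_mode=5, max_excited_modes=3)
        spectra = {}
        for kind in ("AH", "VH", "VG"):
            model = build_vibronic_model(gen, kind, basis)
            spectra[kind] = compute_stick_spectrum(
                model, gen.expansion, mode_label="FC_HT", caps=caps
            )
        ref = {l.quanta: (l.energy_ev, l.delta_au) for l in spectra["AH"].lines}
        for kind in ("VH", "VG"):
            other = {l.quanta: (l.energy_ev, l.delta_au) for l in spectra[kind].lines}
            assert set(other) == set(ref)
            for q, (e, s) in ref.items():
                assert other[q][0] == pytest.approx(e, abs=1e-8)
                assert other[q][1] == pytest.approx(s, rel=1e-8, abs=1e-12)


def test_dense_grid_path_matches_state_by_state_recursion(rng, monkeypatch):
    """The vectorized full-grid evaluation and the memoized per-state
    recursion are the same recurrence and must agree to round-off."""
    m = random_vibronic_model(rng, 3, shift_scale=0.5)
    exp = random_expansion(rng, 3)
    caps = EnumerationCaps(max_quanta_per_mode=6, max_excited_modes=3)
    for label in ("FC", "FC_HT", "HT_pure"):
        dense = compute_stick_spectrum(m, exp, mode_label=label, caps=caps)
        monkeypatch.delattr(DuschinskyEngine, "overlap_grid")
        sparse = compute_stick_spectrum(m, exp, mode_label=label, caps=caps)
        monkeypatch.undo()
        sa = {l.quanta: l.delta_au for l in dense.lines}
        sb = {l.quanta: l.delta_au for l in sparse.lines}
        assert set(sa) == set(sb)
        for q in sa:
            assert sa[q] == pytest.approx(sb[q], rel=1e-10, abs=1e-13)


class TestQuadratureOracle:
    def test_agrees_with_recursion_line_by_line(self, rng):
        caps = EnumerationCaps(max_quanta_per_mode=5, max_excited_modes=2)
        for _ in range(5):
            n = int(rng.integers(1, 3))
            m = random_vibronic_model(rng, n)
            exp = random_expansion(rng, n)
            fast = compute_stick_spectrum(m, exp, mode_label="FC_HT", caps=caps)
            slow = quadrature_oracle(m, exp, mode_label="FC_HT", caps=caps)
            sf = {l.quanta: l.delta_au for l in fast.lines}
            ss = {l.quanta: l.delta_au for l in slow.lines}
            for q in set(sf) | set(ss):
                assert sf.get(q, 0.0) == pytest.approx(ss.get(q, 0.0), abs=1e-6)

    def test_rejects_more_than_two_modes(self, rng):
        m = random_vibronic_model(rng, 3)
        with pytest.raises(ValueError, match="at most 2"):
            QuadratureEngine(m)


class TestBroadening:
    def test_area_preserved_with_frozen_prefactor(self):
        m = one_mode_model(1.0)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="FC")
        conv = CrossSectionConvention()
        freeze = stick.lines[0].photon_energy_ev
        for hwhm in (0.005, 0.100):
            out = broaden(
                stick,
                LineshapeSpec(hwhm=hwhm),
                conv,
                freeze_photon_energy_ev=freeze,
            )
            area_gm_ev = np.trapezoid(out.sigma_gm, out.photon_energy_ev)
            from vibronic2pa.constants import HARTREE_TO_EV, ev_to_hartree

            pref = conv.prefactor_au(float(ev_to_hartree(freeze)))
            expected = pref * stick.total_delta * HARTREE_TO_EV
            assert area_gm_ev == pytest.approx(expected, rel=1e-6)

    def test_single_line_peaks_at_line_wavelength(self):
        m = one_mode_model(0.0)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="FC")
        out = broaden(stick, LineshapeSpec(hwhm=0.01))
        peak_nm = out.wavelength_nm[np.argmax(out.sigma_gm)]
        assert peak_nm == pytest.approx(stick.lines[0].photon_wavelength_nm, rel=1e-3)

    def test_empty_stick_rejected(self):
        m = one_mode_model(0.7)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="HT_pure")
        with pytest.raises(ValueError, match="empty"):
            broaden(stick)

    def test_narrow_grid_warns(self):
        m = one_mode_model(0.0)
        stick = compute_stick_spectrum(m, xx_expansion(5.0, 0.0), mode_label="FC")
        e0 = stick.lines[0].photon_energy_ev
        with pytest.warns(RuntimeWarning, match="5 HWHM"):
            broaden(
                stick,
                LineshapeSpec(hwhm=0.1),
                photon_energy_grid_ev=np.linspace(e0 - 0.1, e0 + 0.1, 50),
            )
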