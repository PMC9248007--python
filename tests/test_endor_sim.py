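"""Orientation-selective Mims ENDOR simulator."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from endorkit.dipolar_geometry import pake_pattern, read_splitting
from endorkit.endor_sim import (
    AcquisitionSettings,
    Spectrum,
    compose_observer_sum,
    compose_tau_sum,
    effective_g,
    endor_frequencies,
    epr_envelope_weights,
    mims_response,
    normalize,
    observer_field,
    orientation_grid,
    selection_weight,
    simulate_mims_endor,
)
from endorkit.spin_models import (
    TYROSYL_G,
    GTensor,
    HyperfineTensor,
    NucleusCoupling,
    NucleusSpec,
    SpinSystem,
    build_axial_hyperfine,
    larmor_frequency,
    resonance_field,
)


def _system(g, *couplings, label="test"):
    return SpinSystem(g=g, nuclei=tuple(couplings), label=label)


def _f(tensor, **kw):
    return NucleusCoupling(nucleus=NucleusSpec.from_isotope("19F"), tensor=tensor, **kw)


G_ISO = GTensor(2.0044, 2.0044, 2.0044)


class TestOrientationGrid:
    @pytest.mark.parametrize("n", [100, 1234, 10000])
    def test_weights_sum_to_one(self, n):
        _, w = orientation_grid(n)
        assert w.sum() == pytest.approx(1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            orientation_grid(50)

    def test_isotropy_of_second_legendre(self):
        vecs, w = orientation_grid(10000)
        mean = np.sum(w * (3 * vecs[:, 2] ** 2 - 1))
        assert abs(mean) < 1e-3

    def test_powder_average_of_g(self):
        vecs, w = orientation_grid(20000)
        avg = np.sum(w * effective_g(vecs, TYROSYL_G))
        assert avg == pytest.approx(TYROSYL_G.isotropic, abs=1e-4)


class TestEffectiveG:
    def test_principal_directions(self):
        assert effective_g(np.array([1.0, 0, 0]), TYROSYL_G) == pytest.approx(2.0062)
        assert effective_g(np.array([0, 0, 1.0]), TYROSYL_G) == pytest.approx(2.0022)

    def test_bounds(self):
        vecs, _ = orientation_grid(1000)
        ge = effective_g(vecs, TYROSYL_G)
        assert np.all(ge >= TYROSYL_G.gz - 1e-12)
        assert np.all(ge <= TYROSYL_G.gx + 1e-12)


class TestSelectionWeight:
    def test_on_resonance_without_strong_nuclei(self):
        sys_ = _system(TYROSYL_G)
        l = np.array([[1.0, 0.0, 0.0]])
        b = resonance_field(2.0062, 94.0)
        w = selection_weight(l, sys_, b, 94.0, 0.3)
        assert w[0] == pytest.approx(1.0)

    def test_gaussian_tail(self):
        sys_ = _system(TYROSYL_G)
        l = np.array([[1.0, 0.0, 0.0]])
        b = resonance_field(2.0062, 94.0) + 5 * 0.3e-3
        assert selection_weight(l, sys_, b, 94.0, 0.3)[0] < 1e-5

    def test_strong_proton_splits_the_envelope(self):
        beta_h = NucleusCoupling(
            nucleus=NucleusSpec.from_isotope("1H"),
            tensor=HyperfineTensor(principal_khz=(50000.0, 50000.0, 50000.0)),
            selection_only=True,
        )
        sys_ = _system(TYROSYL_G, beta_h)
        l = np.array([[1.0, 0.0, 0.0]])
        b = resonance_field(2.0062, 94.0)  # unsplit position
        w = selection_weight(l, sys_, b, 94.0, 0.3)
        assert w[0] < 1.0  # both m_I branches moved off-resonance


class TestEndorFrequencies:
    def test_zero_coupling(self):
        l = np.array([[0.0, 0.0, 1.0]])
        na, nb = endor_frequencies(l, np.zeros((3, 3)), 134.0)
        assert na[0] == pytest.approx(134.0)
        assert nb[0] == pytest.approx(134.0)

    def test_isotropic_coupling(self):
        l = np.array([[0.0, 0.0, 1.0]])
        na, nb = endor_frequencies(l, np.eye(3) * 1.0, 134.0)
        assert sorted([na[0], nb[0]]) == pytest.approx([133.5, 134.5])

    def test_axial_perpendicular_splitting_reads_T(self):
        A = np.diag([-0.246, -0.246, 0.492])
        l = np.array([[1.0, 0.0, 0.0]])  # perpendicular to unique axis
        na, nb = endor_frequencies(l, A, 134.0)
        assert abs(na[0] - nb[0]) == pytest.approx(0.246, abs=1e-6)


class TestMimsResponse:
    @pytest.mark.parametrize("a,tau", [(1.0, 1000.0), (2.0, 500.0), (4.0, 250.0)])
    def test_blind_spots_at_integer_a_tau(self, a, tau):
        assert mims_response(a, tau) == pytest.approx(0.0, abs=1e-12)

    def test_central_blind_spot(self):
        assert mims_response(0.0, 620.0) == 0.0

    def test_direct_evaluation(self):
        assert mims_response(1.6, 236.0) == pytest.approx(
            0.5 * np.sin(np.pi * 1.6 * 0.236) ** 2
        )
        assert mims_response(1.6, 236.0) == pytest.approx(0.43, abs=0.01)

    def test_bounded_by_half(self):
        a = np.linspace(0, 10, 1001)
        assert np.all(mims_response(a, 236.0) <= 0.5 + 1e-12)


class TestSimulateMims:
    def test_full_powder_prominent_splitting_fa(self):
        """Rhombic proximal-fluorine tensor gives ~1.6-1.8 MHz peak separation."""
        fa = _f(HyperfineTensor(principal_khz=(580.0, -1668.0, -1952.0)), label="F_a")
        sys_ = _system(G_ISO, fa)
        st = AcquisitionSettings(
            observer="gy", tau_ns=250.0, rf_half_span_mhz=4.0, rf_step_mhz=0.008,
            n_orientations=20000, orientation_selection=False,
        )
        spec = simulate_mims_endor(sys_, st)
        sep = read_splitting(spec.axis_mhz, spec.intensity, linewidth_khz=250.0)
        assert 1.6 <= sep <= 1.85

    def test_empty_nucleus_list_flat_zero(self):
        spec = simulate_mims_endor(_system(G_ISO), AcquisitionSettings())
        assert np.all(spec.intensity == 0.0)

    def test_deterministic_repeat(self):
        fb = _f(build_axial_hyperfine(246.0, 0.0, (0, 90)), label="F_b")
        sys_ = _system(TYROSYL_G, fb)
        st = AcquisitionSettings(observer="gx", tau_ns=620.0, rf_half_span_mhz=0.6,
                                 rf_step_mhz=0.004, n_orientations=2000)
        a = simulate_mims_endor(sys_, st)
        b = simulate_mims_endor(sys_, st)
        assert np.array_equal(a.intensity, b.intensity)

    def test_symmetric_for_traceless_tensor(self):
        fb = _f(build_axial_hyperfine(246.0, 0.0), label="F_b")
        st = AcquisitionSettings(observer="gy", tau_ns=620.0, rf_half_span_mhz=0.6,
                                 rf_step_mhz=0.004, n_orientations=10000,
                                 orientation_selection=False)
        spec = simulate_mims_endor(_system(G_ISO, fb), st)
        assert np.allclose(spec.intensity, spec.intensity[::-1], atol=1e-3 * spec.intensity.max())

    def test_matches_analytic_powder_oracle(self):
        """Simulator agrees with an independent cos(theta) powder summation."""
        T, a_iso, tau = 246.0, 0.0, 620.0
        fb = _f(build_axial_hyperfine(T, a_iso), label="F_b")
        st = AcquisitionSettings(observer="gy", tau_ns=tau, rf_half_span_mhz=0.6,
                                 rf_step_mhz=0.004, n_orientations=30000,
                                 orientation_selection=False)
        spec = simulate_mims_endor(_system(G_ISO, fb), st)

        # oracle: dense analytic powder sum with Mims weighting (axial tensor,
        # isotropic g: splitting depends only on the polar angle)
        axis = st.axis_mhz()
        x = np.linspace(0, 1, 200001)
        a_mhz = (a_iso + T * (3 * x**2 - 1)) / 1e3
        w = mims_response(np.abs(a_mhz), tau) / len(x)
        hist = np.zeros_like(axis)
        step = axis[1] - axis[0]
        for sign in (0.5, -0.5):
            idx = np.clip(np.round((sign * a_mhz - axis[0]) / step).astype(int), 0, len(axis) - 1)
            np.add.at(hist, idx, w)
        hist = gaussian_filter1d(hist, 25.0 / 1e3 / 2.3548 / step, mode="constant")

        sim = normalize(spec, "max").intensity
        oracle = hist / hist.max()
        assert np.max(np.abs(sim - oracle)) < 0.02

    def test_grid_convergence_below_one_percent(self):
        fb = _f(build_axial_hyperfine(246.0, 0.0, (0, 90)), label="F_b")
        sys_ = _system(TYROSYL_G, fb)
        specs = []
        for n in (10000, 20000):
            st = AcquisitionSettings(observer="gx", tau_ns=620.0, rf_half_span_mhz=0.6,
                                     rf_step_mhz=0.004, n_orientations=n)
            specs.append(normalize(simulate_mims_endor(sys_, st), "max").intensity)
        assert np.max(np.abs(specs[0] - specs[1])) < 0.01

    def test_gx_selection_enhances_parallel_edge(self):
        """Unique axis || x observed at gx: parallel/perpendicular intensity
        ratio grows >= 3x over the full powder."""
        fb = _f(build_axial_hyperfine(246.0, 0.0, (0, 90)), label="F_b")
        sys_ = _system(TYROSYL_G, fb)
        kw = dict(tau_ns=620.0, rf_half_span_mhz=0.6, rf_step_mhz=0.004,
                  n_orientations=20000)
        sel = simulate_mims_endor(sys_, AcquisitionSettings(observer="gx", **kw))
        full = simulate_mims_endor(
            sys_, AcquisitionSettings(observer="gx", orientation_selection=False, **kw)
        )
        ax = sel.axis_mhz
        par = (ax > 0.2) & (ax < 0.3)      # parallel edge at +T
        perp = (ax > 0.08) & (ax < 0.16)   # perpendicular peak at +T/2

        def ratio(s):
            return s.intensity[par].max() / s.intensity[perp].max()

        assert ratio(sel) / ratio(full) >= 3.0

    def test_truncated_peak_warning_names_nucleus(self):
        fa = _f(HyperfineTensor(principal_khz=(580.0, -1668.0, -1952.0)), label="F_a")
        st = AcquisitionSettings(observer="gy", tau_ns=250.0, rf_half_span_mhz=0.5,
                                 rf_step_mhz=0.004, n_orientations=500,
                                 orientation_selection=False)
        with pytest.warns(UserWarning, match="F_a"):
            simulate_mims_endor(_system(G_ISO, fa), st)


class TestComposition:
    def _spec(self, y, tau=236.0):
        ax = np.linspace(-1, 1, len(y))
        return Spectrum(axis_mhz=ax, intensity=np.asarray(y, float),
                        metadata={"settings": {"tau_ns": tau}})

    def test_observer_sum_of_equal_spectra(self):
        s = self._spec([0.0, 1.0, 0.0, 2.0, 0.0])
        out = compose_observer_sum([s, s, s], [3.0, 1.0, 2.0])
        assert np.allclose(out.intensity, s.intensity)

    def test_observer_sum_single_weight(self):
        a = self._spec([1.0, 0.0, 0.0, 0.0, 0.0])
        b = self._spec([0.0, 0.0, 0.0, 0.0, 1.0])
        out = compose_observer_sum([a, b], [1.0, 0.0])
        assert np.allclose(out.intensity, a.intensity)

    def test_observer_sum_axis_mismatch(self):
        a = self._spec([1.0, 0.0, 1.0])
        b = Spectrum(axis_mhz=[0.0, 1.0, 2.0], intensity=[1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="axis"):
            compose_observer_sum([a, b], [1.0, 1.0])

    def test_isotropic_g_observer_sum_equals_full_powder(self):
        fb = _f(build_axial_hyperfine(246.0, 0.0, (0, 90)), label="F_b")
        sys_ = _system(G_ISO, fb)
        kw = dict(tau_ns=620.0, rf_half_span_mhz=0.6, rf_step_mhz=0.004,
                  n_orientations=5000)
        settings = [AcquisitionSettings(observer=o, **kw) for o in ("gx", "gy", "gz")]
        specs = [simulate_mims_endor(sys_, st) for st in settings]
        weights = epr_envelope_weights(sys_, settings)
        summed = normalize(compose_observer_sum(specs, weights), "max")
        full = normalize(
            simulate_mims_endor(
                sys_, AcquisitionSettings(observer="gy", orientation_selection=False, **kw)
            ),
            "max",
        )
        assert np.max(np.abs(summed.intensity - full.intensity)) < 0.02

    def test_tau_sum_identical_spectra_unchanged(self):
        a = self._spec([0.0, 1.0, 0.5], tau=236.0)
        b = self._spec([0.0, 1.0, 0.5], tau=266.0)
        out = compose_tau_sum(a, b)
        assert np.allclose(out.intensity, a.intensity)

    def test_tau_sum_warns_on_identical_tau(self):
        a = self._spec([0.0, 1.0, 0.5])
        with pytest.warns(UserWarning, match="tau"):
            compose_tau_sum(a, a.copy_with())

    def test_tau_sum_fills_blind_spot_at_half_amplitude(self):
        # a coupling blind at tau_a but visible at tau_b appears at half height
        a_mhz = 1.0 / 0.236  # blind at 236 ns
        amp_b = mims_response(a_mhz, 266.0)
        avg = 0.5 * (mims_response(a_mhz, 236.0) + amp_b)
        assert avg == pytest.approx(amp_b / 2.0)

    def test_double_blind_artifact_suppression(self):
        # proton artifact with a*tau near-integer at both tau values is
        # suppressed >10x relative to the single-tau worst case (0.5)
        a = 33.87  # MHz; a*0.236 ~ 8, a*0.266 ~ 9
        avg = 0.5 * (mims_response(a, 236.0) + mims_response(a, 266.0))
        assert avg < 0.5 / 10.0


class TestObserverField:
    def test_named_positions(self):
        sys_ = _system(TYROSYL_G)
        st = AcquisitionSettings(observer="gx")
        assert observer_field(sys_, st) == pytest.approx(resonance_field(2.0062, 94.0))
        st2 = AcquisitionSettings(observer=3.35)
        assert observer_field(sys_, st2) == 3.35

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="observer"):
            observer_field(_system(TYROSYL_G), AcquisitionSettings(observer="g4"))

    def test_reference_larmor_consistency(self, f19):
        # spectra are centered at the 19F Larmor frequency of the observer field
        b = resonance_field(TYROSYL_G.gy, 94.0)
        assert larmor_frequency(f19, b) == pytest.approx(134.3, abs=0.3)
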