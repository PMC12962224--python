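import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdinvert as mi
from mdinvert.signal_model import (
    Acquisition, Component, InvalidParameterError, Protocol,
    encoding_attenuation_exponent, kernel_value,
)

COMP_II = Component(2.5, 0.1, np.deg2rad(78), np.deg2rad(78),
                    2.0, 200.0, 700.0, 1.5, 20.0)


class TestLorentzian:
    @pytest.mark.parametrize("d0, dinf, gamma, omega, expected", [
        (2.5, 2.0, 200.0, 0.0, 2.5),       # zero-frequency limit
        (2.5, 2.0, 200.0, 200.0, 2.25),    # omega = gamma -> halfway
        (3.0, 3.0, 123.0, 55.0, 3.0),      # flat spectrum when d0 = dinf
    ])
    def test_closed_form(self, d0, dinf, gamma, omega, expected):
        assert mi.lorentzian_diffusivity(d0, dinf, gamma, omega) == \
            pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(InvalidParameterError):
            mi.lorentzian_diffusivity(1.0, 2.0, 0.0, 10.0)

    @given(d0=st.floats(0.05, 5), dinf=st.floats(0.05, 5),
           gamma=st.floats(0.01, 1e4), omega=st.floats(0, 1e5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_monotone_between_limits(self, d0, dinf, gamma, omega):
        lam = mi.lorentzian_diffusivity(d0, dinf, gamma, omega)
        lo, hi = min(d0, dinf), max(d0, dinf)
        assert lo - 1e-12 <= lam <= hi + 1e-12


class TestDiffusionScalars:
    def test_isotropic_component_has_zero_anisotropy(self, phantom):
        diso, dsq = mi.diffusion_scalars(phantom.components[0], 0.0)
        assert diso == pytest.approx(0.5)
        assert dsq == pytest.approx(0.0, abs=1e-15)

    def test_crossing_fiber_component_at_zero_frequency(self):
        diso, dsq = mi.diffusion_scalars(COMP_II, 0.0)
        assert diso == pytest.approx(0.9)
        assert dsq == pytest.approx((2.4 / 2.7) ** 2, abs=1e-12)

    @pytest.mark.parametrize("omega", [0.0, 50.0, 500.0])
    def test_equal_axial_radial_is_isotropic_at_all_frequencies(self, omega):
        c = Component(1.2, 1.2, 0.3, 0.4, 2.0, 100.0, 100.0, 1.0, 10.0)
        _, dsq = mi.diffusion_scalars(c, omega)
        assert dsq == pytest.approx(0.0, abs=1e-15)


class TestEncodingAttenuation:
    def test_spherical_encoding_reads_isotropic_diffusivity(self):
        acq = Acquisition(1.0, 0.0, 0.0, 0.0, 0.0, 0.05, 5.0)
        assert encoding_attenuation_exponent(acq, COMP_II) == \
            pytest.approx(0.9, abs=1e-12)

    def test_linear_encoding_parallel_reads_axial_diffusivity(self):
        acq = Acquisition(1.0, 1.0, COMP_II.theta, COMP_II.phi,
                          0.0, 0.05, 5.0)
        assert encoding_attenuation_exponent(acq, COMP_II) == \
            pytest.approx(2.5, abs=1e-12)

    def test_zero_b_gives_zero_exponent(self):
        acq = Acquisition(0.0, 1.0, 0.3, 0.8, 40.0, 0.05, 5.0)
        assert encoding_attenuation_exponent(acq, COMP_II) == \
            pytest.approx(0.0, abs=1e-15)

    def test_invariant_under_joint_rotation(self):
        # rotating encoding axis and component axis together about z
        for dphi in (0.5, 1.7, 3.0):
            acq = Acquisition(1.5, 1.0, 1.1, 0.4, 40.0, 0.05, 5.0)
            acq_rot = Acquisition(1.5, 1.0, 1.1, 0.4 + dphi, 40.0, 0.05, 5.0)
            c = COMP_II
            c_rot = Component(c.d_par, c.d_perp, c.theta,
                              (c.phi + dphi) % (2 * np.pi), c.d0,
                              c.gamma_par, c.gamma_perp, c.r1, c.r2)
            assert encoding_attenuation_exponent(acq, c) == pytest.approx(
                encoding_attenuation_exponent(acq_rot, c_rot), rel=1e-12)


class TestKernel:
    def test_unit_kernel_in_the_no_weighting_limit(self):
        acq = Acquisition(0.0, 0.0, 0.0, 0.0, 0.0, 1e-9, 1e6)
        c = Component(0.5, 0.5, 0.0, 0.0, 2.0, 250.0, 250.0, 1.0, 13.0)
        assert kernel_value(acq, c) == pytest.approx(1.0, abs=1e-6)

    def test_relaxation_weighting_closed_form(self):
        acq = Acquisition(0.0, 0.0, 0.0, 0.0, 0.0, 0.04, 7.6)
        c = Component(0.5, 0.5, 0.0, 0.0, 2.0, 250.0, 250.0, 1.0, 13.0)
        expected = (1 - np.exp(-7.6)) * np.exp(-0.52)
        assert kernel_value(acq, c) == pytest.approx(expected, abs=1e-10)

    def test_kernel_decreases_with_echo_time(self):
        a1 = Acquisition(0.5, 0.0, 0.0, 0.0, 40.0, 0.05, 5.0)
        a2 = Acquisition(0.5, 0.0, 0.0, 0.0, 40.0, 0.10, 5.0)
        assert kernel_value(a2, COMP_II) < kernel_value(a1, COMP_II)

    def test_matrix_entries_in_unit_interval(self, protocol, phantom):
        K = mi.kernel_matrix(protocol, list(phantom.components))
        assert K.shape == (protocol.M, 4)
        assert np.all(K > 0) and np.all(K <= 1)

    def test_matrix_column_permutation(self, small_protocol, phantom):
        comps = list(phantom.components)
        K = mi.kernel_matrix(small_protocol, comps)
        K_perm = mi.kernel_matrix(small_protocol, comps[::-1])
        assert np.allclose(K, K_perm[:, ::-1])

    def test_isotropic_csf_column_decays_as_exp_minus_3b(self, phantom):
        # spherical encodings at fixed TE/TR isolate the b-dependence
        csf = phantom.components[3]
        acqs = [Acquisition(b, 0.0, 0.0, 0.0, 60.0, 0.05, 5.0)
                for b in (0.0, 0.5, 1.0, 2.0)]
        K = mi.kernel_matrix(Protocol.from_acquisitions(acqs), [csf])
        ratio = K[:, 0] / K[0, 0]
        assert np.allclose(ratio, np.exp(-3.0 * np.array([0, 0.5, 1, 2])),
                           rtol=1e-10)


class TestSynthesize:
    def test_linearity_in_weights(self, small_protocol, phantom):
        comps = list(phantom.components)
        w1 = np.array([0.1, 0.2, 0.3, 0.4])
        w2 = np.array([0.4, 0.3, 0.2, 0.1])
        s12 = mi.synthesize_signal(small_protocol, comps, w1 + w2)
        s1 = mi.synthesize_signal(small_protocol, comps, w1)
        s2 = mi.synthesize_signal(small_protocol, comps, w2)
        assert np.allclose(s12, s1 + s2, atol=1e-14)

    def test_zero_weights_give_zero_signal(self, small_protocol, phantom):
        s = mi.synthesize_signal(small_protocol, list(phantom.components),
                                 np.zeros(4))
        assert np.all(s == 0)

    def test_unit_basis_weight_reproduces_kernel_column(self, small_protocol,
                                                        phantom):
        comps = list(phantom.components)
        K = mi.kernel_matrix(small_protocol, comps)
        s = mi.synthesize_signal(small_protocol, comps,
                                 np.array([0.0, 1.0, 0.0, 0.0]))
        assert np.allclose(s, K[:, 1], atol=1e-14)

    def test_negative_weight_rejected(self, small_protocol, phantom):
        with pytest.raises(ValueError):
            mi.synthesize_signal(small_protocol, list(phantom.components),
                                 np.array([0.5, -0.1, 0.3, 0.3]))


class TestProtocol:
    def test_requires_b_zero_acquisition(self):
        with pytest.raises(InvalidParameterError):
            Protocol([1.0], [0.0], [0.0], [0.0], [40.0], [0.05], [5.0])

    def test_dataframe_roundtrip(self, protocol):
        df = protocol.to_dataframe()
        back = Protocol.from_dataframe(df)
        assert back == protocol
        assert np.allclose(back.omega_cent, protocol.omega_cent)

    def test_component_validation(self):
        with pytest.raises(InvalidParameterError):
            Component(-1.0, 0.5, 0.0, 0.0, 2.0, 250.0, 250.0, 1.0, 13.0)
        with pytest.raises(InvalidParameterError):
            Component(0.5, 0.5, 4.0, 0.0, 2.0, 250.0, 250.0, 1.0, 13.0)
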