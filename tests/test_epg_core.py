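"""Operator-level checks of the EPG core against independent oracles.

The RF operator is checked against a dense isochromat ensemble rotated with
plain 3x3 real rotation matrices and Fourier-transformed back; the diffusion
attenuation of an interval is checked against numerical quadrature of the
spatial-frequency trajectory.  Neither oracle shares code with the operators.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import simpson

from rfspoil import (
    ConfigurationStateSet,
    EvolutionInterval,
    TissueParams,
    evolve_interval,
    rf_rotation,
    shift,
    truncate,
)

DQ = (10.0, 4.0)  # rad/mm per order on (readout, slice)


def random_states(rng, max_order=6, amp=0.25):
    f = amp * (rng.normal(size=2 * max_order + 1) + 1j * rng.normal(size=2 * max_order + 1))
    z = amp * (rng.normal(size=max_order + 1) + 1j * rng.normal(size=max_order + 1))
    z[0] = amp * abs(rng.normal())  # Z_0 is real (Mz(theta) is a real field)
    return ConfigurationStateSet(f=f, z=z, dephasing_per_tr=DQ)


def rotation_matrix(flip_deg, phase_deg):
    """3x3 real rotation: flip about an axis at azimuth `phase_deg` in xy."""
    a, p = math.radians(flip_deg), math.radians(phase_deg)
    rx = np.array(
        [[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]]
    )
    rz = np.array(
        [[math.cos(p), -math.sin(p), 0], [math.sin(p), math.cos(p), 0], [0, 0, 1]]
    )
    return rz @ rx @ rz.T


def isochromat_rotation_oracle(states, flip_deg, phase_deg, m=512):
    """Rotate the equivalent isochromat ensemble and Fourier back to F_k/Z_k."""
    k_max = states.max_order
    theta = 2.0 * np.pi * np.arange(m) / m
    k = np.arange(-k_max, k_max + 1)
    phases = np.exp(1j * np.outer(theta, k))
    mplus = phases @ states.f
    z_full = np.array([states.z_at(int(kk)) for kk in k])
    mz = (phases @ z_full).real
    vec = np.stack([mplus.real, mplus.imag, mz])
    out = rotation_matrix(flip_deg, phase_deg) @ vec
    mp2, mz2 = out[0] + 1j * out[1], out[2]
    inv = np.exp(-1j * np.outer(k, theta)) / m
    return inv @ mp2, (inv @ mz2)[k_max:]


class TestRfRotation:
    def test_zero_flip_is_identity(self, rng):
        s = random_states(rng)
        out = rf_rotation(s, 0.0, 123.0)
        np.testing.assert_allclose(out.f, s.f, atol=1e-15)
        np.testing.assert_allclose(out.z, s.z, atol=1e-15)

    def test_inversion_from_equilibrium(self):
        s = ConfigurationStateSet.equilibrium()
        out = rf_rotation(s, 180.0, 0.0)
        assert out.z_at(0) == pytest.approx(-1.0, abs=1e-12)
        assert abs(out.f_at(0)) < 1e-12

    def test_90_degree_excitation(self):
        s = ConfigurationStateSet.equilibrium()
        out = rf_rotation(s, 90.0, 37.0)
        assert abs(out.f_at(0)) == pytest.approx(1.0, abs=1e-12)
        assert abs(out.z_at(0)) < 1e-12

    @pytest.mark.parametrize("flip,phase", [(90.0, 0.0), (35.0, 117.0), (160.0, 294.5)])
    def test_matches_isochromat_rotation(self, rng, flip, phase):
        s = random_states(rng)
        out = rf_rotation(s, flip, phase)
        f_ref, z_ref = isochromat_rotation_oracle(s, flip, phase)
        np.testing.assert_allclose(out.f, f_ref, atol=1e-12)
        np.testing.assert_allclose(out.z, z_ref, atol=1e-12)

    def test_flip_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            rf_rotation(random_states(rng), 200.0, 0.0)

    def test_z0_stays_real(self, rng):
        s = random_states(rng)
        for flip, phase in [(30, 10), (70, 200), (110, 45)]:
            s = rf_rotation(s, flip, phase)
        assert abs(s.z[0].imag) < 1e-12


class TestEvolveInterval:
    TISSUE = TissueParams(t1=800.0, t2=100.0, d=2.0e-3)

    def test_no_diffusion_is_pure_relaxation(self, rng):
        s = random_states(rng)
        iv = EvolutionInterval(duration=3.0, moment=(5.0, 2.0), start_offset=(1.0, 0.0))
        dry = TissueParams(t1=800.0, t2=100.0, d=0.0)
        out = evolve_interval(s, iv, dry)
        np.testing.assert_allclose(out.f, s.f * math.exp(-3.0 / 100.0), atol=1e-15)
        expected_z = s.z * math.exp(-3.0 / 800.0)
        expected_z[0] += 1.0 - math.exp(-3.0 / 800.0)
        np.testing.assert_allclose(out.z, expected_z, atol=1e-15)

    def test_gap_longitudinal_constant_k_formula(self, rng):
        s = random_states(rng, max_order=3)
        tau = 5.0
        iv = EvolutionInterval(duration=tau, moment=(0.0, 0.0))
        out = evolve_interval(s, iv, self.TISSUE)
        for k in (1, 2, 3):
            b = sum((k * dq) ** 2 * tau * 1e-3 for dq in DQ)
            expected = s.z[k] * math.exp(-tau / 800.0) * math.exp(-self.TISSUE.d * b)
            assert out.z[k] == pytest.approx(expected, rel=1e-12)

    def test_lobe_attenuation_matches_quadrature(self, rng):
        """Transverse decay through a lobe = exp(-D int q(t)^2 dt), by Simpson."""
        s = random_states(rng, max_order=4)
        tau = 2.0
        iv = EvolutionInterval(
            duration=tau, moment=(7.0, -3.0), start_offset=(1.5, 0.5)
        )
        out = evolve_interval(s, iv, self.TISSUE)
        t = np.linspace(0.0, tau, 4001)
        for k in range(-4, 5):
            b = 0.0
            for ax, dq in enumerate(DQ):
                q = (k * dq + iv.start_offset[ax]) + iv.moment[ax] * t / tau
                b += simpson(q**2, x=t) * 1e-3
            expected = s.f_at(k) * math.exp(-tau / 100.0) * math.exp(-self.TISSUE.d * b)
            assert out.f_at(k) == pytest.approx(expected, rel=1e-9)

    def test_regrowth_reaches_equilibrium(self):
        s = ConfigurationStateSet(f=[0.0], z=[0.2], dephasing_per_tr=DQ)
        iv = EvolutionInterval(duration=1e5, moment=(0.0, 0.0))
        out = evolve_interval(s, iv, self.TISSUE)
        assert out.z_at(0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("d_low,d_high", [(0.0, 1e-4), (1e-4, 2e-3), (2e-3, 0.1)])
    def test_diffusion_monotonicity(self, rng, d_low, d_high):
        """More diffusion never increases any dephased transverse amplitude."""
        s = random_states(rng)
        iv = EvolutionInterval(duration=4.0, moment=(6.0, 3.0), start_offset=(2.0, 1.0))
        lo = evolve_interval(s, iv, TissueParams(t1=800, t2=100, d=d_low))
        hi = evolve_interval(s, iv, TissueParams(t1=800, t2=100, d=d_high))
        k = s.orders
        mask = k != 0
        assert np.all(np.abs(hi.f[mask]) <= np.abs(lo.f[mask]) + 1e-15)


class TestShiftAndTruncate:
    def test_zero_shift_identity(self, rng):
        s = random_states(rng)
        out = shift(s, 0)
        np.testing.assert_array_equal(out.f, s.f)

    @given(n1=st.integers(-4, 4), n2=st.integers(-4, 4))
    def test_shift_composes(self, n1, n2):
        rng = np.random.default_rng(7)
        s = random_states(rng)
        once = shift(shift(s, n1), n2)
        twice = shift(s, n1 + n2)
        k = min(once.max_order, twice.max_order)
        for kk in range(-k, k + 1):
            assert once.f_at(kk) == pytest.approx(twice.f_at(kk), abs=1e-15)

    @given(n=st.integers(-6, 6))
    def test_shift_conserves_transverse_energy(self, n):
        rng = np.random.default_rng(11)
        s = random_states(rng)
        assert shift(s, n).transverse_energy == pytest.approx(
            s.transverse_energy, rel=1e-12
        )

    def test_truncate_zero_floor_identity(self, rng):
        s = random_states(rng)
        out = truncate(s, 0.0)
        np.testing.assert_array_equal(out.f, s.f)

    def test_truncate_to_z0(self):
        s = ConfigurationStateSet.equilibrium(max_order=5)
        s.f += 1e-15
        out = truncate(s, 1e-12)
        assert out.max_order == 0
        assert out.z_at(0) == 1.0


def test_amplitudes_stay_physical(schedule, zur):
    """|F_k| <= 1 and |Z_k| <= 1 along a phase-cycled train from equilibrium."""
    from rfspoil import quadratic_phase, schedule_to_intervals, SpoilingScheme

    intervals, _ = schedule_to_intervals(schedule)
    scheme = SpoilingScheme(117.0)
    s = ConfigurationStateSet.equilibrium(
        dephasing_per_tr=schedule.dephasing_per_tr
    )
    for n in range(40):
        s = rf_rotation(s, 60.0, quadratic_phase(scheme, n))
        for iv in intervals:
            s = evolve_interval(s, iv, zur)
        s = shift(s, 1)
        assert np.all(np.abs(s.f) <= 1.0 + 1e-12)
        assert np.all(np.abs(s.z) <= 1.0 + 1e-12)
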