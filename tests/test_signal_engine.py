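"""Steady-state engine checks: oracle equivalence, limits, symmetries."""

import numpy as np
import pytest

from rfspoil import (
    DEFAULT_FLIPS,
    SpoilingScheme,
    TissueParams,
    build_default_protocol,
    curve_to_csv,
    ernst_amplitude,
    isochromat_signal,
    signal_curve,
    simulate_batch,
    steady_state_signal,
)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # short train, no steady state
@pytest.mark.parametrize("psi,flip", [(117.0, 30.0), (150.0, 75.0), (50.0, 12.0)])
def test_epg_equals_isochromat_ensemble(schedule, zur, psi, flip):
    """Demodulated F_0 after every pulse of a 200-pulse train matches the
    mean transverse magnetization of a dense isochromat ensemble (D = 0)."""
    n = 200
    scheme = SpoilingScheme(psi)
    hp, hm = simulate_batch(
        schedule, zur, scheme, [flip], n_pulses=n, return_history=True
    )
    ip, im = isochromat_signal(
        schedule, zur, scheme, flip, m_isochromats=4 * n, n_pulses=n,
        return_history=True,
    )
    assert np.abs(hp[:, 0] - ip).max() < 1e-6
    assert np.abs(hm[:, 0] - im).max() < 1e-6


def test_zur_parameters_match_oracle_in_steady_state(schedule, zur):
    """T1/TR = T2/TR = 20, alpha = 30 deg, psi = 117 deg: EPG steady state
    agrees with the isochromat integral to better than 0.1%."""
    n = 1200
    hp, _ = isochromat_signal(
        schedule,
        zur,
        SpoilingScheme(117.0),
        30.0,
        m_isochromats=2 * n,
        n_pulses=n,
        return_history=True,
    )
    oracle = np.abs(hp[-100:]).mean()
    s_plus, _ = steady_state_signal(schedule, zur, SpoilingScheme(117.0), 30.0)
    assert s_plus == pytest.approx(oracle, rel=1e-3)


def test_signal_depends_only_on_ratios_without_diffusion():
    """Doubling (TR, T1, T2) jointly leaves S+ unchanged when D = 0."""
    scheme = SpoilingScheme(117.0)
    a = signal_curve(
        build_default_protocol(tr=20.0, te=4.0),
        TissueParams(t1=400.0, t2=300.0),
        scheme,
        n_pulses=1500,
    )
    b = signal_curve(
        build_default_protocol(tr=40.0, te=8.0),
        TissueParams(t1=800.0, t2=600.0),
        scheme,
        n_pulses=1500,
    )
    np.testing.assert_allclose(a.s_plus, b.s_plus, rtol=1e-9)


def test_long_tr_limit_reaches_ernst(schedule):
    """TR >> T2: transverse history dies each TR and S+ is the Ernst amplitude."""
    tissue = TissueParams(t1=400.0, t2=0.2)
    curve = signal_curve(schedule, tissue, SpoilingScheme(117.0), n_pulses=600)
    ref = ernst_amplitude(schedule.tr / tissue.t1, curve.flip_angles)
    assert np.max(np.abs(curve.s_plus - ref) / ref) < 1e-3
    # with full decoherence nothing survives to the end of the TR
    assert np.all(curve.s_minus < 1e-6)


def test_strong_diffusion_reaches_ernst(schedule):
    """Very large D with a nonzero spoiler destroys all dephased history."""
    tissue = TissueParams(t1=400.0, t2=400.0, d=1.0)
    curve = signal_curve(schedule, tissue, SpoilingScheme(50.0), n_pulses=600)
    ref = ernst_amplitude(schedule.tr / tissue.t1, curve.flip_angles)
    assert np.max(np.abs(curve.s_plus - ref) / ref) < 1e-3


def test_mirror_symmetry_in_psi(schedule, zur):
    """Signal magnitudes for psi and 360 - psi coincide."""
    a = signal_curve(schedule, zur, SpoilingScheme(117.0), n_pulses=800)
    b = signal_curve(schedule, zur, SpoilingScheme(243.0), n_pulses=800)
    np.testing.assert_allclose(a.s_plus, b.s_plus, rtol=1e-12)


def test_reproducibility_is_bitwise(schedule, zur):
    a = signal_curve(schedule, zur, SpoilingScheme(115.4), [10.0, 40.0], n_pulses=400)
    b = signal_curve(schedule, zur, SpoilingScheme(115.4), [10.0, 40.0], n_pulses=400)
    assert np.array_equal(a.s_plus, b.s_plus)
    assert np.array_equal(a.s_minus, b.s_minus)


def test_signal_bounded_by_sine(schedule, h2o_cuso4):
    """0 <= s_plus <= m0 sin(alpha) over the default grid."""
    curve = signal_curve(schedule, h2o_cuso4, SpoilingScheme(50.0), n_pulses=800)
    bound = np.sin(np.deg2rad(curve.flip_angles))
    assert np.all(curve.s_plus >= 0.0)
    assert np.all(curve.s_plus <= bound + 1e-9)


def test_ernst_angle_signal_identical_across_psi(
    schedule, h2o_cuso4, silicone_oil
):
    """At the Ernst angle the phantom curves coincide for all studied psi
    (the property that justifies normalizing measured curves there)."""
    from rfspoil import ernst_angle

    for tissue in (h2o_cuso4, silicone_oil):
        ae = ernst_angle(schedule.tr / tissue.t1)
        vals = np.array(
            [
                steady_state_signal(schedule, tissue, SpoilingScheme(psi), ae)[0]
                for psi in (50.0, 115.4, 117.0, 150.0, 169.0)
            ]
        )
        assert np.ptp(vals) / vals.mean() < 0.01


def test_default_flip_grid():
    assert len(DEFAULT_FLIPS) == 18
    assert DEFAULT_FLIPS[0] == 5.0 and DEFAULT_FLIPS[-1] == 90.0


def test_single_flip_matches_curve(schedule, zur):
    scheme = SpoilingScheme(169.0)
    sp, sm = steady_state_signal(schedule, zur, scheme, 25.0, n_pulses=400)
    curve = signal_curve(schedule, zur, scheme, [25.0], n_pulses=400)
    assert curve.s_plus[0] == sp and curve.s_minus[0] == sm


def test_truncation_floor_does_not_bias_signal(schedule, zur):
    """The 1e-12 amplitude floor reproduces the untruncated signal to 1e-9."""
    scheme = SpoilingScheme(117.0)
    exact, _, _ = simulate_batch(
        schedule, zur, scheme, [30.0], n_pulses=800, floor=0.0
    )
    floored, _, _ = simulate_batch(
        schedule, zur, scheme, [30.0], n_pulses=800, floor=1e-12
    )
    assert abs(exact[0] - floored[0]) / exact[0] < 1e-9


def test_te_sampling_is_post_pulse_with_echo_decay(schedule, zur):
    """With D = 0 the echo at TE is the post-pulse F_0 decayed by exp(-TE/T2):
    no other configuration refocuses between the pulse and the echo."""
    scheme = SpoilingScheme(117.0)
    post, _, _ = simulate_batch(
        schedule, zur, scheme, [30.0], n_pulses=600, sample="post_pulse"
    )
    at_te, _, _ = simulate_batch(
        schedule, zur, scheme, [30.0], n_pulses=600, sample="te"
    )
    assert at_te[0] == pytest.approx(
        post[0] * np.exp(-schedule.te / zur.t2), rel=1e-9
    )


def test_ernst_curve_container():
    from rfspoil import ErnstCurve, ernst_angle

    curve = ErnstCurve.compute(0.05)
    assert curve.flip_angles.size == 18
    assert curve.amplitudes[0] < curve.amplitudes.max()
    assert curve.ernst_angle == pytest.approx(ernst_angle(0.05))
    # amplitudes peak nearest the Ernst angle on the 5-deg grid
    peak_flip = curve.flip_angles[np.argmax(curve.amplitudes)]
    assert abs(peak_flip - curve.ernst_angle) <= 2.5


class TestIsochromatOracle:
    def test_single_90_pulse(self, schedule):
        tissue = TissueParams(t1=500.0, t2=300.0)
        sp, _ = isochromat_signal(
            schedule, tissue, SpoilingScheme(117.0), 90.0, m_isochromats=8, n_pulses=1
        )
        assert sp == pytest.approx(1.0, abs=1e-12)

    def test_rejects_diffusion(self, schedule, h2o_cuso4):
        with pytest.raises(ValueError, match="D = 0"):
            isochromat_signal(
                schedule, h2o_cuso4, SpoilingScheme(117.0), 30.0,
                m_isochromats=100, n_pulses=10,
            )

    def test_rejects_sparse_ensemble(self, schedule, zur):
        with pytest.raises(ValueError, match="aliasing"):
            isochromat_signal(
                schedule, zur, SpoilingScheme(117.0), 30.0,
                m_isochromats=50, n_pulses=100,
            )


def test_invalid_flips_rejected(schedule, zur):
    with pytest.raises(ValueError):
        signal_curve(schedule, zur, SpoilingScheme(117.0), [])
    with pytest.raises(ValueError):
        signal_curve(schedule, zur, SpoilingScheme(117.0), [0.0])
    with pytest.raises(ValueError):
        signal_curve(schedule, zur, SpoilingScheme(117.0), [190.0])


def test_curve_csv_roundtrip(tmp_path, schedule, zur):
    curve = signal_curve(schedule, zur, SpoilingScheme(117.0), [10.0, 30.0], n_pulses=300)
    out = tmp_path / "curve.csv"
    curve_to_csv(curve, out, schedule=schedule, tissue=zur)
    lines = out.read_text().splitlines()
    assert lines[0] == "flip_deg,s_plus,s_minus,psi_deg"
    assert len(lines) == 3
    meta = out.with_suffix(".csv.meta.json")
    assert meta.exists() and '"tr_ms": 20.0' in meta.read_text()
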