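"""Mix-and-inject design calculations and the radial diffusion solver.

The production solver is cross-checked against a Bessel-series closed form
of the same continuum problem (eigenfunction expansion in J0 with zero-flux
walls), which is independent of both the production and the fine-grid
reference discretisations.
"""

import numpy as np
import pytest
from scipy import optimize, special

from jetkit import mixing as M


def series_mixing_time_ms(frr, radius_um, diffusivity, threshold, n_terms=300):
    """Closed-form centreline crossing time via the J0 eigenfunction expansion."""
    rho_i = M.focused_stream_radius(frr, radius_um) / radius_um
    lam = special.jn_zeros(1, n_terms)
    coeff = -2.0 * rho_i * special.j1(lam * rho_i) / (lam * special.j0(lam) ** 2)
    cbar = 1.0 - rho_i**2

    def centreline(tau):
        return cbar + np.sum(coeff * np.exp(-(lam**2) * tau))

    tau = optimize.brentq(lambda t: centreline(t) - threshold, 1e-8, 5.0)
    return tau * (radius_um * 1e-6) ** 2 / diffusivity * 1e3


class TestDilution:
    def test_ten_to_one_gives_elevenfold(self):
        assert M.dilution_factor(M.FlowRateRatio(100.0, 10.0)) == pytest.approx(11.0)

    def test_three_to_one_gives_fourfold(self):
        assert M.dilution_factor(M.FlowRateRatio(30.0, 10.0)) == pytest.approx(4.0)

    def test_no_sheath_no_dilution(self):
        assert M.dilution_factor(M.FlowRateRatio(0.0, 10.0)) == pytest.approx(1.0)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            M.FlowRateRatio(10.0, 0.0)

    def test_ratio_string_parser(self):
        frr = M.FlowRateRatio.from_string("10:1", q_sample_ul_min=7.0)
        assert frr.q_sheath_ul_min == pytest.approx(70.0)
        assert M.dilution_factor(frr) == pytest.approx(11.0)


class TestFocusedStreamRadius:
    def test_no_sheath_fills_channel(self):
        assert M.focused_stream_radius(M.FlowRateRatio(0.0, 5.0), 100.0) == 100.0

    def test_ten_to_one(self):
        r = M.focused_stream_radius(M.FlowRateRatio(100.0, 10.0), 100.0)
        assert r == pytest.approx(30.2, abs=0.05)

    def test_three_to_one(self):
        r = M.focused_stream_radius(M.FlowRateRatio(30.0, 10.0), 100.0)
        assert r == pytest.approx(50.0)


class TestMixingTime:
    def test_matches_bessel_series_closed_form(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)
        problem = M.MixingProblem(frr=frr, channel_radius_um=100.0)
        res = M.mixing_time(problem)
        expected = series_mixing_time_ms(frr, 100.0, 6.0e-10, 0.125)
        assert res.t_mix_ms == pytest.approx(expected, rel=5e-3)

    def test_doubling_diffusivity_halves_time(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)
        base = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=100.0), convergence_check=False
        )
        fast = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=100.0, diffusivity_m2_s=1.2e-9),
            convergence_check=False,
        )
        assert fast.t_mix_ms == pytest.approx(base.t_mix_ms / 2.0, rel=1e-12)

    def test_radius_squared_self_similarity(self):
        frr = M.FlowRateRatio.from_string("3:1", 12.0)
        small = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=50.0), convergence_check=False
        )
        large = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=100.0), convergence_check=False
        )
        assert large.t_mix_ms == pytest.approx(4.0 * small.t_mix_ms, rel=1e-12)

    def test_time_vanishes_with_threshold(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)
        times = [
            M.mixing_time(
                M.MixingProblem(
                    frr=frr, channel_radius_um=100.0, threshold_fraction=thr
                ),
                convergence_check=False,
            ).t_mix_ms
            for thr in (0.2, 0.05, 0.01, 0.002)
        ]
        assert all(t2 < t1 for t1, t2 in zip(times, times[1:]))
        # the decrease is slow (the diffusion front must first reach the axis)
        assert times[-1] < 0.3 * times[0]

    def test_unreachable_threshold_raises(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)  # equilibrium 10/11
        with pytest.raises(ValueError, match="threshold unreachable"):
            M.mixing_time(
                M.MixingProblem(frr=frr, channel_radius_um=100.0, threshold_fraction=0.95)
            )

    def test_mass_conserved_to_machine_precision(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)
        res = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=100.0), convergence_check=False
        )
        assert res.mass_drift < 1e-3  # contract: 0.1%; scheme is conservative

    def test_depletion_sink_slows_mixing(self):
        frr = M.FlowRateRatio.from_string("10:1", 9.8)
        base = M.mixing_time(
            M.MixingProblem(frr=frr, channel_radius_um=100.0), convergence_check=False
        )
        sink = M.mixing_time(
            M.MixingProblem(
                frr=frr,
                channel_radius_um=100.0,
                depletion="first_order_sink",
                sink_rate_s=2.0,
            ),
            convergence_check=False,
        )
        assert sink.t_mix_ms > base.t_mix_ms


class TestChannelLength:
    def test_half_second_at_typical_flow(self):
        assert M.channel_length_for_delay(500.0, 108.0, 100.0) == pytest.approx(28.6, abs=0.05)

    def test_zero_delay(self):
        assert M.channel_length_for_delay(0.0, 108.0, 100.0) == 0.0

    def test_linear_in_flow(self):
        assert M.channel_length_for_delay(500.0, 54.0, 100.0) == pytest.approx(14.3, abs=0.05)

    def test_round_trip_with_capillary_delay(self):
        # channel of radius R and the delay of a capillary of diameter 2R invert
        t = M.delay_for_capillary_extension(
            M.channel_length_for_delay(123.0, 80.0, 100.0), 80.0, 200.0
        )
        assert t == pytest.approx(123.0, rel=1e-12)


class TestCapillaryDelay:
    def test_published_extension_bookkeeping(self):
        assert M.delay_for_capillary_extension(28.0, 108.0, 200.0) == pytest.approx(489, abs=0.5)

    def test_zero_length(self):
        assert M.delay_for_capillary_extension(0.0, 108.0, 200.0) == 0.0

    def test_linear_in_length(self):
        one = M.delay_for_capillary_extension(14.0, 108.0, 200.0)
        two = M.delay_for_capillary_extension(28.0, 108.0, 200.0)
        assert two == pytest.approx(2 * one)


def test_catalogued_mixer_geometries_available():
    geom = M.MIXER_GEOMETRIES["MVED_Z"]
    assert geom.d_channel_um == 200.0
    assert geom.channel_radius_um == 100.0
    assert set(M.MIXER_GEOMETRIES) == {
        "MVED_Y", "MVED_Z", "MVED_S", "MVED_V", "JKMH_10", "JKMH_10H",
    }
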