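"""Engine tests: calibration, RHS correctness, integration fidelity.

The RHS kernel is cross-checked against an independent assembly built from
the pure flux functions, and the production Euler scheme against an
adaptive stiff integrator running the same RHS.
"""

import numpy as np
import pytest

from astrosim import (CompartmentGeometry, SimulationTrace, StimulusProtocol,
                      calibrate_rest, default_parameters, extracellular_state,
                      fluxes, integrate_reference, membrane_rate_factor,
                      resting_ip3, rhs, simulate)
from astrosim.engine import SimulationError, apply_toggles


def independent_rhs(y, g, geom, p):
    """RHS assembled from the flux-module functions (test-only oracle)."""
    ca, caer, na, ki, v, ip3, h = y
    cao = p.Ca_o_rest + (ca - p.Ca_i_rest) + (p.Ca_ER_rest - caer)
    nao = p.Na_o_rest + (p.Na_i_rest - na)
    ko = p.K_o_rest + (p.K_i_rest - ki)
    conv = membrane_rate_factor(geom, p)
    if geom.ratio_er > 0:
        j_net = (fluxes.ip3r_flux(ca, caer, ip3, h, p)
                 - fluxes.serca_flux(ca, p)
                 + fluxes.er_leak_flux(ca, caer, p))
    else:
        j_net = 0.0
    i_glut = fluxes.glut_current(ki, nao, g, p)
    i_nka = fluxes.nka_current(na, ko, p)
    i_ncx = fluxes.ncx_current(na, nao, ca, cao, v, p)
    i_na_l, i_k_l = fluxes.leak_currents(v, na, nao, ki, ko, p)
    dca = conv * i_ncx + geom.ratio_er * j_net
    dcaer = -j_net
    dna = conv / 1e3 * (3 * i_glut - 3 * i_nka - 3 * i_ncx - i_na_l)
    dki = conv / 1e3 * (-i_glut + 2 * i_nka - i_k_l)
    i_er = -2.0 * j_net / conv
    dv = -(i_er + i_ncx - 2 * i_glut + i_nka + i_na_l + i_k_l) / p.C_m * 1e3
    dip3 = fluxes.ip3_rate(ca, ip3, g, p)
    dh = fluxes.h_rate(ca, ip3, h, p)
    return np.array([dca, dcaer, dna, dki, dv, dip3, dh])


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

class TestCalibration:
    def test_resting_ip3_matches_published_initial_value(self, params):
        # root of the production/degradation balance at resting Ca
        assert resting_ip3(params) == pytest.approx(0.15659, abs=5e-6)

    def test_resting_gate_matches_published_initial_value(self, params):
        cal = calibrate_rest(apply_toggles(params, mglur_only=True),
                             CompartmentGeometry(svr=1.0, ratio_er=0.15))
        assert cal.h_rest == pytest.approx(0.7892, abs=5e-5)
        assert cal.ip3_rest == pytest.approx(0.15659, abs=5e-6)

    def test_store_balance_root(self, params, geom):
        # flux balance J_IP3R + J_leak = J_Serca at the mGluR-only rest
        cal = calibrate_rest(apply_toggles(params, mglur_only=True), geom)
        j = (fluxes.ip3r_flux(cal.ca_i_rest, cal.ca_er_rest, cal.ip3_rest,
                              cal.h_rest, cal.params)
             + fluxes.er_leak_flux(cal.ca_i_rest, cal.ca_er_rest, cal.params)
             - fluxes.serca_flux(cal.ca_i_rest, cal.params))
        assert j == pytest.approx(0.0, abs=1e-12)
        assert cal.ca_er_rest == pytest.approx(8.768, abs=2e-3)

    def test_ncx_rest_sits_at_reversal(self, params, geom):
        cal = calibrate_rest(params, geom)
        i = fluxes.ncx_current(cal.params.Na_i_rest, cal.params.Na_o_rest,
                               cal.ca_i_rest, cal.params.Ca_o_rest,
                               cal.params.V_rest, cal.params)
        assert i == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("toggles", [
        {}, {"mglur_only": True}, {"block_glut": True},
    ])
    @pytest.mark.parametrize("ratio_er", [0.0, 0.05, 0.15])
    def test_rest_is_fixed_point_for_every_recalibration(self, params,
                                                         toggles, ratio_er):
        g = CompartmentGeometry(svr=1.0, ratio_er=ratio_er)
        cal = calibrate_rest(apply_toggles(params, **toggles), g)
        dy = rhs(cal.state, 0.0, g, cal.params)
        scale = np.maximum(np.abs(cal.state), 1.0)
        assert np.max(np.abs(dy) / scale) < 1e-9

    def test_printed_mode_reproduces_table_verbatim(self, params, geom):
        cal = calibrate_rest(params, geom, mode="printed")
        assert cal.ip3_rest == 0.15659
        assert cal.h_rest == 0.7892
        assert cal.ca_er_rest == 25.0
        assert cal.params.g_Na_leak == 0.0065
        assert cal.params.g_K_leak == 0.0791

    def test_printed_store_option_sets_load_only(self, params, geom):
        cal = calibrate_rest(apply_toggles(params, mglur_only=True), geom,
                             store_init="printed")
        assert cal.ca_er_rest == 25.0
        assert cal.ip3_rest == pytest.approx(0.15659, abs=5e-6)


# --------------------------------------------------------------------------
# RHS assembly
# --------------------------------------------------------------------------

class TestRhs:
    def test_matches_independent_assembly_on_random_states(self, params, rng):
        for _ in range(50):
            y = np.array([rng.uniform(0.01, 2.0), rng.uniform(0.5, 20.0),
                          rng.uniform(5.0, 40.0), rng.uniform(60.0, 102.0),
                          rng.uniform(-120.0, 20.0), rng.uniform(0.05, 1.0),
                          rng.uniform(0.05, 0.95)])
            g = rng.uniform(0.0, 200.0)
            geom = CompartmentGeometry(svr=rng.uniform(0.2, 5.0),
                                       ratio_er=rng.uniform(0.0, 0.15))
            got = rhs(y, g, geom, params)
            want = independent_rhs(y, g, geom, params)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_er_exchange_conserves_total_calcium(self, params, rng):
        # cytosolic ER contribution equals -ratio_er * d[Ca_ER]/dt at any state
        geom = CompartmentGeometry(svr=1.0, ratio_er=0.11)
        p0 = params.replace(I_NCX_max=0.0)
        for _ in range(20):
            y = np.array([rng.uniform(0.01, 1.0), rng.uniform(1.0, 30.0),
                          15.0, 100.0, -85.0, rng.uniform(0.1, 0.8),
                          rng.uniform(0.1, 0.9)])
            dy = rhs(y, 0.0, geom, p0)
            assert dy[0] == pytest.approx(-geom.ratio_er * dy[1], rel=1e-12)

    def test_extracellular_mirror(self, params):
        rest = np.array([params.Ca_i_rest, params.Ca_ER_rest,
                         params.Na_i_rest, params.K_i_rest, params.V_rest,
                         0.15659, 0.7892])
        assert extracellular_state(rest, params) == pytest.approx(
            (1800.0, 145.0, 3.0))
        shifted = rest + np.array([0.1, -2.9, 10.0, 0, 0, 0, 0])
        ca_o, na_o, _ = extracellular_state(shifted, params)
        assert ca_o == pytest.approx(1803.0)   # Eq: +0.1 from cytosol, +2.9 from store
        assert na_o == pytest.approx(135.0)

    def test_rhs_rejects_malformed_state(self, params, geom):
        with pytest.raises(ValueError):
            rhs(np.ones(5), 0.0, geom, params)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

class TestSimulate:
    def test_unstimulated_run_stays_at_rest(self, params, geom):
        proto = StimulusProtocol(mode="none", duration=10.0)
        tr = simulate(proto, params=params, geometry=geom, save_every=10)
        for name in ("Ca_i", "Ca_ER", "Na_i", "K_i", "V", "IP3", "h"):
            x = tr[name]
            assert np.max(np.abs(x - x[0])) <= 1e-6 * max(abs(x[0]), 1.0)

    def test_no_store_no_ncx_keeps_calcium_exactly_constant(self, params):
        p0 = params.replace(I_NCX_max=0.0)
        proto = StimulusProtocol(mode="poisson", rate=50.0, duration=5.0,
                                 seed=4)
        tr = simulate(proto, params=p0, er_free=True,
                      geometry=CompartmentGeometry(svr=1.0, ratio_er=0.15))
        assert np.all(tr["Ca_i"] == tr["Ca_i"][0])
        assert np.all(tr["Ca_ER"] == tr["Ca_ER"][0])

    def test_mglur_only_freezes_membrane_ions(self, params, geom):
        proto = StimulusProtocol(mode="poisson", rate=100.0, duration=5.0,
                                 seed=1)
        tr = simulate(proto, params=params, geometry=geom, mglur_only=True)
        assert np.all(tr["Na_i"] == tr["Na_i"][0])
        assert np.all(tr["K_i"] == tr["K_i"][0])
        assert np.any(tr["Ca_i"] != tr["Ca_i"][0])   # store pathway active

    def test_euler_agrees_with_adaptive_reference(self, params, geom):
        # 5-s constant-glutamate run; same RHS, independent integrator
        proto = StimulusProtocol(mode="constant", glutamate_level=100.0,
                                 duration=5.0)
        tr = simulate(proto, params=params, geometry=geom, save_every=100)
        cal_p = tr.metadata["parameters"]
        from astrosim import load_parameters
        p_cal = load_parameters(cal_p)
        y0 = tr.data[["Ca_i", "Ca_ER", "Na_i", "K_i", "V", "IP3", "h"]].iloc[0]
        ref = integrate_reference(np.asarray(y0), lambda t: 100.0, geom,
                                  p_cal, tr.t)
        euler = tr.data[["Ca_i", "Ca_ER", "Na_i", "K_i", "V", "IP3",
                         "h"]].to_numpy()
        for j, name in enumerate(("Ca_i", "Ca_ER", "Na_i", "K_i", "V",
                                  "IP3", "h")):
            scale = np.maximum(np.abs(ref[:, j]), 1e-3)
            err = np.max(np.abs(euler[:, j] - ref[:, j]) / scale)
            assert err < 0.02, f"{name}: Euler deviates {err:.3%}"

    def test_halving_dt_changes_endpoint_below_one_percent(self, params, geom):
        proto = StimulusProtocol(mode="constant", glutamate_level=100.0,
                                 duration=5.0)
        end = {}
        for dt in (1e-3, 5e-4):
            tr = simulate(proto, params=params, geometry=geom, dt=dt,
                          save_every=int(5.0 / dt / 10), record_fluxes=False)
            end[dt] = tr.data.iloc[-1][["Ca_i", "Ca_ER", "Na_i", "K_i", "V",
                                        "IP3", "h"]].to_numpy(dtype=float)
        rel = np.abs(end[5e-4] - end[1e-3]) / np.maximum(np.abs(end[5e-4]),
                                                         1e-3)
        assert np.max(rel) < 0.01

    def test_identical_runs_are_bit_identical(self, params, geom):
        proto = StimulusProtocol(mode="poisson", rate=20.0, duration=3.0,
                                 seed=9)
        a = simulate(proto, params=params, geometry=geom)
        b = simulate(proto, params=params, geometry=geom)
        assert a.data.equals(b.data)

    def test_flux_breakdown_recorded_and_finite(self, params, geom):
        proto = StimulusProtocol(mode="poisson", rate=30.0, duration=2.0,
                                 seed=2)
        tr = simulate(proto, params=params, geometry=geom)
        for col in ("J_IP3R", "J_Serca", "I_GluT", "I_NKA", "I_NCX",
                    "prod_PLCbeta", "degr_IP_5P"):
            assert np.all(np.isfinite(tr[col]))
        assert np.all(tr["J_Serca"] >= 0)
        assert np.all(tr["I_GluT"] >= 0)

    def test_unstable_configuration_aborts_with_diagnostic(self, params, geom):
        # a capacitance far below the leak-conductance stability bound makes
        # the voltage update diverge; the engine must abort, not emit garbage
        proto = StimulusProtocol(mode="constant", glutamate_level=100.0,
                                 duration=5.0)
        with pytest.raises(SimulationError, match="step"):
            simulate(proto, params=params.replace(C_m=1e-3), geometry=geom)

    def test_metadata_round_trips_the_run(self, params, geom):
        proto = StimulusProtocol(mode="poisson", rate=10.0, duration=2.0,
                                 seed=5)
        tr = simulate(proto, params=params, geometry=geom)
        md = tr.metadata
        assert md["geometry"]["ratio_er"] == geom.ratio_er
        assert md["protocol"]["seed"] == 5
        assert md["calibration"]["scaled_residual"] < 1e-9
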