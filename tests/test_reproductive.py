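"""Estrous-cycle network: initial values, couplings and cycle dynamics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bovsim import (ReproductiveParams, ReproductiveState,
                    TABLE7_REFERENCE_VALUES, bovcycle_rhs, igf_rhs,
                    lh_follicle_response, oxytocin_rhs)
from bovsim.events import cycle_lengths, detect_ovulations
from bovsim.hill import hill_neg, hill_pos
from bovsim.reproductive import (STATE_NAMES, gonadotropin_pituitary_rhs,
                                 oxytocin_lactation_source)

MAINTENANCE_INS = 15.26  # mU/L, blood insulin at maintenance intake


def _integrate(rp, ins, days, y0=None, lactating=False, exo=lambda t: 0.0):
    y0 = ReproductiveState().as_array() if y0 is None else y0
    sol = solve_ivp(
        lambda t, y: bovcycle_rhs(y, ins, t, rp, lactating=lactating,
                                  exogenous_oxytocin=exo(t)),
        (0.0, days), y0, method="LSODA", rtol=1e-6, atol=1e-9,
        max_step=0.1, t_eval=np.arange(0.0, days, 0.05))
    assert sol.success, sol.message
    return sol.t, {n: sol.y[i] for i, n in enumerate(STATE_NAMES)}


def test_default_initial_values_match_reference_table():
    s = ReproductiveState()
    expected = [0.667, 0.551, 0.316, 0.395, 1.0, 0.642, 1.0, 0.00506,
                0.0, 0.004, 0.89, 0.826, 0.0, 0.0183, 0.48, 0.35]
    assert s.as_array().tolist() == expected
    assert ReproductiveState.lactating().oxy == 2.5


def test_recalibrated_values_and_reference_toggle():
    rp = ReproductiveParams()
    assert (rp.c_lh_cle, rp.c_p4_base) == (2.0, 0.1)
    assert (rp.ex_enz_pgf, rp.ex_oxy_pgf) == (1.0, 10.0)
    assert (rp.ex_p4_enz, rp.ex_pgf_iof, rp.ex_cl_iof) == (1.0, 10.0, 1.0)
    assert (rp.T_foll_fsh, rp.T_fsh_foll, rp.T_cl_cl) == (1.497, 0.322, 0.2807)
    assert (rp.c_cl_cl, rp.c_cl_lh) == (0.0335, 0.4)
    ref = rp.with_reference_values()
    assert ref.c_lh_cle == 12.0 and ref.c_p4_base == 0.0
    assert ref.T_foll_fsh == 0.57
    # individually toggleable
    one = rp.with_reference_values(["c_lh_cle"])
    assert one.c_lh_cle == 12.0 and one.T_foll_fsh == 1.497
    with pytest.raises(KeyError):
        rp.with_reference_values(["no_such_parameter"])
    assert set(TABLE7_REFERENCE_VALUES) == {
        "c_lh_cle", "c_p4_base", "ex_cl_cl", "ex_enz_pgf", "ex_oxy_pgf",
        "ex_p4_enz", "ex_pgf_iof", "ex_cl_iof", "T_foll_fsh", "T_fsh_foll",
        "T_cl_cl", "c_cl_cl", "c_cl_lh"}


def test_igf_equilibria_follow_hill_limits():
    rp = ReproductiveParams()
    # P4 -> 0, insulin large: both Hills ~ 1, equilibrium (c17+c18)/c19
    d = igf_rhs(0.0, 1e3, (rp.c17 + rp.c18) / rp.c19, rp)
    assert d == pytest.approx(0.0, abs=1e-9)
    assert (rp.c17 + rp.c18) / rp.c19 == pytest.approx(0.8235, abs=1e-4)
    # P4 large or insulin 0: basal-only equilibrium c17/c19
    d = igf_rhs(1e3, 0.0, rp.c17 / rp.c19, rp)
    assert d == pytest.approx(0.0, abs=1e-9)
    assert rp.c17 / rp.c19 == pytest.approx(0.2353, abs=1e-4)


def test_lh_response_threshold_depends_on_igf():
    rp = ReproductiveParams()
    # IGF at its threshold halves the Hill: T13 = 0.5*c21
    r = lh_follicle_response(0.5 * rp.c21, rp.T14, rp)
    assert r == pytest.approx(rp.c20 * 0.5, rel=1e-9)
    # abundant IGF-1 drives T13 -> 0 and the response saturates at c20
    assert lh_follicle_response(0.05, 1e6, rp) == pytest.approx(rp.c20,
                                                               rel=1e-3)
    # direct evaluation: igf=0.2 -> T13 = H-(0.2,0.5,2) = 0.8621
    t13 = rp.c21 * hill_neg(0.2, rp.T14, 2)
    assert t13 == pytest.approx(0.8621, abs=1e-4)
    resp = lh_follicle_response(0.5, 0.2, rp)
    assert resp == pytest.approx(3.49 * 0.25 / (0.25 + t13 ** 2), rel=1e-6)
    assert resp == pytest.approx(0.8785, abs=2e-3)


def test_insulin_gates_on_gonadotropin_synthesis():
    rp = ReproductiveParams()
    s = ReproductiveState()
    # insulin 0: synthesis halts entirely
    d_lh, d_fsh, _, _ = gonadotropin_pituitary_rhs(s, 0.0, rp)
    s0 = ReproductiveState(lh_pit=0.0, fsh_pit=0.0)
    d_lh0, d_fsh0, *_ = gonadotropin_pituitary_rhs(s0, 0.0, rp)
    assert d_lh0 == 0.0 and d_fsh0 == 0.0
    # Hill gates at their thresholds / worked values
    assert rp.c23 * hill_pos(rp.T16, rp.T16, 10) == pytest.approx(0.525)
    assert rp.c22 * hill_pos(16.0, rp.T15, 10) == pytest.approx(1.969,
                                                                abs=2e-3)


def test_lactation_oxytocin_source_is_a_decaying_gaussian():
    rp = ReproductiveParams()
    assert oxytocin_lactation_source(0.0, rp, True) == pytest.approx(1.5)
    assert oxytocin_lactation_source(100.0, rp, True) == pytest.approx(
        1.5 * np.exp(-7.0), rel=1e-9)
    assert oxytocin_lactation_source(100.0, rp, True) == pytest.approx(
        1.368e-3, abs=2e-6)
    assert oxytocin_lactation_source(50.0, rp, False) == 0.0
    # the rhs recovers the plain oxytocin balance when not lactating
    d_lact = oxytocin_rhs(0.5, 10.0, 0.3, rp, lactating=True)
    d_dry = oxytocin_rhs(0.5, 10.0, 0.3, rp, lactating=False)
    assert d_lact - d_dry == pytest.approx(
        oxytocin_lactation_source(10.0, rp, True))


def test_cyclicity_at_adequate_insulin():
    """With maintenance insulin the network settles into a regular
    estrous cycle of approximately three weeks."""
    rp = ReproductiveParams()
    t, s = _integrate(rp, MAINTENANCE_INS, 150.0)
    ov = [o for o in detect_ovulations(t, s["lh_blood"], s["p4"]) if o > 25]
    cyc = cycle_lengths(ov)
    assert len(cyc) >= 3
    assert 17.0 < np.mean(cyc) < 24.0
    # successive intervals stay close after the burn-in
    assert np.max(np.abs(np.diff(cyc))) < 4.0
    assert s["p4"].max() > 1.0


def test_low_insulin_abolishes_ovulation():
    """Forcing insulin far below the pituitary gates for >= 30 days
    abolishes LH surges and ovulations."""
    rp = ReproductiveParams()
    low = 0.5 * min(rp.T15, rp.T16)
    t, s = _integrate(rp, low, 60.0)
    ov = [o for o in detect_ovulations(t, s["lh_blood"], s["p4"]) if o > 5]
    assert ov == []


def test_p4_and_igf_anticorrelated_over_a_cycle(maintenance_run):
    res = maintenance_run
    ov = res.events.ovulation_times_d
    a, b = ov[-2], ov[-1]
    m = (res.time >= a) & (res.time <= b)
    r = np.corrcoef(res["p4"][m], res["igf"][m])[0, 1]
    assert r < -0.5


def test_all_states_stay_nonnegative(maintenance_run):
    assert (maintenance_run.states.to_numpy() > -1e-9).all()


def test_exogenous_oxytocin_shortens_the_cycle():
    """Daily oxytocin injections from cycle day 2 advance luteolysis:
    P4 rises normally for ~5 days, then falls, and the inter-ovulatory
    interval shrinks to roughly half its normal length."""
    rp = ReproductiveParams()
    t, s = _integrate(rp, MAINTENANCE_INS, 60.0)
    ov = detect_ovulations(t, s["lh_blood"], s["p4"])
    t0 = ov[1]  # a post-burn-in ovulation
    control = ov[2] - ov[1]

    from bovsim import PulseSchedule

    pulse = PulseSchedule(start=t0 + 2.0, stop=t0 + 30.0)
    t2, s2 = _integrate(rp, MAINTENANCE_INS, t0 + 35.0, exo=pulse)
    ov2 = [o for o in detect_ovulations(t2, s2["lh_blood"], s2["p4"])
           if o >= t0 - 0.5]
    assert len(ov2) >= 2
    treated = ov2[1] - ov2[0]
    assert treated < 0.75 * control
    # P4 rises normally through cycle day ~4 ...
    i4 = np.searchsorted(t2, ov2[0] + 4.0)
    assert s2["p4"][i4] > 1.0
    # ... but falls to a low inter-cycle trough before the (early) next
    # ovulation instead of sustaining a full-length luteal phase
    m = (t2 > ov2[0] + 5.0) & (t2 < ov2[1])
    assert s2["p4"][m].min() < 0.5
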