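"""Estrous-cycle hormone network of the cow, coupled to metabolism.

Sixteen dimensionless ("relative") state variables describe the
hypothalamus-pituitary-ovary axis: GnRH (hypothalamus and pituitary
pools), FSH and LH (pituitary pool and blood), the lumped follicular
function, the corpus luteum (CL), progesterone (P4), estradiol (E2),
inhibin, prostaglandin F2alpha (PGF2a), the endometrial enzyme pool
driving PGF2a synthesis, oxytocin, IGF-1, and an interovarian factor
(IOF) mediating luteolysis.

The regulatory topology is the classical one for the bovine cycle:

* P4 suppresses GnRH/LH synthesis and follicular function; the
  pituitary accumulates LH during the luteal phase.
* FSH (inhibin-limited) drives follicle growth; the follicle secretes
  E2 and inhibin.
* High E2 at low P4 triggers the GnRH surge, which discharges pituitary
  LH; the LH surge terminates follicular function (ovulation) and
  induces a CL, which is then self-sustaining above a size threshold.
* Luteolysis requires two conditions met simultaneously: an endometrial
  enzyme pool primed by sustained P4 exposure, and oxytocin driven by
  follicular E2.  Their conjunction produces PGF2a, which acts through
  the IOF on the CL.  A cow without follicular activity therefore keeps
  a persistent CL (luteolysis failure), as observed under acute feed
  restriction.

Nutritional input enters at three points: insulin gates LH and FSH
synthesis (steep Hill switches at T16 and T15), insulin and P4 shape
IGF-1, and IGF-1 sets the LH threshold for the ovarian response.  During
lactation an additional Gaussian oxytocin source term decays over the
lactation (peaking at calving).

All rates are per day; time is days (postpartum time for the lactation
source term).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .hill import _hill_neg_unchecked as Hm
from .hill import _hill_pos_unchecked as Hp

__all__ = [
    "ReproductiveState",
    "ReproductiveParams",
    "TABLE7_REFERENCE_VALUES",
    "igf_rhs",
    "lh_follicle_response",
    "gonadotropin_pituitary_rhs",
    "oxytocin_rhs",
    "bovcycle_rhs",
]

STATE_NAMES = (
    "gnrh_hypo", "gnrh_pit", "fsh_pit", "fsh_blood", "lh_pit", "lh_blood",
    "follicle", "pgf2a", "cl", "p4", "e2", "inhibin", "enzyme", "oxy",
    "igf", "iof",
)


@dataclass(frozen=True)
class ReproductiveState:
    """Relative concentrations of the 16 cycle components.

    Defaults are the standard non-lactating initial snapshot (a cow at
    estrus, shortly before ovulation).  For lactating simulations use
    :meth:`lactating` which starts at calving with elevated oxytocin.
    """

    gnrh_hypo: float = 0.667
    gnrh_pit: float = 0.551
    fsh_pit: float = 0.316
    fsh_blood: float = 0.395
    lh_pit: float = 1.0
    lh_blood: float = 0.642
    follicle: float = 1.0
    pgf2a: float = 0.00506
    cl: float = 0.0
    p4: float = 0.004
    e2: float = 0.89
    inhibin: float = 0.826
    enzyme: float = 0.0
    oxy: float = 0.0183
    igf: float = 0.48
    iof: float = 0.35

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ReproductiveState":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(STATE_NAMES),):
            raise ValueError(f"expected {len(STATE_NAMES)} states, got {x.shape}")
        return cls(**dict(zip(STATE_NAMES, x)))

    @classmethod
    def lactating(cls) -> "ReproductiveState":
        """Initial state at calving (high oxytocin, no CL)."""
        return cls(oxy=2.5)


# Recalibrated parameters: reference value in the original cycle model vs
# the value used here (the coupled model's defaults).  The ex_cl_cl row of
# the source table is typographically ambiguous; it is resolved as
# 2 -> 30 (a steep switch at the CL self-growth threshold), consistent
# with the switch-like CL self-maintenance the recalibration requires.
TABLE7_REFERENCE_VALUES = {
    "c_lh_cle": (12.0, 2.0),      # LH clearance rate, 1/d
    "c_p4_base": (0.0, 0.1),      # basal P4 production, [P4]/d
    "ex_cl_cl": (2.0, 30.0),      # exponent, CL self-growth switch
    "ex_enz_pgf": (5.0, 1.0),     # exponent, enzyme -> PGF2a
    "ex_oxy_pgf": (2.0, 10.0),    # exponent, oxytocin -> PGF2a
    "ex_p4_enz": (5.0, 1.0),      # exponent, P4 -> enzyme
    "ex_pgf_iof": (5.0, 10.0),    # exponent, PGF2a -> IOF
    "ex_cl_iof": (10.0, 1.0),     # exponent, CL -> IOF
    "T_foll_fsh": (0.57, 1.497),  # FSH threshold for follicle growth
    "T_fsh_foll": (0.22, 0.322),  # follicle size damping FSH influence
    "T_cl_cl": (0.1, 0.2807),     # CL self-growth threshold
    "c_cl_cl": (0.0334, 0.0335),  # CL self-growth rate, [CL]/d
    "c_cl_lh": (0.334, 0.4),      # LH-driven CL growth rate, [CL]/d
}


@dataclass(frozen=True)
class ReproductiveParams:
    """All rate constants, thresholds and Hill exponents of the cycle
    network, including the nutritional coupling constants c17..c25 and
    thresholds T11..T16.

    Defaults are the coupled-model calibration (recalibrated values where
    a reference value exists, see :data:`TABLE7_REFERENCE_VALUES`).
    """

    # --- nutritional couplings -------------------------------------------
    c17: float = 0.4      # basal IGF-1 synthesis, [IGF]/d
    c18: float = 1.0      # P4/insulin-regulated IGF-1 synthesis, [IGF]/d
    c19: float = 1.7      # IGF-1 clearance, 1/d
    c20: float = 3.49     # max effect of LH on follicular function, 1/d
    c21: float = 1.0      # cap of the IGF-dependent LH threshold, [LH]
    c22: float = 3.0      # max insulin effect on FSH synthesis (-)
    c23: float = 1.05     # max insulin effect on LH synthesis (-)
    c24: float = 1.5      # peak lactation oxytocin source, [Oxy]/d
    c25: float = 0.0007   # width of the lactation oxytocin source, 1/d^2
    T11: float = 0.3      # [P4] inhibiting IGF-1 synthesis
    T12: float = 15.0     # mU/L insulin stimulating IGF-1 synthesis
    T14: float = 0.5      # [IGF] restoring follicular LH responsiveness
    T15: float = 15.0     # mU/L insulin gating FSH synthesis
    T16: float = 16.0     # mU/L insulin gating LH synthesis

    # --- recalibrated cycle parameters -----------------------------------
    c_lh_cle: float = 2.0
    c_p4_base: float = 0.1
    ex_cl_cl: float = 30.0
    ex_enz_pgf: float = 1.0
    ex_oxy_pgf: float = 10.0
    ex_p4_enz: float = 1.0
    ex_pgf_iof: float = 10.0
    ex_cl_iof: float = 1.0
    T_foll_fsh: float = 1.497
    T_fsh_foll: float = 0.322
    T_cl_cl: float = 0.2807
    c_cl_cl: float = 0.0335
    c_cl_lh: float = 0.4

    # --- GnRH axis --------------------------------------------------------
    c_gnrh_syn: float = 1.5    # hypothalamic GnRH synthesis, 1/d
    T_gnrh_p4: float = 0.5     # P4 suppressing GnRH synthesis
    b_gnrh_rel: float = 0.02   # basal GnRH release, 1/d
    c_gnrh_rel: float = 10.0   # surge GnRH release, 1/d
    T_gnrh_e2: float = 0.9     # E2 threshold for the GnRH surge
    ex_gnrh_e2: float = 30.0   # steepness of the surge trigger (all-or-none)
    T_gnrhrel_p4: float = 0.15 # P4 blocking the GnRH surge
    c_gnrh_auto: float = 15.0  # autocatalytic surge release (latch), 1/d
    T_gnrh_auto: float = 0.2   # pituitary GnRH level sustaining the surge
    c_gnrh_cle: float = 6.0    # pituitary GnRH clearance, 1/d

    # --- gonadotropins ----------------------------------------------------
    c_lh_syn: float = 10.0     # LH synthesis, [LH]/d
    lh_pit_max: float = 12.0   # pituitary LH storage capacity, [LH]
    T_lhsyn_p4: float = 0.5    # P4 suppressing LH synthesis
    b_lhsyn_e2: float = 0.3    # E2-independent fraction of LH synthesis
    T_lhsyn_e2: float = 0.5    # E2 stimulating LH synthesis
    b_lh_rel: float = 0.004    # basal LH release, 1/d
    s_lh_gnrh: float = 0.5     # LH released per unit GnRH discharge (-)
    s_lh_rel: float = 0.75     # pituitary -> blood scaling for LH (-)
    c_fsh_syn: float = 0.22    # FSH synthesis, [FSH]/d
    fsh_pit_max: float = 3.2   # pituitary FSH storage capacity, [FSH]
    T_fsh_inh: float = 0.8     # inhibin suppressing FSH synthesis
    b_fsh_rel: float = 0.0037  # basal FSH release, 1/d (slow store turnover)
    s_fsh_gnrh: float = 0.02   # FSH released per unit GnRH discharge (-)
    s_fsh_rel: float = 171.0   # pituitary -> blood scaling for FSH (-)
    c_fsh_cle: float = 1.5     # blood FSH clearance, 1/d

    # --- ovary ------------------------------------------------------------
    c_foll_fsh: float = 8.0    # FSH-driven follicle growth, [Foll]/d
    b_foll_growth: float = 0.15  # self-amplification-independent fraction (-)
    T_foll_self: float = 0.5   # dominance threshold for follicle runaway
    ex_foll_self: float = 6.0  # steepness of the dominance runaway
    c_foll_p4: float = 1.0     # P4-driven loss of follicular function, 1/d
    T_p4_foll: float = 0.9     # P4 threshold suppressing the follicle
    ex_p4_foll: float = 4.0
    T_ov_lh: float = 0.85      # surge LH threshold triggering ovulation
    T_cl_lh: float = 0.85      # blood LH threshold inducing a CL
    s_cl_foll: float = 0.5     # luteinized fraction of ovulated follicle (-)
    c_cl_decay: float = 0.06   # basal CL regression, 1/d
    c_cl_iof: float = 4.0      # IOF-driven CL regression, 1/d
    T_cl_iof: float = 0.3      # IOF threshold for CL regression
    c_p4_cl: float = 3.2       # CL P4 production, [P4]/d
    c_p4_cle: float = 1.3      # P4 clearance, 1/d
    b_e2: float = 0.1          # basal E2 production, [E2]/d
    T_pulse_ins: float = 9.0   # mU/L insulin sustaining LH pulsatility
    ex_pulse_ins: float = 20.0  # steepness of the hypothalamic glucose switch
    T_pulse_store: float = 1.5  # pituitary LH store sustaining pulsatility
    b_foll_pulse: float = 0.5  # pulse-independent fraction of follicle growth
    c_e2_foll: float = 2.0     # follicular E2 production, [E2]/d
    ex_e2_foll: float = 1.0    # superlinearity of E2 in follicular function
    c_e2_cle: float = 2.0      # E2 clearance, 1/d
    b_inh: float = 0.05        # basal inhibin production, [Inh]/d
    c_inh_foll: float = 0.75   # follicular inhibin production, [Inh]/d
    c_inh_cle: float = 1.5     # inhibin clearance, 1/d

    # --- luteolysis loop ---------------------------------------------------
    c_enz_p4: float = 0.029    # P4-primed enzyme synthesis, [Enz]/d
    T_enz_p4: float = 0.6      # P4 threshold priming the enzyme
    c_enz_cle: float = 0.01    # basal enzyme clearance, 1/d
    c_enz_reset: float = 6.0   # enzyme re-set at low P4 (around estrus), 1/d
    T_enz_reset: float = 0.3   # P4 threshold below which the enzyme re-sets
    b_oxy: float = 0.02        # basal oxytocin synthesis, [Oxy]/d
    c_oxy_e2: float = 1.05     # E2-driven oxytocin synthesis, [Oxy]/d
    T_oxy_e2: float = 0.55     # E2 threshold for oxytocin synthesis
    c_oxy_cle: float = 1.0     # oxytocin clearance, 1/d
    c_pgf: float = 9.0         # PGF2a synthesis, [PGF]/d
    T_pgf_enz: float = 0.9     # enzyme threshold for PGF2a synthesis
    T_pgf_oxy: float = 0.40    # oxytocin threshold for PGF2a synthesis
    c_pgf_sat: float = 1.5     # PGF2a from supra-physiological oxytocin, [PGF]/d
    T_pgf_sat: float = 2.0     # receptor-saturation threshold, [Oxy]
    c_pgf_cle: float = 2.0     # PGF2a clearance, 1/d
    c_iof: float = 3.0         # IOF synthesis, [IOF]/d
    T_iof_pgf: float = 1.2     # PGF2a threshold for IOF synthesis
    T_iof_cl: float = 0.2      # CL threshold for IOF synthesis
    c_iof_cle: float = 2.0     # IOF clearance, 1/d

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")

    def replace(self, **kw) -> "ReproductiveParams":
        return replace(self, **kw)

    def with_reference_values(self, names=None) -> "ReproductiveParams":
        """Revert recalibrated parameters to their reference-model values.

        ``names`` selects a subset (default: all thirteen); each override
        is individually toggleable for regression comparisons.
        """
        if names is None:
            names = list(TABLE7_REFERENCE_VALUES)
        unknown = set(names) - set(TABLE7_REFERENCE_VALUES)
        if unknown:
            raise KeyError(f"not recalibrated parameters: {sorted(unknown)}")
        return self.replace(**{n: TABLE7_REFERENCE_VALUES[n][0] for n in names})


def _gnrh_release(state: ReproductiveState, p: ReproductiveParams) -> float:
    """Hypothalamic GnRH release flux.

    The surge latches: once ignited by high E2 at low P4, pituitary GnRH
    reinforces its own release until the hypothalamic store empties.
    """
    return (p.b_gnrh_rel
            + p.c_gnrh_rel * Hp(state.e2, p.T_gnrh_e2, p.ex_gnrh_e2)
            * Hm(state.p4, p.T_gnrhrel_p4, 4)
            + p.c_gnrh_auto * Hp(state.gnrh_pit, p.T_gnrh_auto, 4)
            ) * state.gnrh_hypo


def igf_rhs(p4: float, ins: float, igf: float,
            params: ReproductiveParams) -> float:
    """IGF-1 dynamics: basal synthesis plus a term requiring low P4 and
    adequate insulin, minus first-order clearance.  Makes IGF-1 run
    anti-phase to P4 over the cycle and collapse under low insulin."""
    p = params
    return (p.c17 + p.c18 * Hm(p4, p.T11, 4) * Hp(ins, p.T12, 10)
            - p.c19 * igf)


def lh_follicle_response(lh_blood: float, igf: float,
                         params: ReproductiveParams) -> float:
    """Ovarian response to blood LH with an IGF-1-dependent threshold.

    The LH level required for an ovarian response rises when IGF-1 is
    low: ``T13 = c21 * H-(IGF, T14, 2)``.  Returns the stimulation rate
    ``c20 * H+(LH, T13, 2)`` in 1/d.
    """
    p = params
    t13 = p.c21 * Hm(igf, p.T14, 2)
    return p.c20 * Hp(lh_blood, t13, 2)


def _insulin_multipliers(ins: float, params: ReproductiveParams):
    """Hill gates of insulin on LH and FSH synthesis (Eqs. hp_Ins)."""
    p = params
    hp_lh = p.c23 * Hp(ins, p.T16, 10)
    hp_fsh = p.c22 * Hp(ins, p.T15, 10)
    return hp_lh, hp_fsh


def gonadotropin_pituitary_rhs(state: ReproductiveState, ins: float,
                               params: ReproductiveParams):
    """Pituitary LH/FSH balances: synthesis (insulin-gated) - release."""
    p = params
    hp_lh, hp_fsh = _insulin_multipliers(ins, p)
    lh_syn = (p.c_lh_syn * Hm(state.p4, p.T_lhsyn_p4, 2)
              * (p.b_lhsyn_e2 + (1 - p.b_lhsyn_e2)
                 * Hp(state.e2, p.T_lhsyn_e2, 2)))
    gnrh_rel = _gnrh_release(state, p)
    lh_rel = (p.b_lh_rel + p.s_lh_gnrh * gnrh_rel) * state.lh_pit
    fsh_syn = p.c_fsh_syn * Hm(state.inhibin, p.T_fsh_inh, 5)
    fsh_rel = (p.b_fsh_rel + p.s_fsh_gnrh * gnrh_rel) * state.fsh_pit
    d_lh_pit = (lh_syn * hp_lh * max(1.0 - state.lh_pit / p.lh_pit_max, 0.0)
                - lh_rel)
    d_fsh_pit = (fsh_syn * hp_fsh
                 * max(1.0 - state.fsh_pit / p.fsh_pit_max, 0.0) - fsh_rel)
    return d_lh_pit, d_fsh_pit, lh_rel, fsh_rel


def oxytocin_lactation_source(t: float, params: ReproductiveParams,
                              lactating: bool) -> float:
    """Gaussian postpartum oxytocin source ``c24*exp(-c25*t^2)``; zero in
    non-lactating scenarios.  ``t`` is days since calving."""
    if not lactating:
        return 0.0
    return params.c24 * float(np.exp(-params.c25 * t * t))


def oxytocin_rhs(oxy: float, t: float, e2: float,
                 params: ReproductiveParams, lactating: bool = False,
                 exogenous: float = 0.0) -> float:
    """Oxytocin balance: lactation source + E2-driven synthesis + optional
    exogenous administration - clearance."""
    p = params
    oxy_lac = oxytocin_lactation_source(t, p, lactating)
    oxy_syn = p.b_oxy + p.c_oxy_e2 * Hp(e2, p.T_oxy_e2, 2)
    oxy_cle = p.c_oxy_cle * oxy
    return oxy_lac + oxy_syn - oxy_cle + exogenous


def bovcycle_rhs(x, ins: float, t: float, params: ReproductiveParams,
                 lactating: bool = False,
                 exogenous_oxytocin: float = 0.0) -> np.ndarray:
    """Full right-hand side of the 16-state cycle network.

    Parameters
    ----------
    x : array of 16 states in :data:`STATE_NAMES` order.
    ins : instantaneous blood insulin, mU/L (from the metabolic model or
        held constant for decoupled studies).
    t : time in days (postpartum time for the lactation source).
    lactating : activates the postpartum oxytocin source.
    exogenous_oxytocin : additive oxytocin administration rate, [Oxy]/d.
    """
    s = ReproductiveState.from_array(x)
    p = params

    # GnRH: synthesis suppressed by P4; surge release needs high E2 at low P4
    gnrh_syn = (p.c_gnrh_syn * Hm(s.p4, p.T_gnrh_p4, 2)
                * max(1.0 - s.gnrh_hypo, 0.0))
    gnrh_rel = _gnrh_release(s, p)
    d_gnrh_hypo = gnrh_syn - gnrh_rel
    d_gnrh_pit = gnrh_rel - p.c_gnrh_cle * s.gnrh_pit

    d_lh_pit, d_fsh_pit, lh_rel, fsh_rel = gonadotropin_pituitary_rhs(s, ins, p)
    d_lh_blood = p.s_lh_rel * lh_rel - p.c_lh_cle * s.lh_blood
    d_fsh_blood = p.s_fsh_rel * fsh_rel - p.c_fsh_cle * s.fsh_blood

    # follicle: FSH-driven growth (self-limited), terminated by the LH
    # surge (IGF-gated responsiveness) and suppressed by P4
    # dominance runaway: above T_foll_self the follicle amplifies its own
    # growth (deviation of the dominant follicle), giving the E2 rise
    # momentum through the surge threshold.  Basal LH pulsatility -
    # requiring adequate glucose/insulin (hypothalamic gating) and a
    # non-empty pituitary LH store - is permissive for follicular
    # function; severe feed restriction therefore collapses the follicle
    # and its E2 within days, which blocks luteolysis
    pulse_support = (Hp(ins, p.T_pulse_ins, p.ex_pulse_ins)
                     * Hp(s.lh_pit, p.T_pulse_store, 2))
    growth = (p.c_foll_fsh * Hp(s.fsh_blood, p.T_foll_fsh, 2)
              * (p.b_foll_pulse + (1.0 - p.b_foll_pulse) * pulse_support)
              * (p.b_foll_growth + (1.0 - p.b_foll_growth)
                 * Hp(s.follicle, p.T_foll_self, p.ex_foll_self))
              * Hm(s.follicle, p.T_fsh_foll, 2))
    # ovulation is an all-or-none surge event: the IGF-gated ovarian
    # response (lh_follicle_response) acts on the follicle only at
    # surge-level LH; basal LH supports rather than destroys the
    # dominant follicle
    ovulatory_loss = (lh_follicle_response(s.lh_blood, s.igf, p)
                      * Hp(s.lh_blood, p.T_ov_lh, 10) * s.follicle)
    p4_loss = p.c_foll_p4 * Hp(s.p4, p.T_p4_foll, p.ex_p4_foll) * s.follicle
    d_follicle = growth - ovulatory_loss - p4_loss

    # CL: luteinization of the ovulated follicle plus LH-driven growth,
    # self-sustaining above T_cl_cl, regressed by the IOF
    luteinization = (p.s_cl_foll * Hp(s.lh_blood, p.T_cl_lh, 10)
                     * ovulatory_loss)
    d_cl = (luteinization
            + p.c_cl_lh * Hp(s.lh_blood, p.T_cl_lh, 10) * max(1.0 - s.cl, 0.0)
            + p.c_cl_cl * Hp(s.cl, p.T_cl_cl, p.ex_cl_cl) * max(1.0 - s.cl, 0.0)
            - p.c_cl_iof * Hp(s.iof, p.T_cl_iof, 2) * s.cl
            - p.c_cl_decay * s.cl)

    d_p4 = p.c_p4_base + p.c_p4_cl * s.cl - p.c_p4_cle * s.p4
    d_e2 = (p.b_e2 + p.c_e2_foll * s.follicle ** p.ex_e2_foll
            - p.c_e2_cle * s.e2)
    d_inhibin = p.b_inh + p.c_inh_foll * s.follicle - p.c_inh_cle * s.inhibin

    # luteolysis loop: P4-primed enzyme AND E2-driven oxytocin -> PGF2a
    # the enzyme integrates P4 exposure (the luteolysis timer) and is
    # re-set around estrus when P4 is basal
    d_enzyme = (p.c_enz_p4 * Hp(s.p4, p.T_enz_p4, p.ex_p4_enz)
                - p.c_enz_cle * s.enzyme
                - p.c_enz_reset * Hm(s.p4, p.T_enz_reset, 4) * s.enzyme)
    d_oxy = oxytocin_rhs(s.oxy, t, s.e2, p, lactating, exogenous_oxytocin)
    # endometrial PGF2a: enzyme-timed synthesis gated by physiological
    # oxytocin, plus a receptor-saturation route engaged only by
    # supra-physiological (exogenous) oxytocin doses
    d_pgf2a = (p.c_pgf * Hp(s.enzyme, p.T_pgf_enz, p.ex_enz_pgf)
               * Hp(s.oxy, p.T_pgf_oxy, p.ex_oxy_pgf)
               + p.c_pgf_sat * Hp(s.oxy, p.T_pgf_sat, 4)
               * Hp(s.enzyme, 0.1, 1)
               - p.c_pgf_cle * s.pgf2a)
    d_iof = (p.c_iof * Hp(s.pgf2a, p.T_iof_pgf, p.ex_pgf_iof)
             * Hp(s.cl, p.T_iof_cl, p.ex_cl_iof)
             - p.c_iof_cle * s.iof)

    d_igf = igf_rhs(s.p4, ins, s.igf, p)

    return np.array([
        d_gnrh_hypo, d_gnrh_pit, d_fsh_pit, d_fsh_blood, d_lh_pit,
        d_lh_blood, d_follicle, d_pgf2a, d_cl, d_p4, d_e2, d_inhibin,
        d_enzyme, d_oxy, d_igf, d_iof,
    ])
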