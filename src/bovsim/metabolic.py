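"""Glucose-insulin-glucagon metabolism of the dairy cow.

Six state variables describe the flow of feed-derived glucose through a
standard 600-kg cow:

====================  =========================================  ======
state                 meaning                                    unit
====================  =========================================  ======
``glu_blood``         glucose concentration in the blood         g/L
``glu_liver``         glucose pool generated in the liver        g
``glu_store``         glycogen store                             g
``fat``               body fat                                   kg
``ins``               insulin concentration in the blood         mU/L
``gluca``             glucagon concentration in the blood        ng/L
====================  =========================================  ======

Feed enters as dry-matter intake (DMI, g/d), of which a fraction ``c0``
is glucose plus glucogenic substances; a fraction ``c1`` of that pool is
absorbed directly into the blood and the rest is converted to glucose in
the liver by gluconeogenesis.  Insulin and glucagon are secreted by the
pancreas in response to blood glucose via steep Hill switches and steer
storage (glycogenesis, lipogenesis) and mobilization (glycogenolysis,
fat-derived gluconeogenesis).  Sinks are a non-mammary maintenance term
and a mammary term proportional to daily milk yield.

All fluxes are in g/d except the pancreatic rates (mU/(L*d), ng/(L*d)).
The fat state is carried in kg; the corresponding g/d flux difference is
divided by 1000 in the right-hand side so that glucose mass is conserved
with an explicit unit factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .hill import _hill_neg_unchecked as Hm
from .hill import _hill_pos_unchecked as Hp

__all__ = [
    "MetabolicParams",
    "MetabolicState",
    "FluxVector",
    "StateConsistencyError",
    "feed_fluxes",
    "pancreatic_rates",
    "liver_fluxes",
    "usage_fluxes",
    "metabolic_fluxes",
    "metabolic_rhs",
]

#: validation bands for blood metabolites (warnings only, not constraints)
PHYSIOLOGICAL_RANGES = {
    "glu_blood": (0.39, 0.59),  # g/L
    "ins": (2.0, 50.0),         # mU/L
    "gluca": (50.0, 120.0),     # ng/L
}


class StateConsistencyError(ValueError):
    """A metabolic state violates a structural assumption of the model."""


@dataclass(frozen=True)
class MetabolicState:
    """The six metabolic state variables with their default initial values."""

    glu_blood: float = 0.48   # g/L
    glu_liver: float = 110.0  # g
    glu_store: float = 535.0  # g
    fat: float = 150.0        # kg
    ins: float = 15.5         # mU/L
    gluca: float = 105.0      # ng/L

    _FIELDS = ("glu_blood", "glu_liver", "glu_store", "fat", "ins", "gluca")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, x) -> "MetabolicState":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError(f"expected 6 metabolic states, got shape {x.shape}")
        return cls(**dict(zip(cls._FIELDS, x)))


@dataclass(frozen=True)
class MetabolicParams:
    """Rate constants, thresholds and geometry of the metabolic model.

    Defaults describe a 600-kg cow at maintenance intake.  ``c0`` is the
    relative glucose(+glucogenic) content of the DMI, ``c1`` the fraction
    of that pool absorbed directly into the blood.
    """

    c0: float = 0.08        # relative glucose content of the DMI (-)
    c1: float = 0.08        # directly absorbable fraction (-)
    c2: float = 84211.0     # insulin secretion, mU/(L*d)
    c3: float = 2105.0      # insulin degradation, 1/d
    c4: float = 70182.0     # glucagon secretion, ng/(L*d)
    c5: float = 350.87      # glucagon degradation, 1/d
    c6: float = 50.0        # blood -> liver uptake, (g*L)/(mU*d)
    c7: float = 180.0       # glycogenesis, L/(mU*d)
    c8: float = 0.22683     # lipogenesis, L/(mU*d)
    c9: float = 1350.0      # glycogenolysis, (g*L)/(ng*d)
    c10: float = 3.5272     # gluconeogenesis from glycerol, (g*L)/(ng*d)
    c11: float = 0.0684     # hepatic release, L/(ng*d)
    c12: float = 1000.0     # non-mammary usage, g/d
    c13: float = 72.0       # mammary usage, g per kg milk
    c14: float = 5.0        # liver metabolism usage, 1/d
    T1: float = 0.5         # g/L, blood glucose -> insulin secretion
    T2: float = 0.5         # g/L, blood glucose -| glucagon secretion
    T3: float = 0.45        # g/L, blood glucose -> hepatic uptake
    T4: float = 10.0        # L/d milk -| glycogenesis
    T5: float = 10.0        # L/d milk -| lipogenesis
    T6: float = 1000.0      # g store -> lipogenesis
    T7: float = 10.0        # g store -> glycogenolysis
    T8: float = 10.0        # g store -| fat-derived gluconeogenesis
    T9: float = 150.0       # kg fat -> fat-derived gluconeogenesis
    T10: float = 0.5        # g/L, blood glucose -> non-mammary usage
    V: float = 22.8         # extracellular blood volume, L
    K: float = 1000.0       # glycogen carrying capacity, g
    DMI: float = 11700.0    # dry-matter intake, g/d

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v!r}")
        if not (0 < self.c0 <= 1):
            raise ValueError(f"c0 must lie in (0, 1], got {self.c0!r}")
        if not (0 < self.c1 <= 1):
            raise ValueError(f"c1 must lie in (0, 1], got {self.c1!r}")

    def replace(self, **kw) -> "MetabolicParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FluxVector:
    """All instantaneous rates of the metabolic model (g/d, pancreatic
    rates in their concentration units)."""

    glu_feed_bl: float
    glu_feed_gng: float
    glu_bl_lv: float
    glu_st_lv: float
    glu_lv_st: float
    glu_lv_fat: float
    glu_fat_lv: float
    glu_prod: float
    glu_bl_usage: float
    glu_lv_usage: float
    ins_sec: float
    ins_deg: float
    gluca_sec: float
    gluca_deg: float

    _GLUCOSE_FLUXES = (
        "glu_feed_bl", "glu_feed_gng", "glu_bl_lv", "glu_st_lv",
        "glu_lv_st", "glu_lv_fat", "glu_fat_lv", "glu_prod",
        "glu_bl_usage", "glu_lv_usage",
    )


def feed_fluxes(params: MetabolicParams) -> tuple[float, float]:
    """Split the dietary glucose pool ``c0*DMI`` into direct absorption
    and the gluconeogenic route.  The two routes sum to the pool exactly
    (100% efficiency, no loss)."""
    glu_pool = params.c0 * params.DMI
    glu_feed_bl = params.c1 * glu_pool
    glu_feed_gng = (1.0 - params.c1) * glu_pool
    return glu_feed_bl, glu_feed_gng


def pancreatic_rates(state: MetabolicState, params: MetabolicParams):
    """Insulin/glucagon secretion and first-order degradation rates."""
    p = params
    ins_sec = p.c2 * Hp(state.glu_blood, p.T1, 10)
    gluca_sec = p.c4 * Hm(state.glu_blood, p.T2, 2)
    ins_deg = p.c3 * state.ins
    gluca_deg = p.c5 * state.gluca
    return ins_sec, ins_deg, gluca_sec, gluca_deg


def liver_fluxes(state: MetabolicState, milk: float, params: MetabolicParams,
                 check: bool = True):
    """Hepatic uptake, storage, mobilization and release rate laws.

    ``glu_lv_st`` carries the logistic store factor ``1 - glu_store/K``
    and therefore goes negative if the store overshoots its carrying
    capacity; a clear violation (>0.1% above K) is flagged as a
    :class:`StateConsistencyError` rather than silently clipped.
    """
    if milk < 0:
        raise ValueError(f"milk must be >= 0, got {milk!r}")
    p = params
    if check and state.glu_store > p.K * 1.001:
        raise StateConsistencyError(
            f"glycogen store {state.glu_store:.3f} g exceeds carrying "
            f"capacity K={p.K:.0f} g"
        )
    glu_bl_lv = p.c6 * Hp(state.glu_blood, p.T3, 10) * state.ins
    glu_lv_st = (
        p.c7 * Hm(milk, p.T4, 2) * (1.0 - state.glu_store / p.K)
        * state.glu_liver * state.ins
    )
    glu_lv_fat = (
        p.c8 * Hm(milk, p.T5, 1) * Hp(state.glu_store, p.T6, 10)
        * state.glu_liver * state.ins
    )
    glu_st_lv = p.c9 * Hp(state.glu_store, p.T7, 10) * state.gluca
    glu_fat_lv = (
        p.c10 * Hm(state.glu_store, p.T8, 10) * Hp(state.fat, p.T9, 1)
        * state.gluca
    )
    glu_prod = p.c11 * state.glu_liver * state.gluca
    return glu_bl_lv, glu_lv_st, glu_lv_fat, glu_st_lv, glu_fat_lv, glu_prod


def usage_fluxes(state: MetabolicState, milk: float, params: MetabolicParams):
    """Glucose sinks: non-mammary maintenance + mammary demand (blood)
    and liver metabolism."""
    if milk < 0:
        raise ValueError(f"milk must be >= 0, got {milk!r}")
    p = params
    glu_bl_usage = p.c12 * Hp(state.glu_blood, p.T10, 10) + p.c13 * milk
    glu_lv_usage = p.c14 * state.glu_liver
    return glu_bl_usage, glu_lv_usage


def metabolic_fluxes(state: MetabolicState, milk: float,
                     params: MetabolicParams,
                     check: bool = True) -> FluxVector:
    """Evaluate every rate law of the model at one state.

    With ``check=False`` the store-overshoot consistency check is
    skipped; used by solvers whose trial points may transiently probe
    beyond the carrying capacity (the negative glycogenesis flux there
    is the self-correcting mathematical continuation).
    """
    glu_feed_bl, glu_feed_gng = feed_fluxes(params)
    ins_sec, ins_deg, gluca_sec, gluca_deg = pancreatic_rates(state, params)
    (glu_bl_lv, glu_lv_st, glu_lv_fat,
     glu_st_lv, glu_fat_lv, glu_prod) = liver_fluxes(state, milk, params,
                                                     check=check)
    glu_bl_usage, glu_lv_usage = usage_fluxes(state, milk, params)
    return FluxVector(
        glu_feed_bl=glu_feed_bl, glu_feed_gng=glu_feed_gng,
        glu_bl_lv=glu_bl_lv, glu_st_lv=glu_st_lv, glu_lv_st=glu_lv_st,
        glu_lv_fat=glu_lv_fat, glu_fat_lv=glu_fat_lv, glu_prod=glu_prod,
        glu_bl_usage=glu_bl_usage, glu_lv_usage=glu_lv_usage,
        ins_sec=ins_sec, ins_deg=ins_deg,
        gluca_sec=gluca_sec, gluca_deg=gluca_deg,
    )


def metabolic_rhs(x, milk: float, params: MetabolicParams) -> np.ndarray:
    """Time derivative of the six metabolic states.

    ``x`` is the state as an array ``[glu_blood, glu_liver, glu_store,
    fat, ins, gluca]``.  Glucose mass is conserved: ``V*d(glu_blood) +
    d(glu_liver) + d(glu_store) + 1000*d(fat)`` equals intake minus the
    two usage sinks, exactly.
    """
    state = MetabolicState.from_array(x)
    fl = metabolic_fluxes(state, milk, params, check=False)
    for name in FluxVector._GLUCOSE_FLUXES + ("ins_sec", "gluca_sec"):
        v = getattr(fl, name)
        if not np.isfinite(v):
            raise FloatingPointError(
                f"non-finite flux {name}={v!r} at state {state}"
            )
    d_glu_blood = (fl.glu_feed_bl + fl.glu_prod - fl.glu_bl_lv
                   - fl.glu_bl_usage) / params.V
    d_glu_liver = (fl.glu_feed_gng - fl.glu_prod + fl.glu_bl_lv
                   - fl.glu_lv_st + fl.glu_st_lv - fl.glu_lv_fat
                   + fl.glu_fat_lv - fl.glu_lv_usage)
    d_glu_store = fl.glu_lv_st - fl.glu_st_lv
    d_fat = (fl.glu_lv_fat - fl.glu_fat_lv) / 1000.0  # g/d -> kg/d
    d_ins = fl.ins_sec - fl.ins_deg
    d_gluca = fl.gluca_sec - fl.gluca_deg
    return np.array([d_glu_blood, d_glu_liver, d_glu_store,
                     d_fat, d_ins, d_gluca])
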