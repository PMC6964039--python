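"""Local finite-difference sensitivity of scalar observables.

Each model parameter ``p_i`` is perturbed to ``p_i * (1 + eps)`` (and
optionally ``1 - eps``), the scenario is re-simulated, and the relative
sensitivity is approximated by the one-sided quotient

    S_i ~ [y(p + eps*p_i*e_i) - y(p)] / (eps * |y(p)|),

where ``y`` is the observable (default: the day of onset of luteal
activity, i.e. the first time the relative P4 level exceeds 1).  The
un-normalized numerator ``y_pert - y_base`` is reported alongside, since
the denominator is the same for every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .events import NO_EVENT, detect_luteal_onset
from .metabolic import MetabolicParams
from .reproductive import ReproductiveParams
from .simulate import simulate

__all__ = ["SensitivityReport", "parameter_table", "local_sensitivity",
           "luteal_onset_observable"]


def parameter_table(mparams: Optional[MetabolicParams] = None,
                    rparams: Optional[ReproductiveParams] = None
                    ) -> pd.DataFrame:
    """Documented enumeration of every scalar model parameter.

    Columns: index, module ('metabolic'/'reproductive'), name, value.
    This published list replaces reliance on positional indices.
    """
    mparams = mparams or MetabolicParams()
    rparams = rparams or ReproductiveParams()
    rows = []
    for f in fields(mparams):
        rows.append(("metabolic", f.name, getattr(mparams, f.name)))
    for f in fields(rparams):
        rows.append(("reproductive", f.name, getattr(rparams, f.name)))
    df = pd.DataFrame(rows, columns=["module", "name", "value"])
    df.insert(0, "index", np.arange(len(df)))
    return df


@dataclass
class SensitivityReport:
    """Per-parameter sensitivities of one observable."""

    observable: str
    baseline: float
    epsilon: float
    table: pd.DataFrame  # module, name, value, sign, perturbed, numerator, rel_sensitivity

    def ranking(self) -> pd.DataFrame:
        """Parameters ordered by largest |relative sensitivity| over the
        evaluated signs; parameters whose perturbed observable was
        undefined are excluded."""
        t = self.table.dropna(subset=["rel_sensitivity"]).copy()
        t["magnitude"] = t["rel_sensitivity"].abs()
        best = (t.groupby(["module", "name"], sort=False)["magnitude"]
                .max().reset_index())
        return best.sort_values("magnitude", ascending=False,
                                ignore_index=True)


def luteal_onset_observable(scenario, threshold: float = 1.0,
                            **sim_kw) -> Callable:
    """Observable factory: day of luteal onset for the given scenario.

    A ``c0`` override on the scenario is transferred to the metabolic
    parameters so that perturbations of ``c0`` itself are honoured.
    """
    if scenario.c0 is not None:
        from dataclasses import replace as _replace

        base_c0, scenario = scenario.c0, _replace(scenario, c0=None)
    else:
        base_c0 = None

    def observable(mparams, rparams) -> float:
        if base_c0 is not None and mparams.c0 == MetabolicParams().c0:
            mparams = mparams.replace(c0=base_c0)
        res = simulate(scenario, mparams, rparams, **sim_kw)
        return detect_luteal_onset(res.time, res["p4"], threshold)

    observable.__name__ = "luteal_onset_d"
    return observable


def local_sensitivity(observable: Callable,
                      mparams: Optional[MetabolicParams] = None,
                      rparams: Optional[ReproductiveParams] = None,
                      parameters: Optional[Sequence[str]] = None,
                      epsilon: float = 0.1,
                      signs: Sequence[int] = (+1,),
                      progress: bool = False) -> SensitivityReport:
    """One-sided (optionally two-sided) local sensitivity analysis.

    ``observable(mparams, rparams) -> float`` must be well-defined at the
    baseline.  ``parameters`` restricts the scan to named parameters
    (default: every parameter in :func:`parameter_table`).  If a
    perturbation makes the observable undefined (no event detected), the
    entry is recorded with NaN sensitivity and excluded from the ranking.
    """
    mparams = mparams or MetabolicParams()
    rparams = rparams or ReproductiveParams()
    y0 = observable(mparams, rparams)
    if not np.isfinite(y0):
        raise ValueError("observable undefined at the baseline parameters")

    ptable = parameter_table(mparams, rparams)
    if parameters is not None:
        missing = set(parameters) - set(ptable["name"])
        if missing:
            raise KeyError(f"unknown parameters: {sorted(missing)}")
        ptable = ptable[ptable["name"].isin(parameters)]

    rows = []
    for _, prow in ptable.iterrows():
        module, name, value = prow["module"], prow["name"], prow["value"]
        for sign in signs:
            pval = value * (1.0 + sign * epsilon)
            try:
                if module == "metabolic":
                    y = observable(mparams.replace(**{name: pval}), rparams)
                else:
                    y = observable(mparams, rparams.replace(**{name: pval}))
            except Exception:
                y = NO_EVENT
            numer = y - y0 if np.isfinite(y) else np.nan
            rel = (numer / (epsilon * abs(y0))
                   if np.isfinite(y) and y0 != 0 else np.nan)
            rows.append((module, name, value, sign, y, numer, rel))
            if progress:
                print(f"  {name} ({sign:+d}{epsilon:.0%}): y={y:.2f}")
    table = pd.DataFrame(rows, columns=["module", "name", "value", "sign",
                                        "perturbed", "numerator",
                                        "rel_sensitivity"])
    return SensitivityReport(observable=getattr(observable, "__name__", "y"),
                             baseline=float(y0), epsilon=epsilon, table=table)
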