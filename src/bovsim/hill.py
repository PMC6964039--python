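"""Hill threshold kinetics.

Every regulatory interaction in the model is a sigmoidal switch: a
stimulatory (positive) or inhibitory (negative) Hill function of a
substance ``S`` around a threshold ``T`` with steepness ``n``.  The
positive form is ``S**n / (S**n + T**n)``; the negative form is its
complement.  Both map ``[0, inf)`` into ``[0, 1]`` and cross 0.5 exactly
at ``S == T``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hill_pos", "hill_neg"]


def _validate(S, T, n):
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("Hill input S must be finite")
    if np.any(S < 0):
        raise ValueError("Hill input S must be non-negative")
    if not np.isfinite(T) or T <= 0:
        raise ValueError(f"Hill threshold T must be positive, got {T!r}")
    if n < 1:
        raise ValueError(f"Hill coefficient n must be >= 1, got {n!r}")
    return S


def hill_pos(S, T, n):
    """Stimulatory Hill function ``S**n / (S**n + T**n)``.

    Parameters
    ----------
    S : float or array_like
        Substance level, >= 0.
    T : float
        Switching threshold, > 0.
    n : float
        Hill coefficient (steepness), >= 1.
    """
    S = _validate(S, T, n)
    # compute in ratio form for numerical safety at large S**n
    r = (S / T) ** n
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def hill_neg(S, T, n):
    """Inhibitory Hill function ``T**n / (S**n + T**n)`` = 1 - hill_pos."""
    S = _validate(S, T, n)
    r = (S / T) ** n
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def _hill_pos_unchecked(S, T, n):
    """Positive Hill with the input clipped at zero instead of validated.

    Used inside right-hand sides, where implicit solvers may probe states
    a few ulp below zero; the state itself is never modified.
    """
    S = S if S > 0.0 else 0.0
    r = (S / T) ** n
    return r / (1.0 + r)


def _hill_neg_unchecked(S, T, n):
    S = S if S > 0.0 else 0.0
    r = (S / T) ** n
    return 1.0 / (1.0 + r)
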