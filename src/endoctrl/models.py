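"""Right-hand sides of the tumor-estrogen-fat models.

The basic model couples logistic tumor growth driven by estrogen through
Michaelis-Menten kinetics with fat-driven estrogen production and tumor fat
consumption::

    dT/dt = k1*E/(a1+E) * T * (1 - m1*T)
    dE/dt = r*F - mu*E
    dF/dt = -alpha*T*F

The extended model splits the tumor into a sensitive compartment S, which
dies below estrogen threshold ``a2`` and converts to resistance below
``a3`` (steep Hill switches with coefficient ``l``), and an
estrogen-independent resistant compartment R.  Aromatase-inhibitor dosing
enters as a control ``u`` in [0, 1) scaling down estrogen production,
``dE/dt = (1-u)*r*F - mu*E``; a constant dose is the special case
``u = 1 - p``.

State vectors passed to the RHS functions are clipped at zero before the
Hill terms are evaluated: adaptive solvers probe slightly negative values,
and a negative estrogen raised to an even Hill power would be finite but
meaningless.
"""

from __future__ import annotations

import math

import numpy as np

from .params import BaseParams, ExtParams

__all__ = ["hill_inhibition", "base_rhs", "ext_rhs", "growth_rate"]


def hill_inhibition(E, a, l):
    """Decreasing Hill switch ``a^l / (a^l + E^l)`` in [0, 1].

    Equals 1 at ``E = 0``, 1/2 at ``E = a`` and tends to 0 as ``E`` grows.
    Computed through ``1 / (1 + exp(l*(log E - log a)))`` so that steep
    coefficients (``l = 10``) never overflow for large ``E/a``.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("estrogen concentration E must be non-negative")
    if a <= 0:
        raise ValueError("Hill threshold a must be positive")
    if l < 1:
        raise ValueError("Hill coefficient l must be >= 1")
    out = np.ones_like(E)
    pos = E > 0
    with np.errstate(over="ignore"):
        z = l * (np.log(E[pos]) - math.log(a))
        out[pos] = 1.0 / (1.0 + np.exp(np.clip(z, -745.0, 745.0)))
    return float(out) if out.ndim == 0 else out


def _hill(E: float, a: float, l: float) -> float:
    """Scalar fast path of :func:`hill_inhibition` (inputs already validated)."""
    if E <= 0.0:
        return 1.0
    z = l * (math.log(E) - math.log(a))
    if z > 700.0:
        return math.exp(-z)
    if z < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def growth_rate(E: float, k1: float, a1: float) -> float:
    """Estrogen-driven proliferation rate ``k1*E/(a1+E)`` (Michaelis-Menten)."""
    if E <= 0.0:
        return 0.0
    return k1 * E / (a1 + E)


def base_rhs(t: float, state, params: BaseParams):
    """Time derivative of the basic model at state ``(T, E, F)``.

    Accepts any length-3 array-like; returns ``numpy.ndarray`` of shape (3,).
    """
    T, E, F = (max(float(x), 0.0) for x in np.asarray(state, dtype=float))
    dT = growth_rate(E, params.k1, params.a1) * T * (1.0 - params.m1 * T)
    dE = params.r * F - params.mu * E
    dF = -params.alpha * T * F
    return np.array([dT, dE, dF])


def _ext_rhs_scalar(S: float, R: float, E: float, F: float,
                    u: float, p: ExtParams) -> tuple[float, float, float, float]:
    """Scalar extended-model RHS; hot path shared by the fixed-step solvers."""
    S = S if S > 0.0 else 0.0
    R = R if R > 0.0 else 0.0
    E = E if E > 0.0 else 0.0
    F = F if F > 0.0 else 0.0
    crowd = 1.0 - p.m1 * (S + p.eta * R)
    death = p.c * _hill(E, p.a2, p.l)
    adapt = p.c * _hill(E, p.a3, p.l)
    dS = growth_rate(E, p.k1, p.a1) * S * crowd - death * S - adapt * S
    dR = p.k3 * R * crowd + adapt * S
    dE = (1.0 - u) * p.r * F - p.mu * E
    dF = p.k2 * F * (1.0 - p.m2 * F) - p.alpha * (S + R) * F
    return dS, dR, dE, dF


def ext_rhs(t: float, state, params: ExtParams, u: float = 0.0):
    """Time derivative of the extended model at state ``(S, R, E, F)``.

    ``u`` is the instantaneous aromatase-inhibitor control in [0, 1); a
    constant dose ``p`` corresponds to ``u = 1 - p``.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("control u must lie in [0, 1)")
    S, R, E, F = (float(x) for x in np.asarray(state, dtype=float))
    return np.array(_ext_rhs_scalar(S, R, E, F, u, params))
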