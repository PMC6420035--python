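"""Local rules of the colonization model, as pure functions.

Every rule acts on one cell (or the shared nutrient pool) given the local
sessile-cell density ``Q`` — the number of sessile cells within the sensing
radius ``R`` — and the hydration state ``W`` of the current hour.

Probability unit conventions
----------------------------
Input rates from the parameter table are hourly probabilities, except the
preferential-attachment ceiling ``A_PA`` which is per time step.  Hourly
probabilities are mapped to the ``dt`` scheduler with the compounding
identity ``p_step = 1 - (1 - p_hourly) ** dt`` (not ``p * dt``), so that
survival over any window multiplies correctly regardless of step size.
"""

from __future__ import annotations

import math

import numpy as np

from .params import SimulationParams, StrategySpec

__all__ = [
    "wetness",
    "grow_mass",
    "hourly_death_prob",
    "per_step_prob",
    "attachment_prob_step",
    "detachment_prob_step",
    "update_nutrient",
    "equivalent_constant_stress",
]

# mod(t, 24) accumulates float error when t is a multiple of dt=0.05;
# comparisons against H use this slack so cycle boundaries stay wet.
_T_EPS = 1e-9


def wetness(t: float, H: float, stress_mode: str = "periodic") -> int:
    """Hydration state at time ``t`` (hours).

    Under the periodic diel schedule each 24 h cycle opens with ``H`` wet
    hours followed by ``24 - H`` dry hours; the hour with ``mod(t, 24) == H``
    still counts as wet.  Under constant stress the surface is permanently
    dry (``W = 0``).
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t!r}")
    if stress_mode == "constant":
        return 0
    if stress_mode != "periodic":
        raise ValueError(f"unknown stress_mode {stress_mode!r}")
    return 1 if math.fmod(t, 24.0) <= H + _T_EPS else 0


def grow_mass(m, f: float, c: float, params: SimulationParams):
    """Biomass after one time step of Monod growth.

    A fraction ``f`` of the biomass is diverted to EPS and does not
    compound (sessile cells pay ``f = f_sessile``, planktonic cells
    ``f = 0``)::

        m' = (1 - f) * m * exp(mu_max * c / (c + K_s) * dt) + f * m

    Accepts scalar or ndarray ``m``.
    """
    mu = params.mu_max * c / (c + params.K_s) if c > 0 else 0.0
    g = math.exp(mu * params.dt)
    return (1.0 - f) * m * g + f * m


def hourly_death_prob(Q: float, W: int, params: SimulationParams) -> float:
    """Hourly death probability of a cell at local sessile density ``Q``.

    Three regimes: below the protection threshold ``Q_L`` the cell is
    exposed to desiccation whenever the surface is dry; at or above the
    overcrowding threshold ``Q_H`` it suffers overcrowding stress
    regardless of hydration; in between only the background hazard
    applies.
    """
    if Q < 0:
        raise ValueError(f"density must be non-negative, got {Q!r}")
    if Q >= params.Q_H:
        return params.S_H + params.S_B
    if Q < params.Q_L:
        return (1 - W) * params.S_L + params.S_B
    return params.S_B


def per_step_prob(p_hourly: float, dt: float):
    """Convert an hourly probability to the per-step probability.

    Uses the compounding rule ``1 - (1 - p) ** dt``; monotone in ``p``
    and exact at both endpoints.  Accepts scalar or ndarray ``p_hourly``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(p_hourly, (int, float)):
        if not 0.0 <= p_hourly <= 1.0:
            raise ValueError("hourly probability must lie in [0, 1]")
        return 1.0 - (1.0 - p_hourly) ** dt
    p = np.asarray(p_hourly, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("hourly probability must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** dt


def attachment_prob_step(Q, strategy: StrategySpec, dt: float):
    """Per-step attachment probability of a planktonic cell.

    RA strategies attach at the density-independent baseline
    ``per_step_prob(A_RA, dt)``.  PA strategies follow a Hill curve of
    the local sessile density ``Q``::

        A(Q) = (A_PA - a_ra) / ((Q_PA / Q)^n + 1) + a_ra

    with ``a_ra = per_step_prob(A_RA, dt)`` (``A_PA`` is already per
    step).  ``Q = 0`` returns the baseline (the curve's lower asymptote);
    the upper asymptote is ``A_PA``.  Accepts scalar or ndarray ``Q``.
    """
    q = np.asarray(Q, dtype=float)
    if np.any(q < 0):
        raise ValueError("density must be non-negative")
    a_ra = per_step_prob(strategy.A_RA, dt)
    if strategy.kind == "RA":
        out = np.full_like(q, a_ra)
        return float(out) if np.isscalar(Q) else out
    out = np.full_like(q, a_ra)
    pos = q > 0
    if strategy.Q_PA == 0:
        out[pos] = strategy.A_PA  # threshold-free PA saturates immediately
    else:
        ratio = (strategy.Q_PA / q[pos]) ** strategy.n_hill
        out[pos] = (strategy.A_PA - a_ra) / (ratio + 1.0) + a_ra
    return float(out) if np.isscalar(Q) else out


def detachment_prob_step(params: SimulationParams) -> float:
    """Per-step detachment probability; constant for every sessile cell."""
    return per_step_prob(params.D, params.dt)


def update_nutrient(c: float, n_divisions: int, params: SimulationParams) -> float:
    """Nutrient concentration after one step.

    The single well-mixed pool relaxes toward the infinite source at rate
    ``k_perm`` and loses ``C_div`` grams per division event, spread over
    the bulk water volume; clipped at zero::

        c' = max(0, c + k_perm * (N_c - c) * dt - n_div * C_div / V_water)
    """
    if c < 0:
        raise ValueError("nutrient concentration must be non-negative")
    if n_divisions < 0:
        raise ValueError("division count must be non-negative")
    c_new = (c + params.k_perm * (params.N_c - c) * params.dt
             - n_divisions * params.C_div / params.water_volume)
    return max(0.0, c_new)


def equivalent_constant_stress(S_periodic: float, H_dry: float, T: float) -> float:
    """Constant hourly death rate matching periodic-stress survival.

    Returns the rate ``S'`` such that surviving ``T`` hours at ``S'``
    equals surviving ``H_dry`` dry hours at ``S_periodic``::

        (1 - S')**T = (1 - S_periodic)**H_dry
    """
    if not (0.0 <= S_periodic <= 1.0):
        raise ValueError("S_periodic must lie in [0, 1]")
    if not (0.0 < H_dry <= T):
        raise ValueError("need 0 < H_dry <= T")
    if S_periodic == 1.0:
        return 1.0
    return 1.0 - (1.0 - S_periodic) ** (H_dry / T)
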