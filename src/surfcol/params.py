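"""Parameter containers for the colonization model.

All rates are hourly probabilities unless stated otherwise; lengths are in
micrometres, masses in grams, concentrations in g·m⁻³, times in hours.
The one deliberate exception is ``A_PA``, the preferential-attachment
probability, which is expressed per scheduler time step (``dt``) rather
than per hour; see :mod:`surfcol.model` for how the two scales are combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

__all__ = ["StrategySpec", "SimulationParams"]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class StrategySpec:
    """Surface-attachment strategy of planktonic cells.

    kind
        ``"PA"`` — preferential attachment: the per-step attachment
        probability rises sigmoidally (step-like for large ``n_hill``)
        from the random-attachment baseline up to ``A_PA`` as the local
        sessile density crosses ``Q_PA``.
        ``"RA"`` — random attachment: a density-independent constant
        hourly probability ``A_RA``.
    A_PA
        Upper asymptote of the PA attachment probability, per time step.
    A_RA
        Baseline attachment probability, per hour. Used directly by RA
        strategies and as the lower asymptote of the PA curve.
    Q_PA
        Local sessile-cell density (count within the sensing radius) at
        which the PA curve reaches its half-way point.
    n_hill
        Hill exponent controlling the steepness of the PA curve.
    """

    kind: Literal["PA", "RA"] = "PA"
    A_PA: float = 0.5
    A_RA: float = 0.01
    Q_PA: float = 12.0
    n_hill: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("PA", "RA"):
            raise ValueError(f"strategy kind must be 'PA' or 'RA', got {self.kind!r}")
        _check_prob("A_PA", self.A_PA)
        _check_prob("A_RA", self.A_RA)
        if self.Q_PA < 0:
            raise ValueError(f"Q_PA must be >= 0, got {self.Q_PA!r}")
        if self.n_hill < 1:
            raise ValueError(f"n_hill must be >= 1, got {self.n_hill!r}")

    @staticmethod
    def random_attachment(A_RA: float = 0.01) -> "StrategySpec":
        return StrategySpec(kind="RA", A_RA=A_RA)

    @staticmethod
    def preferential(Q_PA: float = 12.0, *, A_PA: float = 0.5,
                     A_RA: float = 0.01, n_hill: float = 10.0) -> "StrategySpec":
        return StrategySpec(kind="PA", A_PA=A_PA, A_RA=A_RA,
                            Q_PA=Q_PA, n_hill=n_hill)


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set of one simulation.

    Defaults are the model's standard environmental bacterium on a
    1 mm × 1 mm surface under a 12 h wet / 12 h dry diel cycle.
    """

    # -- individual cells ------------------------------------------------
    mu_max: float = 0.4          # maximum hourly growth rate (h^-1)
    K_s: float = 0.3             # Monod nutrient affinity constant (g m^-3)
    f_sessile: float = 0.5       # biomass fraction diverted to EPS by sessile cells
    M_div: float = 2e-12         # mean division mass (g)
    C_div: float = 3e-13         # nutrient consumed per division (g)
    R: float = 10.0              # sensing / protection neighborhood radius (um)
    V: float = 50.0              # maximal planktonic swimming speed (um s^-1)
    # -- domain ----------------------------------------------------------
    k_perm: float = 0.1          # nutrient permeation rate from the source (h^-1)
    domain_side: float = 1000.0  # side of the square domain (um)
    water_volume: float = 1e-10  # bulk fluid volume (m^3)
    dt: float = 0.05             # scheduler time step (h)
    # -- stress ----------------------------------------------------------
    S_L: float = 0.4             # hourly death probability, desiccation (unprotected, dry)
    S_H: float = 0.3             # hourly death probability, overcrowding
    S_B: float = 0.025           # hourly death probability, background
    Q_L: int = 40                # density threshold for desiccation protection
    Q_H: int = 75                # density threshold for overcrowding stress
    # -- transitions -----------------------------------------------------
    D: float = 0.01              # hourly detachment probability
    strategy: StrategySpec = field(default_factory=StrategySpec)
    # -- environment schedule --------------------------------------------
    N_c: float = 30.0            # source nutrient concentration (g m^-3)
    H: float = 12.0              # wet hours per 24 h diel cycle
    n_days: int = 5              # diel cycles per run
    N0: int = 100                # initial planktonic population
    stress_mode: Literal["periodic", "constant"] = "periodic"
    # -- resolved modelling choices ---------------------------------------
    cell_diameter: float = 1.0   # physical cell size for shoving (um)
    contact_dist: float = 1.2    # centre distance defining aggregate adjacency (um)
    div_mass_cv: float = 0.1     # relative jitter of per-cell division thresholds
    grow_during_dry: bool = True
    motion_mode: Literal["well_mixed", "bounded_walk"] = "well_mixed"

    def __post_init__(self) -> None:
        for name in ("S_L", "S_H", "S_B", "D"):
            _check_prob(name, getattr(self, name))
        if self.S_L + self.S_B > 1.0 + 1e-12:
            raise ValueError("S_L + S_B must not exceed 1")
        if self.S_H + self.S_B > 1.0 + 1e-12:
            raise ValueError("S_H + S_B must not exceed 1")
        if not self.Q_L < self.Q_H:
            raise ValueError(f"Q_L ({self.Q_L}) must be < Q_H ({self.Q_H})")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.H <= 24.0):
            raise ValueError("H must lie in [0, 24]")
        if self.N0 < 1:
            raise ValueError("N0 must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("mu_max", "K_s", "M_div", "C_div", "R", "domain_side",
                     "water_volume", "cell_diameter", "contact_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("V", "k_perm", "N_c", "div_mass_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.contact_dist < self.cell_diameter:
            raise ValueError("contact_dist must be >= cell_diameter")
        if self.stress_mode not in ("periodic", "constant"):
            raise ValueError(f"unknown stress_mode {self.stress_mode!r}")
        if self.motion_mode not in ("well_mixed", "bounded_walk"):
            raise ValueError(f"unknown motion_mode {self.motion_mode!r}")
        if not isinstance(self.strategy, StrategySpec):
            raise TypeError("strategy must be a StrategySpec")

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        """Scheduler steps in a full run (``n_days`` diel cycles)."""
        return int(round(self.n_days * 24.0 / self.dt))

    @property
    def t_end(self) -> float:
        return self.n_days * 24.0

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        import dataclasses
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategy"] = asdict(self.strategy)
        return d

    @staticmethod
    def from_dict(data: dict) -> "SimulationParams":
        data = dict(data)
        strat = data.pop("strategy", None)
        known = {f.name for f in SimulationParams.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        if strat is not None:
            if isinstance(strat, dict):
                s_known = set(StrategySpec.__dataclass_fields__)
                s_unknown = set(strat) - s_known
                if s_unknown:
                    raise ValueError(
                        f"unknown strategy key(s): {sorted(s_unknown)}")
                strat = StrategySpec(**strat)
            data["strategy"] = strat
        return SimulationParams(**data)
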