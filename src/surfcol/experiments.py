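"""Replicated runs and parameter scans.

Reproduces the study designs built on the simulator: attachment-strategy
scans (over the preferential-attachment threshold Q_PA, the random rate
A_RA or the Hill exponent), best-strategy selection, nutrient × stress
phase planes with zone classification, wet-dry split scans and
protection-threshold scans.

All experiments are pure functions of ``(params, grids, base_seed)``:
replicate r of every grid point runs with seed ``base_seed + r`` (common
random numbers across settings, which tightens paired comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import population_yield
from .params import SimulationParams, StrategySpec
from .simulate import RunResult, run

__all__ = [
    "DEFAULT_A_RA_GRID", "DEFAULT_Q_PA_GRID",
    "ScanResult", "PhasePlaneResult", "Advantage",
    "replicate_yields", "replicate_runs", "scan_strategy",
    "relative_advantage", "phase_plane", "wetdry_scan", "ql_scan",
]

DEFAULT_A_RA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 0.9)
DEFAULT_Q_PA_GRID = tuple(range(2, 41, 2))

# a zone counts as "PA-only" when every random-attachment setting goes
# extinct in at least this fraction of replicates while PA persists
EXTINCTION_FRACTION_THRESHOLD = 0.8


def _with_strategy(params: SimulationParams, name: str, value: float) -> SimulationParams:
    s = params.strategy
    if name == "A_RA":
        return params.replace(strategy=StrategySpec.random_attachment(A_RA=value))
    if name == "Q_PA":
        return params.replace(strategy=StrategySpec(
            kind="PA", A_PA=s.A_PA, A_RA=s.A_RA, Q_PA=value, n_hill=s.n_hill))
    if name == "n_hill":
        return params.replace(strategy=StrategySpec(
            kind="PA", A_PA=s.A_PA, A_RA=s.A_RA, Q_PA=s.Q_PA, n_hill=value))
    raise ValueError(f"cannot scan parameter {name!r}")


def replicate_runs(params: SimulationParams, n_reps: int,
                   base_seed: int) -> list[RunResult]:
    """Run ``n_reps`` replicates with seeds base_seed .. base_seed+n-1."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [run(params, base_seed + r) for r in range(n_reps)]


def replicate_yields(params: SimulationParams, n_reps: int, base_seed: int):
    """Yields of ``n_reps`` replicates plus their mean and standard error.

    SE is the sample standard deviation over sqrt(n); with a single
    replicate it is reported as 0 (no dispersion estimate).
    """
    yields = np.array([population_yield(r)
                       for r in replicate_runs(params, n_reps, base_seed)],
                      dtype=float)
    mean = float(yields.mean())
    se = float(yields.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return yields, mean, se


@dataclass
class ScanResult:
    """Yields over a one-parameter strategy grid."""

    param_name: str
    grid: np.ndarray
    yields: np.ndarray          # (n_grid, n_reps)
    mean: np.ndarray
    se: np.ndarray
    best_index: int
    extinction_fraction: np.ndarray

    @property
    def best_setting(self) -> float:
        return float(self.grid[self.best_index])

    @property
    def best_mean_yield(self) -> float:
        return float(self.mean[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.param_name: self.grid,
            "mean_yield": self.mean,
            "se_yield": self.se,
            "extinction_fraction": self.extinction_fraction,
            "is_best": np.arange(len(self.grid)) == self.best_index,
        })


def scan_strategy(params: SimulationParams, param_name: str, grid,
                  n_reps: int = 10, base_seed: int = 0) -> ScanResult:
    """One replicate set per grid point of ``Q_PA``, ``A_RA`` or ``n_hill``.

    The best setting maximizes mean yield; ties break toward the smaller
    parameter value (argmax of the first maximum).
    """
    grid = np.asarray(list(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    all_yields, ext = [], []
    for value in grid:
        p = _with_strategy(params, param_name, value)
        results = replicate_runs(p, n_reps, base_seed)
        ys = np.array([population_yield(r) for r in results], dtype=float)
        all_yields.append(ys)
        ext.append(np.mean([r.extinct for r in results]))
    yields = np.vstack(all_yields)
    mean = yields.mean(axis=1)
    se = (yields.std(axis=1, ddof=1) / np.sqrt(n_reps)) if n_reps > 1 \
        else np.zeros(len(grid))
    return ScanResult(
        param_name=param_name, grid=grid, yields=yields, mean=mean, se=se,
        best_index=int(np.argmax(mean)),
        extinction_fraction=np.asarray(ext),
    )


@dataclass(frozen=True)
class Advantage:
    """Best-PA vs best-RA comparison at one environmental setting."""

    ratio: float | None          # best_pa / best_ra, when defined
    flag: str | None             # "PA-only" | "extinct" | None


def relative_advantage(best_pa: float, best_ra: float,
                       ra_min_extinction_fraction: float = 0.0,
                       pa_extinction_fraction: float = 0.0,
                       threshold: float = EXTINCTION_FRACTION_THRESHOLD) -> Advantage:
    """Fitness ratio of the optimal PA over the optimal RA strategy.

    When every RA setting goes extinct in at least ``threshold`` of its
    replicates while PA persists, the point is a niche extension
    ("PA-only"); when both strategies die out it is "extinct".
    """
    pa_alive = best_pa > 0 and pa_extinction_fraction < threshold
    if ra_min_extinction_fraction >= threshold and pa_alive:
        return Advantage(ratio=None, flag="PA-only")
    if best_pa == 0 and best_ra == 0:
        return Advantage(ratio=None, flag="extinct")
    if best_ra == 0:
        return Advantage(ratio=None, flag="PA-only")
    return Advantage(ratio=best_pa / best_ra, flag=None)


# zone labels, following the phase-plane reading: a = PA-only niche
# extension, b = PA-favored, c = near-equal yields
ZONES = ("extinct", "PA-only", "PA-favored", "RA-favored", "equal")
EQUAL_BAND = 0.1   # |ratio - 1| below this counts as "equal"


def _classify(adv: Advantage) -> str:
    if adv.flag == "extinct":
        return "extinct"
    if adv.flag == "PA-only":
        return "PA-only"
    if abs(adv.ratio - 1.0) <= EQUAL_BAND:
        return "equal"
    return "PA-favored" if adv.ratio > 1.0 else "RA-favored"


@dataclass
class PhasePlaneResult:
    """Best-strategy comparison over a nutrient × stress grid."""

    N_c_grid: np.ndarray
    S_L_grid: np.ndarray
    stress_mode: str
    table: pd.DataFrame          # one row per (N_c, S_L) cell

    def zone(self, N_c: float, S_L: float) -> str:
        row = self.table[(self.table["N_c"] == N_c) & (self.table["S_L"] == S_L)]
        return row["zone"].iloc[0]

    def to_long(self) -> pd.DataFrame:
        """Long-format (N_c, S_L, metric, value) view for plotting tools."""
        return self.table.melt(id_vars=["N_c", "S_L"], var_name="metric",
                               value_name="value")


def phase_plane(params: SimulationParams, N_c_grid, S_L_grid,
                stress_mode: str = "periodic", n_reps: int = 10,
                ra_grid=DEFAULT_A_RA_GRID, qpa_grid=DEFAULT_Q_PA_GRID,
                base_seed: int = 0) -> PhasePlaneResult:
    """Scan best-RA and best-PA yields over (N_c, S_L) and classify zones.

    For constant-stress planes pass the already-transformed S_L values
    (see :func:`surfcol.model.equivalent_constant_stress`) when the aim
    is a like-for-like comparison with a periodic plane.
    """
    N_c_grid = np.asarray(list(N_c_grid), dtype=float)
    S_L_grid = np.asarray(list(S_L_grid), dtype=float)
    if len(N_c_grid) == 0 or len(S_L_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for S_L in S_L_grid:
        for N_c in N_c_grid:
            p = params.replace(N_c=N_c, S_L=S_L, stress_mode=stress_mode)
            ra = scan_strategy(p, "A_RA", ra_grid, n_reps, base_seed)
            pa = scan_strategy(p, "Q_PA", qpa_grid, n_reps, base_seed)
            adv = relative_advantage(
                pa.best_mean_yield, ra.best_mean_yield,
                ra_min_extinction_fraction=float(ra.extinction_fraction.min()),
                pa_extinction_fraction=float(
                    pa.extinction_fraction[pa.best_index]),
            )
            rows.append({
                "N_c": N_c, "S_L": S_L,
                "best_A_RA": ra.best_setting,
                "best_ra_yield": ra.best_mean_yield,
                "ra_min_extinction_fraction": float(ra.extinction_fraction.min()),
                "best_Q_PA": pa.best_setting,
                "best_pa_yield": pa.best_mean_yield,
                "pa_extinction_fraction": float(
                    pa.extinction_fraction[pa.best_index]),
                "ratio": adv.ratio if adv.ratio is not None else np.nan,
                "zone": _classify(adv),
            })
    return PhasePlaneResult(N_c_grid, S_L_grid, stress_mode, pd.DataFrame(rows))


def wetdry_scan(params: SimulationParams, H_values, qpa_grid=DEFAULT_Q_PA_GRID,
                n_reps: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Strategy scan per wet-period length ``H``.

    Returns one row per (H, Q_PA) with the yield relative to the per-H
    optimum (1.0 at the best threshold).
    """
    rows = []
    for H in H_values:
        if not (0.0 < H < 24.0):
            raise ValueError("H values must lie strictly inside (0, 24)")
        scan = scan_strategy(params.replace(H=float(H)), "Q_PA", qpa_grid,
                             n_reps, base_seed)
        best = scan.best_mean_yield
        for i, q in enumerate(scan.grid):
            rows.append({
                "H": float(H), "Q_PA": float(q),
                "mean_yield": scan.mean[i], "se_yield": scan.se[i],
                "relative_yield": scan.mean[i] / best if best > 0 else np.nan,
                "is_best": i == scan.best_index,
            })
    return pd.DataFrame(rows)


def _quadratic_argmax(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the argmax and its two neighbors."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:   # degenerate (flat or convex): fall back to the grid point
        return float(x1)
    vertex = -b / (2 * a)
    return float(np.clip(vertex, x[0], x[-1]))


def ql_scan(params: SimulationParams, Q_L_values, qpa_grid=DEFAULT_Q_PA_GRID,
            n_reps: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Optimal attachment threshold per protection threshold ``Q_L``.

    Returns one row per Q_L with the grid argmax and a quadratic
    interpolation of the optimum around it.
    """
    rows = []
    for Q_L in Q_L_values:
        if not Q_L < params.Q_H:
            raise ValueError("Q_L values must stay below Q_H")
        scan = scan_strategy(params.replace(Q_L=int(Q_L)), "Q_PA", qpa_grid,
                             n_reps, base_seed)
        rows.append({
            "Q_L": float(Q_L),
            "best_Q_PA": scan.best_setting,
            "interpolated_Q_PA": _quadratic_argmax(scan.grid, scan.mean,
                                                   scan.best_index),
            "best_mean_yield": scan.best_mean_yield,
        })
    return pd.DataFrame(rows)
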