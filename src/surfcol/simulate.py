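"""The simulation scheduler.

Advances a population of planktonic and sessile cells in fixed ``dt``
steps over ``n_days`` diel wet-dry cycles.  Each step applies, in this
fixed order:

1. hydration state ``W`` from the diel schedule,
2. planktonic motion,
3. local sessile-density evaluation against the sessile surface as it
   stood when the step began,
4. lifestyle transitions (attachment with the strategy's density
   response, then shoving; detachment at the constant rate),
5. growth and division,
6. stress-dependent death (sessile cells use the step's local density;
   planktonic cells are always unprotected, Q = 0),
7. well-mixed nutrient balance.

The population lives in structure-of-arrays form for speed; snapshots
and event logs are exported as :class:`pandas.DataFrame` tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import model, spatial

log = logging.getLogger(__name__)
from .params import SimulationParams

__all__ = ["Cell", "Event", "SimulationState", "RunResult",
           "initial_state", "step", "run"]

_KINDS = np.array(["attach", "detach", "divide", "death"])
_CAUSES = np.array(["desiccation", "overcrowding", "background"])

SNAPSHOT_COLUMNS = ["cell_id", "lineage_id", "state", "x", "y", "mass"]
TIMESERIES_COLUMNS = ["t", "N_planktonic", "N_sessile", "c"]
EVENT_COLUMNS = ["kind", "t", "cell_id", "Q_at_event", "cause"]


@dataclass(frozen=True)
class Cell:
    """One bacterium (snapshot view)."""

    id: int
    lineage_id: int
    state: Literal["planktonic", "sessile"]
    x: float
    y: float
    mass: float
    div_threshold: float


@dataclass(frozen=True)
class Event:
    """One attach / detach / divide / death record."""

    kind: str
    t: float
    cell_id: int
    Q_at_event: int | None = None   # attach events: sessile neighbors at the site
    cause: str | None = None        # death events: dominant hazard branch


@dataclass
class SimulationState:
    """Live population plus the shared environment at one instant."""

    step_index: int
    c: float
    ids: np.ndarray        # int64 (n,)
    lineage: np.ndarray    # int64 (n,)
    sessile: np.ndarray    # bool  (n,)
    pos: np.ndarray        # float (n, 2), um
    mass: np.ndarray       # float (n,), g
    divthr: np.ndarray     # float (n,), g
    next_id: int
    dt: float

    @property
    def t(self) -> float:
        return self.step_index * self.dt

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def n_sessile(self) -> int:
        return int(self.sessile.sum())

    @property
    def n_planktonic(self) -> int:
        return self.n_cells - self.n_sessile

    @property
    def cells(self) -> list[Cell]:
        states = np.where(self.sessile, "sessile", "planktonic")
        return [Cell(int(i), int(l), str(s), float(x), float(y), float(m), float(d))
                for i, l, s, (x, y), m, d in
                zip(self.ids, self.lineage, states, self.pos, self.mass, self.divthr)]

    def snapshot(self) -> pd.DataFrame:
        """Tabular snapshot (one row per live cell)."""
        return pd.DataFrame({
            "cell_id": self.ids,
            "lineage_id": self.lineage,
            "state": np.where(self.sessile, "sessile", "planktonic"),
            "x": self.pos[:, 0],
            "y": self.pos[:, 1],
            "mass": self.mass,
        }, columns=SNAPSHOT_COLUMNS)


@dataclass
class RunResult:
    """Everything one run produces; the unit all metrics consume."""

    params: SimulationParams
    seed: int
    timeseries: pd.DataFrame          # per-step t, N_planktonic, N_sessile, c
    events: pd.DataFrame              # kind, t, cell_id, Q_at_event, cause
    final_snapshot: pd.DataFrame      # SNAPSHOT_COLUMNS
    extinct: bool
    extinction_time: float | None = None

    @property
    def yield_(self) -> int:
        return 0 if self.extinct else len(self.final_snapshot)


class _EventLog:
    """Columnar accumulator for per-step event batches."""

    def __init__(self) -> None:
        self.kind: list[np.ndarray] = []
        self.t: list[np.ndarray] = []
        self.cell_id: list[np.ndarray] = []
        self.q: list[np.ndarray] = []
        self.cause: list[np.ndarray] = []

    def add(self, kind_code: int, t: float, cell_ids: np.ndarray,
            q: np.ndarray | None = None, cause: np.ndarray | None = None) -> None:
        n = len(cell_ids)
        if n == 0:
            return
        self.kind.append(np.full(n, kind_code, dtype=np.int8))
        self.t.append(np.full(n, t))
        self.cell_id.append(np.asarray(cell_ids, dtype=np.int64))
        self.q.append(np.full(n, -1, dtype=np.int64) if q is None
                      else np.asarray(q, dtype=np.int64))
        self.cause.append(np.full(n, -1, dtype=np.int8) if cause is None
                          else np.asarray(cause, dtype=np.int8))

    def to_frame(self) -> pd.DataFrame:
        if not self.kind:
            return pd.DataFrame(columns=EVENT_COLUMNS)
        kind = np.concatenate(self.kind)
        cause = np.concatenate(self.cause)
        q = np.concatenate(self.q)
        return pd.DataFrame({
            "kind": _KINDS[kind],
            "t": np.concatenate(self.t),
            "cell_id": np.concatenate(self.cell_id),
            "Q_at_event": np.where(q >= 0, q, pd.NA),
            "cause": np.where(cause >= 0, _CAUSES[np.clip(cause, 0, 2)], pd.NA),
        }, columns=EVENT_COLUMNS)


def _draw_div_thresholds(n: int, params: SimulationParams,
                         rng: np.random.Generator) -> np.ndarray:
    cv = params.div_mass_cv
    if cv == 0:
        return np.full(n, params.M_div)
    return params.M_div * (1.0 + rng.uniform(-cv, cv, size=n))


def initial_state(params: SimulationParams, rng: np.random.Generator) -> SimulationState:
    """Fresh colonization scenario: N0 planktonic foragers over an empty
    surface, nutrient in equilibrium with the source."""
    n = params.N0
    ids = np.arange(n, dtype=np.int64)
    return SimulationState(
        step_index=0,
        c=params.N_c,
        ids=ids,
        lineage=ids.copy(),                 # every founder heads its own lineage
        sessile=np.zeros(n, dtype=bool),
        pos=rng.uniform(0.0, params.domain_side, size=(n, 2)),
        mass=rng.uniform(params.M_div / 2.0, params.M_div, size=n),
        divthr=_draw_div_thresholds(n, params, rng),
        next_id=n,
        dt=params.dt,
    )


def _sessile_death_profile(Q: np.ndarray, W: int, params: SimulationParams):
    """Vectorized hourly death probability and hazard label for sessile cells."""
    p = np.where(Q >= params.Q_H, params.S_H + params.S_B,
                 np.where(Q < params.Q_L,
                          (1 - W) * params.S_L + params.S_B, params.S_B))
    cause = np.where(Q >= params.Q_H, 1,
                     np.where((Q < params.Q_L) & (W == 0), 0, 2))
    return p, cause


def step(state: SimulationState, params: SimulationParams,
         rng: np.random.Generator, events: _EventLog | None = None):
    """Advance the state by one time step in place.

    Returns ``(state, events)`` where ``events`` is the event log the
    step appended to (a fresh one if none was passed).
    """
    from ._grid import count_neighbors

    if events is None:
        events = _EventLog()
    t = state.t
    L = params.domain_side
    W = model.wetness(t, params.H, params.stress_mode)

    n = state.n_cells
    if n == 0:
        state.step_index += 1
        state.c = model.update_nutrient(state.c, 0, params)
        return state, events

    sess = state.sessile
    plank_idx = np.flatnonzero(~sess)
    sess_idx = np.flatnonzero(sess)
    # density reference for this step: the sessile surface as it stood
    # when the step began
    sess_pos0 = np.mod(state.pos[sess_idx], L) if len(sess_idx) else \
        np.zeros((0, 2))

    # (2) planktonic motion ------------------------------------------------
    if len(plank_idx):
        state.pos[plank_idx] = spatial.move_planktonic(
            state.pos[plank_idx], params, rng)

    # (3)+(4a) attachment: density response of the strategy ----------------
    strat = params.strategy
    a_ra_step = model.per_step_prob(strat.A_RA, params.dt)
    new_attach = np.zeros(0, dtype=np.int64)
    attach_q = np.zeros(0, dtype=np.int64)
    if len(plank_idx):
        u = rng.random(len(plank_idx))
        if strat.kind == "RA":
            cap = a_ra_step
        else:
            cap = max(strat.A_PA, a_ra_step)
        cand = np.flatnonzero(u < cap)   # cells that could possibly attach
        if len(cand):
            # local density of *existing* sessile cells at candidate sites
            q_cand = count_neighbors(sess_pos0,
                                     np.mod(state.pos[plank_idx[cand]], L),
                                     params.R, L)
            p_att = model.attachment_prob_step(q_cand, strat, params.dt)
            hit = u[cand] < p_att
            new_attach = plank_idx[cand[hit]]
            attach_q = q_cand[hit]

    # (4b) detachment of cells sessile at step start -----------------------
    new_detach = np.zeros(0, dtype=np.int64)
    if len(sess_idx):
        d_step = model.detachment_prob_step(params)
        v = rng.random(len(sess_idx))
        new_detach = sess_idx[v < d_step]

    state.sessile[new_attach] = True
    state.sessile[new_detach] = False
    events.add(0, t, state.ids[new_attach], q=attach_q)
    events.add(1, t, state.ids[new_detach])

    # (5) growth and division ----------------------------------------------
    f = np.where(state.sessile, params.f_sessile, 0.0)
    if params.grow_during_dry or W == 1:
        state.mass = model.grow_mass(state.mass, f, state.c, params)
    div_idx = np.flatnonzero(state.mass >= state.divthr)
    n_div = len(div_idx)
    if n_div:
        thr = _draw_div_thresholds(2 * n_div, params, rng)
        ang = rng.uniform(0.0, 2.0 * np.pi, size=n_div)
        half_mass = state.mass[div_idx] / 2.0
        state.mass[div_idx] = half_mass
        state.divthr[div_idx] = thr[:n_div]
        d_sessile = state.sessile[div_idx]
        offset = np.where(d_sessile[:, None],
                          params.cell_diameter *
                          np.column_stack([np.cos(ang), np.sin(ang)]),
                          0.0)
        d_pos = spatial.wrap(state.pos[div_idx] + offset, L)
        d_ids = state.next_id + np.arange(n_div, dtype=np.int64)
        state.next_id += n_div
        state.ids = np.concatenate([state.ids, d_ids])
        state.lineage = np.concatenate([state.lineage, state.lineage[div_idx]])
        state.sessile = np.concatenate([state.sessile, d_sessile])
        state.pos = np.concatenate([state.pos, d_pos])
        state.mass = np.concatenate([state.mass, half_mass])
        state.divthr = np.concatenate([state.divthr, thr[n_div:]])
        events.add(2, t, state.ids[div_idx])

    # shoving: restore the single-layer packing, cascading outward from
    # the cells placed this step
    n_before = state.n_cells - n_div
    newly = np.zeros(state.n_cells, dtype=bool)
    newly[new_attach] = True
    if n_div:
        newly[n_before:] = state.sessile[n_before:]
    if newly.any():
        s_now = np.flatnonzero(state.sessile)
        if len(s_now) > 1:
            from ._grid import relax_overlaps
            relaxed, converged = relax_overlaps(
                np.mod(state.pos[s_now], L), params.cell_diameter, L,
                spatial.SHOVE_TOL, seeds=np.flatnonzero(newly[s_now]))
            if not converged:
                log.warning("shoving budget exhausted at t=%.2f", t)
            state.pos[s_now] = relaxed

    # (6) death -------------------------------------------------------------
    # one uniform per cell; the local density only matters for cells
    # whose draw falls below the largest branch probability, so it is
    # evaluated just for those (identical outcome, far fewer queries)
    n_now = state.n_cells
    w_draw = rng.random(n_now)
    p_plank_step = model.per_step_prob((1 - W) * params.S_L + params.S_B,
                                       params.dt)
    p_sess_max = max(params.S_H + params.S_B,
                     (1 - W) * params.S_L + params.S_B)
    p_sess_max_step = model.per_step_prob(p_sess_max, params.dt)
    dies = np.zeros(n_now, dtype=bool)
    cause = np.zeros(n_now, dtype=np.int8)
    plank_now = ~state.sessile
    # planktonic cells are solitary foragers in the bulk fluid: Q = 0
    dies[plank_now] = w_draw[plank_now] < p_plank_step
    cause[plank_now] = 0 if W == 0 else 2
    s_cand = np.flatnonzero(state.sessile & (w_draw < p_sess_max_step))
    if len(s_cand):
        Q = count_neighbors(sess_pos0, np.mod(state.pos[s_cand], L),
                            params.R, L)
        p_hourly, s_cause = _sessile_death_profile(Q, W, params)
        dies[s_cand] = w_draw[s_cand] < model.per_step_prob(p_hourly, params.dt)
        cause[s_cand] = s_cause
    dead_idx = np.flatnonzero(dies)
    if len(dead_idx):
        events.add(3, t, state.ids[dead_idx], cause=cause[dead_idx])
        keep = ~dies
        state.ids = state.ids[keep]
        state.lineage = state.lineage[keep]
        state.sessile = state.sessile[keep]
        state.pos = state.pos[keep]
        state.mass = state.mass[keep]
        state.divthr = state.divthr[keep]

    # (7) nutrient balance ---------------------------------------------------
    state.c = model.update_nutrient(state.c, n_div, params)
    state.step_index += 1
    return state, events


def run(params: SimulationParams, seed: int) -> RunResult:
    """Execute one full simulation (``n_days`` diel cycles).

    Deterministic: identical ``(params, seed)`` reproduce the run
    bit-for-bit.  Stops early (with yield zero) if the population goes
    extinct.
    """
    rng = np.random.default_rng(seed)
    state = initial_state(params, rng)
    events = _EventLog()
    ts_rows = [(state.t, state.n_planktonic, state.n_sessile, state.c)]
    extinct = False
    extinction_time = None
    for _ in range(params.n_steps):
        step(state, params, rng, events)
        ts_rows.append((state.t, state.n_planktonic, state.n_sessile, state.c))
        if state.n_cells == 0:
            extinct = True
            extinction_time = state.t
            break
    timeseries = pd.DataFrame(ts_rows, columns=TIMESERIES_COLUMNS)
    return RunResult(
        params=params,
        seed=seed,
        timeseries=timeseries,
        events=events.to_frame(),
        final_snapshot=state.snapshot(),
        extinct=extinct,
        extinction_time=extinction_time,
    )
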