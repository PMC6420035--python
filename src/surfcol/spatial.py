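"""2D geometry on the periodic square surface.

Fixed-radius neighbor counts, planktonic motion, single-layer shoving
(overlap relaxation) and aggregate detection.  The domain is a square of
side ``domain_side`` with periodic boundary conditions; all distance
queries go through :class:`scipy.spatial.cKDTree` with ``boxsize`` set,
which implements the minimum-image metric exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AggregateRecord",
    "local_sessile_density",
    "move_planktonic",
    "resolve_overlaps",
    "aggregate_labels",
    "detect_aggregates",
]

log = logging.getLogger(__name__)

# residual overlap tolerated by the shoving relaxation, as a fraction of
# the cell diameter
SHOVE_TOL = 0.01


@dataclass
class AggregateRecord:
    """One contact-connected cluster of sessile cells."""

    aggregate_id: int
    member_ids: frozenset
    size: int
    lineage_counts: dict
    centroid: tuple

    def n_lineages(self) -> int:
        return len(self.lineage_counts)


def _tree(points: np.ndarray, domain_side: float | None) -> cKDTree:
    if domain_side is not None:
        return cKDTree(np.mod(points, domain_side), boxsize=domain_side)
    return cKDTree(points)


def wrap(points: np.ndarray, domain_side: float) -> np.ndarray:
    """Map coordinates into [0, domain_side) by periodic wrapping."""
    out = np.mod(points, domain_side)
    # float rounding can produce exactly domain_side for tiny negatives
    out[out >= domain_side] = 0.0
    return out


def local_sessile_density(points, sessile_positions, R: float,
                          domain_side: float | None = None) -> np.ndarray:
    """Number of sessile cells within distance ``R`` of each query point.

    Distances are minimum-image when ``domain_side`` is given, plain
    Euclidean otherwise.  A sessile cell counts itself when queried at
    its own center (distance zero).  Returns an int array shaped like
    the query batch (scalar int for a single point).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    sess = np.asarray(sessile_positions, dtype=float).reshape(-1, 2)
    if len(sess) == 0:
        out = np.zeros(len(pts), dtype=np.int64)
        return int(out[0]) if single else out
    tree = _tree(sess, domain_side)
    q = np.mod(pts, domain_side) if domain_side is not None else pts
    counts = tree.query_ball_point(q, r=R, return_length=True)
    counts = np.asarray(counts, dtype=np.int64)
    return int(counts[0]) if single else counts


def move_planktonic(positions: np.ndarray, params, rng: np.random.Generator) -> np.ndarray:
    """New positions of planktonic cells after one time step.

    ``well_mixed``: positions are redrawn uniformly over the domain — at
    the default swimming speed a cell covers V*dt = 9000 um per step,
    several times the domain side, so the fluid is effectively mixed
    between steps.  ``bounded_walk``: each cell takes one step of length
    uniform in [0, V*dt] in a uniform random direction, wrapped at the
    boundaries.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n == 0:
        return pos.copy()
    L = params.domain_side
    if params.motion_mode == "well_mixed":
        return rng.uniform(0.0, L, size=(n, 2))
    max_step = params.V * 3600.0 * params.dt  # um s^-1 -> um per step
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    length = rng.uniform(0.0, max_step, size=n)
    step = np.column_stack([length * np.cos(theta), length * np.sin(theta)])
    return wrap(pos + step, L)


def resolve_overlaps(positions: np.ndarray, cell_diameter: float,
                     domain_side: float, max_iter: int = 200) -> np.ndarray:
    """Shove overlapping sessile cells apart (single-layer mechanics).

    Iterative pairwise relaxation: every pair closer than the cell
    diameter ``d`` (beyond the tolerance) is pushed apart symmetrically
    along its center line; displacements are accumulated Jacobi-style
    and applied at once, then wrapped.  Stops when no pair is closer
    than ``d * (1 - SHOVE_TOL)`` or after ``max_iter`` sweeps (logged,
    not fatal).  Coincident cells are separated along a deterministic
    per-pair direction so the routine needs no randomness; cells with no
    neighbor within ``d`` never move.
    """
    from ._grid import relax_overlaps

    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        return pos.copy()
    pos = wrap(pos.copy(), domain_side)
    out, converged = relax_overlaps(pos, cell_diameter, domain_side,
                                    SHOVE_TOL, max_iter)
    if not converged:
        log.warning("shoving hit max_iter=%d with residual overlaps", max_iter)
    return out


def aggregate_labels(positions: np.ndarray, contact_dist: float,
                     domain_side: float | None = None) -> np.ndarray:
    """Connected-component label per cell under the contact relation.

    Two sessile cells are in contact when their center distance is at
    most ``contact_dist``; aggregates are the connected components of
    that graph.  Returns an int label array (labels are arbitrary but
    stable for a given input).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(pos)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    tree = _tree(pos, domain_side)
    pairs = tree.query_pairs(r=contact_dist, output_type="ndarray")
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    if len(pairs) == 0:
        return np.arange(n, dtype=np.int64)
    data = np.ones(len(pairs), dtype=np.int8)
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels.astype(np.int64)


def _periodic_centroid(pos: np.ndarray, domain_side: float | None) -> tuple:
    if domain_side is None:
        return tuple(pos.mean(axis=0))
    # circular mean per axis: correct for clusters spanning the wrap seam
    ang = pos / domain_side * 2.0 * np.pi
    mean_ang = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return tuple(np.mod(mean_ang / (2.0 * np.pi) * domain_side, domain_side))


def detect_aggregates(ids, lineage_ids, positions, contact_dist: float,
                      domain_side: float | None = None) -> list[AggregateRecord]:
    """Partition sessile cells into contact-connected aggregates.

    Every sessile cell lands in exactly one record; each record carries
    the member ids, per-lineage counts and the (periodic) centroid.
    """
    ids = np.asarray(ids)
    lineage_ids = np.asarray(lineage_ids)
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if not (len(ids) == len(lineage_ids) == len(pos)):
        raise ValueError("ids, lineage_ids and positions must align")
    if len(ids) == 0:
        return []
    labels = aggregate_labels(pos, contact_dist, domain_side)
    records = []
    for agg_id, lab in enumerate(np.unique(labels)):
        mask = labels == lab
        lin, cnt = np.unique(lineage_ids[mask], return_counts=True)
        records.append(AggregateRecord(
            aggregate_id=agg_id,
            member_ids=frozenset(ids[mask].tolist()),
            size=int(mask.sum()),
            lineage_counts={int(k): int(v) for k, v in zip(lin, cnt)},
            centroid=_periodic_centroid(pos[mask], domain_side),
        ))
    return records
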