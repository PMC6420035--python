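"""Summary statistics over completed runs.

Population yield (the fitness measure), attachment-density histograms,
aggregate-size and lineage structure, within-aggregate relatedness and
planktonic/sessile composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SimulationParams
from .simulate import RunResult
from .spatial import AggregateRecord, detect_aggregates

__all__ = [
    "population_yield",
    "snapshot_aggregates",
    "attachment_density_histogram",
    "vacant_attachment_fraction",
    "aggregate_size_histogram",
    "lineage_stats",
    "mean_relatedness",
    "timeseries_summary",
    "AggregateSizeHistogram",
]


def population_yield(result: RunResult) -> int:
    """Total live cells at the end of the run; zero for extinct runs."""
    return 0 if result.extinct else len(result.final_snapshot)


def snapshot_aggregates(snapshot: pd.DataFrame, params: SimulationParams) -> list[AggregateRecord]:
    """Contact-connected aggregates of the sessile cells in a snapshot."""
    s = snapshot[snapshot["state"] == "sessile"]
    return detect_aggregates(
        s["cell_id"].to_numpy(), s["lineage_id"].to_numpy(),
        s[["x", "y"]].to_numpy(float), params.contact_dist, params.domain_side)


def attachment_density_histogram(events: pd.DataFrame,
                                 bins=None) -> pd.DataFrame:
    """Relative frequency of attachment events by local density at the site.

    ``events`` may come from one run or be pooled over replicates.  The
    default binning keeps each integer density its own bin up to the
    observed maximum.  Returns a table with ``Q_bin_left``,
    ``Q_bin_right`` (inclusive), ``count`` and ``frequency`` columns;
    frequencies sum to one.  With no attachment events an empty table is
    returned.
    """
    att = events[events["kind"] == "attach"]
    if len(att) == 0:
        return pd.DataFrame(columns=["Q_bin_left", "Q_bin_right",
                                     "count", "frequency"])
    q = att["Q_at_event"].to_numpy(dtype=float).astype(np.int64)
    if bins is None:
        edges = np.arange(q.max() + 2)          # one bin per integer density
    else:
        edges = np.asarray(bins)
    counts, _ = np.histogram(q, bins=edges)
    return pd.DataFrame({
        "Q_bin_left": edges[:-1],
        "Q_bin_right": edges[1:] - 1,
        "count": counts,
        "frequency": counts / counts.sum(),
    })


def vacant_attachment_fraction(events: pd.DataFrame) -> float:
    """Fraction of attachment events landing at vacant sites (Q = 0).

    NaN when the run produced no attachments.
    """
    att = events[events["kind"] == "attach"]
    if len(att) == 0:
        return float("nan")
    q = att["Q_at_event"].to_numpy(dtype=float)
    return float(np.mean(q == 0))


def _pow2_edges(max_size: int) -> np.ndarray:
    """Power-of-two size-bin edges: [1,2], [3,4], [5,8], [9,16], ..."""
    edges = [1, 3]
    while edges[-1] <= max_size:
        edges.append((edges[-1] - 1) * 2 + 1)
    return np.asarray(edges)


@dataclass
class AggregateSizeHistogram:
    """Aggregate counts per size bin, with mean lineage richness per bin."""

    time: float
    bin_edges: np.ndarray            # left-closed, right-open on size+1 scale
    bin_counts: np.ndarray
    mean_lineages_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size_min": self.bin_edges[:-1],
            "size_max": self.bin_edges[1:] - 1,
            "n_aggregates": self.bin_counts,
            "mean_lineages": self.mean_lineages_per_bin,
        })


def aggregate_size_histogram(aggregates: list[AggregateRecord],
                             time: float = float("nan"),
                             bin_edges=None) -> AggregateSizeHistogram:
    """Histogram of aggregate sizes (default: power-of-two bins)."""
    sizes = np.array([a.size for a in aggregates], dtype=np.int64)
    nlin = np.array([a.n_lineages() for a in aggregates], dtype=float)
    if bin_edges is None:
        bin_edges = _pow2_edges(int(sizes.max()) if len(sizes) else 1)
    else:
        bin_edges = np.asarray(bin_edges)
    counts, _ = np.histogram(sizes, bins=bin_edges)
    mean_lin = np.full(len(counts), np.nan)
    which = np.digitize(sizes, bin_edges) - 1
    for b in range(len(counts)):
        sel = which == b
        if sel.any():
            mean_lin[b] = nlin[sel].mean()
    return AggregateSizeHistogram(time, bin_edges, counts, mean_lin)


def lineage_stats(aggregates: list[AggregateRecord]) -> float:
    """Mean number of distinct founder lineages per aggregate."""
    if not aggregates:
        raise ValueError("need at least one aggregate")
    return float(np.mean([a.n_lineages() for a in aggregates]))


def _aggregate_relatedness(agg: AggregateRecord) -> float:
    """Fraction of within-aggregate cell pairs sharing a founder lineage."""
    n = agg.size
    if n < 2:
        raise ValueError("relatedness undefined for singleton aggregates")
    same = sum(k * (k - 1) // 2 for k in agg.lineage_counts.values())
    return same / (n * (n - 1) / 2)


def mean_relatedness(aggregates: list[AggregateRecord],
                     min_size: int = 100) -> float | None:
    """Unweighted mean pairwise relatedness over large aggregates.

    Relatedness of a pair is 1 when both cells descend from the same
    founder, 0 otherwise; the per-aggregate value is averaged over all
    aggregates of at least ``min_size`` cells.  ``None`` when no
    aggregate qualifies.
    """
    vals = [_aggregate_relatedness(a) for a in aggregates if a.size >= min_size]
    if not vals:
        return None
    return float(np.mean(vals))


def timeseries_summary(result: RunResult) -> pd.DataFrame:
    """Per-step totals and planktonic fraction (0 where the population is empty)."""
    ts = result.timeseries
    n_tot = ts["N_planktonic"] + ts["N_sessile"]
    with np.errstate(invalid="ignore"):
        frac = np.where(n_tot > 0, ts["N_planktonic"] / n_tot.where(n_tot > 0, 1), 0.0)
    return pd.DataFrame({
        "t": ts["t"],
        "N_total": n_tot,
        "planktonic_fraction": frac,
        "c": ts["c"],
    })
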