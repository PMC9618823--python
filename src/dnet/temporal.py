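"""Time-resolved community signatures, peak calling, and temporal ordering.

Each community gets a heatmap of its genes' perturbation response over
time. Per gene, both condition series are first made relative to the start
of the experiment (subtract the time-0 value, then scale to unit Euclidean
norm; positive = up-regulation), the untreated relative series is
subtracted from the treated one, and the difference row is rescaled to unit
norm so entries lie in [-1, 1]. Rows are ordered by complete-linkage
(farthest-point) hierarchical clustering on Euclidean distance. A
community's activation peak is the timepoint where the across-gene mean of
the heatmap is largest in absolute value (t0 excluded — it is identically
zero by construction); communities sorted by peak time give the temporal
activation ordering. Timepoint indices are 0-based throughout (t0 is the
first sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

log = logging.getLogger(__name__)


@dataclass
class CommunityHeatmap:
    """Normalized treated-minus-untreated response of one community."""

    community_label: str
    values: pd.DataFrame            # rows in dendrogram leaf order
    peak_time: int | None = None    # None when every row is zero
    peak_sign: str | None = None    # "up" | "down"
    peak_magnitude: float = 0.0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TemporalOrdering:
    entries: list[tuple[str, int, str, float]]  # (label, peak_time, sign, magnitude)
    silent_timepoints: set[int] = field(default_factory=set)


def relative_series(series: np.ndarray) -> np.ndarray:
    """Response relative to time 0, scaled to unit Euclidean norm.

    d_i = x_i - x_0 (so d_0 = 0, up-regulation positive); returns d/||d||
    or the zero vector for a constant series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 timepoints")
    d = x - x[0]
    norm = np.linalg.norm(d)
    return d / norm if norm > 0 else d


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return m / safe


def heatmap_matrix(
    community_genes,
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    community_label: str = "C?",
    aggregate: str = "mean",
) -> CommunityHeatmap:
    """Build one community's normalized response heatmap.

    Rows are ``relative_series(treated) - relative_series(untreated)`` per
    gene, rescaled to unit norm (zero rows stay zero), then reordered to the
    complete-linkage dendrogram leaf order. The community peak is attached.
    """
    genes = list(community_genes)
    for g in genes:
        if g not in treated.index:
            raise KeyError(f"gene {g!r} missing from the treated matrix")
        if g not in untreated.index:
            raise KeyError(f"gene {g!r} missing from the untreated matrix")
    if treated.shape[1] != untreated.shape[1]:
        raise ValueError("treated and untreated matrices differ in timepoint count")
    T = np.vstack([relative_series(treated.loc[g].to_numpy()) for g in genes])
    U = np.vstack([relative_series(untreated.loc[g].to_numpy()) for g in genes])
    rows = _unit_rows(T - U)
    if len(genes) > 2:
        order = leaves_list(linkage(rows, method="complete", metric="euclidean"))
    elif len(genes) == 2:
        order = leaves_list(linkage(rows, method="complete", metric="euclidean"))
    else:
        order = np.array([0]) if genes else np.array([], dtype=int)
    values = pd.DataFrame(
        rows[order], index=[genes[i] for i in order], columns=list(treated.columns)
    )
    hm = CommunityHeatmap(community_label=community_label, values=values)
    pk = peak_time(hm, aggregate=aggregate)
    if pk is not None:
        hm.peak_time, hm.peak_sign, hm.peak_magnitude = pk
    return hm


def peak_time(
    heatmap: CommunityHeatmap | pd.DataFrame, aggregate: str = "mean"
) -> tuple[int, str, float] | None:
    """Community activation peak: argmax over t>0 of |aggregate column value|.

    ``aggregate`` is "mean" (default) or "median" across the community's
    genes. Ties go to the earliest timepoint. Returns None (a "no response"
    flag) when the aggregate signal is identically zero, e.g. for a heatmap
    whose up- and down-regulated rows cancel.
    """
    values = heatmap.values if isinstance(heatmap, CommunityHeatmap) else heatmap
    if values.empty:
        return None
    agg = values.mean(axis=0) if aggregate == "mean" else values.median(axis=0)
    s = agg.to_numpy()[1:]  # t0 is identically zero by construction
    if s.size == 0 or np.all(s == 0):
        return None
    i = int(np.argmax(np.abs(s))) + 1
    mag = float(abs(s[i - 1]))
    sign = "up" if s[i - 1] > 0 else "down"
    return i, sign, mag


def temporal_ordering(heatmaps: list[CommunityHeatmap]) -> TemporalOrdering:
    """Sort communities by activation peak time.

    Heatmaps flagged "no response" (peak_time None) are excluded with a log
    note. Ties on peak time fall back to the community label. Silent
    timepoints are those that are no community's peak.
    """
    entries = []
    n_tp = 0
    for hm in heatmaps:
        n_tp = max(n_tp, hm.values.shape[1])
        if hm.peak_time is None:
            log.info("temporal_ordering: %s has no response; excluded", hm.community_label)
            continue
        entries.append((hm.community_label, hm.peak_time, hm.peak_sign, hm.peak_magnitude))
    entries.sort(key=lambda e: (e[1], e[0]))
    peaks = {e[1] for e in entries}
    return TemporalOrdering(
        entries=entries, silent_timepoints=set(range(n_tp)) - peaks
    )
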