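"""Quality control and perturbation-responsive gene selection.

An expression matrix is a pandas DataFrame with gene identifiers as the
index and timepoint labels as columns; missing measurements are NaN before
QC. ``qc_filter`` applies the fixed cleaning sequence (duplicate rows,
sparsity, zero-imputation, floor-at-1, zero-variance). ``delta_tu`` scores
each gene by its time-averaged relative treated/untreated difference

    delta_TU = (1/N) * sum_i (T_i - U_i) / (T_i + U_i)

which is bounded in [-1, 1]; ``select_genes`` keeps the genes in the bottom
or top quarter of that score's distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QCError

log = logging.getLogger(__name__)


@dataclass
class DeltaTUScores:
    """Per-gene delta_TU scores with the quartile selection attached."""

    scores: pd.Series
    lower_quartile: float | None = None
    upper_quartile: float | None = None
    selected: list[str] = field(default_factory=list)


def qc_filter(
    raw: pd.DataFrame, sparsity_threshold: float = 1 / 8
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean one expression matrix; returns (matrix, per-rule removal log).

    Rules, in order: (1) drop duplicate gene rows keeping the first;
    (2) drop genes missing at *more than* ``sparsity_threshold`` of the
    timepoints (judged on the original blanks); (3) replace remaining
    missing entries with 0; (4) floor every value at 1; (5) drop genes whose
    floored series has zero variance (which also removes constant genes).
    Raises :class:`QCError` naming the rule that removed the last gene.
    """
    if raw.shape[0] < 1 or raw.shape[1] < 2:
        raise QCError("expression matrix needs >= 1 gene and >= 2 timepoints")
    counts: dict[str, int] = {}
    m = raw.copy()

    dup = m.index.duplicated(keep="first")
    counts["duplicate_gene"] = int(dup.sum())
    m = m[~dup]

    n_tp = m.shape[1]
    sparse = m.isna().sum(axis=1) > sparsity_threshold * n_tp
    counts["sparse"] = int(sparse.sum())
    m = m[~sparse]
    if m.empty:
        raise QCError("sparsity rule removed the last gene")

    m = m.fillna(0.0)
    m = m.where(m >= 1.0, 1.0)

    variable = m.var(axis=1, ddof=0) > 0
    counts["zero_variance"] = int((~variable).sum())
    m = m[variable]
    if m.empty:
        raise QCError("zero-variance rule removed the last gene")

    for rule, n in counts.items():
        if n:
            log.info("qc_filter removed %d gene(s) by rule %r", n, rule)
    return m, counts


def delta_tu(treated: pd.DataFrame, untreated: pd.DataFrame) -> DeltaTUScores:
    """Time-averaged relative difference between paired conditions.

    Both matrices must be QC'd (floored at 1, so T_i + U_i > 0) and share a
    timepoint count; genes present in only one matrix are dropped with a
    warning because the score needs paired values.
    """
    if treated.shape[1] != untreated.shape[1]:
        raise ValueError(
            f"timepoint count mismatch: {treated.shape[1]} vs {untreated.shape[1]}"
        )
    shared = treated.index.intersection(untreated.index)
    n_dropped = len(treated.index.union(untreated.index)) - len(shared)
    if n_dropped:
        log.warning("delta_tu: dropped %d gene(s) present in only one condition", n_dropped)
    if len(shared) == 0:
        raise ValueError("no shared genes between treated and untreated matrices")
    T = treated.loc[shared].to_numpy(dtype=float)
    U = untreated.loc[shared].to_numpy(dtype=float)
    denom = T + U
    if np.any(denom == 0):
        raise ValueError("T_i + U_i = 0 encountered; run qc_filter first")
    scores = pd.Series(((T - U) / denom).mean(axis=1), index=shared, name="delta_tu")
    return DeltaTUScores(scores=scores)


def select_genes(scores: DeltaTUScores | pd.Series, quartile: float = 0.25) -> list[str]:
    """Keep genes in the bottom or top ``quartile`` of the delta_TU distribution.

    Quartiles use linear interpolation between order statistics; ties at the
    cutoffs are included (<=, >=), so the selection is never empty. The
    computed cutoffs are stored on the ``DeltaTUScores`` object when one is
    passed. Note no expression-abundance filter is applied here beyond the
    QC floor-at-1; highly-expressed status is not re-checked.
    """
    holder = scores if isinstance(scores, DeltaTUScores) else None
    s = scores.scores if holder is not None else scores
    if len(s) < 4:
        raise ValueError("need at least 4 scored genes to take quartiles")
    lo = float(np.quantile(s.to_numpy(), quartile))
    hi = float(np.quantile(s.to_numpy(), 1 - quartile))
    selected = s.index[(s <= lo) | (s >= hi)].tolist()
    if holder is not None:
        holder.lower_quartile = lo
        holder.upper_quartile = hi
        holder.selected = selected
    log.info(
        "select_genes: quartiles [%.4g, %.4g], %d of %d genes selected",
        lo, hi, len(selected), len(s),
    )
    return selected
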