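"""Pathway over-representation analysis of DN communities.

Each sufficiently large community (default: 8 or more genes, below which
enrichment is rarely informative) is tested against a user-supplied gene-set
collection in GMT format. The test is the one-sided hypergeometric
(Fisher's exact enrichment): with a universe of M annotated genes, a
pathway of K members and n community genes inside the universe, the p-value
is P(X >= k) for the observed overlap k. Benjamini-Hochberg FDR is applied
across all pathways within each community; communities are corrected
independently, mirroring per-community enrichment reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "community", "pathway", "overlap_count", "set_size",
    "community_annotated_size", "universe_size", "p_value", "fdr", "overlap_genes",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) plus their annotation universe."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{i}: duplicate gene set name {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in sorted(collection.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora_test(
    community_genes,
    collection: GeneSetCollection,
    min_community_size: int = 8,
    community_label: str = "C?",
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of one community in each pathway.

    Communities below ``min_community_size`` are skipped (empty table,
    logged). ``universe`` defaults to the collection's annotated genes; pass
    an explicit set (e.g. all genes in the experiment) to change the
    convention. Pathways with no overlap are reported with p = 1; FDR is BH
    across all pathways of this community.
    """
    if not collection.sets:
        raise ValueError("gene-set collection is empty")
    genes = set(community_genes)
    if len(genes) < min_community_size:
        log.info(
            "ora_test: community %s has %d genes (< %d); skipped",
            community_label, len(genes), min_community_size,
        )
        return pd.DataFrame(columns=RESULT_COLUMNS)
    uni = set(universe) if universe is not None else collection.universe
    annotated = genes & uni
    if not annotated:
        log.warning("ora_test: community %s has no gene in the universe", community_label)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    M, n = len(uni), len(annotated)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & uni
        k = len(annotated & members)
        K = len(members)
        # upper tail P(X >= k); k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "community": community_label, "pathway": name,
                "overlap_count": k, "set_size": K,
                "community_annotated_size": n, "universe_size": M,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(sorted(annotated & members)),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df[RESULT_COLUMNS]


def enrich_communities(
    partition,
    collection: GeneSetCollection,
    min_community_size: int = 8,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Run ora_test over every community of a partition; one stacked table."""
    tables = [
        ora_test(
            partition.members(label), collection,
            min_community_size=min_community_size,
            community_label=label, universe=universe,
        )
        for label in partition.labels()
    ]
    tables = [t for t in tables if not t.empty]
    if not tables:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def significant_pathways(results: pd.DataFrame, fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Rows with FDR below the cutoff, sorted by FDR within community."""
    if results.empty:
        return results
    out = results[results["fdr"] < fdr_cutoff]
    if out.empty:
        log.info("significant_pathways: nothing below FDR %.3g", fdr_cutoff)
        return out
    return out.sort_values(["community", "fdr", "pathway"], kind="stable").reset_index(
        drop=True
    )
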