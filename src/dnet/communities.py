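"""Community detection, pruning/labeling, and hub identification on the DN.

Communities come from the Louvain method — greedy modularity maximization
alternating a local node-moving stage with graph aggregation — run by
default on the weighted DN (treated correlation weights) with resolution 1.
Louvain is order-dependent, so an explicit seed fixes the node-visit order
and makes partitions reproducible. Community labels C0, C1, ... are
assigned by descending size, ties broken by the lexicographically smallest
member gene; communities below a minimum size are pruned. Hubs are the
top-five genes by degree centrality computed on each community's induced
subgraph alone (local, not global, connectivity), with equal centralities
tied in rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    assignment: dict[str, str]                # gene -> "C0", "C1", ...
    modularity: float
    min_size_kept: int = 1
    seed: int | None = None
    weighted: bool = True

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return out

    def members(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.assignment.items() if lab == label)

    def labels(self) -> list[str]:
        return sorted(self.sizes, key=lambda lab: int(lab[1:]))


def _label_by_size(groups: list[set[str]]) -> dict[str, str]:
    ordered = sorted(groups, key=lambda c: (-len(c), min(c)))
    return {g: f"C{i}" for i, c in enumerate(ordered) for g in c}


def detect_communities(
    dn: nx.Graph, seed: int = 0, weighted: bool = True
) -> CommunityPartition:
    """Louvain partition of the differential network.

    ``weighted`` uses the treated correlation weights in the modularity
    objective; ``seed`` controls the node-visit order. The achieved
    modularity of the returned partition is reported on the result.
    """
    if dn.number_of_nodes() == 0:
        raise ValueError("differential network is empty")
    weight = "weight" if weighted else None
    groups = nx.community.louvain_communities(dn, weight=weight, seed=seed, resolution=1)
    groups = [set(c) for c in groups]
    q = nx.community.modularity(dn, groups, weight=weight)
    part = CommunityPartition(
        assignment=_label_by_size(groups),
        modularity=float(q),
        min_size_kept=1,
        seed=seed,
        weighted=weighted,
    )
    log.info(
        "detect_communities: %d communities, modularity %.4f (weighted=%s, seed=%s)",
        len(groups), q, weighted, seed,
    )
    return part


def prune_and_label(
    partition: CommunityPartition, min_size: int = 5
) -> CommunityPartition:
    """Drop communities smaller than ``min_size`` and relabel the survivors.

    Genes of the pruned communities leave the assignment entirely; survivors
    are relabeled C0, C1, ... by descending size with the same deterministic
    tie rule used at detection.
    """
    groups: dict[str, set[str]] = {}
    for g, lab in partition.assignment.items():
        groups.setdefault(lab, set()).add(g)
    kept = [c for c in groups.values() if len(c) >= min_size]
    n_pruned = len(groups) - len(kept)
    if not kept:
        raise ValueError(f"no community reaches min_size={min_size}")
    if n_pruned:
        log.info(
            "prune_and_label: pruned %d communities (< %d genes), %d kept",
            n_pruned, min_size, len(kept),
        )
    return CommunityPartition(
        assignment=_label_by_size(kept),
        modularity=partition.modularity,
        min_size_kept=min_size,
        seed=partition.seed,
        weighted=partition.weighted,
    )


def community_hubs(dn: nx.Graph, partition: CommunityPartition) -> pd.DataFrame:
    """Top-five degree-centrality genes of each community.

    Degree centrality is deg(v)/(n_c - 1) on the induced subgraph of the
    community's n_c members; every gene whose centrality ties the
    fifth-ranked value is reported, so a community may list more than five
    hubs. Returns a table with columns community, gene_id,
    degree_centrality, rank (competition ranking: ties share the smallest
    rank).
    """
    rows = []
    for label in partition.labels():
        members = partition.members(label)
        if len(members) < 2:
            log.warning("community %s has a single gene; degree centrality undefined", label)
            continue
        sub = dn.subgraph(members)
        dc = nx.degree_centrality(sub)
        ranked = sorted(dc.items(), key=lambda kv: (-kv[1], kv[0]))
        cutoff = ranked[min(4, len(ranked) - 1)][1]
        kept = [(g, v) for g, v in ranked if v >= cutoff]
        rank, prev = 0, None
        for i, (g, v) in enumerate(kept, start=1):
            if v != prev:
                rank, prev = i, v
            rows.append(
                {"community": label, "gene_id": g, "degree_centrality": v, "rank": rank}
            )
    return pd.DataFrame(rows, columns=["community", "gene_id", "degree_centrality", "rank"])
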