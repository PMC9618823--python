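"""End-to-end pipeline driver.

Chains every stage — quality control, delta_TU gene selection,
per-condition co-expression networks (with replicate intersection when a
duplicated design is given), differential-network construction, Louvain
communities with pruning, hub identification, temporal heatmaps and
ordering, and optional pathway enrichment — writing each intermediate
artifact plus a JSON manifest of parameters, thresholds and removal counts
to the output directory. Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import io
from .communities import CommunityPartition, community_hubs, detect_communities, prune_and_label
from .enrichment import enrich_communities, read_gmt, significant_pathways
from .errors import ConfigurationError
from .network import build_network, correlation_matrix, differential_network, intersect_networks
from .preprocess import delta_tu, qc_filter, select_genes
from .simulate import SimulationConfig, generate_dataset, write_truth
from .temporal import heatmap_matrix, temporal_ordering

log = logging.getLogger(__name__)

try:
    __version__ = version("dnet")
except PackageNotFoundError:  # running from a source tree
    __version__ = "unknown"


@dataclass
class PipelineConfig:
    """Everything one run needs: either file inputs or a simulation recipe."""

    outdir: str | Path = "dnet_out"
    treated_paths: list[str] = field(default_factory=list)
    untreated_paths: list[str] = field(default_factory=list)
    simulation: SimulationConfig | None = None
    gmt_path: str | None = None
    quantile: float = 0.995
    sparsity_threshold: float = 1 / 8
    quartile: float = 0.25
    min_community_size: int = 5
    min_enrich_size: int = 8
    fdr_cutoff: float = 0.05
    weighted: bool = True
    aggregate: str = "mean"
    render_png: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            if not self.treated_paths or not self.untreated_paths:
                raise ConfigurationError(
                    "either a simulation config or treated/untreated paths are required"
                )
            if len(self.treated_paths) != len(self.untreated_paths):
                raise ConfigurationError("treated and untreated replicate counts differ")
            for p in [*self.treated_paths, *self.untreated_paths]:
                if not Path(p).exists():
                    raise ConfigurationError(f"input path does not exist: {p}")
        for name in ("quantile", "sparsity_threshold", "quartile"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.gmt_path and not Path(self.gmt_path).exists():
            raise ConfigurationError(f"GMT path does not exist: {self.gmt_path}")


@dataclass
class PipelineResult:
    """In-memory view of everything a run produced."""

    manifest: dict
    treated: list[pd.DataFrame]
    untreated: list[pd.DataFrame]
    truth: object | None
    scores: object
    selected: list[str]
    treated_network: object
    untreated_network: object
    dn: object
    partition: CommunityPartition
    hubs: pd.DataFrame
    heatmaps: list
    ordering: object
    enrichment: pd.DataFrame | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow; see the module docstring for the stages."""
    config.validate()
    out = Path(config.outdir)
    for sub in ("input", "network", "community", "heatmap", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "quantile": config.quantile,
            "sparsity_threshold": config.sparsity_threshold,
            "quartile": config.quartile,
            "min_community_size": config.min_community_size,
            "min_enrich_size": config.min_enrich_size,
            "fdr_cutoff": config.fdr_cutoff,
            "weighted": config.weighted,
            "aggregate": config.aggregate,
        },
        "stages": [],
    }

    def stage(name: str, **record):
        manifest["stages"].append({"name": name, **record})
        io.write_manifest(manifest, out / "manifest.json")  # partial on abort

    # --- input: simulate or load ---------------------------------------
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        treated, untreated, truth = generate_dataset(sim)
        for r, (t, u) in enumerate(zip(treated, untreated), start=1):
            io.write_expression(t, out / "input" / f"treated_rep{r}.tsv")
            io.write_expression(u, out / "input" / f"untreated_rep{r}.tsv")
        write_truth(truth, out / "input" / "truth.json")
        stage(
            "simulate",
            n_genes=sim.n_genes, n_timepoints=sim.n_timepoints,
            n_modules=sim.n_modules, n_replicates=sim.n_replicates, seed=sim.seed,
            outputs=[f"input/treated_rep{r + 1}.tsv" for r in range(sim.n_replicates)],
        )
    else:
        treated = [io.read_expression(p) for p in config.treated_paths]
        untreated = [io.read_expression(p) for p in config.untreated_paths]
        stage(
            "load",
            treated=[Path(p).name for p in config.treated_paths],
            untreated=[Path(p).name for p in config.untreated_paths],
        )

    # --- qc --------------------------------------------------------------
    qc_counts = {}
    for label, mats in (("treated", treated), ("untreated", untreated)):
        for r in range(len(mats)):
            mats[r], counts = qc_filter(mats[r], config.sparsity_threshold)
            qc_counts[f"{label}_rep{r + 1}"] = counts
    # delta_TU needs paired genes: restrict every matrix to the common set
    common = treated[0].index
    for m in treated[1:] + untreated:
        common = common.intersection(m.index)
    treated = [m.loc[common] for m in treated]
    untreated = [m.loc[common] for m in untreated]
    for r, (t, u) in enumerate(zip(treated, untreated), start=1):
        io.write_expression(t, out / "input" / f"treated_rep{r}_qc.tsv")
        io.write_expression(u, out / "input" / f"untreated_rep{r}_qc.tsv")
    stage("qc", removal_counts=qc_counts, genes_retained=int(len(common)))

    # --- delta_TU selection ---------------------------------------------
    per_rep = [delta_tu(t, u) for t, u in zip(treated, untreated)]
    scores = per_rep[0]
    if len(per_rep) > 1:  # replicate average of the per-replicate Eq.-style scores
        scores.scores = sum(s.scores for s in per_rep) / len(per_rep)
    selected = select_genes(scores, config.quartile)
    io.write_scores(scores, out / "input" / "delta_tu.csv")
    stage(
        "select",
        lower_quartile=scores.lower_quartile, upper_quartile=scores.upper_quartile,
        n_selected=len(selected), n_scored=int(len(scores.scores)),
    )

    # --- per-condition networks (+ replicate intersection) ----------------
    nets = {}
    thresholds = {}
    for label, mats in (("treated", treated), ("untreated", untreated)):
        reps = []
        for r, m in enumerate(mats, start=1):
            corr = correlation_matrix(m.loc[selected])
            G = build_network(corr, config.quantile)
            thresholds[f"{label}_rep{r}"] = G.graph["threshold"]
            if len(mats) > 1:
                io.write_edge_list(G, out / "network" / f"{label}_rep{r}_edges.tsv")
            reps.append(G)
        nets[label] = reps[0] if len(reps) == 1 else intersect_networks(*reps)
        io.write_edge_list(nets[label], out / "network" / f"{label}_edges.tsv")
    stage(
        "network",
        quantile=config.quantile, thresholds=thresholds,
        treated_edges=nets["treated"].number_of_edges(),
        untreated_edges=nets["untreated"].number_of_edges(),
        intersected=len(treated) > 1,
    )

    # --- differential network --------------------------------------------
    dn = differential_network(nets["treated"], nets["untreated"])
    io.write_edge_list(dn, out / "network" / "dn_edges.tsv")
    stage("differential", nodes=dn.number_of_nodes(), edges=dn.number_of_edges())

    # --- communities ------------------------------------------------------
    raw_partition = detect_communities(dn, seed=config.seed, weighted=config.weighted)
    partition = prune_and_label(raw_partition, config.min_community_size)
    io.write_communities(partition, out / "community" / "communities.csv")
    stage(
        "communities",
        modularity=raw_partition.modularity,
        n_detected=len(raw_partition.sizes), n_kept=len(partition.sizes),
        sizes={lab: partition.sizes[lab] for lab in partition.labels()},
    )

    # --- hubs -------------------------------------------------------------
    hubs = community_hubs(dn, partition)
    io.write_hubs(hubs, out / "community" / "hubs.csv")
    stage("hubs", n_rows=int(len(hubs)))

    # --- temporal ---------------------------------------------------------
    heatmaps = [
        heatmap_matrix(
            partition.members(label), treated[0], untreated[0],
            community_label=label, aggregate=config.aggregate,
        )
        for label in partition.labels()
    ]
    for hm in heatmaps:
        io.write_heatmap(hm, out / "heatmap" / f"{hm.community_label}.tsv")
        if config.render_png:
            io.render_heatmap(hm, out / "heatmap" / f"{hm.community_label}.png")
    ordering = temporal_ordering(heatmaps)
    io.write_ordering(ordering, out / "heatmap" / "ordering.csv")
    stage(
        "temporal",
        ordering=[[lab, t] for lab, t, _s, _m in ordering.entries],
        silent_timepoints=sorted(ordering.silent_timepoints),
    )

    # --- enrichment (optional) --------------------------------------------
    enr = None
    if config.gmt_path:
        collection = read_gmt(config.gmt_path)
        enr = enrich_communities(partition, collection, config.min_enrich_size)
        enr.to_csv(out / "enrichment" / "enrichment.csv", index=False, float_format="%.10g")
        sig = significant_pathways(enr, config.fdr_cutoff)
        sig.to_csv(out / "enrichment" / "significant.csv", index=False, float_format="%.10g")
        stage(
            "enrichment",
            n_tested=int(len(enr)),
            n_significant=int(len(sig)),
            fdr_cutoff=config.fdr_cutoff,
        )

    return PipelineResult(
        manifest=manifest, treated=treated, untreated=untreated, truth=truth,
        scores=scores, selected=selected,
        treated_network=nets["treated"], untreated_network=nets["untreated"],
        dn=dn, partition=partition, hubs=hubs, heatmaps=heatmaps,
        ordering=ordering, enrichment=enr,
    )
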