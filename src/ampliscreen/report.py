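"""Pipeline orchestration and rendering.

``run_pipeline`` drives the full analysis for one configuration:
load panel -> (16S extraction | whole-genome pass-through) -> in-silico
amplification -> allele clustering -> summaries -> overlap/network ->
artifact rendering. Each primer pair gets its own artifact
subdirectory; a panel-level screening table (one row per primer pair
with amplification rate and summed Shannon diversity) sits at the top
of the output directory. All tabular artifacts are byte-deterministic
for a fixed config and panel.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from . import clustering, overlap, rrna_mode, summaries
from .errors import AmpliscreenError, ValidationError
from .genome_io import GenomePanel, load_panel, write_panel_manifest
from .insilico_pcr import (
    PrimerPair,
    amplify_genome,
    read_primer_file,
    write_amplicons_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_PRIMER_FILE = Path(__file__).parent / "data" / "default_primers.tsv"


@dataclass
class RunConfig:
    """One pipeline invocation, serialized into the output directory."""

    genomes: str | Path  # genome directory or manifest
    outdir: str | Path
    primers: Sequence[PrimerPair] | None = None
    primer_file: str | Path | None = None  # used when primers is None
    mode: Literal["sixteen_s", "whole_genome"] = "whole_genome"
    identity: float = 1.0
    frag: bool = False
    genus_label: str = "local"
    make_plots: bool = True
    seed: int = 0  # only fixtures are stochastic; recorded for provenance

    def resolve_primers(self) -> list[PrimerPair]:
        if self.primers is not None:
            return list(self.primers)
        path = self.primer_file or DEFAULT_PRIMER_FILE
        return read_primer_file(path)


@dataclass
class PrimerResult:
    """All computed objects for one primer pair on the panel."""

    pair: PrimerPair
    amplicons_by_genome: dict
    clusters: list
    genome_summaries: list
    stats: summaries.PanelStats
    presence: pd.DataFrame
    graph: nx.Graph
    overlap: overlap.SpeciesOverlap
    outdir: Path


@dataclass
class GenusReport:
    """The consolidated result of one run."""

    config: RunConfig
    panel: GenomePanel
    results: dict[str, PrimerResult] = field(default_factory=dict)


def run_pipeline(config: RunConfig, panel: GenomePanel | None = None) -> GenusReport:
    """Execute the full workflow and write all artifacts.

    ``panel`` may be passed directly (e.g. a synthetic or
    adapter-fetched panel); otherwise it is loaded from
    ``config.genomes``. Raises a package error (single-line diagnostic)
    on invalid configuration before any computation.
    """
    clustering.validate_threshold(config.identity)
    primers = config.resolve_primers()

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(outdir)
    _write_config(config, outdir / "config.txt")

    if panel is None:
        panel = load_panel(config.genomes, frag_allowed=config.frag,
                           genus_label=config.genus_label)
    logger.info("panel %s: %d genomes", panel.genus_label, len(panel))
    write_panel_manifest(panel, outdir / "panel_manifest.tsv")
    species_by_accession = {g.accession: g.species for g in panel.genomes}

    report = GenusReport(config=config, panel=panel)
    stat_rows = []
    for pair in primers:
        result = _run_primer(config, panel, pair, species_by_accession, outdir)
        report.results[pair.name] = result
        stat_rows.append((pair.name, config.mode, result.stats))
    summaries.write_panel_stats(stat_rows, outdir / "panel_stats.tsv")
    return report


def _run_primer(
    config: RunConfig,
    panel: GenomePanel,
    pair: PrimerPair,
    species_by_accession: Mapping[str, str],
    outdir: Path,
) -> PrimerResult:
    pair_dir = outdir / pair.name
    pair_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "sixteen_s":
        amplicons_by_genome, genes_by_genome = rrna_mode.run_16s_mode(panel, pair)
        for accession, genes in genes_by_genome.items():
            if not genes:
                logger.info("%s: no 16S detected", accession)
        all_genes = [g for genes in genes_by_genome.values() for g in genes]
        rrna_mode.write_genes_fasta(all_genes, pair_dir / "rrna_genes.fasta")
    else:
        amplicons_by_genome = {
            g.accession: amplify_genome(g, pair) for g in panel.genomes
        }

    all_amplicons = [
        amp
        for g in panel.genomes
        for amp in amplicons_by_genome.get(g.accession, [])
    ]
    write_amplicons_fasta(all_amplicons, pair_dir / "amplicons.fasta")
    logger.info("%s: %d amplicons from %d genomes", pair.name,
                len(all_amplicons), len(panel))

    if all_amplicons:
        clusters = clustering.cluster(all_amplicons, config.identity,
                                      species_by_accession)
    else:
        clusters = []
        logger.info("%s: no amplification in this panel", pair.name)
    clustering.write_cluster_table(clusters, pair_dir / "clusters.tsv")
    clustering.write_centroid_fasta(clusters, pair_dir / "centroids.fasta")

    genome_summaries = [
        summaries.genome_summary(
            g, amplicons_by_genome.get(g.accession, []), clusters
        )
        for g in panel.genomes
    ]
    summaries.write_genome_summaries(genome_summaries,
                                     pair_dir / "genome_summaries.tsv")
    stats = summaries.panel_stats(panel, amplicons_by_genome)

    presence = overlap.presence_matrix(panel, clusters)
    overlap.write_presence_matrix(presence, pair_dir / "presence_matrix.tsv")
    graph = overlap.build_graph(presence)
    overlap.write_edge_list(graph, pair_dir / "network_edges.tsv")
    overlap.write_graphml(graph, pair_dir / "network.graphml")
    sp_overlap = overlap.species_overlap(clusters, panel)
    overlap.write_overlap_report(clusters, sp_overlap, pair_dir / "overlap_report.txt")

    if config.make_plots:
        render_heatmap(presence, pair_dir / "presence_heatmap.png")
        render_network(graph, pair_dir / "network.png",
                       species_by_accession=species_by_accession)

    _write_summary_text(pair, stats, sp_overlap, genome_summaries,
                        pair_dir / "summary.txt")
    return PrimerResult(
        pair=pair,
        amplicons_by_genome=amplicons_by_genome,
        clusters=clusters,
        genome_summaries=genome_summaries,
        stats=stats,
        presence=presence,
        graph=graph,
        overlap=sp_overlap,
        outdir=pair_dir,
    )


def render_heatmap(presence: pd.DataFrame, path: str | Path) -> Path:
    """Presence/absence heatmap: genomes x clusters, counts annotated."""
    path = Path(path)
    n_rows = max(len(presence.index), 1)
    n_cols = max(len(presence.columns), 1)
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * n_cols + 1.5), max(2.5, 0.35 * n_rows + 1.0))
    )
    if presence.size == 0 or (presence.values == 0).all():
        ax.text(0.5, 0.5, "no amplification", ha="center", va="center")
        ax.set_axis_off()
    else:
        binary = (presence.values > 0).astype(int)
        ax.imshow(binary, cmap="Greys", aspect="auto", vmin=0, vmax=1)
        for i in range(presence.shape[0]):
            for j in range(presence.shape[1]):
                count = presence.values[i, j]
                if count:
                    ax.text(j, i, str(count), ha="center", va="center",
                            color="white" if binary[i, j] else "black", fontsize=7)
        ax.set_xticks(range(n_cols), [f"c{c}" for c in presence.columns],
                      fontsize=7, rotation=90)
        ax.set_yticks(range(len(presence.index)), presence.index, fontsize=7)
        ax.set_xlabel("allele cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def edge_widths(graph: nx.Graph, min_width: float = 0.8,
                max_width: float = 6.0) -> dict[tuple[str, str], float]:
    """Stroke width per edge, strictly increasing in shared-allele count."""
    weights = {tuple(sorted(e)): graph.edges[e]["weight"] for e in graph.edges()}
    if not weights:
        return {}
    w_max = max(weights.values())
    return {
        e: min_width + (max_width - min_width) * w / w_max
        for e, w in sorted(weights.items())
    }


def render_network(
    graph: nx.Graph,
    path: str | Path,
    species_by_accession: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], float]:
    """Shared-allele network figure.

    Isolated genomes are excluded from the drawing; edge width scales
    with the number of shared alleles; nodes are colored by species.
    Returns the edge-width mapping actually used.
    """
    path = Path(path)
    species_by_accession = species_by_accession or {}
    widths = edge_widths(graph)
    connected = graph.subgraph([n for n, d in graph.degree() if d > 0])

    fig, ax = plt.subplots(figsize=(6, 6))
    if connected.number_of_nodes() == 0:
        ax.text(0.5, 0.5, "no shared alleles between genomes",
                ha="center", va="center")
        ax.set_axis_off()
    else:
        pos = nx.spring_layout(connected, seed=0)
        species = sorted({species_by_accession.get(n, "unknown")
                          for n in connected.nodes()})
        cmap = plt.colormaps["tab20"]
        color_of = {sp: cmap(i % 20) for i, sp in enumerate(species)}
        node_colors = [color_of[species_by_accession.get(n, "unknown")]
                       for n in connected.nodes()]
        edge_list = list(connected.edges())
        nx.draw_networkx_edges(
            connected, pos, ax=ax, edgelist=edge_list,
            width=[widths[tuple(sorted(e))] for e in edge_list], alpha=0.6,
        )
        nx.draw_networkx_nodes(connected, pos, ax=ax, node_color=node_colors,
                               node_size=250)
        nx.draw_networkx_labels(connected, pos, ax=ax, font_size=7)
        handles = [plt.Line2D([], [], marker="o", ls="", color=color_of[sp],
                              label=sp) for sp in species]
        ax.legend(handles=handles, fontsize=7, loc="best")
        ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return widths


def _write_config(config: RunConfig, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in dataclasses.asdict(config).items():
            if key == "primers" and value is not None:
                value = ",".join(p["name"] for p in value)
            fh.write(f"{key}\t{value}\n")


def _setup_run_logging(outdir: Path) -> None:
    handler_path = outdir / "run.log"
    root = logging.getLogger("ampliscreen")
    for handler in list(root.handlers):
        if isinstance(handler, logging.FileHandler):
            root.removeHandler(handler)
            handler.close()
    file_handler = logging.FileHandler(handler_path, mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(file_handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)


def _write_summary_text(
    pair: PrimerPair,
    stats: summaries.PanelStats,
    sp_overlap: overlap.SpeciesOverlap,
    genome_summaries: Sequence[summaries.GenomeSummary],
    path: Path,
) -> None:
    multiplicities = [s.n_amplicons for s in genome_summaries]
    mean_mult = (sum(multiplicities) / len(multiplicities)) if multiplicities else 0.0
    with open(path, "w") as fh:
        fh.write(f"primer\t{pair.name}\n")
        fh.write(f"n_genomes\t{stats.n_genomes}\n")
        fh.write(f"n_amplified\t{stats.n_amplified}\n")
        fh.write(f"amplification_rate\t{stats.amplification_rate:.3f}\n")
        fh.write(f"shannon_sum\t{stats.shannon_sum:.2f}\n")
        fh.write(f"mean_multiplicity\t{mean_mult:.3f}\n")
        if sp_overlap.fraction is None:
            fh.write("species_overlap_fraction\tundefined\n")
        else:
            fh.write(f"species_overlap_fraction\t{sp_overlap.fraction:.4f}\n")
        if stats.n_amplified == 0:
            fh.write("note\tno amplification in this panel\n")
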