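"""End-to-end pipeline: quantify -> knockout-filter -> classify ->
enrich -> cluster, from a single declarative config.

The stage order mirrors the analysis it implements: normalize both
label-free quantifications, average replicates per genotype, apply the
knockout specificity filter, compute log2(WT/Ala56) fold changes and
categories for the kept interactors, tally categories and test the
increase/decrease bias with a chi-square goodness-of-fit, score
gene-set overlaps hypergeometrically, and cluster the score-thresholded
interaction graph with MCL (plus a resampling edge-enrichment test).

Every stage writes a TSV; the run ends with one JSON report.  The same
config and seed always produce an identical report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as io_formats
from .containers import ION_INTENSITY, SPECTRAL_COUNT, GeneSet, SampleMeta
from .differential import DECREASED_ALA56, INCREASED_ALA56, category_tally, differential_table
from .enrichment import DEFAULT_BACKGROUND_N, chi_square_gof, enrich_sets
from .filters import decisions_frame, filter_funnel, filter_specific
from .network import edge_enrichment_permutation, mcl, threshold_graph
from .normalize import average_replicates, normalize_intensities, normalize_spectral_counts
from .simulate import (
    BundleOptions,
    SimulatedDataset,
    SimulationConfig,
    make_edges,
    make_gene_sets,
    generate_interactome,
)

logger = logging.getLogger("coipnet")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class InputPaths:
    counts: str
    spectra: str
    samples: str
    annotations: str
    gene_sets: str | None = None
    edges: str | None = None
    edge_score_scale: str = "unit"


@dataclass(frozen=True)
class StageParams:
    ko_ratio: float = 1.5  # knockout enrichment threshold r (inclusive)
    fc_threshold: float = 0.5  # classification threshold t on log2(WT/Ala56)
    pseudocount: float = 0.5
    mw_mode: str = "normal"
    background_n: int = DEFAULT_BACKGROUND_N
    score_cutoff: float = 0.9
    mcl_inflation: float = 2.0
    mcl_min_size: int = 7
    edge_permutations: int = 1000
    intensity_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.ko_ratio <= 0 or self.fc_threshold < 0 or self.pseudocount < 0:
            raise ValueError("ko_ratio must be positive; fc_threshold/pseudocount non-negative")
        if not 0.0 <= self.score_cutoff <= 1.0:
            raise ValueError("score_cutoff must lie in [0, 1]")
        if self.mw_mode not in ("normal", "exact"):
            raise ValueError("mw_mode must be 'normal' or 'exact'")


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: InputPaths | None = None
    params: StageParams = field(default_factory=StageParams)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.get("simulation")
        inputs = raw.get("inputs")
        return cls(
            outdir=raw.get("outdir", "coipnet_out"),
            seed=int(raw.get("seed", 0)),
            simulation=SimulationConfig(**sim) if sim is not None else None,
            inputs=InputPaths(**inputs) if inputs is not None else None,
            params=StageParams(**raw.get("params", {})),
        )


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        data = generate_interactome(sim)
        # same derived stream as write_fixture_bundle, so in-memory and
        # on-disk simulation runs see identical gene sets and edges
        rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 7]))
        options = BundleOptions()
        gene_sets = make_gene_sets(data, options, rng)
        edges = make_edges(data, options, rng)
        return data, gene_sets, edges
    inputs = config.inputs
    meta = io_formats.read_sample_meta(inputs.samples)
    counts = io_formats.read_quant_table(inputs.counts, meta, SPECTRAL_COUNT)
    spectra = io_formats.read_spectra(inputs.spectra, meta)
    annotations = io_formats.read_annotations(inputs.annotations)
    data = SimulatedDataset(  # reused as a plain dataset container
        config=None, samples=meta, counts=counts, spectra=spectra,
        annotations=annotations, truth=pd.DataFrame(),
    )
    gene_sets = io_formats.read_gmt(inputs.gene_sets) if inputs.gene_sets else []
    edges = (
        io_formats.read_edges(inputs.edges, inputs.edge_score_scale) if inputs.edges else None
    )
    return data, gene_sets, edges


def run_pipeline(
    config: PipelineConfig,
    gene_sets: Sequence[GeneSet] | None = None,
    edges: nx.Graph | None = None,
) -> dict:
    """Execute every stage and return (and write) the run report.

    ``gene_sets`` and ``edges`` may be passed in-memory; they override
    whatever the config names (or, for simulation runs, the synthetic
    gene sets and edge list derived from the simulated ground truth).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    params = config.params

    data, file_gene_sets, file_edges = _load_inputs(config)
    gene_sets = list(gene_sets) if gene_sets is not None else file_gene_sets
    edges = edges if edges is not None else file_edges
    genes = {a.accession: a.gene for a in data.annotations}
    n_input = len(data.counts.accessions)
    logger.info("input: %d proteins, %d samples", n_input, len(data.samples))

    # --- normalization + replicate averaging ------------------------------
    norm_sc, report_sc = normalize_spectral_counts(data.counts)
    norm_ii, report_ii = normalize_intensities(
        data.spectra, data.samples, tol=params.intensity_tol
    )
    summary_sc = average_replicates(norm_sc, data.samples)
    summary_ii = average_replicates(norm_ii, data.samples)
    # align the intensity summary to the spectral-count universe
    summary_ii.values = summary_ii.values.reindex(summary_sc.accessions)
    logger.info(
        "normalization: %d/%d spectra pruned as shared",
        report_ii.n_spectra_pruned_shared,
        report_ii.n_spectra_total,
    )

    # --- specificity filter ----------------------------------------------
    decisions = filter_specific(summary_sc, summary_ii, data.annotations, r=params.ko_ratio)
    funnel = filter_funnel(decisions)
    decisions_frame(decisions).to_csv(outdir / "filter_funnel.tsv", sep="\t", index=False)
    kept = [d.accession for d in decisions if d.kept]
    logger.info(
        "specificity filter: %d identified -> %d specific interactors",
        funnel["n_input"],
        funnel["n_kept"],
    )

    # --- differential interaction ----------------------------------------
    table = differential_table(
        summary_sc,
        summary_ii,
        norm_sc,
        norm_ii,
        data.samples,
        accessions=kept,
        pseudocount=params.pseudocount,
        t=params.fc_threshold,
        mw_mode=params.mw_mode,
        genes=genes,
    )
    table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    classified = table.loc[table["category_defined"]]
    tally = category_tally(classified["category"])
    n_unclassified = int((~table["category_defined"]).sum())
    if n_unclassified:
        logger.info(
            "classification: %d kept protein(s) lack an ion-intensity fold change "
            "and are excluded from the category tally",
            n_unclassified,
        )
    logger.info("category tally: %s", tally["counts"])

    n_dec = tally["counts"][DECREASED_ALA56]
    n_inc = tally["counts"][INCREASED_ALA56]
    if n_dec + n_inc > 0:
        chi_stat, chi_df, chi_p = chi_square_gof([n_dec, n_inc])
        chi_square = {"observed": [n_dec, n_inc], "statistic": chi_stat, "df": chi_df, "p": chi_p}
    else:
        chi_square = {"observed": [0, 0], "statistic": None, "df": None, "p": None}

    # --- gene-set enrichment ---------------------------------------------
    kept_genes = sorted({genes[a] for a in kept if genes.get(a)})
    enrichment = (
        enrich_sets(kept_genes, gene_sets, params.background_n) if gene_sets else []
    )
    if enrichment:
        pd.DataFrame(
            [
                {"set": r.set_name, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q}
                for r in enrichment
            ]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        for r in enrichment:
            logger.info("enrichment: %s k=%d p=%.3g q=%.3g", r.set_name, r.k, r.p, r.q)

    # --- network clustering ----------------------------------------------
    network_report = None
    if edges is not None and edges.number_of_nodes() > 0:
        thresholded = threshold_graph(edges, params.score_cutoff)
        assignment = mcl(
            thresholded, inflation=params.mcl_inflation, min_size=params.mcl_min_size
        )
        cluster_rows = [
            {"cluster_id": i + 1, "size": len(c), "members": ";".join(sorted(c))}
            for i, c in enumerate(assignment.clusters)
        ]
        pd.DataFrame(
            cluster_rows or [], columns=["cluster_id", "size", "members"]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        subset = [a for a in kept if thresholded.has_node(a)]
        edge_enrichment = (
            edge_enrichment_permutation(
                thresholded,
                subset,
                n_perm=max(params.edge_permutations, 100),
                seed=np.random.default_rng(np.random.SeedSequence([config.seed, 11])),
            )
            if subset
            else None
        )
        network_report = {
            "n_nodes": thresholded.number_of_nodes(),
            "n_edges_at_cutoff": thresholded.number_of_edges(),
            "score_cutoff": params.score_cutoff,
            "clusters": [{"size": len(c)} for c in assignment.clusters],
            "n_clusters": len(assignment.clusters),
            "n_unclustered": len(assignment.unclustered),
            "edge_enrichment": edge_enrichment,
        }
        logger.info(
            "network: %d clusters (min size %d) from %d edges at cutoff %.2f",
            len(assignment.clusters),
            params.mcl_min_size,
            thresholded.number_of_edges(),
            params.score_cutoff,
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "params": asdict(params),
        "n_samples": len(data.samples),
        "normalization": {
            "spectral_count": report_sc.to_dict(),
            "ion_intensity": report_ii.to_dict(),
        },
        "filter_funnel": funnel,
        "category_tally": tally,
        "n_kept_unclassified": n_unclassified,
        "chi_square_decreased_vs_increased": chi_square,
        "enrichment": [
            {"set": r.set_name, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q}
            for r in enrichment
        ],
        "network": network_report,
    }
    io_formats.write_report(_sanitize(report), outdir)
    return report


def _sanitize(obj):
    """Replace NaN/inf with None so the JSON report is strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not math.isfinite(obj):
        return None
    return obj


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    path = outdir / "run.log"
    have = any(
        isinstance(h, logging.FileHandler) and Path(getattr(h, "baseFilename", "")) == path.resolve()
        for h in logger.handlers
    )
    if not have:
        handler = logging.FileHandler(path, encoding="utf-8")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
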