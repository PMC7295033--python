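"""Synthetic co-IP interactome generator with known ground truth.

The generator emulates the study design the pipeline targets: three
genotypes (WT, variant, knockout) x three technical replicates, with
~1000 proteins of which a configurable fraction are non-specific bead
binders, specific interactors are depleted in the knockout (a small
configurable "leak" keeps the 1.5x ratio rule — not mere
presence/absence — exercised), and a planted subset of specific
interactors carries genotype-dependent log2 effects.  Sample-level
sampling-depth factors (counts) and additive log2 shifts (intensities)
are injected so the normalization stages have real work to do.

Counts are drawn from a negative binomial with mean = protein
abundance x genotype effect x sample depth (Poisson in the
dispersion->0 limit; dispersion exactly 0 disables sampling and uses
rounded means, giving noise-free data for analytic tests).  Spectrum
intensities live on the log2 scale: abundance + genotype effect +
per-sample shift + Gaussian noise.  Non-specific proteins are modeled
with a modest knockout enrichment (background binders recover more
from bait-free beads) and a fraction detected only in the knockout,
so the knockout filter has signal to find; ribosomal proteins are
flagged among the non-specific pool.

Everything is deterministic under a fixed seed (byte-identical output
files).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    GENOTYPES,
    SPECTRAL_COUNT,
    GeneSet,
    Genotype,
    ProteinAnnotation,
    ProteinQuantMatrix,
    SampleMeta,
)
from . import io as io_formats

SPECIFIC = "SPECIFIC"
NONSPECIFIC = "NONSPECIFIC"
UNCHANGED = "UNCHANGED"
INCREASED_ALA56 = "INCREASED_ALA56"
DECREASED_ALA56 = "DECREASED_ALA56"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic interactome.

    Defaults mirror the funnel and category proportions of the kind of
    knockout-controlled co-IP study the pipeline analyzes: about half
    the identified proteins are non-specific, and among specific
    interactors roughly 67% lose and 15% gain association with the
    variant, with a one-log2-unit planted effect.
    """

    n_proteins: int = 1000
    n_replicates: int = 3
    frac_nonspecific: float = 0.50
    frac_ribosomal: float = 0.05  # of all proteins; drawn from the non-specific pool
    frac_increased: float = 0.15  # of specific proteins
    frac_decreased: float = 0.67
    effect_log2: float = 1.0
    ko_leak_frac: float = 0.05  # knockout recovery of specific interactors
    ko_enrichment: float = 3.0  # knockout multiplier for non-specific binders
    frac_ko_only: float = 0.20  # of non-specific proteins: absent in WT/variant
    mean_log2_abundance: float = 5.0
    sd_log2_abundance: float = 1.2
    nonspecific_abundance_log2: float = -1.0  # shift of non-specific binders vs specific
    count_dispersion: float = 0.05  # negative-binomial overdispersion; 0 = noise-free
    intensity_sigma: float = 0.25  # sd of log2 spectrum noise; 0 = noise-free
    depth_bias: float | Sequence[float] | None = None  # None: drawn lognormal(sd=0.15)
    intensity_shift_log2: float | Sequence[float] | None = None  # None: drawn N(0, 0.75)
    frac_shared_spectra: float = 0.05
    intensity_base_log2: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be positive")
        for name in (
            "frac_nonspecific",
            "frac_ribosomal",
            "frac_increased",
            "frac_decreased",
            "frac_ko_only",
            "frac_shared_spectra",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_increased + self.frac_decreased > 1.0 + 1e-12:
            raise ValueError("frac_increased + frac_decreased must not exceed 1")
        if self.frac_ribosomal > self.frac_nonspecific + 1e-12:
            raise ValueError("frac_ribosomal cannot exceed frac_nonspecific")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be non-negative")
        if self.count_dispersion < 0 or self.intensity_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.ko_leak_frac <= 1.0:
            raise ValueError("ko_leak_frac must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return 3 * self.n_replicates

    def resolve_depth_bias(self, rng: np.random.Generator) -> np.ndarray:
        return _per_sample(self.depth_bias, self.n_samples, lambda: rng.lognormal(0.0, 0.15, self.n_samples))

    def resolve_intensity_shift(self, rng: np.random.Generator) -> np.ndarray:
        return _per_sample(
            self.intensity_shift_log2, self.n_samples, lambda: rng.normal(0.0, 0.75, self.n_samples)
        )


def _per_sample(value, n: int, draw) -> np.ndarray:
    if value is None:
        return np.asarray(draw(), dtype=float)
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"per-sample parameter needs length {n}, got {arr.shape}")
    return arr


@dataclass
class SimulatedDataset:
    """Generated tables plus the ground truth they were drawn from."""

    config: SimulationConfig
    samples: list[SampleMeta]
    counts: ProteinQuantMatrix  # raw integer spectral counts
    spectra: pd.DataFrame  # spectrum_id, sample_id, accessions, intensity
    annotations: list[ProteinAnnotation]
    truth: pd.DataFrame  # accession, label, class, effect_log2, is_ribosomal

    @property
    def genes(self) -> dict[str, str]:
        return {a.accession: a.gene for a in self.annotations}


def generate_interactome(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset; same config and seed => identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins

    samples = [
        SampleMeta(f"{g.value}_{r}", g, r)
        for g in GENOTYPES
        for r in range(1, config.n_replicates + 1)
    ]
    genotype_of = np.array([s.genotype.value for s in samples])

    n_nonspecific = int(round(n * config.frac_nonspecific))
    n_specific = n - n_nonspecific
    n_ribosomal = min(int(round(n * config.frac_ribosomal)), n_nonspecific)
    n_increased = int(round(n_specific * config.frac_increased))
    n_decreased = int(round(n_specific * config.frac_decreased))
    n_ko_only = int(round(n_nonspecific * config.frac_ko_only))

    labels = np.array([SPECIFIC] * n_specific + [NONSPECIFIC] * n_nonspecific)
    planted = np.array([UNCHANGED] * n, dtype=object)
    planted[:n_increased] = INCREASED_ALA56
    planted[n_increased : n_increased + n_decreased] = DECREASED_ALA56
    true_effect = np.zeros(n)
    true_effect[:n_increased] = -config.effect_log2
    true_effect[n_increased : n_increased + n_decreased] = config.effect_log2
    is_ribosomal = np.zeros(n, dtype=bool)
    is_ribosomal[n_specific : n_specific + n_ribosomal] = True
    ko_only = np.zeros(n, dtype=bool)
    ko_only[n - n_ko_only :] = True  # tail of the non-specific block

    accessions = np.array([f"P{i:05d}" for i in range(n)])
    genes = np.array(
        [
            f"RPL{i:04d}" if is_ribosomal[i] else f"GENE{i:04d}"
            for i in range(n)
        ]
    )

    abundance_log2 = rng.normal(config.mean_log2_abundance, config.sd_log2_abundance, n)
    abundance_log2 = abundance_log2 + np.where(
        labels == NONSPECIFIC, config.nonspecific_abundance_log2, 0.0
    )

    # per-protein, per-genotype log2 multiplier relative to WT abundance
    offsets = {g.value: np.zeros(n) for g in GENOTYPES}
    offsets["ALA56"] = -true_effect  # log2(WT/Ala56) = true_effect
    with np.errstate(divide="ignore"):
        ko_specific = np.log2(config.ko_leak_frac) if config.ko_leak_frac > 0 else -np.inf
        offsets["KO"] = np.where(labels == SPECIFIC, ko_specific, np.log2(config.ko_enrichment))
    for col in ("WT", "ALA56"):
        offsets[col] = np.where(ko_only, -np.inf, offsets[col])

    depth = config.resolve_depth_bias(rng)
    shift = config.resolve_intensity_shift(rng)

    mean = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        mean[:, j] = np.exp2(abundance_log2 + offsets[s.genotype.value]) * depth[j]

    if config.count_dispersion == 0:
        counts = np.rint(mean).astype(np.int64)
    else:
        size = 1.0 / config.count_dispersion
        prob = size / (size + mean)
        counts = rng.negative_binomial(size, prob)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(accessions, name="accession"), columns=[s.sample_id for s in samples]
    )

    spectra = _draw_spectra(config, rng, counts, accessions, abundance_log2, offsets, shift, samples)

    annotations = [
        ProteinAnnotation(accessions[i], genes[i], bool(is_ribosomal[i])) for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "accession": accessions,
            "label": labels,
            "class": planted,
            "effect_log2": true_effect,
            "is_ribosomal": is_ribosomal,
        }
    )
    return SimulatedDataset(
        config=config,
        samples=samples,
        counts=ProteinQuantMatrix(SPECTRAL_COUNT, counts_df),
        spectra=spectra,
        annotations=annotations,
        truth=truth,
    )


def _draw_spectra(config, rng, counts, accessions, abundance_log2, offsets, shift, samples):
    """One spectrum per counted MS/MS event, plus shared-spectrum decoys."""
    protein_idx = []
    sample_idx = []
    for j in range(len(samples)):
        reps = counts[:, j]
        protein_idx.append(np.repeat(np.arange(len(accessions)), reps))
        sample_idx.append(np.full(int(reps.sum()), j))
    protein_idx = np.concatenate(protein_idx)
    sample_idx = np.concatenate(sample_idx)
    total = len(protein_idx)

    geno = np.array([s.genotype.value for s in samples])
    offset_mat = np.stack([offsets[g] for g in geno], axis=1)  # n x samples
    log2_i = (
        config.intensity_base_log2
        + abundance_log2[protein_idx]
        + offset_mat[protein_idx, sample_idx]
        + shift[sample_idx]
    )
    if config.intensity_sigma > 0:
        log2_i = log2_i + rng.normal(0.0, config.intensity_sigma, total)

    acc_col = accessions[protein_idx].astype(object)

    n_shared = int(round(total * config.frac_shared_spectra))
    if n_shared and total > 0:
        pick = rng.integers(0, total, n_shared)
        partner = accessions[rng.integers(0, len(accessions), n_shared)]
        shared_acc = np.array(
            [f"{acc_col[p]};{q}" if acc_col[p] != q else f"{acc_col[p]};P_DECOY" for p, q in zip(pick, partner)],
            dtype=object,
        )
        acc_col = np.concatenate([acc_col, shared_acc])
        sample_idx = np.concatenate([sample_idx, sample_idx[pick]])
        log2_shared = log2_i[pick]
        if config.intensity_sigma > 0:
            log2_shared = log2_shared + rng.normal(0.0, config.intensity_sigma, n_shared)
        log2_i = np.concatenate([log2_i, log2_shared])

    sample_ids = np.array([s.sample_id for s in samples])
    return pd.DataFrame(
        {
            "spectrum_id": [f"spec{k:08d}" for k in range(len(acc_col))],
            "sample_id": sample_ids[sample_idx],
            "accessions": acc_col,
            "intensity": np.exp2(log2_i),
        }
    )


# ---------------------------------------------------------------------------
# fixture bundle


@dataclass(frozen=True)
class BundleOptions:
    """Shape of the auxiliary gene-set and edge-list fixtures."""

    gmt_overlap_frac: float = 0.5  # fraction of planted-effect genes in the set
    gmt_filler_genes: int = 600  # background-only symbols padding the set
    n_modules: int = 2
    module_size: int = 10
    n_background_edges: int = 300


def write_fixture_bundle(
    outdir: str | Path,
    config: SimulationConfig,
    options: BundleOptions = BundleOptions(),
) -> dict[str, Path]:
    """Generate a dataset and write every input file the pipeline reads.

    Returns a name -> path mapping: counts, spectra, samples,
    annotations, gene_sets, edges, truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_interactome(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    paths = {
        "counts": outdir / "counts.tsv",
        "spectra": outdir / "spectra.tsv",
        "samples": outdir / "samples.tsv",
        "annotations": outdir / "annotations.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "edges": outdir / "edges.tsv",
        "truth": outdir / "truth.tsv",
    }
    io_formats.write_quant_table(data.counts, paths["counts"], genes=data.genes)
    io_formats.write_spectra(data.spectra, paths["spectra"])
    io_formats.write_sample_meta(data.samples, paths["samples"])
    io_formats.write_annotations(data.annotations, paths["annotations"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)

    io_formats.write_gmt(make_gene_sets(data, options, rng), paths["gene_sets"])
    io_formats.write_edges(make_edges(data, options, rng), paths["edges"], score_scale="unit")
    return paths


def make_gene_sets(data: SimulatedDataset, options: BundleOptions, rng) -> list[GeneSet]:
    truth = data.truth
    genes = data.genes
    planted = [genes[a] for a in truth.loc[truth["class"] != UNCHANGED, "accession"]]
    n_overlap = int(round(len(planted) * options.gmt_overlap_frac))
    chosen = list(rng.choice(planted, size=n_overlap, replace=False)) if n_overlap else []
    filler = [f"BGGENE{i:05d}" for i in range(options.gmt_filler_genes)]
    sets = [
        GeneSet("PLANTED_EFFECT", frozenset(chosen + filler), "planted-effect genes plus background"),
        GeneSet("DISJOINT_SET", frozenset(filler[: max(options.gmt_filler_genes // 2, 1)]), "no dataset genes"),
    ]
    return sets


def make_edges(data: SimulatedDataset, options: BundleOptions, rng):
    import networkx as nx

    truth = data.truth
    graph = nx.Graph()
    graph.add_nodes_from(truth["accession"])
    specific = truth.loc[truth["label"] == SPECIFIC, "accession"].to_numpy()

    # planted high-confidence modules (cliques) among specific interactors
    needed = options.n_modules * options.module_size
    if needed > len(specific):
        raise ValueError("not enough specific proteins to plant the requested modules")
    module_nodes = specific[:needed]
    for m in range(options.n_modules):
        block = module_nodes[m * options.module_size : (m + 1) * options.module_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                graph.add_edge(block[i], block[j], score=float(rng.uniform(0.92, 0.99)))

    # low-confidence background edges (below the 0.9 cutoff)
    nodes = truth["accession"].to_numpy()
    added = 0
    while added < options.n_background_edges:
        u, v = rng.choice(nodes, size=2, replace=False)
        if graph.has_edge(u, v):
            continue
        graph.add_edge(u, v, score=float(rng.uniform(0.15, 0.85)))
        added += 1
    return graph


def read_truth_table(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", comment="#")
    truth["is_ribosomal"] = truth["is_ribosomal"].astype(bool)
    return truth
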