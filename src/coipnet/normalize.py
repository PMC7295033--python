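"""Label-free quantification normalization and replicate averaging.

Two independent abundance proxies are carried through the pipeline:

* **Spectral counts** — per-sample totals are equalized by scaling each
  sample to the grand-mean total (the classic total-spectrum-count
  normalization).
* **Precursor ion intensities** — spectrum records are pruned of
  multi-protein matches, log2-transformed, and iteratively
  median-centered across samples; each protein's per-sample value is
  the median of its surviving spectra.

Replicate averaging differs by method: arithmetic mean for counts,
median of present values for intensities (an intensity average over an
empty set stays absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    GENOTYPES,
    ION_INTENSITY,
    SPECTRAL_COUNT,
    GenotypeSummary,
    ProteinQuantMatrix,
    SampleMeta,
    SpectrumEntry,
    validate_samples,
)
from .io import spectra_frame


@dataclass
class NormalizationReport:
    """Machine-readable record of what normalization did."""

    method: str
    scale_factors: dict[str, float] = field(default_factory=dict)  # spectral counts
    log2_offsets: dict[str, float] = field(default_factory=dict)  # intensities
    iterations: int = 0
    n_spectra_total: int = 0
    n_spectra_pruned_shared: int = 0
    averaging: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scale_factors": dict(self.scale_factors),
            "log2_offsets": dict(self.log2_offsets),
            "iterations": self.iterations,
            "n_spectra_total": self.n_spectra_total,
            "n_spectra_pruned_shared": self.n_spectra_pruned_shared,
            "averaging": self.averaging,
        }


def normalize_spectral_counts(
    matrix: ProteinQuantMatrix,
) -> tuple[ProteinQuantMatrix, NormalizationReport]:
    """Scale each sample by (grand mean of sample totals) / (its total).

    Post-normalization, every sample's total equals the grand mean, so
    the overall sum of the matrix is conserved.
    """
    if matrix.method != SPECTRAL_COUNT:
        raise ValueError("normalize_spectral_counts expects a spectral_count matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cannot scale sample(s) with zero total counts: {zero}")
    factors = totals.mean() / totals
    normalized = matrix.values.mul(factors, axis=1)
    report = NormalizationReport(
        method=SPECTRAL_COUNT,
        scale_factors={s: float(f) for s, f in factors.items()},
        averaging="mean",
    )
    return ProteinQuantMatrix(SPECTRAL_COUNT, normalized), report


def normalize_intensities(
    spectra: pd.DataFrame | Iterable[SpectrumEntry],
    meta: Sequence[SampleMeta],
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[ProteinQuantMatrix, NormalizationReport]:
    """Prune shared spectra, log2-transform, median-center, summarize.

    1. Drop every spectrum assigned to more than one protein.
    2. log2-transform the remaining intensities.
    3. Iteratively subtract each sample's median until the largest
       per-sample shift falls below ``tol`` (error at ``max_iter``).
    4. Summarize each protein in each sample as the median of its
       spectra; proteins with no surviving spectrum in a sample are
       absent (NaN) there.
    """
    validate_samples(meta)
    df = spectra_frame(spectra)
    known = {s.sample_id for s in meta}
    bad = set(df["sample_id"]) - known
    if bad:
        raise ValueError(f"unknown sample_id(s) in spectra: {sorted(bad)}")
    if (df["intensity"] <= 0).any():
        raise ValueError("spectrum intensities must be positive")

    n_total = len(df)
    shared = df["accessions"].str.contains(";", regex=False)
    df = df.loc[~shared].copy()
    n_pruned = int(shared.sum())
    if df.empty:
        raise ValueError("no spectra survive multi-protein pruning")

    df["log2_intensity"] = np.log2(df["intensity"].to_numpy(dtype=float))

    offsets = {s.sample_id: 0.0 for s in meta}
    report = NormalizationReport(
        method=ION_INTENSITY,
        n_spectra_total=n_total,
        n_spectra_pruned_shared=n_pruned,
        averaging="median",
    )
    iterations = 0
    while True:
        medians = df.groupby("sample_id")["log2_intensity"].median()
        if medians.abs().max() < tol:
            break
        if iterations >= max_iter:
            report.iterations = iterations
            report.log2_offsets = offsets
            raise RuntimeError(
                f"intensity normalization did not converge in {max_iter} iterations "
                f"(largest residual median {medians.abs().max():.3g}); report: {report.to_dict()}"
            )
        df["log2_intensity"] = df["log2_intensity"] - df["sample_id"].map(medians).fillna(0.0)
        for sid, m in medians.items():
            offsets[sid] += float(m)
        iterations += 1
    report.iterations = iterations
    report.log2_offsets = {k: float(v) for k, v in offsets.items()}

    summary = (
        df.groupby(["accessions", "sample_id"])["log2_intensity"].median().unstack("sample_id")
    )
    summary.index.name = "accession"
    summary = summary.reindex(columns=[s.sample_id for s in meta])
    return ProteinQuantMatrix(ION_INTENSITY, summary), report


def average_replicates(
    matrix: ProteinQuantMatrix, meta: Sequence[SampleMeta]
) -> GenotypeSummary:
    """Average replicates within each genotype.

    Spectral counts use the arithmetic mean; intensities use the median
    of present values (NaN if the protein is absent from every
    replicate of the genotype).
    """
    validate_samples(meta, require_all_genotypes=True)
    by_id = {s.sample_id: s for s in meta}
    missing = [c for c in matrix.sample_ids if c not in by_id]
    if missing:
        raise ValueError(f"sample column(s) without metadata: {missing}")

    columns = {}
    for genotype in GENOTYPES:
        cols = [c for c in matrix.sample_ids if by_id[c].genotype is genotype]
        if not cols:
            raise ValueError(f"genotype {genotype.value} has no sample columns in the matrix")
        block = matrix.values[cols]
        if matrix.method == SPECTRAL_COUNT:
            columns[genotype.value] = block.mean(axis=1)
        else:
            columns[genotype.value] = block.median(axis=1, skipna=True)
    summary = pd.DataFrame(columns, index=matrix.accessions)
    return GenotypeSummary(matrix.method, summary)
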