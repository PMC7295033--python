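"""Core in-memory containers shared across pipeline stages.

The pipeline quantifies bait-associated proteins under two label-free
methods — spectral counts (integer MS/MS evidence counts, linear scale)
and precursor ion intensities (MS1 signal, kept on the log2 scale) —
across three genotypes: wild type (WT), the gain-of-function variant
(ALA56), and the transporter knockout (KO) negative control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPECTRAL_COUNT = "spectral_count"
ION_INTENSITY = "ion_intensity"
METHODS = (SPECTRAL_COUNT, ION_INTENSITY)


class Genotype(str, enum.Enum):
    """Experimental genotype of an immunoprecipitation sample."""

    WT = "WT"
    ALA56 = "ALA56"
    KO = "KO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GENOTYPES = (Genotype.WT, Genotype.ALA56, Genotype.KO)


@dataclass(frozen=True)
class SampleMeta:
    """One IP sample: a (genotype, technical replicate) pair."""

    sample_id: str
    genotype: Genotype
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        if self.replicate < 1:
            raise ValueError(
                f"replicate must be a positive integer, got {self.replicate}"
            )


def validate_samples(samples: Sequence[SampleMeta], require_all_genotypes: bool = False) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    if require_all_genotypes:
        present = {s.genotype for s in samples}
        missing = [g.value for g in GENOTYPES if g not in present]
        if missing:
            raise ValueError(f"genotype(s) absent from sample metadata: {missing}")


@dataclass(frozen=True)
class ProteinAnnotation:
    """Static per-protein annotation used by the specificity filter."""

    accession: str
    gene: str
    is_ribosomal: bool = False
    known_sip: bool = False


@dataclass(frozen=True)
class SpectrumEntry:
    """One quantified MS/MS spectrum.

    ``accessions`` lists every protein the spectrum matched; spectra
    matched to more than one protein are pruned before quantification.
    """

    spectrum_id: str
    sample_id: str
    accessions: tuple[str, ...]
    intensity: float

    def __post_init__(self) -> None:
        if isinstance(self.accessions, str):
            object.__setattr__(self, "accessions", tuple(self.accessions.split(";")))
        else:
            object.__setattr__(self, "accessions", tuple(self.accessions))
        if len(self.accessions) < 1:
            raise ValueError("spectrum must match at least one protein")
        if not self.intensity > 0:
            raise ValueError(f"intensity must be positive, got {self.intensity}")


@dataclass
class ProteinQuantMatrix:
    """Protein x sample quantities under one quantification method.

    Missing-value conventions: an unobserved spectral count is a genuine
    zero; an unobserved intensity is absent (NaN), never zero.  Intensity
    values are log2-scale after normalization.
    """

    method: str
    values: pd.DataFrame  # index: accession, columns: sample_id

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown quantification method: {self.method!r}")
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate accession(s): {dups}")
        vals = self.values.to_numpy(dtype=float)
        if self.method == SPECTRAL_COUNT:
            if np.isnan(vals).any():
                raise ValueError("spectral-count matrix may not contain missing values")
            # counts are linear-scale and non-negative; log2 intensities
            # may go negative after median centering
            if vals.size and np.nanmin(vals) < 0:
                raise ValueError("spectral counts must be non-negative")

    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(self.method, self.values.copy())


@dataclass
class GenotypeSummary:
    """Replicate-averaged quantity per protein and genotype.

    Columns are WT / ALA56 / KO.  For intensities, NaN marks a protein
    absent from every replicate of that genotype.
    """

    method: str
    values: pd.DataFrame  # index: accession, columns: WT, ALA56, KO

    def __post_init__(self) -> None:
        want = [g.value for g in GENOTYPES]
        if list(self.values.columns) != want:
            self.values = self.values.reindex(columns=want)

    @property
    def accessions(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; members are upper-cased for cross-species matching."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        members = frozenset(m.upper() for m in self.members if m)
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)


def annotations_frame(annotations: Iterable[ProteinAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, indexed by accession (must be unique)."""
    rows = list(annotations)
    df = pd.DataFrame(
        {
            "accession": [a.accession for a in rows],
            "gene": [a.gene for a in rows],
            "is_ribosomal": [bool(a.is_ribosomal) for a in rows],
            "known_sip": [bool(a.known_sip) for a in rows],
        }
    ).set_index("accession")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate annotation accession(s): {dups}")
    return df
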