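"""Readers and writers for every on-disk format the pipeline touches.

All tabular files are UTF-8, tab-separated, with ``#`` comment lines
skipped.  Parsers validate and reject rather than silently coerce:
unknown sample columns, duplicate accessions, negative quantities and
malformed lines are errors (with line numbers where applicable).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ION_INTENSITY,
    SPECTRAL_COUNT,
    GeneSet,
    Genotype,
    ProteinAnnotation,
    ProteinQuantMatrix,
    SampleMeta,
    SpectrumEntry,
    validate_samples,
)

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False, encoding="utf-8")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, **_READ_KW)


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path)
    for col in ("sample_id", "genotype", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    samples = [
        SampleMeta(row.sample_id, Genotype(row.genotype), int(row.replicate))
        for row in df.itertuples()
    ]
    validate_samples(samples)
    return samples


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype.value for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein annotations


def read_annotations(path: str | Path) -> list[ProteinAnnotation]:
    df = _read_tsv(path)
    for col in ("accession", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    seen: set[str] = set()
    out: list[ProteinAnnotation] = []
    truthy = {"1", "true", "True", "TRUE"}
    for row in df.itertuples():
        if row.accession in seen:
            raise ValueError(f"{path}: duplicate accession {row.accession!r}")
        seen.add(row.accession)
        out.append(
            ProteinAnnotation(
                accession=row.accession,
                gene=row.gene,
                is_ribosomal=getattr(row, "is_ribosomal", "0") in truthy,
                known_sip=getattr(row, "known_sip", "0") in truthy,
            )
        )
    return out


def write_annotations(annotations: Sequence[ProteinAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "accession": [a.accession for a in annotations],
            "gene": [a.gene for a in annotations],
            "is_ribosomal": [int(a.is_ribosomal) for a in annotations],
            "known_sip": [int(a.known_sip) for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quantification tables


def read_quant_table(
    path: str | Path, meta: Sequence[SampleMeta], method: str = SPECTRAL_COUNT
) -> ProteinQuantMatrix:
    """Read a protein-level quant TSV (columns: accession, gene, <sample ids>).

    Empty cells follow the method's missing-value convention: 0 for
    spectral counts, absent (NaN) for intensities.  Any other
    unparseable numeric cell is an error.
    """
    df = _read_tsv(path)
    if "accession" not in df.columns:
        raise ValueError(f"{path}: missing required column 'accession'")
    known = {s.sample_id for s in meta}
    sample_cols = [c for c in df.columns if c not in ("accession", "gene")]
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(f"{path}: unknown sample column(s) {unknown}")
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate accession {dup.iloc[0]!r}")

    fill = 0.0 if method == SPECTRAL_COUNT else np.nan
    values = pd.DataFrame(index=pd.Index(df["accession"], name="accession"))
    for col in sample_cols:
        raw = df[col].str.strip()
        try:
            num = pd.to_numeric(raw.mask(raw == ""))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: unparseable value in column {col!r}: {exc}") from exc
        values[col] = num.fillna(fill).to_numpy() if method == SPECTRAL_COUNT else num.to_numpy()
    if (values.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative quantity encountered")
    return ProteinQuantMatrix(method, values)


def write_quant_table(
    matrix: ProteinQuantMatrix,
    path: str | Path,
    genes: Mapping[str, str] | None = None,
) -> None:
    df = matrix.values.copy()
    df.insert(0, "gene", [genes.get(a, "") if genes else "" for a in df.index])
    df.to_csv(path, sep="\t", index=True, index_label="accession", na_rep="")


# ---------------------------------------------------------------------------
# spectrum-level intensity records


def read_spectra(path: str | Path, meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Read spectrum records (spectrum_id, sample_id, accessions, intensity).

    ``accessions`` is a ';'-joined list; spectra matching several
    proteins are retained here and pruned during normalization.
    """
    df = _read_tsv(path)
    for col in ("spectrum_id", "sample_id", "accessions", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    known = {s.sample_id for s in meta}
    bad = set(df["sample_id"]) - known
    if bad:
        raise ValueError(f"{path}: unknown sample_id(s) {sorted(bad)}")
    intensity = pd.to_numeric(df["intensity"])
    if (intensity <= 0).any():
        i = int(np.argmax(intensity.to_numpy() <= 0))
        raise ValueError(f"{path}: non-positive intensity for spectrum {df['spectrum_id'].iloc[i]!r}")
    out = df[["spectrum_id", "sample_id", "accessions"]].copy()
    out["intensity"] = intensity.astype(float)
    return out


def write_spectra(spectra: pd.DataFrame | Iterable[SpectrumEntry], path: str | Path) -> None:
    df = spectra_frame(spectra)
    df.to_csv(path, sep="\t", index=False)


def spectra_frame(spectra: pd.DataFrame | Iterable[SpectrumEntry]) -> pd.DataFrame:
    """Coerce spectrum records to the canonical DataFrame form."""
    if isinstance(spectra, pd.DataFrame):
        return spectra
    rows = list(spectra)
    return pd.DataFrame(
        {
            "spectrum_id": [s.spectrum_id for s in rows],
            "sample_id": [s.sample_id for s in rows],
            "accessions": [";".join(s.accessions) for s in rows],
            "intensity": [s.intensity for s in rows],
        }
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, description, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, members=frozenset(members), description=description))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# weighted edge lists (STRING-export dialect)

SCORE_SCALES = {"unit": 1.0, "thousand": 1000.0}


def read_edges(path: str | Path, score_scale: str) -> nx.Graph:
    """Read a protein1/protein2/combined_score TSV into a weighted graph.

    ``score_scale`` is mandatory and explicit: 'unit' for scores already
    in [0,1], 'thousand' for STRING's 0-1000 integers.  Duplicate edges
    keep the maximum score; self-loops are rejected.
    """
    if score_scale not in SCORE_SCALES:
        raise ValueError(f"score_scale must be one of {sorted(SCORE_SCALES)}")
    divisor = SCORE_SCALES[score_scale]
    graph = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        header: list[str] | None = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:3] != ["protein1", "protein2", "combined_score"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header protein1/protein2/combined_score"
                    )
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw) / divisor
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable score {raw!r}") from exc
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside [0,1] under {score_scale!r} scale"
                )
            if graph.has_edge(u, v):
                score = max(score, graph.edges[u, v]["score"])
            graph.add_edge(u, v, score=score)
    if header is None:
        raise ValueError(f"{path}: empty edge file")
    return graph


def write_edges(graph: nx.Graph, path: str | Path, score_scale: str = "unit") -> None:
    if score_scale not in SCORE_SCALES:
        raise ValueError(f"score_scale must be one of {sorted(SCORE_SCALES)}")
    mult = SCORE_SCALES[score_scale]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(graph.edges(data=True)):
            score = data["score"] * mult
            text = f"{score:.0f}" if score_scale == "thousand" else f"{score:.6g}"
            handle.write(f"{u}\t{v}\t{text}\n")


# ---------------------------------------------------------------------------
# run report


def write_report(report: Mapping, outdir: str | Path) -> Path:
    """Write the JSON run report (and return its path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, allow_nan=False, default=_jsonable)
        handle.write("\n")
    return path


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
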