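"""Knockout-control specificity filtering.

A protein is removed from the interactor list when any of the
following holds, otherwise it is kept:

* **KO_ONLY** — detected only in knockout samples (zero/absent in all
  WT and variant averages under both quantification methods).
* **KO_ENRICHED_VS_WT / KO_ENRICHED_VS_ALA56** — the knockout average
  is at least ``r`` times (default 1.5, inclusive) the WT or variant
  average under either method.  Intensity ratios are computed as
  ``2**(KO_log2 - other_log2)``.  A zero/absent denominator with a
  detected KO counts as enriched (ratio +inf) — the limiting case of
  KO-only detection — with no pseudocount.
* **RIBOSOMAL** — annotated as a ribosomal protein (translation
  machinery, removed regardless of quantification).

Decisions depend only on a protein's own replicate-averaged rows and
annotation, so the kept set is non-decreasing in ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ION_INTENSITY,
    SPECTRAL_COUNT,
    GenotypeSummary,
    ProteinAnnotation,
    annotations_frame,
)

KO_ONLY = "KO_ONLY"
KO_ENRICHED_VS_WT = "KO_ENRICHED_VS_WT"
KO_ENRICHED_VS_ALA56 = "KO_ENRICHED_VS_ALA56"
RIBOSOMAL = "RIBOSOMAL"
REASONS = (KO_ONLY, KO_ENRICHED_VS_WT, KO_ENRICHED_VS_ALA56, RIBOSOMAL)


@dataclass(frozen=True)
class FilterDecision:
    accession: str
    kept: bool
    reasons: frozenset[str]
    methods: frozenset[str]  # quantification method(s) triggering removal

    def __post_init__(self) -> None:
        if self.kept != (not self.reasons):
            raise ValueError("kept must be equivalent to an empty reason set")


def _as_annotation_frame(
    annotations: pd.DataFrame | Sequence[ProteinAnnotation] | Mapping[str, ProteinAnnotation],
) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        return annotations
    if isinstance(annotations, Mapping):
        annotations = list(annotations.values())
    return annotations_frame(annotations)


def filter_specific(
    summary_sc: GenotypeSummary,
    summary_ii: GenotypeSummary,
    annotations: pd.DataFrame | Sequence[ProteinAnnotation],
    r: float = 1.5,
) -> list[FilterDecision]:
    """Apply the knockout elimination rules to the shared protein universe."""
    if r <= 0:
        raise ValueError("ratio threshold r must be positive")
    if summary_sc.method != SPECTRAL_COUNT or summary_ii.method != ION_INTENSITY:
        raise ValueError("expected (spectral_count, ion_intensity) summaries")
    if set(summary_sc.accessions) != set(summary_ii.accessions):
        raise ValueError("summaries cover different protein universes")
    ann = _as_annotation_frame(annotations)

    sc = summary_sc.values
    ii = summary_ii.values.reindex(summary_sc.accessions)

    wt_c, al_c, ko_c = (sc[g].to_numpy(float) for g in ("WT", "ALA56", "KO"))
    wt_i, al_i, ko_i = (ii[g].to_numpy(float) for g in ("WT", "ALA56", "KO"))

    present_wt = (wt_c > 0) | ~np.isnan(wt_i)
    present_al = (al_c > 0) | ~np.isnan(al_i)
    present_ko = (ko_c > 0) | ~np.isnan(ko_i)
    ko_only = present_ko & ~present_wt & ~present_al

    log2_r = np.log2(r)

    def enriched_counts(other: np.ndarray) -> np.ndarray:
        return (ko_c > 0) & ((other == 0) | (ko_c >= r * other))

    def enriched_intensity(other: np.ndarray) -> np.ndarray:
        ko_present = ~np.isnan(ko_i)
        with np.errstate(invalid="ignore"):
            ratio_hit = (ko_i - other) >= log2_r
        return ko_present & (np.isnan(other) | ratio_hit)

    enr_wt_sc = enriched_counts(wt_c)
    enr_al_sc = enriched_counts(al_c)
    enr_wt_ii = enriched_intensity(wt_i)
    enr_al_ii = enriched_intensity(al_i)

    ribosomal = (
        ann["is_ribosomal"].reindex(summary_sc.accessions).fillna(False).to_numpy(bool)
        if "is_ribosomal" in ann.columns
        else np.zeros(len(sc), dtype=bool)
    )

    decisions: list[FilterDecision] = []
    for i, accession in enumerate(summary_sc.accessions):
        reasons: set[str] = set()
        methods: set[str] = set()
        if ko_only[i]:
            reasons.add(KO_ONLY)
            methods |= {SPECTRAL_COUNT, ION_INTENSITY}
        if enr_wt_sc[i] or enr_wt_ii[i]:
            reasons.add(KO_ENRICHED_VS_WT)
        if enr_al_sc[i] or enr_al_ii[i]:
            reasons.add(KO_ENRICHED_VS_ALA56)
        if enr_wt_sc[i] or enr_al_sc[i]:
            methods.add(SPECTRAL_COUNT)
        if enr_wt_ii[i] or enr_al_ii[i]:
            methods.add(ION_INTENSITY)
        if ribosomal[i]:
            reasons.add(RIBOSOMAL)
        decisions.append(
            FilterDecision(
                accession=str(accession),
                kept=not reasons,
                reasons=frozenset(reasons),
                methods=frozenset(methods),
            )
        )
    return decisions


def filter_funnel(decisions: Sequence[FilterDecision]) -> dict:
    """Stage-count summary: input, kept, removed, and per-reason counts.

    A removed protein may carry several reasons, so per-reason counts
    can sum to more than ``n_removed``; ``n_removed_multiple_reasons``
    accounts for the overlap.
    """
    n_input = len(decisions)
    n_kept = sum(d.kept for d in decisions)
    by_reason = {reason: 0 for reason in REASONS}
    n_multi = 0
    for d in decisions:
        for reason in d.reasons:
            by_reason[reason] += 1
        if len(d.reasons) > 1:
            n_multi += 1
    return {
        "n_input": n_input,
        "n_kept": n_kept,
        "n_removed": n_input - n_kept,
        "removed_by_reason": by_reason,
        "n_removed_multiple_reasons": n_multi,
    }


def decisions_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Tabular form of the filter decisions for the funnel TSV."""
    return pd.DataFrame(
        {
            "accession": [d.accession for d in decisions],
            "kept": [int(d.kept) for d in decisions],
            "reasons": [";".join(sorted(d.reasons)) for d in decisions],
            "methods": [";".join(sorted(d.methods)) for d in decisions],
        }
    )
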