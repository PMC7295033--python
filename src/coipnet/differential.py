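"""Differential interaction analysis between WT and variant genotypes.

For every specific interactor the log2(WT/Ala56) fold change is
computed under both quantification methods.  The three-way category —
increased / decreased / unchanged association with the variant — is
driven by the ion-intensity fold change with a symmetric threshold
``t`` (default 0.5, closed interval for "unchanged"):

* log2fc < -t  -> INCREASED_ALA56 (more of the protein co-purifies
  with the variant),
* log2fc >  t  -> DECREASED_ALA56,
* otherwise    -> UNCHANGED.

Spectral counts contribute two flags: ``discordant`` (the two methods
land in different categories) and ``nominated`` (a difference present
by at least one method).  Replicate-level differences are additionally
tested with a two-sided Mann-Whitney U test at an unadjusted 0.05
level; with only three replicates per genotype the exact test can
never reach p < 0.05 (its minimum two-sided p is 0.1), so the normal
approximation is the default mode and the exact mode warns when that
floor collides with the 0.05 flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    ION_INTENSITY,
    SPECTRAL_COUNT,
    GenotypeSummary,
    Genotype,
    ProteinQuantMatrix,
    SampleMeta,
)

INCREASED_ALA56 = "INCREASED_ALA56"
DECREASED_ALA56 = "DECREASED_ALA56"
UNCHANGED = "UNCHANGED"
CATEGORIES = (INCREASED_ALA56, DECREASED_ALA56, UNCHANGED)

_EXACT_ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class FoldChangeRecord:
    accession: str
    log2fc_sc: float  # NaN when undefined
    log2fc_ii: float
    mw_p_sc: float = float("nan")
    mw_p_ii: float = float("nan")


@dataclass(frozen=True)
class InteractionClass:
    accession: str
    category: str
    discordant: bool
    nominated: bool


def log2_fold_change(
    wt_avg: float, ala56_avg: float, pseudocount: float = 0.5, method: str = SPECTRAL_COUNT
) -> float:
    """log2(WT/Ala56) for one protein; NaN when undefined (both absent).

    Counts: ``log2((wt + c) / (ala56 + c))`` with pseudocount ``c``;
    with ``c == 0`` a single-sided zero yields an infinite fold change.
    Intensities are already log2-scale, so the fold change is the plain
    difference of the genotype averages and is undefined if either is
    absent.
    """
    if method == SPECTRAL_COUNT:
        if wt_avg < 0 or ala56_avg < 0:
            raise ValueError("spectral-count averages must be non-negative")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if wt_avg == 0 and ala56_avg == 0:
            return float("nan")
        num, den = wt_avg + pseudocount, ala56_avg + pseudocount
        if den == 0:
            return float("inf")
        if num == 0:
            return float("-inf")
        return float(np.log2(num / den))
    if method == ION_INTENSITY:
        if math.isnan(wt_avg) or math.isnan(ala56_avg):
            return float("nan")
        return float(wt_avg - ala56_avg)
    raise ValueError(f"unknown method {method!r}")


def classify(
    record: FoldChangeRecord | None = None,
    t: float = 0.5,
    *,
    log2fc_ii: float | None = None,
    log2fc_sc: float | None = None,
    accession: str = "",
) -> InteractionClass:
    """Three-way category from the ion-intensity fold change.

    ``discordant`` is true when the spectral-count fold change falls in
    a different category under the same rule; ``nominated`` is true
    when either method's value lies outside the [-t, t] band.
    """
    if record is not None:
        accession = record.accession
        log2fc_ii = record.log2fc_ii
        log2fc_sc = record.log2fc_sc
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    if log2fc_ii is None or math.isnan(log2fc_ii):
        raise ValueError(f"ion-intensity fold change undefined for {accession!r}")

    def band(fc: float) -> str:
        if fc < -t:
            return INCREASED_ALA56
        if fc > t:
            return DECREASED_ALA56
        return UNCHANGED

    category = band(log2fc_ii)
    sc_defined = log2fc_sc is not None and not math.isnan(log2fc_sc)
    discordant = sc_defined and band(log2fc_sc) != category
    nominated = category != UNCHANGED or (sc_defined and band(log2fc_sc) != UNCHANGED)
    return InteractionClass(accession, category, bool(discordant), bool(nominated))


def mann_whitney(
    xs: Sequence[float], ys: Sequence[float], mode: str = "normal"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic, p-value).

    ``mode='exact'`` enumerates the permutation null (tie-aware; group
    sizes up to C(n1+n2, n1) <= 200k, or any size for tie-free data via
    the exact U distribution).  ``mode='normal'`` uses the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if np.ptp(pooled) == 0:  # every value identical: no evidence either way
        return u_obs, 1.0

    if mode == "normal":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if mode != "exact":
        raise ValueError("mode must be 'normal' or 'exact'")

    if min(n1, n2) == 3 and max(n1, n2) == 3:
        warnings.warn(
            "exact Mann-Whitney with 3 vs 3 replicates cannot reach p < 0.05 "
            "(minimum two-sided p is 0.1)",
            stacklevel=2,
        )
    mu = n1 * n2 / 2
    if math.comb(n1 + n2, n1) <= _EXACT_ENUMERATION_LIMIT:
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        base = n1 * (n1 + 1) / 2
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            hits += abs(u - mu) >= dev_obs - 1e-12
            total += 1
        return u_obs, hits / total
    if np.unique(pooled).size == pooled.size:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(
        "exact mode with ties requires C(n1+n2, n1) <= "
        f"{_EXACT_ENUMERATION_LIMIT}; use mode='normal'"
    )


def category_tally(categories: Iterable[str]) -> dict:
    """Counts and 2-decimal percentages per category (sums to total)."""
    cats = list(categories)
    total = len(cats)
    counts = {c: 0 for c in CATEGORIES}
    for c in cats:
        if c not in counts:
            raise ValueError(f"unknown category {c!r}")
        counts[c] += 1
    percentages = {
        c: round(100.0 * n / total, 2) if total else 0.0 for c, n in counts.items()
    }
    return {"total": total, "counts": counts, "percentages": percentages}


def differential_table(
    summary_sc: GenotypeSummary,
    summary_ii: GenotypeSummary,
    sc_matrix: ProteinQuantMatrix,
    ii_matrix: ProteinQuantMatrix,
    meta: Sequence[SampleMeta],
    accessions: Sequence[str] | None = None,
    pseudocount: float = 0.5,
    t: float = 0.5,
    mw_mode: str = "normal",
    genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-protein fold changes, Mann-Whitney p-values and categories.

    ``accessions`` restricts the table (e.g. to specificity-filtered
    proteins).  Proteins whose ion-intensity fold change is undefined
    get category ``""`` and are excluded from downstream tallies; the
    ``category_defined`` column records the exclusion.  BH q-values are
    reported per method for reference and never gate classification.
    """
    if accessions is None:
        accessions = list(summary_sc.accessions)
    by_id = {s.sample_id: s for s in meta}
    wt_cols = [c for c in sc_matrix.sample_ids if by_id[c].genotype is Genotype.WT]
    al_cols = [c for c in sc_matrix.sample_ids if by_id[c].genotype is Genotype.ALA56]
    wt_cols_ii = [c for c in ii_matrix.sample_ids if by_id[c].genotype is Genotype.WT]
    al_cols_ii = [c for c in ii_matrix.sample_ids if by_id[c].genotype is Genotype.ALA56]

    rows = []
    for acc in accessions:
        fc_sc = log2_fold_change(
            float(summary_sc.values.at[acc, "WT"]),
            float(summary_sc.values.at[acc, "ALA56"]),
            pseudocount,
            SPECTRAL_COUNT,
        )
        if acc in summary_ii.values.index:
            fc_ii = log2_fold_change(
                float(summary_ii.values.at[acc, "WT"]),
                float(summary_ii.values.at[acc, "ALA56"]),
                pseudocount,
                ION_INTENSITY,
            )
        else:
            fc_ii = float("nan")

        p_sc = _mw_or_nan(
            sc_matrix.values.loc[acc, wt_cols], sc_matrix.values.loc[acc, al_cols], mw_mode
        )
        if acc in ii_matrix.values.index:
            xs = ii_matrix.values.loc[acc, wt_cols_ii].dropna()
            ys = ii_matrix.values.loc[acc, al_cols_ii].dropna()
            p_ii = _mw_or_nan(xs, ys, mw_mode)
        else:
            p_ii = float("nan")

        if math.isnan(fc_ii):
            category, discordant, nominated, defined = "", False, False, False
        else:
            cls = classify(log2fc_ii=fc_ii, log2fc_sc=fc_sc, t=t, accession=acc)
            category, discordant, nominated, defined = (
                cls.category,
                cls.discordant,
                cls.nominated,
                True,
            )
        rows.append(
            {
                "accession": acc,
                "gene": (genes or {}).get(acc, ""),
                "log2fc_sc": fc_sc,
                "log2fc_ii": fc_ii,
                "mw_p_sc": p_sc,
                "mw_p_ii": p_ii,
                "category": category,
                "category_defined": defined,
                "discordant": discordant,
                "nominated": nominated,
            }
        )
    table = pd.DataFrame(rows)
    for col in ("mw_p_sc", "mw_p_ii"):
        table[f"bh_q{col[4:]}"] = _bh_with_nan(table[col].to_numpy())
    return table


def _mw_or_nan(xs, ys, mode: str) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    xs = xs[~np.isnan(xs)]
    ys = ys[~np.isnan(ys)]
    if xs.size == 0 or ys.size == 0:
        return float("nan")
    return mann_whitney(xs, ys, mode=mode)[1]


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
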