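"""Gene-set overlap statistics and the genotype-bias chi-square test.

Overlap between the interactor list and an external gene set is scored
with the one-sided (upper-tail) hypergeometric test, identical to a
one-sided Fisher exact test on the 2x2 table.  The background
population size ``N`` must be explicit: it defaults to 16918, the size
of the mouse UniProt release searched during protein identification,
and is echoed in every result so the choice is auditable.  Gene-symbol
matching is case-insensitive (mouse/human symbol case differs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSet

DEFAULT_BACKGROUND_N = 16918


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    n: int  # query list size
    K: int  # gene-set size
    N: int  # background size
    p: float
    q: float = float("nan")  # BH q across the tested family

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("overlap k must satisfy 0 <= k <= min(n, K)")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


def hypergeometric_overlap(
    list_genes: Iterable[str], gene_set: GeneSet, background_n: int = DEFAULT_BACKGROUND_N
) -> EnrichmentResult:
    """P[X >= k] for the overlap k between the query list and the set."""
    query = {g.upper() for g in list_genes if g}
    members = gene_set.members  # already upper-cased
    n, K = len(query), len(members)
    union = len(query | members)
    if background_n < union:
        raise ValueError(
            f"background N={background_n} smaller than the observed union ({union})"
        )
    k = len(query & members)
    p = float(stats.hypergeom.sf(k - 1, background_n, K, n))
    return EnrichmentResult(gene_set.name, k, n, K, background_n, min(p, 1.0))


def enrich_sets(
    list_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background_n: int = DEFAULT_BACKGROUND_N,
) -> list[EnrichmentResult]:
    """Test every set and attach BH q-values across the family."""
    query = {g.upper() for g in list_genes if g}
    results = [hypergeometric_overlap(query, gs, background_n) for gs in gene_sets]
    if results:
        qvals = bh_fdr([r.p for r in results])
        results = [
            EnrichmentResult(r.set_name, r.k, r.n, r.K, r.N, r.p, float(q))
            for r, q in zip(results, qvals)
        ]
    return results


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit: returns (statistic, df, upper-tail p).

    ``expected=None`` means a uniform split of the observed total.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two cells")
    if expected is None:
        exp = np.full(obs.shape, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValueError("observed and expected must have the same length")
        if not np.isclose(obs.sum(), exp.sum()):
            raise ValueError("observed and expected totals must match")
    if (exp <= 0).any():
        raise ValueError("expected counts must be strictly positive")
    statistic, p = stats.chisquare(obs, exp)
    return float(statistic), obs.size - 1, float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
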