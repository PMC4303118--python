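"""Hypergeometric gene-set over-representation with BH correction.

One-sided upper-tail test: for a gene set with K members inside the
background of N genes and a foreground of n genes hitting k of them,
p = P(X >= k) under Hypergeometric(N, K, n).  Adjustment is
Benjamini-Hochberg across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import GeneSet

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # foreground hits
    K: int  # set size within background
    n: int  # foreground size
    N: int  # background size
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise EnrichmentError(f"inconsistent counts for {self.set_name!r}")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for Hypergeometric(N, K, n)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    gene_sets: Sequence[GeneSet],
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the foreground.

    Symbols are uppercased for matching.  Gene sets are intersected with the
    background first; sets with an empty intersection are skipped (logged).
    Results come back sorted by adjusted then raw p.
    """
    bg = {g.upper() for g in background}
    fg = {g.upper() for g in foreground}
    stray = fg - bg
    if stray:
        raise EnrichmentError(
            f"foreground gene(s) absent from background: {sorted(stray)[:10]}"
        )
    N, n = len(bg), len(fg)

    rows: list[tuple[str, int, int]] = []
    for gs in gene_sets:
        members = gs.members & bg
        if not members:
            logger.info("enrich: set %r has no background overlap, skipped", gs.set_name)
            continue
        rows.append((gs.set_name, len(fg & members), len(members)))

    if not rows:
        return []
    p_raw = [hypergeom_pvalue(k, K, n, N) for (_, k, K) in rows]
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    results = [
        EnrichmentResult(name, k, K, n, N, float(pr), float(pa))
        for (name, k, K), pr, pa in zip(rows, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.set_name))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """All count columns are emitted so every p is externally recomputable."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
            }
            for r in results
        ]
    )
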