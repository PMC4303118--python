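"""Descriptive cross-cutting summaries: hierarchical clustering, tri-set
overlap counts, kinase-class intensity aggregation and fold-change screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import IntensityMatrix
from .tables_io import parse_site_key

logger = logging.getLogger(__name__)

KINASE_CLASSES = ("RTK", "nonRTK-TK", "S/T", "dual", "other")


class SummarizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    standardised: pd.DataFrame


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    z = values.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)  # zero-SD rows left at 0


def hcluster(matrix: IntensityMatrix, standardise_rows: bool = True) -> ClusteringResult:
    """Cluster sites (rows) and samples (columns).

    Rows are optionally z-scored; distances are Euclidean and linkage is
    complete, with scipy's deterministic index-based tie-breaking.
    """
    values = matrix.values
    if len(values) < 2 or values.shape[1] < 2:
        raise SummarizeError("need >= 2 sites and >= 2 samples to cluster")
    if not matrix.is_complete():
        raise SummarizeError("matrix must be complete")
    data = _zscore_rows(values) if standardise_rows else values

    row_link = hierarchy.complete(pdist(data.to_numpy(), metric="euclidean"))
    col_link = hierarchy.complete(pdist(data.to_numpy().T, metric="euclidean"))
    return ClusteringResult(
        row_order=list(hierarchy.leaves_list(row_link)),
        col_order=list(hierarchy.leaves_list(col_link)),
        row_linkage=row_link,
        col_linkage=col_link,
        standardised=data,
    )


def top_variable_sites(matrix: IntensityMatrix, k: int = 150, method: str = "variance") -> list[str]:
    """The k most variable sites (default ranking: variance; also mad/range)."""
    v = matrix.values
    if method == "variance":
        score = v.var(axis=1, ddof=1)
    elif method == "mad":
        med = v.median(axis=1)
        score = (v.sub(med, axis=0)).abs().median(axis=1)
    elif method == "range":
        score = v.max(axis=1) - v.min(axis=1)
    else:
        raise SummarizeError(f"unknown variability method: {method!r}")
    return list(score.sort_values(ascending=False, kind="stable").index[:k])


def cut_clusters(linkage: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels from a linkage, cutting into ``n_clusters``."""
    return hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")


# ---------------------------------------------------------------------------
# overlap (Venn) counts
# ---------------------------------------------------------------------------


@dataclass
class OverlapCounts:
    """The 7 disjoint regions of a three-set overlap, keyed by membership."""

    names: tuple[str, str, str]
    regions: dict[tuple[bool, bool, bool], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def set_total(self, name: str) -> int:
        i = self.names.index(name)
        return sum(n for key, n in self.regions.items() if key[i])

    def common_all(self) -> int:
        return self.regions[(True, True, True)]


def overlap_counts(sets: Mapping[str, Iterable]) -> OverlapCounts:
    """Exact 7-region partition counts for three named sets."""
    if len(sets) != 3:
        raise SummarizeError("overlap_counts expects exactly three sets")
    names = tuple(sets)
    s = [set(sets[n]) for n in names]
    regions: dict[tuple[bool, bool, bool], int] = {}
    union = s[0] | s[1] | s[2]
    for a in (True, False):
        for b in (True, False):
            for c in (True, False):
                if not (a or b or c):
                    continue
                regions[(a, b, c)] = sum(
                    1
                    for x in union
                    if (x in s[0]) == a and (x in s[1]) == b and (x in s[2]) == c
                )
    return OverlapCounts(names=names, regions=regions)


# ---------------------------------------------------------------------------
# kinase-class intensity aggregation
# ---------------------------------------------------------------------------


def kinase_intensity_summary(
    matrix: IntensityMatrix,
    kinase_class_of: Mapping[str, str],
    gene_of_protein: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total linear-scale pY intensity per protein and per kinase class.

    The per-protein total sums 10**value over that protein's sites and all
    samples (observed cells only).  Proteins without an annotation fall in
    "other" (logged).  Returns (per-protein frame sorted descending, per-class
    frame).
    """
    linear = 10.0 ** matrix.values.where(matrix.observed)
    totals: dict[str, float] = {}
    for site in matrix.sites:
        protein, _, _ = parse_site_key(site)
        gene = (gene_of_protein or {}).get(protein, protein)
        totals[gene] = totals.get(gene, 0.0) + float(np.nansum(linear.loc[site]))

    anno = {g.upper(): c for g, c in kinase_class_of.items()}
    unannotated = [g for g in totals if g.upper() not in anno]
    if unannotated:
        logger.info("kinase_intensity_summary: %d unannotated protein(s) -> 'other'",
                    len(unannotated))

    per_protein = pd.DataFrame(
        {
            "protein": list(totals),
            "kinase_class": [anno.get(g.upper(), "other") for g in totals],
            "total_intensity": list(totals.values()),
        }
    ).sort_values(["total_intensity", "protein"], ascending=[False, True]).reset_index(drop=True)
    per_class = (
        per_protein.groupby("kinase_class", sort=True)["total_intensity"]
        .sum()
        .reset_index()
        .sort_values("total_intensity", ascending=False)
        .reset_index(drop=True)
    )
    return per_protein, per_class


# ---------------------------------------------------------------------------
# fold-change screen
# ---------------------------------------------------------------------------


def fold_change_screen(
    matrix: IntensityMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_fold: float = 10.0,
    protein_rollup: bool = False,
) -> pd.DataFrame:
    """Sites where mean(A) - mean(B) exceeds log10(min_fold).

    Groups must be disjoint, non-empty subsets of the matrix samples; they
    may live within a single class (subgroup screens).  With
    ``protein_rollup`` the result is collapsed per protein by its maximal
    site fold change.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise SummarizeError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise SummarizeError("groups must be disjoint")
    for s in [*ga, *gb]:
        if s not in matrix.values.columns:
            raise SummarizeError(f"unknown sample {s!r}")
    delta = matrix.values[ga].mean(axis=1) - matrix.values[gb].mean(axis=1)
    cutoff = np.log10(min_fold)
    hits = delta[delta > cutoff].sort_values(ascending=False)
    df = pd.DataFrame(
        {
            "site": hits.index,
            "protein": [parse_site_key(s)[0] for s in hits.index],
            "log10_fold": hits.values,
            "fold": 10.0**hits.values,
        }
    ).reset_index(drop=True)
    if protein_rollup:
        df = (
            df.sort_values("log10_fold", ascending=False)
            .drop_duplicates("protein")
            .reset_index(drop=True)
        )
    return df
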