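"""Evidence filtering, spike-in normalisation, site matrix assembly, imputation.

The output of this module — a filtered, normalised, imputed site x sample
log10 intensity matrix — is what every statistical stage consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables_io import EvidenceRecord, write_json

logger = logging.getLogger(__name__)

PROV_MEASURED = "measured"
PROV_KNN = "knn"
PROV_ROW_MIN = "row_min"
PROV_COL_MEAN = "col_mean"


@dataclass
class IntensityMatrix:
    """Site x sample log10 intensity matrix with missingness bookkeeping.

    ``values`` holds NaN where missing until :func:`impute` fills them;
    ``observed`` marks originally measured cells; ``provenance`` records how
    each cell got its value.
    """

    values: pd.DataFrame  # sites x samples, log10 scale
    observed: pd.DataFrame  # boolean, same shape
    provenance: pd.DataFrame  # strings, same shape
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.observed.index) or list(
            self.values.columns
        ) != list(self.observed.columns):
            raise ValueError("values/observed shape mismatch")
        missing_labels = set(self.values.columns) - set(self.class_of)
        if missing_labels:
            raise ValueError(f"samples without class labels: {sorted(missing_labels)}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def classes(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.class_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, cls: str) -> list[str]:
        return [s for s in self.samples if self.class_of[s] == cls]

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.observed.copy(), self.provenance.copy(),
            dict(self.class_of),
        )

    def restrict_sites(self, sites: Iterable[str]) -> "IntensityMatrix":
        keep = [s for s in self.sites if s in set(sites)]
        return IntensityMatrix(
            self.values.loc[keep], self.observed.loc[keep],
            self.provenance.loc[keep], dict(self.class_of),
        )

    # -- serialisation ------------------------------------------------------

    def write(self, matrix_path: str | Path, sidecar_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="site", na_rep="NA")
        write_json(
            {
                "samples": self.samples,
                "class_of": self.class_of,
                "observed": {s: self.observed.loc[s].tolist() for s in self.sites},
                "provenance": {s: self.provenance.loc[s].tolist() for s in self.sites},
            },
            sidecar_path,
        )

    @classmethod
    def read(cls, matrix_path: str | Path, sidecar_path: str | Path) -> "IntensityMatrix":
        from .tables_io import read_json

        values = pd.read_csv(matrix_path, sep="\t", index_col="site", na_values=["NA"])
        side = read_json(sidecar_path)
        observed = pd.DataFrame(
            [side["observed"][s] for s in values.index],
            index=values.index, columns=values.columns,
        ).astype(bool)
        provenance = pd.DataFrame(
            [side["provenance"][s] for s in values.index],
            index=values.index, columns=values.columns,
        )
        return cls(values, observed, provenance, dict(side["class_of"]))


@dataclass
class NormalisationFactors:
    """Per-sample spike-in derived scale factors (divide raw intensities by
    ``factors[sample]`` to normalise)."""

    factors: dict[str, float]
    standard_intensities: pd.DataFrame  # standards x samples, observed raw sums
    expected_amounts: dict[str, float]

    def __post_init__(self) -> None:
        for s, f in self.factors.items():
            if not (f > 0 and math.isfinite(f)):
                raise ValueError(f"non-positive normalisation factor for {s}")


class NormalisationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_evidence(
    records: list[EvidenceRecord], min_loc_prob: float = 0.75
) -> list[EvidenceRecord]:
    """Remove contaminant/reverse rows and rows below the localization
    probability threshold (inclusive: a row at exactly the threshold stays).
    """
    kept: list[EvidenceRecord] = []
    n_contam = n_rev = n_loc = 0
    for r in records:
        if r.is_contaminant:
            n_contam += 1
            continue
        if r.is_reverse:
            n_rev += 1
            continue
        if r.localization_prob < min_loc_prob:
            n_loc += 1
            continue
        kept.append(r)
    logger.info(
        "filter_evidence: %d -> %d (removed %d contaminant, %d reverse, %d loc_prob<%g)",
        len(records), len(kept), n_contam, n_rev, n_loc, min_loc_prob,
    )
    if not kept:
        logger.warning("filter_evidence: no records survived filtering")
    return kept


# ---------------------------------------------------------------------------
# spike-in normalisation
# ---------------------------------------------------------------------------


def compute_spikein_factors(
    records: list[EvidenceRecord], spikein_amounts: Mapping[str, float]
) -> NormalisationFactors:
    """Derive a per-sample scale factor from the spike-in standards.

    Per standard d the reference is the across-sample geometric mean of its
    observed intensity; a sample's factor is the geometric mean over
    standards of (observed / reference).  Dividing a sample's intensities by
    its factor therefore equalises spike-ins across samples.  The geometric
    mean is robust to a single aberrant standard.
    """
    samples = sorted({r.sample_id for r in records})
    standards = sorted(spikein_amounts)
    obs = pd.DataFrame(0.0, index=standards, columns=samples)
    for r in records:
        if r.is_spikein and r.protein_id in spikein_amounts:
            if r.raw_intensity is None or r.raw_intensity <= 0:
                raise NormalisationError(
                    f"zero/absent spike-in intensity for {r.protein_id} in {r.sample_id}"
                )
            obs.loc[r.protein_id, r.sample_id] += r.raw_intensity

    for s in samples:
        if (obs[s] > 0).sum() == 0:
            raise NormalisationError(f"sample {s!r} has no spike-in observations")

    log_obs = np.log(obs.where(obs > 0))
    reference = log_obs.mean(axis=1)  # log of geometric mean per standard
    ratios = log_obs.sub(reference, axis=0)
    factors = {s: float(np.exp(ratios[s].dropna().mean())) for s in samples}
    return NormalisationFactors(
        factors=factors,
        standard_intensities=obs,
        expected_amounts=dict(spikein_amounts),
    )


# ---------------------------------------------------------------------------
# site matrix
# ---------------------------------------------------------------------------


def collapse_to_sites(
    records: list[EvidenceRecord],
    factors: NormalisationFactors,
    class_of: Mapping[str, str],
    aggregate: str = "sum",
) -> IntensityMatrix:
    """Aggregate normalised evidence intensities to a log10 site x sample matrix.

    Multiple evidence rows mapping to the same (site, sample) are combined by
    ``aggregate`` ("sum", the default, or "max") before the log10 transform.
    Spike-in rows are excluded.  Cells with no rows are missing (NaN).
    """
    if aggregate not in ("sum", "max"):
        raise ValueError(f"unknown aggregate: {aggregate!r}")
    cells: dict[tuple[str, str], float] = {}
    sites_seen: dict[str, None] = {}
    for r in records:
        if r.is_spikein or r.raw_intensity is None:
            continue
        norm = r.raw_intensity / factors.factors[r.sample_id]
        key = (r.site_key, r.sample_id)
        sites_seen.setdefault(r.site_key, None)
        if key not in cells:
            cells[key] = norm
        elif aggregate == "sum":
            cells[key] += norm
        else:
            cells[key] = max(cells[key], norm)

    sites = sorted(sites_seen)
    samples = sorted(factors.factors)
    values = pd.DataFrame(np.nan, index=sites, columns=samples)
    for (site, sample), v in cells.items():
        values.loc[site, sample] = np.log10(v)
    observed = ~values.isna()
    provenance = observed.map(lambda o: PROV_MEASURED if o else "")
    return IntensityMatrix(values, observed, provenance, dict(class_of))


# ---------------------------------------------------------------------------
# presence filtering
# ---------------------------------------------------------------------------


def presence_threshold(n_samples: int, fraction: float = 0.75) -> int:
    """Smallest sample count meeting ``fraction`` of ``n_samples`` (ceiling).

    presence_threshold(8, 0.75) == 6 and presence_threshold(5, 0.75) == 4.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    return math.ceil(fraction * n_samples - 1e-12)


def reproducible_sites(matrix: IntensityMatrix, fraction: float = 0.75) -> set[str]:
    """Sites observed in at least ``fraction`` of samples of >= 1 class."""
    keep: set[str] = set()
    thresholds = {
        cls: presence_threshold(len(matrix.samples_of(cls)), fraction)
        for cls in matrix.classes()
    }
    for cls, thr in thresholds.items():
        cols = matrix.samples_of(cls)
        counts = matrix.observed[cols].sum(axis=1)
        keep.update(counts.index[counts >= thr])
    logger.info(
        "reproducible_sites: %d / %d retained at fraction %g",
        len(keep), len(matrix.sites), fraction,
    )
    return keep


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class ImputationError(ValueError):
    pass


def impute(
    matrix: IntensityMatrix, k: int = 10, fallback: str = "row_min"
) -> IntensityMatrix:
    """Fill missing cells, routing on the site's observation fraction.

    A site observed in strictly more than 50% of all samples is k-NN
    imputed: its neighbours are the k other sites with the smallest
    Euclidean distance over mutually observed samples, and the imputed value
    is the unweighted mean of neighbour values in the target sample.  Any
    other site has all of its missing cells filled by the fallback rule —
    ``row_min`` (the site's minimum observed value) or ``col_mean`` (the
    sample's mean over observed values).  Observed cells are never altered.
    """
    if fallback not in (PROV_ROW_MIN, PROV_COL_MEAN):
        raise ValueError(f"fallback must be 'row_min' or 'col_mean', got {fallback!r}")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    obs = out.observed.to_numpy(dtype=bool)
    n_sites, n_samples = vals.shape

    zero_obs = np.nonzero(~obs.any(axis=1))[0]
    if len(zero_obs):
        names = [out.sites[i] for i in zero_obs[:5]]
        raise ImputationError(f"site(s) with zero observations: {names}")

    site_counts = obs.sum(axis=1)
    knn_rows = np.nonzero(site_counts * 2 > n_samples)[0]  # strictly > 50%
    knn_set = set(knn_rows.tolist())
    col_means = np.array(
        [vals[obs[:, j], j].mean() if obs[:, j].any() else np.nan for j in range(n_samples)]
    )

    prov = out.provenance.to_numpy(dtype=object)
    filled = vals.copy()
    for i in range(n_sites):
        missing_cols = np.nonzero(~obs[i])[0]
        if len(missing_cols) == 0:
            continue
        if i in knn_set:
            filled[i, missing_cols] = _knn_impute_row(vals, obs, i, missing_cols, k)
            prov[i, missing_cols] = PROV_KNN
        elif fallback == PROV_ROW_MIN:
            filled[i, missing_cols] = vals[i, obs[i]].min()
            prov[i, missing_cols] = PROV_ROW_MIN
        else:
            filled[i, missing_cols] = col_means[missing_cols]
            prov[i, missing_cols] = PROV_COL_MEAN

    out.values = pd.DataFrame(filled, index=out.sites, columns=out.samples)
    out.provenance = pd.DataFrame(prov, index=out.sites, columns=out.samples)
    return out


def _knn_impute_row(
    vals: np.ndarray, obs: np.ndarray, i: int, missing_cols: np.ndarray, k: int
) -> np.ndarray:
    """k-NN fill for one site: per missing sample, average the k nearest
    sites (Euclidean over mutually observed samples) that observe it."""
    n_sites = vals.shape[0]
    diffs = vals - vals[i]
    shared = obs & obs[i]
    sq = np.where(shared, diffs**2, 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # mean squared difference over shared columns; scale-compensated distance
        dist = np.sqrt(sq.sum(axis=1) / n_shared)
    dist[i] = np.inf
    dist[n_shared == 0] = np.inf

    result = np.empty(len(missing_cols))
    for mi, j in enumerate(missing_cols):
        candidates = np.nonzero(obs[:, j] & np.isfinite(dist))[0]
        if len(candidates) == 0:
            # no neighbour observes this sample; fall back to row mean
            result[mi] = vals[i, obs[i]].mean()
            continue
        if len(candidates) < k:
            logger.warning(
                "impute: only %d eligible neighbours (k=%d) for site row %d, sample %d",
                len(candidates), k, i, j,
            )
        order = candidates[np.argsort(dist[candidates], kind="stable")][:k]
        result[mi] = vals[order, j].mean()
    return result


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


def preprocess_evidence(
    records: list[EvidenceRecord],
    spikein_amounts: Mapping[str, float],
    class_of: Mapping[str, str],
    min_loc_prob: float = 0.75,
    presence_fraction: float = 0.75,
    k: int = 10,
    fallback: str = "row_min",
    aggregate: str = "sum",
) -> tuple[IntensityMatrix, IntensityMatrix, NormalisationFactors]:
    """Full preprocessing chain.

    Returns (full matrix with missing cells, imputed reproducible-site
    matrix, normalisation factors).  Imputation runs after the presence
    filter.
    """
    filtered = filter_evidence(records, min_loc_prob=min_loc_prob)
    factors = compute_spikein_factors(filtered, spikein_amounts)
    matrix = collapse_to_sites(filtered, factors, class_of, aggregate=aggregate)
    keep = reproducible_sites(matrix, fraction=presence_fraction)
    reproducible = matrix.restrict_sites(keep)
    imputed = impute(reproducible, k=k, fallback=fallback)
    return matrix, imputed, factors
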