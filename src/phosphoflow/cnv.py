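"""aCGH copy-number arm: normalisation, outlier smoothing, circular binary
segmentation, plateau-threshold state calling and genome-wide level merging.

State thresholds on segment mean log2 ratio: deletion < -0.5;
-0.5 <= neutral <= 0.5; 0.5 < amplification <= 1.5; high_amplification > 1.5.
Reported fold change is 2**mean relative to the diploid reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tables_io import ProbeRecord, SegmentRecord

logger = logging.getLogger(__name__)

STATE_DELETION = "deletion"
STATE_NEUTRAL = "neutral"
STATE_AMPLIFICATION = "amplification"
STATE_HIGH_AMPLIFICATION = "high_amplification"


@dataclass
class CnvParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 2
    trim_sd: float = 3.0
    smooth_window: int = 5
    merge_delta: float = 0.2
    deletion_threshold: float = -0.5
    amplification_threshold: float = 0.5
    high_amplification_threshold: float = 1.5
    seed: int = 0


# ---------------------------------------------------------------------------
# normalisation and smoothing
# ---------------------------------------------------------------------------


def normalise_probes(probes: list[ProbeRecord]) -> list[ProbeRecord]:
    """Average duplicate probe ids, then subtract the global median log2 ratio."""
    by_id: dict[tuple[str, str], list[ProbeRecord]] = {}
    order: list[tuple[str, str]] = []
    for p in probes:
        key = (p.chrom, p.probe_id)
        if key not in by_id:
            by_id[key] = []
            order.append(key)
        by_id[key].append(p)

    collapsed: list[ProbeRecord] = []
    n_dups = 0
    for key in order:
        group = by_id[key]
        if len(group) > 1:
            n_dups += 1
        collapsed.append(
            ProbeRecord(
                group[0].chrom,
                group[0].position,
                group[0].probe_id,
                float(np.mean([g.log2_ratio for g in group])),
            )
        )
    if n_dups:
        logger.info("normalise_probes: averaged %d duplicated probe id(s)", n_dups)

    med = float(np.median([p.log2_ratio for p in collapsed]))
    out = [
        ProbeRecord(p.chrom, p.position, p.probe_id, p.log2_ratio - med)
        for p in collapsed
    ]
    out.sort(key=lambda p: (p.chrom, p.position))
    return out


def smooth_outliers(
    probes: list[ProbeRecord], trim_sd: float = 3.0, window: int = 5
) -> list[ProbeRecord]:
    """Shrink isolated outlier probes toward their local median.

    A probe is an outlier when it deviates more than ``trim_sd`` robust SDs
    (1.4826 * MAD, computed per chromosome) from its window median AND from
    both immediate neighbours; it is replaced by window median +/-
    trim_sd * SD.  All other probes are untouched.
    """
    out: list[ProbeRecord] = []
    for chrom in sorted({p.chrom for p in probes}):
        cp = [p for p in probes if p.chrom == chrom]
        x = np.array([p.log2_ratio for p in cp])
        n = len(x)
        mad = np.median(np.abs(x - np.median(x)))
        sd = 1.4826 * mad
        if sd == 0 or n < 3:
            out.extend(cp)
            continue
        half = max(1, window // 2)
        new = x.copy()
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            wmed = np.median(np.concatenate([x[lo:i], x[i + 1 : hi]]))
            dev = x[i] - wmed
            if abs(dev) <= trim_sd * sd:
                continue
            left_ok = i == 0 or abs(x[i] - x[i - 1]) > trim_sd * sd
            right_ok = i == n - 1 or abs(x[i] - x[i + 1]) > trim_sd * sd
            if left_ok and right_ok:
                new[i] = wmed + np.sign(dev) * trim_sd * sd
        out.extend(
            ProbeRecord(p.chrom, p.position, p.probe_id, float(v))
            for p, v in zip(cp, new)
        )
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


def _max_circular_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal two-segment circular t statistic.

    Considers every arc (i, j] (0 <= i < j <= n, arc and complement each at
    least ``min_width`` probes) and returns (max |t|, i, j) where t compares
    the arc mean against the complement mean with the segment-wide variance.
    """
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sd = x.std()
    if sd == 0:
        sd = 1.0  # degenerate; any true step still maximises |mean difference|

    i_idx = np.arange(0, n + 1)
    # arc sums: S[j] - S[i] for all i < j
    diff = s[None, :] - s[:, None]  # diff[i, j] = sum of x[i:j]
    k = i_idx[None, :] - i_idx[:, None]  # arc length j - i
    valid = (k >= min_width) & ((n - k) >= min_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in = diff / k
        mean_out = (total - diff) / (n - k)
        t = (mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    t = np.where(valid, np.abs(t), -np.inf)
    flat = np.argmax(t)
    i, j = np.unravel_index(flat, t.shape)
    return float(t[i, j]), int(i), int(j)


def _split_significant(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Permutation test for the best circular split; None if not accepted."""
    n = len(x)
    if n < 2 * min_width or np.allclose(x, x[0]):
        return None
    t_obs, i, j = _max_circular_t(x, min_width)
    if not np.isfinite(t_obs) or t_obs <= 0:
        return None
    exceed = 0
    cutoff = alpha * n_permutations
    for b in range(n_permutations):
        t_perm, _, _ = _max_circular_t(rng.permutation(x), min_width)
        if t_perm >= t_obs:
            exceed += 1
            if exceed > cutoff:  # early exit: cannot reach significance
                return None
    p = exceed / n_permutations
    if p < alpha:
        return i, j
    return None


def _segment_array(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns [start, end) probe index pairs."""
    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        split = _split_significant(seg, alpha, n_permutations, min_width, rng)
        if split is None:
            boundaries.append((lo, hi))
            return
        i, j = split
        parts = []
        if i > 0:
            parts.append((lo, lo + i))
        parts.append((lo + i, lo + j))
        if j < len(seg):
            parts.append((lo + j, hi))
        if len(parts) == 1:  # degenerate: arc covers everything
            boundaries.append((lo, hi))
            return
        for a, b in parts:
            recurse(a, b)

    recurse(0, len(x))
    boundaries.sort()
    return boundaries


def cbs_segment(
    probes: list[ProbeRecord],
    sample: str = "sample",
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[SegmentRecord]:
    """Circular binary segmentation per chromosome.

    At each recursion level the maximal circular two-segment t statistic is
    located and its significance assessed by permuting probe values within
    the current segment; the split is accepted iff the permutation p-value
    is below ``alpha``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    segments: list[SegmentRecord] = []
    for chrom in sorted({p.chrom for p in probes}):
        cp = sorted((p for p in probes if p.chrom == chrom), key=lambda p: p.position)
        x = np.array([p.log2_ratio for p in cp])
        if len(x) < 2 * min_width:
            logger.info(
                "cbs_segment: %s has %d probes (< 2*min_width), single segment",
                chrom, len(x),
            )
            bounds = [(0, len(x))]
        else:
            bounds = _segment_array(x, alpha, n_permutations, min_width, rng)
        for lo, hi in bounds:
            segments.append(
                SegmentRecord(
                    sample=sample,
                    chrom=chrom,
                    start=cp[lo].position,
                    end=cp[hi - 1].position,
                    n_probes=hi - lo,
                    seg_mean=float(x[lo:hi].mean()),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# state calling and level merging
# ---------------------------------------------------------------------------


def classify_segments(
    segments: list[SegmentRecord],
    deletion_threshold: float = -0.5,
    amplification_threshold: float = 0.5,
    high_amplification_threshold: float = 1.5,
) -> list[SegmentRecord]:
    """Assign the four-state copy-number call from each segment mean."""
    for s in segments:
        m = s.seg_mean
        if m < deletion_threshold:
            s.state = STATE_DELETION
        elif m <= amplification_threshold:
            s.state = STATE_NEUTRAL
        elif m <= high_amplification_threshold:
            s.state = STATE_AMPLIFICATION
        else:
            s.state = STATE_HIGH_AMPLIFICATION
    return segments


def fold_change(seg_mean: float) -> float:
    """Copy-number fold change relative to the diploid reference."""
    return float(2.0**seg_mean)


def merge_levels(
    segments: list[SegmentRecord], merge_delta: float = 0.2
) -> tuple[list[SegmentRecord], list[float]]:
    """Cluster segment means genome-wide into common copy-number levels.

    Iterative nearest-pair merging: while the two closest level means differ
    by less than ``merge_delta`` they are pooled (probe-count weighted).
    Each segment gets a level id (sorted by level mean ascending); the
    sorted unique level means are returned alongside — the plateau set.
    """
    if not segments:
        return segments, []
    levels = [[s.seg_mean, float(s.n_probes), [idx]] for idx, s in enumerate(segments)]
    while len(levels) > 1:
        levels.sort(key=lambda L: L[0])
        gaps = [levels[i + 1][0] - levels[i][0] for i in range(len(levels) - 1)]
        gi = int(np.argmin(gaps))
        if gaps[gi] >= merge_delta:
            break
        a, b = levels[gi], levels[gi + 1]
        w = a[1] + b[1]
        merged = [(a[0] * a[1] + b[0] * b[1]) / w, w, a[2] + b[2]]
        levels[gi : gi + 2] = [merged]
    levels.sort(key=lambda L: L[0])
    for lid, (mean, _, idxs) in enumerate(levels):
        for idx in idxs:
            segments[idx].level = lid
    return segments, [float(L[0]) for L in levels]


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------


def call_copy_number(
    probes: list[ProbeRecord],
    sample: str = "sample",
    params: CnvParams | None = None,
) -> tuple[list[SegmentRecord], list[float]]:
    """normalise -> smooth -> segment -> classify -> merge, in one call."""
    params = params or CnvParams()
    norm = normalise_probes(probes)
    smoothed = smooth_outliers(norm, trim_sd=params.trim_sd, window=params.smooth_window)
    segs = cbs_segment(
        smoothed,
        sample=sample,
        alpha=params.alpha,
        n_permutations=params.n_permutations,
        min_width=params.min_width,
        seed=params.seed,
    )
    classify_segments(
        segs,
        deletion_threshold=params.deletion_threshold,
        amplification_threshold=params.amplification_threshold,
        high_amplification_threshold=params.high_amplification_threshold,
    )
    segs, level_means = merge_levels(segs, merge_delta=params.merge_delta)
    return segs, level_means
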