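"""Synthetic-data generators with planted ground truth.

Every downstream stage is testable without any download: the phospho
generator emits an evidence table plus a truth sidecar recording the planted
class-specific sites, the complete (pre-missingness) log10 matrix and the
per-sample technical scale factors; the aCGH generator emits a probe table
plus exact planted breakpoints.

Modelling choices (stated assumptions, not inferences about any real data):

- site baseline log10 intensities ~ Normal(baseline_mean, baseline_sd);
  per-sample residual noise ~ Normal(0, noise_sd);
- planted class-specific sites have their class mean shifted by
  ``+effect_log10`` (1.0 = tenfold);
- detection is abundance-driven: a cell with true log10 value v is observed
  with probability sigmoid(missing_steepness * (v - missing_midpoint)),
  which is monotone non-decreasing in v;
- per-sample technical scale factors are log-normal (log10 SD
  ``scale_factor_sd``), giving spike-in normalisation something to correct;
- localization probabilities ~ Beta(localization_alpha, localization_beta),
  with mass near 1 so the 0.75 filter removes a minority of rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tables_io import (
    EvidenceRecord,
    ProbeRecord,
    format_site_key,
    write_evidence,
    write_json,
    write_probes,
    write_spikeins,
)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# phospho simulation
# ---------------------------------------------------------------------------

DEFAULT_CLASSES = {"p53": 8, "PyMT": 8, "Her2": 5}
DEFAULT_SPIKEINS = {"STD_MK14": 5.0, "STD_EFTU": 0.5, "STD_EGFR": 10.0}


@dataclass
class PhosphoSimConfig:
    """Configuration for the phosphoproteomics generator.

    The default class layout is three classes with 8 + 8 + 5 samples and the
    three spike-in standards at 5 pmol, 0.5 pmol and 10 pmol.
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    n_sites: int = 400
    n_specific_per_class: int = 10
    effect_log10: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 0.8
    noise_sd: float = 0.25
    missing_steepness: float = 1.5
    missing_midpoint: float = 3.5
    missing_enabled: bool = True
    spikein_amounts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPIKEINS))
    spikein_intensity_per_pmol: float = 1e4
    spikein_noise_sd: float = 0.02
    scale_factor_sd: float = 0.15
    localization_alpha: float = 8.0
    localization_beta: float = 0.7
    contaminant_rate: float = 0.01
    reverse_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sites", "n_specific_per_class"):
            if getattr(self, name) < 0 or (name == "n_sites" and self.n_sites < 1):
                raise ConfigError(f"{name} must be positive")
        if not self.n_per_class:
            raise ConfigError("n_per_class must not be empty")
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ConfigError(f"n_per_class[{cls!r}] must be positive")
        if self.n_specific_per_class * len(self.n_per_class) > self.n_sites:
            raise ConfigError("n_specific_per_class: planted sites exceed n_sites")
        if self.effect_log10 < 0:
            raise ConfigError("effect_log10 must be non-negative")
        for name in ("baseline_sd", "noise_sd", "spikein_noise_sd", "scale_factor_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.missing_steepness < 0:
            raise ConfigError("missing_steepness must be non-negative (monotone detection)")
        if not self.spikein_amounts:
            raise ConfigError("spikein_amounts must not be empty")
        for pid, amt in self.spikein_amounts.items():
            if amt <= 0:
                raise ConfigError(f"spikein_amounts[{pid!r}] must be positive")
        for name in ("localization_alpha", "localization_beta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("contaminant_rate", "reverse_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")


@dataclass
class PhosphoTruth:
    """Planted ground truth for one phospho simulation."""

    specific_sites: dict[str, list[str]]  # class -> planted site keys
    true_log10_matrix: "np.ndarray"  # sites x samples, complete
    site_keys: list[str]
    sample_ids: list[str]
    class_of: dict[str, str]
    sample_scale_factors: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "specific_sites": self.specific_sites,
            "true_log10_matrix": self.true_log10_matrix.tolist(),
            "site_keys": self.site_keys,
            "sample_ids": self.sample_ids,
            "class_of": self.class_of,
            "sample_scale_factors": self.sample_scale_factors,
        }


def detection_probability(log10_intensity, steepness: float, midpoint: float):
    """Logistic probability that a value of given log10 intensity is detected."""
    x = np.asarray(log10_intensity, dtype=float)
    return 1.0 / (1.0 + np.exp(-steepness * (x - midpoint)))


def expected_missing_fraction(config: PhosphoSimConfig, n_grid: int = 20001) -> float:
    """Numerically integrate the miss probability over the baseline intensity
    distribution (for sites without planted effects and residual noise folded
    into the effective spread)."""
    sd = float(np.hypot(config.baseline_sd, config.noise_sd))
    lo, hi = config.baseline_mean - 8 * sd, config.baseline_mean + 8 * sd
    grid = np.linspace(lo, hi, n_grid)
    pdf = np.exp(-0.5 * ((grid - config.baseline_mean) / sd) ** 2) / (
        sd * np.sqrt(2 * np.pi)
    )
    miss = 1.0 - detection_probability(grid, config.missing_steepness, config.missing_midpoint)
    return float(np.trapezoid(pdf * miss, grid))


def simulate_phospho(
    config: PhosphoSimConfig,
) -> tuple[list[EvidenceRecord], dict[str, float], PhosphoTruth]:
    """Generate an evidence table, spike-in declarations and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = list(config.n_per_class)
    sample_ids: list[str] = []
    class_of: dict[str, str] = {}
    for cls in classes:
        for i in range(config.n_per_class[cls]):
            sid = f"{cls}_{i + 1:02d}"
            sample_ids.append(sid)
            class_of[sid] = cls
    n_samples = len(sample_ids)

    # site identities: synthetic accessions, all tyrosine
    site_keys = [
        format_site_key(f"SIM{i:04d}", "Y", (i % 60) * 13 + 7) for i in range(config.n_sites)
    ]

    # plant disjoint class-specific blocks at the head of the site list
    specific: dict[str, list[str]] = {}
    cursor = 0
    for cls in classes:
        specific[cls] = site_keys[cursor : cursor + config.n_specific_per_class]
        cursor += config.n_specific_per_class

    site_base = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_sites)
    truth = np.tile(site_base[:, None], (1, n_samples))
    for ci, cls in enumerate(classes):
        cols = [j for j, s in enumerate(sample_ids) if class_of[s] == cls]
        lo = ci * config.n_specific_per_class
        hi = lo + config.n_specific_per_class
        truth[lo:hi][:, cols] += config.effect_log10
    truth = truth + rng.normal(0.0, config.noise_sd, size=truth.shape)

    scale = np.power(10.0, rng.normal(0.0, config.scale_factor_sd, size=n_samples))
    scale_of = {s: float(f) for s, f in zip(sample_ids, scale)}

    if config.missing_enabled:
        p_detect = detection_probability(
            truth, config.missing_steepness, config.missing_midpoint
        )
        observed = rng.random(truth.shape) < p_detect
    else:
        observed = np.ones(truth.shape, dtype=bool)

    loc_probs = rng.beta(
        config.localization_alpha, config.localization_beta, size=config.n_sites
    )

    records: list[EvidenceRecord] = []
    for i, key in enumerate(site_keys):
        protein = key.split("_")[0]
        residue, position = "Y", int(key.split("_")[1][1:])
        for j, sid in enumerate(sample_ids):
            if not observed[i, j]:
                continue
            intensity = float(10.0 ** truth[i, j] * scale[j])
            records.append(
                EvidenceRecord(
                    sample_id=sid,
                    protein_id=protein,
                    gene_symbol=f"Gene{i:04d}",
                    residue=residue,
                    position=position,
                    localization_prob=float(loc_probs[i]),
                    raw_intensity=intensity,
                )
            )

    # spike-in rows: present in every sample, proportional to spiked amount
    for pid, amount in config.spikein_amounts.items():
        base = amount * config.spikein_intensity_per_pmol
        for j, sid in enumerate(sample_ids):
            noise = 10.0 ** rng.normal(0.0, config.spikein_noise_sd)
            records.append(
                EvidenceRecord(
                    sample_id=sid,
                    protein_id=pid,
                    gene_symbol=pid,
                    residue="Y",
                    position=1,
                    localization_prob=1.0,
                    raw_intensity=float(base * scale[j] * noise),
                    is_spikein=True,
                )
            )

    # decoy junk rows exercising the contaminant/reverse filter
    n_contam = rng.binomial(len(records), config.contaminant_rate)
    n_rev = rng.binomial(len(records), config.reverse_rate)
    for k in range(n_contam + n_rev):
        sid = sample_ids[int(rng.integers(n_samples))]
        records.append(
            EvidenceRecord(
                sample_id=sid,
                protein_id=f"JUNK{k:03d}",
                gene_symbol=f"Junk{k:03d}",
                residue="Y",
                position=10,
                localization_prob=float(rng.beta(2.0, 2.0)),
                raw_intensity=float(10.0 ** rng.normal(3.0, 0.5)),
                is_contaminant=k < n_contam,
                is_reverse=k >= n_contam,
            )
        )

    truth_obj = PhosphoTruth(
        specific_sites=specific,
        true_log10_matrix=truth,
        site_keys=site_keys,
        sample_ids=sample_ids,
        class_of=class_of,
        sample_scale_factors=scale_of,
    )
    return records, dict(config.spikein_amounts), truth_obj


# ---------------------------------------------------------------------------
# aCGH simulation
# ---------------------------------------------------------------------------


@dataclass
class CnvSimConfig:
    """Configuration for the aCGH probe generator."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr6": 2_000_000})
    probe_spacing: int = 10_000
    planted_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    noise_sd: float = 0.2
    outlier_rate: float = 0.0
    outlier_magnitude: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must not be empty")
        for c, ln in self.chrom_lengths.items():
            if ln < 1:
                raise ConfigError(f"chrom_lengths[{c!r}] must be positive")
        if self.probe_spacing < 1:
            raise ConfigError("probe_spacing must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not (0 <= self.outlier_rate <= 1):
            raise ConfigError("outlier_rate must be in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, fold in self.planted_segments:
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"planted segment on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ConfigError(
                    f"planted segment {chrom}:{start}-{end} outside chromosome bounds"
                )
            if fold <= 0:
                raise ConfigError("planted fold_change must be > 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ConfigError(f"planted segments overlap on {chrom}")


@dataclass
class CnvTruth:
    """Exact planted breakpoints, as probe indices within each chromosome."""

    segments: list[dict]  # chrom, start/end bp, fold, first/last probe index

    def to_json_dict(self) -> dict:
        return {"segments": self.segments}


def simulate_acgh(config: CnvSimConfig) -> tuple[list[ProbeRecord], CnvTruth]:
    """Generate aCGH probes with planted amplifications/deletions."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    probes: list[ProbeRecord] = []
    truth_segments: list[dict] = []
    for chrom in config.chrom_lengths:
        length = config.chrom_lengths[chrom]
        positions = np.arange(1, length + 1, config.probe_spacing)
        values = rng.normal(0.0, config.noise_sd, size=len(positions))
        for (c, start, end, fold) in config.planted_segments:
            if c != chrom:
                continue
            in_seg = (positions >= start) & (positions <= end)
            values[in_seg] += np.log2(fold)
            idx = np.nonzero(in_seg)[0]
            truth_segments.append(
                {
                    "chrom": chrom,
                    "start_bp": int(start),
                    "end_bp": int(end),
                    "fold_change": float(fold),
                    "first_probe_index": int(idx[0]) if len(idx) else -1,
                    "last_probe_index": int(idx[-1]) if len(idx) else -1,
                }
            )
        if config.outlier_rate > 0:
            hit = rng.random(len(positions)) < config.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=int(hit.sum()))
            values[hit] += signs * config.outlier_magnitude
        for k, (pos, val) in enumerate(zip(positions, values)):
            probes.append(ProbeRecord(chrom, int(pos), f"{chrom}_P{k:06d}", float(val)))
    return probes, CnvTruth(segments=truth_segments)


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------


def write_phospho_run(
    config: PhosphoSimConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate and write evidence.tsv, spikeins.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, amounts, truth = simulate_phospho(config)
    ev, sp, tr = out / "evidence.tsv", out / "spikeins.tsv", out / "phospho_truth.json"
    write_evidence(records, ev)
    write_spikeins(amounts, sp)
    write_json(truth.to_json_dict(), tr)
    return ev, sp, tr


def write_acgh_run(config: CnvSimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Simulate and write probes.tsv and truth json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes, truth = simulate_acgh(config)
    pr, tr = out / "probes.tsv", out / "acgh_truth.json"
    write_probes(probes, pr)
    write_json(truth.to_json_dict(), tr)
    return pr, tr
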