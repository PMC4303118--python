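"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV with a header line.  Readers validate
strictly and never silently drop rows: every exclusion or normalisation is
reported through the module logger.

Dialects
--------
evidence     columns: sample, protein, gene, residue, position, loc_prob,
             intensity, flags.  ``flags`` is a semicolon-joined subset of
             {spikein, contaminant, reverse}, or ``-`` for none.
             ``intensity`` may be empty (missing measurement).
spikeins     columns: peptide_id, amount_pmol
probes       columns: chrom, position, probe_id, log2_ratio
edges        columns: node_a, node_b, provenance, directed
orthologues  columns: mouse_gene, human_gene
gene sets    standard GMT (set name, description, members...)
segments     SEG-like: sample, chrom, start, end, n_probes, seg_mean, state, level
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

_EVIDENCE_FLAGS = {"spikein", "contaminant", "reverse"}


@dataclass(frozen=True)
class EvidenceRecord:
    """One quantified pY peptide observation in one sample."""

    sample_id: str
    protein_id: str
    gene_symbol: str
    residue: str
    position: int
    localization_prob: float
    raw_intensity: float | None
    is_spikein: bool = False
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if not (0.0 <= self.localization_prob <= 1.0):
            raise FormatError(
                f"localization_prob must be in [0, 1], got {self.localization_prob}"
            )
        if self.raw_intensity is not None and self.raw_intensity < 0:
            raise FormatError(
                f"raw_intensity must be non-negative, got {self.raw_intensity}"
            )

    @property
    def site_key(self) -> str:
        return format_site_key(self.protein_id, self.residue, self.position)


def format_site_key(protein_id: str, residue: str, position: int) -> str:
    """Canonical, sortable site identifier, e.g. ``P35569_Y00608``.

    Positions are zero-padded to five digits so lexicographic order matches
    numeric order within a protein.
    """
    return f"{protein_id}_{residue}{position:05d}"


def parse_site_key(key: str) -> tuple[str, str, int]:
    protein, _, tail = key.rpartition("_")
    if not protein or len(tail) < 2:
        raise FormatError(f"malformed site key: {key!r}")
    return protein, tail[0], int(tail[1:])


@dataclass(frozen=True)
class GeneSet:
    set_name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.set_name!r} has no members")


@dataclass(frozen=True)
class EdgeRecord:
    """One interaction edge; undirected edges are stored with sorted endpoints."""

    node_a: str
    node_b: str
    provenance: str  # "mouse" or "human"
    directed: bool = False

    def __post_init__(self) -> None:
        if self.provenance not in ("mouse", "human"):
            raise FormatError(f"unknown edge provenance: {self.provenance!r}")
        if not self.directed and self.node_a > self.node_b:
            a, b = self.node_a, self.node_b
            object.__setattr__(self, "node_a", b)
            object.__setattr__(self, "node_b", a)


@dataclass(frozen=True)
class ProbeRecord:
    chrom: str
    position: int
    probe_id: str
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"probe position must be >= 1, got {self.position}")


@dataclass
class SegmentRecord:
    """One copy-number segment (1-based inclusive coordinates)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_probes: int
    seg_mean: float
    state: str = ""
    level: int = -1


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "sample",
    "protein",
    "gene",
    "residue",
    "position",
    "loc_prob",
    "intensity",
    "flags",
]


def _check_header(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_evidence(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[EvidenceRecord]:
    """Parse an evidence TSV into records.

    Contaminant/reverse rows are retained but flagged; their removal is a
    downstream filtering decision.  ``column_map`` optionally maps our
    canonical column names to the names present in the file, so real search
    engine exports can be pointed at directly.
    """
    path = Path(path)
    colmap = {c: c for c in EVIDENCE_COLUMNS}
    if column_map:
        colmap.update(column_map)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _check_header(header, [colmap[c] for c in EVIDENCE_COLUMNS], path)
        idx = {c: header.index(colmap[c]) for c in EVIDENCE_COLUMNS}
        records: list[EvidenceRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                flags = set()
                raw_flags = fields[idx["flags"]].strip()
                if raw_flags and raw_flags != "-":
                    flags = set(raw_flags.split(";"))
                unknown = flags - _EVIDENCE_FLAGS
                if unknown:
                    raise FormatError(f"unknown flag(s): {sorted(unknown)}")
                intensity_raw = fields[idx["intensity"]].strip()
                records.append(
                    EvidenceRecord(
                        sample_id=fields[idx["sample"]],
                        protein_id=fields[idx["protein"]],
                        gene_symbol=fields[idx["gene"]],
                        residue=fields[idx["residue"]],
                        position=int(fields[idx["position"]]),
                        localization_prob=float(fields[idx["loc_prob"]]),
                        raw_intensity=float(intensity_raw) if intensity_raw else None,
                        is_spikein="spikein" in flags,
                        is_contaminant="contaminant" in flags,
                        is_reverse="reverse" in flags,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read %d evidence records from %s", len(records), path)
    return records


def write_evidence(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in records:
            flags = []
            if r.is_spikein:
                flags.append("spikein")
            if r.is_contaminant:
                flags.append("contaminant")
            if r.is_reverse:
                flags.append("reverse")
            intensity = "" if r.raw_intensity is None else repr(r.raw_intensity)
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.protein_id,
                        r.gene_symbol,
                        r.residue,
                        str(r.position),
                        repr(r.localization_prob),
                        intensity,
                        ";".join(flags) or "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# spike-in declarations
# ---------------------------------------------------------------------------


def read_spikeins(path: str | Path) -> dict[str, float]:
    """Read spike-in standard declarations: peptide id -> spiked amount (pmol)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    _check_header(df.columns, ["peptide_id", "amount_pmol"], path)
    if (df["amount_pmol"] <= 0).any():
        bad = df.loc[df["amount_pmol"] <= 0, "peptide_id"].tolist()
        raise FormatError(f"{path}: non-positive spike-in amount for {bad}")
    return dict(zip(df["peptide_id"], df["amount_pmol"].astype(float)))


def write_spikeins(amounts: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_id\tamount_pmol\n")
        for pid, amt in amounts.items():
            fh.write(f"{pid}\t{amt!r}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file; member symbols are uppercased and deduplicated."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------


def read_probes(path: str | Path) -> list[ProbeRecord]:
    """Read an aCGH probe table, sorted by (chrom, position).

    Duplicate probe ids are allowed on input; averaging them is a
    normalisation step, not a parsing one.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    _check_header(df.columns, ["chrom", "position", "probe_id", "log2_ratio"], path)
    df = df.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return [
        ProbeRecord(r.chrom, int(r.position), r.probe_id, float(r.log2_ratio))
        for r in df.itertuples(index=False)
    ]


def write_probes(probes: Iterable[ProbeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tprobe_id\tlog2_ratio\n")
        for p in probes:
            fh.write(f"{p.chrom}\t{p.position}\t{p.probe_id}\t{p.log2_ratio!r}\n")


# ---------------------------------------------------------------------------
# edges / orthologues
# ---------------------------------------------------------------------------


def read_edges(path: str | Path) -> list[EdgeRecord]:
    """Read an interaction edge list; duplicate undirected edges collapse."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_header(df.columns, ["node_a", "node_b", "provenance", "directed"], path)
    seen: set[tuple] = set()
    edges: list[EdgeRecord] = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        directed = str(r.directed).strip().lower() in ("true", "1", "yes")
        rec = EdgeRecord(r.node_a, r.node_b, r.provenance, directed)
        key = (rec.node_a, rec.node_b, rec.provenance, rec.directed)
        if key in seen:
            logger.info("%s:%d: duplicate edge %s-%s dropped", path, i, rec.node_a, rec.node_b)
            continue
        seen.add(key)
        edges.append(rec)
    return edges


def write_edges(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tprovenance\tdirected\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.provenance}\t{str(e.directed).lower()}\n")


def read_orthologues(path: str | Path) -> dict[str, str]:
    """Read a mouse -> human orthologue table.

    The table must be pre-resolved to at most one human gene per mouse gene;
    rows repeating a mouse gene with a different human gene are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_header(df.columns, ["mouse_gene", "human_gene"], path)
    mapping: dict[str, str] = {}
    for i, r in enumerate(df.itertuples(index=False), start=2):
        if r.mouse_gene in mapping and mapping[r.mouse_gene] != r.human_gene:
            raise FormatError(
                f"{path}:{i}: mouse gene {r.mouse_gene!r} maps to multiple human genes"
            )
        mapping[r.mouse_gene] = r.human_gene
    return mapping


def write_orthologues(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_gene\thuman_gene\n")
        for m, h in mapping.items():
            fh.write(f"{m}\t{h}\n")


# ---------------------------------------------------------------------------
# segments (SEG-like)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "seg_mean", "state", "level"]


def write_segments(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_probes}\t"
                f"{s.seg_mean!r}\t{s.state}\t{s.level}\n"
            )


def read_segments(path: str | Path) -> list[SegmentRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "state": str})
    _check_header(df.columns, SEG_COLUMNS, path)
    return [
        SegmentRecord(
            r.sample, r.chrom, int(r.start), int(r.end), int(r.n_probes),
            float(r.seg_mean), r.state, int(r.level),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
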