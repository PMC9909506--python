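"""Core sequence types, configuration, and FASTA/AGP/BED input-output.

Coordinates are 0-based half-open everywhere inside the library.  AGP is
emitted 1-based inclusive (the AGP v2.1 convention) and BED 0-based
half-open, matching each format's ecosystem.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO as _BioSeqIO

__all__ = [
    "DNA_ALPHABET",
    "SeqRecord",
    "GenomicInterval",
    "Gap",
    "AgpPart",
    "Config",
    "FastaError",
    "AgpError",
    "read_fasta",
    "write_fasta",
    "find_n_runs",
    "read_agp",
    "write_agp",
    "validate_agp",
    "build_object_sequences",
    "write_bed",
]

DNA_ALPHABET = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed or invalid FASTA content."""


class AgpError(ValueError):
    """Malformed AGP content or a plan violating the tiling invariants."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over the uppercase alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if not self.sequence:
            raise FastaError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FastaError(
                f"sequence {self.id!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(ov/len(self), ov/len(other)) — both ends must be covered."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


@dataclass(frozen=True)
class Gap:
    """A maximal run of Ns inside an assembled object."""

    id: str
    interval: GenomicInterval

    @property
    def n_length(self) -> int:
        return self.interval.length

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class AgpPart:
    """One AGP v2.1 row: either a placed component or a gap."""

    object_id: str
    object_beg: int  # 1-based inclusive
    object_end: int  # 1-based inclusive
    part_number: int
    kind: str  # "component" | "gap"
    component_id: str | None = None
    orientation: str | None = None  # "+" | "-"
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("component", "gap"):
            raise AgpError(f"invalid part kind {self.kind!r}")
        if self.object_end < self.object_beg or self.object_beg < 1:
            raise AgpError(
                f"{self.object_id} part {self.part_number}: object_end "
                f"{self.object_end} < object_beg {self.object_beg}"
            )
        if self.part_number < 1:
            raise AgpError("part_number must be >= 1")
        if self.kind == "component":
            if not self.component_id or self.orientation not in ("+", "-"):
                raise AgpError(
                    f"{self.object_id} part {self.part_number}: component "
                    "rows need component_id and orientation"
                )
        else:
            if self.gap_length is None or self.gap_length < 1:
                raise AgpError(
                    f"{self.object_id} part {self.part_number}: gap rows "
                    "need a positive gap_length"
                )
            if self.gap_length != self.object_end - self.object_beg + 1:
                raise AgpError(
                    f"{self.object_id} part {self.part_number}: gap_length "
                    "inconsistent with object span"
                )

    @property
    def span(self) -> int:
        return self.object_end - self.object_beg + 1


@dataclass(frozen=True)
class Config:
    """All numeric knobs of the toolkit, with their working defaults.

    Thresholds quoted from the finishing procedure this package
    implements: donor flank alignments must reach ``flank_min_len`` (1 kb)
    at ``flank_min_identity`` (0.80) on both sides of a gap; telomeres are
    sought within ``terminal_window`` (50 kb) of each chromosome end;
    centromeric monomers are kept between ``monomer_min`` and
    ``monomer_max`` (100-200 bp); the tandem-repeat weights mirror the TRF
    parameter set (2, 7, 7, minscore 50, maxperiod 500).
    """

    # telomere scan
    telomere_units: tuple[str, ...] = ("AAACCCT", "CCCATTT")
    terminal_window: int = 50_000
    telomere_min_units: int = 10
    telomere_max_gap: int = 100
    # gap filling
    flank_min_len: int = 1000
    flank_min_identity: float = 0.80
    flank_window: int = 20_000
    spacer_gap_len: int = 100
    # centromere / tandem repeats
    monomer_min: int = 100
    monomer_max: int = 200
    cluster_identity: float = 0.80
    tr_match: int = 2
    tr_mismatch: int = 7
    tr_indel: int = 7
    tr_min_score: int = 50
    tr_max_period: int = 500
    loc_bin: int = 10_000
    report_bin: int = 100_000
    cen_bin_cov_min: float = 0.2
    cen_merge_gap_bins: int = 5
    cen_min_len: int = 50_000
    sim_window: int = 50_000
    # mapping / anchoring
    kmer_k: int = 15
    min_anchor_fraction: float = 0.5
    chain_max_gap: int = 2000
    chain_min_anchors: int = 3
    anchor_max_occ: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "terminal_window", "telomere_min_units", "telomere_max_gap",
            "flank_min_len", "flank_window", "spacer_gap_len", "monomer_min",
            "monomer_max", "tr_match", "tr_mismatch", "tr_indel",
            "tr_min_score", "tr_max_period", "loc_bin", "report_bin",
            "cen_merge_gap_bins", "cen_min_len", "sim_window", "kmer_k",
            "chain_max_gap", "chain_min_anchors", "anchor_max_occ",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"Config.{name} must be positive")
        if not self.monomer_min < self.monomer_max:
            raise ValueError("monomer_min must be < monomer_max")
        for name in ("flank_min_identity", "cluster_identity",
                     "cen_bin_cov_min", "min_anchor_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"Config.{name} must be in (0, 1]")
        for unit in self.telomere_units:
            if set(unit) - DNA_ALPHABET or "N" in unit:
                raise ValueError(f"invalid telomere unit {unit!r}")

    def with_(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: Union[str, Path, io.TextIOBase]) -> list[SeqRecord]:
    """Read a FASTA file into validated SeqRecords (uppercased).

    Duplicate ids, empty sequences, and characters outside ACGTN are
    rejected.
    """
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    try:
        records: list[SeqRecord] = []
        seen: set[str] = set()
        for rec in _BioSeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, str(rec.seq).upper()))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SeqRecord],
                path: Union[str, Path, io.TextIOBase],
                width: int = 60) -> None:
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# N-run discovery

def find_n_runs(record: SeqRecord, min_len: int = 1) -> list[Gap]:
    """Locate maximal runs of N of length >= min_len, left to right.

    Gap ids are ``{chrom}_gap{k}`` with k starting at 1.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    gaps: list[Gap] = []
    seq = record.sequence
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        if j - i >= min_len:
            gaps.append(Gap(
                id=f"{record.id}_gap{len(gaps) + 1}",
                interval=GenomicInterval(record.id, i, j),
            ))
        i = seq.find("N", j)
    return gaps


# ---------------------------------------------------------------------------
# AGP v2.1

def validate_agp(plan: Sequence[AgpPart]) -> None:
    """Check the tiling invariants: per object, parts tile [1, L] exactly
    with part numbers incrementing from 1."""
    by_object: dict[str, list[AgpPart]] = {}
    for part in plan:
        by_object.setdefault(part.object_id, []).append(part)
    for obj, parts in by_object.items():
        parts = sorted(parts, key=lambda p: p.part_number)
        expected_beg = 1
        for k, part in enumerate(parts, start=1):
            if part.part_number != k:
                raise AgpError(
                    f"{obj}: part numbers not consecutive at part {k}"
                )
            if part.object_beg != expected_beg:
                raise AgpError(
                    f"{obj} part {k}: hole or overlap at object_beg "
                    f"{part.object_beg} (expected {expected_beg})"
                )
            expected_beg = part.object_end + 1


def write_agp(plan: Sequence[AgpPart],
              path: Union[str, Path, io.TextIOBase]) -> None:
    validate_agp(plan)
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    try:
        handle.write("##agp-version\t2.1\n")
        for p in sorted(plan, key=lambda q: (q.object_id, q.part_number)):
            if p.kind == "component":
                comp_len = p.object_end - p.object_beg + 1
                row = [p.object_id, p.object_beg, p.object_end,
                       p.part_number, "W", p.component_id, 1, comp_len,
                       p.orientation]
            else:
                row = [p.object_id, p.object_beg, p.object_end,
                       p.part_number, "N", p.gap_length,
                       p.gap_type or "scaffold", p.linkage or "yes",
                       p.evidence or "align_genus"]
            handle.write("\t".join(str(x) for x in row) + "\n")
    finally:
        if close:
            handle.close()


def read_agp(path: Union[str, Path, io.TextIOBase]) -> list[AgpPart]:
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    try:
        plan: list[AgpPart] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AgpError(f"line {lineno}: expected 9 columns, got "
                               f"{len(fields)}")
            try:
                beg, end, num = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise AgpError(f"line {lineno}: non-integer coordinate") \
                    from exc
            kind_code = fields[4]
            if kind_code == "W":
                plan.append(AgpPart(
                    object_id=fields[0], object_beg=beg, object_end=end,
                    part_number=num, kind="component",
                    component_id=fields[5], orientation=fields[8],
                ))
            elif kind_code in ("N", "U"):
                plan.append(AgpPart(
                    object_id=fields[0], object_beg=beg, object_end=end,
                    part_number=num, kind="gap",
                    gap_length=int(fields[5]), gap_type=fields[6],
                    linkage=fields[7], evidence=fields[8],
                ))
            else:
                raise AgpError(f"line {lineno}: unsupported component type "
                               f"{kind_code!r}")
        validate_agp(plan)
        return plan
    finally:
        if close:
            handle.close()


def build_object_sequences(plan: Sequence[AgpPart],
                           components: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Materialize AGP objects by concatenating oriented components and
    N spacers in part order."""
    from .pairwise import revcomp  # local import to avoid a cycle

    validate_agp(plan)
    by_id = {c.id: c for c in components}
    if len(by_id) != len(components):
        raise AgpError("duplicate component ids")
    by_object: dict[str, list[AgpPart]] = {}
    for part in plan:
        by_object.setdefault(part.object_id, []).append(part)
    out: list[SeqRecord] = []
    for obj, parts in by_object.items():
        pieces: list[str] = []
        for part in sorted(parts, key=lambda p: p.part_number):
            if part.kind == "gap":
                pieces.append("N" * part.gap_length)
            else:
                comp = by_id.get(part.component_id)
                if comp is None:
                    raise AgpError(
                        f"{obj} part {part.part_number}: unknown component "
                        f"{part.component_id!r}"
                    )
                if comp.length != part.span:
                    raise AgpError(
                        f"{obj} part {part.part_number}: component "
                        f"{comp.id!r} length {comp.length} != object span "
                        f"{part.span}"
                    )
                pieces.append(comp.sequence if part.orientation == "+"
                              else revcomp(comp.sequence))
        out.append(SeqRecord(obj, "".join(pieces)))
    return out


def write_bed(intervals: Iterable[GenomicInterval],
              path: Union[str, Path, io.TextIOBase],
              names: Iterable[str] | None = None) -> None:
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    try:
        names_it = iter(names) if names is not None else None
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names_it is not None:
                cols += [next(names_it), "0", iv.strand]
            handle.write("\t".join(cols) + "\n")
    finally:
        if close:
            handle.close()
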