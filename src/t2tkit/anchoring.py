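"""Reference-guided contig anchoring without splitting (finishing stage 1).

Contigs are re-mapped against guide pseudochromosomes; each contig is
assigned, whole and uncut, to the chromosome collecting most of its
matched bases, oriented by the dominant strand there, and ordered along
the chromosome by the match-weighted median of its alignment midpoints.
Contigs whose anchored fraction falls below ``min_anchor_fraction`` go
to the unplaced set: a contig mostly unaligned to the guide is treated
as evidence of guide error, not grounds for forcing a join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .mapper import AlignmentRecord, TargetIndex
from .seqio import AgpPart, Config, SeqRecord

__all__ = ["Placement", "place_contigs", "build_plan", "anchor"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Placement:
    contig_id: str
    chrom: str
    orientation: str
    anchor_pos: float  # match-weighted median of target midpoints
    aligned_bases: int
    anchored_fraction: float


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def _weighted_median(values: list[float], weights: list[int]) -> float:
    pairs = sorted(zip(values, weights))
    half = sum(weights) / 2.0
    acc = 0
    for v, w in pairs:
        acc += w
        if acc >= half:
            return v
    return pairs[-1][0]


def place_contigs(contigs: Sequence[SeqRecord],
                  guide: Sequence[SeqRecord],
                  alignments: Sequence[AlignmentRecord],
                  cfg: Config | None = None
                  ) -> tuple[list[Placement], list[str]]:
    """Assign each contig a chromosome, orientation and anchor position.

    Returns (placements, unplaced contig ids); every contig appears
    exactly once across the two.
    """
    cfg = cfg or Config()
    contig_ids = {c.id for c in contigs}
    guide_ids = {g.id for g in guide}
    for rec in alignments:
        if rec.query_id not in contig_ids:
            raise ValueError(f"alignment query {rec.query_id!r} is not a "
                             "contig")
        if rec.target_id not in guide_ids:
            raise ValueError(f"alignment target {rec.target_id!r} is not "
                             "in the guide")
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_contig.setdefault(rec.query_id, []).append(rec)

    placements: list[Placement] = []
    unplaced: list[str] = []
    lengths = {c.id: len(c) for c in contigs}
    for contig in contigs:
        recs = by_contig.get(contig.id, [])
        if not recs:
            unplaced.append(contig.id)
            continue
        match_by_chrom: dict[str, int] = {}
        for r in recs:
            match_by_chrom[r.target_id] = \
                match_by_chrom.get(r.target_id, 0) + r.matches
        best_sum = max(match_by_chrom.values())
        tied = sorted(c for c, m in match_by_chrom.items()
                      if m == best_sum)
        if len(tied) > 1:
            log.warning("contig %s: chromosome tie %s, keeping %s",
                        contig.id, tied, tied[0])
        chrom = tied[0]
        strand_matches = {"+": 0, "-": 0}
        for r in recs:
            if r.target_id == chrom:
                strand_matches[r.strand] += r.matches
        orientation = "+" if strand_matches["+"] >= strand_matches["-"] \
            else "-"
        chosen = [r for r in recs
                  if r.target_id == chrom and r.strand == orientation]
        aligned = _union_len([(r.query_start, r.query_end)
                              for r in chosen])
        frac = aligned / lengths[contig.id]
        if frac < cfg.min_anchor_fraction:
            unplaced.append(contig.id)
            continue
        anchor_pos = _weighted_median(
            [(r.target_start + r.target_end) / 2.0 for r in chosen],
            [r.matches for r in chosen])
        placements.append(Placement(
            contig_id=contig.id, chrom=chrom, orientation=orientation,
            anchor_pos=anchor_pos, aligned_bases=aligned,
            anchored_fraction=frac))
    return placements, unplaced


def build_plan(placements: Sequence[Placement],
               contigs: Sequence[SeqRecord],
               cfg: Config | None = None) -> list[AgpPart]:
    """Order placed contigs per chromosome into an AGP plan, separated
    by fixed-length N spacer gaps.  No contig is ever cut."""
    cfg = cfg or Config()
    seen: set[str] = set()
    for p in placements:
        if p.contig_id in seen:
            raise ValueError(f"contig {p.contig_id!r} placed twice")
        seen.add(p.contig_id)
    lengths = {c.id: len(c) for c in contigs}
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)
    plan: list[AgpPart] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom],
            key=lambda p: (p.anchor_pos, -lengths[p.contig_id],
                           p.contig_id))
        # flag overlapping reference spans (kept intact, order by anchor)
        pos = 1
        for k, p in enumerate(ordered):
            if k > 0:
                plan.append(AgpPart(
                    object_id=chrom, object_beg=pos,
                    object_end=pos + cfg.spacer_gap_len - 1,
                    part_number=2 * k, kind="gap",
                    gap_length=cfg.spacer_gap_len, gap_type="scaffold",
                    linkage="yes", evidence="align_genus"))
                pos += cfg.spacer_gap_len
            clen = lengths[p.contig_id]
            plan.append(AgpPart(
                object_id=chrom, object_beg=pos,
                object_end=pos + clen - 1, part_number=2 * k + 1,
                kind="component", component_id=p.contig_id,
                orientation=p.orientation))
            pos += clen
    return plan


def anchor(contigs: Sequence[SeqRecord], guide: Sequence[SeqRecord],
           cfg: Config | None = None,
           alignments: Sequence[AlignmentRecord] | None = None
           ) -> tuple[list[AgpPart], list[Placement], list[str]]:
    """Map (unless alignments are supplied), place, and build the plan."""
    cfg = cfg or Config()
    if alignments is None:
        index = TargetIndex(guide, cfg.kmer_k)
        alignments = []
        for contig in contigs:
            # repeat k-mers carry no placement signal; cap them
            alignments.extend(index.map(contig, cfg,
                                        max_occ=cfg.anchor_max_occ))
    placements, unplaced = place_contigs(contigs, guide, alignments, cfg)
    plan = build_plan(placements, contigs, cfg)
    return plan, placements, unplaced
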