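"""Donor-contig gap filling with dual-flank overlap criteria (stage 2).

For every N-run gap, donors are mapped to both gap flanks; each flank
hit is re-verified with an exact global alignment, and a donor qualifies
only when both flanks align with block length >= 1 kb and identity >=
0.80 (inclusive bounds), on the same donor strand, in consistent order
along the donor.  The winning donor's spanning segment — the stretch
between the inner ends of its two flank alignments — replaces the
gap-tied sequence of the object.

Flank alignments that overlap on the donor are treated as abutting
contigs: the overlap is trimmed from the right side of the splice, so a
zero-length spanning segment is a legitimate closure of a spacer gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .mapper import AlignmentRecord, TargetIndex
from .pairwise import AlignmentStats, global_align, revcomp
from .seqio import Config, Gap, GenomicInterval, SeqRecord, find_n_runs

__all__ = ["DonorCandidate", "GapFillResult", "collect_candidates",
           "select_donor", "fill_gaps"]

log = logging.getLogger(__name__)

_LEFT = "__left_flank__"
_RIGHT = "__right_flank__"


@dataclass(frozen=True)
class DonorCandidate:
    donor_id: str
    donor_strand: str
    left_stats: AlignmentStats
    right_stats: AlignmentStats
    # object coordinates of the verified flank alignments
    left_obj: tuple[int, int]
    right_obj: tuple[int, int]
    # donor coordinates in splice orientation (reverse-complement space
    # for '-' donors)
    left_donor: tuple[int, int]
    right_donor: tuple[int, int]
    spanning: tuple[int, int]
    replaced: tuple[int, int]  # object interval the splice replaces
    mean_flank_identity: float

    @property
    def total_flank_block(self) -> int:
        return self.left_stats.block_length + self.right_stats.block_length


@dataclass(frozen=True)
class GapFillResult:
    gap_id: str
    status: str  # filled | no_candidate | threshold_fail | inconsistent_span
    chosen: DonorCandidate | None
    replaced_interval: GenomicInterval | None
    inserted_length: int


def _flanks(obj: SeqRecord, gap: Gap, window: int
            ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Up to ``window`` non-N bases on each side of the gap (object
    coordinates)."""
    seq = obj.sequence
    s = gap.start
    while s > 0 and gap.start - s < window and seq[s - 1] != "N":
        s -= 1
    e = gap.end
    L = len(seq)
    while e < L and e - gap.end < window and seq[e] != "N":
        e += 1
    return (s, gap.start), (gap.end, e)


def collect_candidates(obj: SeqRecord, gap: Gap,
                       donors: Sequence[SeqRecord],
                       cfg: Config | None = None
                       ) -> tuple[list[DonorCandidate], bool]:
    """Qualified donor candidates for one gap, sorted by the selection
    key.  The second return value reports whether any donor reached both
    flanks but failed the thresholds (distinguishes threshold_fail from
    no_candidate)."""
    cfg = cfg or Config()
    (lf0, lf1), (rf0, rf1) = _flanks(obj, gap, cfg.flank_window)
    if lf1 - lf0 == 0 or rf1 - rf0 == 0:
        log.warning("gap %s at object edge: missing a flank", gap.id)
        return [], False
    left_rec = SeqRecord(_LEFT, obj.sequence[lf0:lf1])
    right_rec = SeqRecord(_RIGHT, obj.sequence[rf0:rf1])
    index = TargetIndex([left_rec, right_rec], cfg.kmer_k)
    candidates: list[DonorCandidate] = []
    saw_dual_hit = False
    for donor in donors:
        recs = index.map(donor, cfg)
        for strand in ("+", "-"):
            lhits = [r for r in recs
                     if r.target_id == _LEFT and r.strand == strand]
            rhits = [r for r in recs
                     if r.target_id == _RIGHT and r.strand == strand]
            if not lhits or not rhits:
                continue
            saw_dual_hit = True
            lhit, rhit = lhits[0], rhits[0]  # map() sorts by matches
            cand = _verify_pair(obj, donor, strand, lhit, rhit,
                                lf0, rf0, cfg)
            if cand is not None:
                candidates.append(cand)
    candidates.sort(key=lambda c: (-c.mean_flank_identity,
                                   -c.total_flank_block, c.donor_id))
    return candidates, saw_dual_hit


def _oriented(donor: SeqRecord, strand: str) -> str:
    return donor.sequence if strand == "+" else revcomp(donor.sequence)


def _to_oriented(rec: AlignmentRecord, donor_len: int, strand: str
                 ) -> tuple[int, int]:
    """Donor interval of a hit, in splice orientation."""
    if strand == "+":
        return rec.query_start, rec.query_end
    return donor_len - rec.query_end, donor_len - rec.query_start


def _verify_pair(obj: SeqRecord, donor: SeqRecord, strand: str,
                 lhit: AlignmentRecord, rhit: AlignmentRecord,
                 lf0: int, rf0: int, cfg: Config) -> DonorCandidate | None:
    dlen = len(donor)
    oriented = _oriented(donor, strand)
    lq0, lq1 = _to_oriented(lhit, dlen, strand)
    rq0, rq1 = _to_oriented(rhit, dlen, strand)
    lt0, lt1 = lhit.target_start + lf0, lhit.target_end + lf0
    rt0, rt1 = rhit.target_start + rf0, rhit.target_end + rf0
    lstats = global_align(obj.sequence[lt0:lt1], oriented[lq0:lq1],
                          cfg.tr_match, -cfg.tr_mismatch, -cfg.tr_indel)
    rstats = global_align(obj.sequence[rt0:rt1], oriented[rq0:rq1],
                          cfg.tr_match, -cfg.tr_mismatch, -cfg.tr_indel)
    for st in (lstats, rstats):
        if st.block_length < cfg.flank_min_len \
                or st.identity < cfg.flank_min_identity:
            return None
    trim = 0
    if lq1 > rq0:
        # flank alignments overlap on the donor: abutting closure; trim
        # the overlap from the right side of the splice
        trim = lq1 - rq0
        if trim > rq1 - rq0 or trim > lq1 - lq0:
            log.warning("donor %s: flank overlap exceeds an alignment, "
                        "inconsistent span", donor.id)
            return None
    if rq0 + trim < lq1:  # flank order inverted on the donor
        return None
    return DonorCandidate(
        donor_id=donor.id, donor_strand=strand,
        left_stats=lstats, right_stats=rstats,
        left_obj=(lt0, lt1), right_obj=(rt0, rt1),
        left_donor=(lq0, lq1), right_donor=(rq0, rq1),
        spanning=(lq1, rq0 + trim),
        replaced=(lt1, rt0 + trim),
        mean_flank_identity=(lstats.identity + rstats.identity) / 2.0,
    )


def select_donor(candidates: Sequence[DonorCandidate]) -> DonorCandidate:
    """Deterministic argmax by (mean flank identity, total flank block
    length, lexicographically smallest donor id)."""
    if not candidates:
        raise ValueError("no candidates")
    return min(candidates, key=lambda c: (-c.mean_flank_identity,
                                          -c.total_flank_block,
                                          c.donor_id))


def fill_gaps(obj: SeqRecord, gaps: Sequence[Gap] | None,
              donors: Sequence[SeqRecord], cfg: Config | None = None
              ) -> tuple[SeqRecord, list[GapFillResult], pd.DataFrame]:
    """Close the gaps of one object with spanning donors.

    Gaps are processed right to left so earlier coordinates stay valid.
    Returns the new record, one result per gap, and a liftover table of
    the unreplaced blocks (old_start, old_end, new_start).
    """
    cfg = cfg or Config()
    if gaps is None:
        gaps = find_n_runs(obj)
    gaps = sorted(gaps, key=lambda g: g.start)
    for a, b in zip(gaps, gaps[1:]):
        if a.end > b.start:
            raise ValueError("gaps must be non-overlapping and sorted")
    seq = obj.sequence
    results: list[GapFillResult] = []
    replacements: list[tuple[int, int, str]] = []  # old interval, new seq
    leftmost_replaced = len(seq) + 1
    for gap in reversed(gaps):
        candidates, saw_dual = collect_candidates(obj, gap, donors, cfg)
        if not candidates:
            status = "threshold_fail" if saw_dual else "no_candidate"
            results.append(GapFillResult(gap.id, status, None, None, 0))
            continue
        chosen = select_donor(candidates)
        r0, r1 = chosen.replaced
        if r1 > leftmost_replaced:
            log.warning("gap %s: replaced interval collides with the "
                        "next gap's, skipping", gap.id)
            results.append(GapFillResult(gap.id, "inconsistent_span",
                                         None, None, 0))
            continue
        leftmost_replaced = r0
        s0, s1 = chosen.spanning
        insert = _oriented(
            next(d for d in donors if d.id == chosen.donor_id),
            chosen.donor_strand)[s0:s1]
        replacements.append((r0, r1, insert))
        results.append(GapFillResult(
            gap.id, "filled", chosen,
            GenomicInterval(obj.id, r0, r1), len(insert)))
    results.reverse()
    # apply right-to-left (already collected right-to-left)
    new_seq = seq
    for r0, r1, insert in replacements:
        new_seq = new_seq[:r0] + insert + new_seq[r1:]
    # liftover of unreplaced blocks, left to right
    rows = []
    shift = 0
    prev_end = 0
    for r0, r1, insert in sorted(replacements):
        if r0 > prev_end:
            rows.append({"old_start": prev_end, "old_end": r0,
                         "new_start": prev_end + shift})
        shift += len(insert) - (r1 - r0)
        prev_end = r1
    if prev_end < len(seq):
        rows.append({"old_start": prev_end, "old_end": len(seq),
                     "new_start": prev_end + shift})
    liftover = pd.DataFrame(rows,
                            columns=["old_start", "old_end", "new_start"])
    if not new_seq:
        new_seq = seq  # degenerate: everything replaced by nothing
    return SeqRecord(obj.id, new_seq), results, liftover
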