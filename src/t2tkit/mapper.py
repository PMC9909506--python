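"""Anchor-based local mapping with PAF semantics.

Exact k-mer anchors between query and target (both strands) are chained
greedily in target order: an anchor extends a chain when it advances both
the query and the target by at most ``chain_max_gap`` bases.  Each chain
with at least ``chain_min_anchors`` anchors is reported as one
AlignmentRecord.  This is a desk-scale stand-in for a production long-read
mapper; externally produced PAF can be imported anywhere mappings are
consumed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .pairwise import revcomp
from .seqio import Config, SeqRecord

__all__ = [
    "AlignmentRecord", "TargetIndex", "map_query", "import_paf", "write_paf",
    "PafError",
]


class PafError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment in PAF semantics (query coords on the forward
    strand, 0-based half-open)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"query interval out of range: {self}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"target interval out of range: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.matches > self.block_length or self.block_length < 1:
            raise ValueError("matches must be <= block_length (>= 1)")

    @property
    def identity(self) -> float:
        return self.matches / self.block_length


_ENC = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode all k-mers of seq as uint64; k-mers containing non-ACGT
    characters are excluded.  Returns (codes, start positions)."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    valid = codes >= 0
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        ok &= valid[j:j + n]
    enc = np.zeros(n, dtype=np.uint64)
    c = np.where(valid, codes, 0).astype(np.uint64)
    for j in range(k):
        enc = enc * np.uint64(4) + c[j:j + n]
    pos = np.nonzero(ok)[0].astype(np.int64)
    return enc[ok], pos


class TargetIndex:
    """Sorted k-mer index over a set of target sequences.

    Build once, map many queries (used heavily by centromere
    localization, where every cluster representative is mapped against
    every chromosome).
    """

    def __init__(self, targets: Sequence[SeqRecord], k: int = 15):
        ids = [t.id for t in targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        self.k = k
        self.targets = list(targets)
        self._codes: list[np.ndarray] = []
        self._pos: list[np.ndarray] = []
        for t in targets:
            codes, pos = _kmer_codes(t.sequence, k)
            order = np.argsort(codes, kind="stable")
            self._codes.append(codes[order])
            self._pos.append(pos[order])

    def map(self, query: SeqRecord, cfg: Config | None = None,
            max_occ: int | None = None) -> list[AlignmentRecord]:
        """Map one query.  ``max_occ`` drops query k-mers occurring more
        than that many times in a target — the usual repeat filter when
        placing long queries, where only unique anchors are
        informative.  Leave None when repetitive hits are the point
        (e.g. satellite monomer mapping)."""
        cfg = cfg or Config()
        k = self.k
        if len(query) < k:
            return []
        records: list[AlignmentRecord] = []
        # subsample anchors on very long queries; a stride below k keeps
        # query coverage gapless while shrinking the chaining workload
        stride = 4 if len(query) >= 200_000 else 1
        for strand in ("+", "-"):
            qseq = query.sequence if strand == "+" \
                else revcomp(query.sequence)
            qcodes, qpos = _kmer_codes(qseq, k)
            if stride > 1 and len(qcodes):
                keep = qpos % stride == 0
                qcodes, qpos = qcodes[keep], qpos[keep]
            if len(qcodes) == 0:
                continue
            for t, tcodes, tpos in zip(self.targets, self._codes, self._pos):
                lo = np.searchsorted(tcodes, qcodes, side="left")
                hi = np.searchsorted(tcodes, qcodes, side="right")
                counts = hi - lo
                if max_occ is not None:
                    counts = np.where(counts > max_occ, 0, counts)
                hit_idx = np.nonzero(counts)[0]
                if len(hit_idx) == 0:
                    continue
                # expand to (qpos, tpos) anchor pairs (vectorized ragged
                # gather over [lo, hi) runs)
                c = counts[hit_idx]
                run_starts = lo[hit_idx]
                total = int(c.sum())
                offsets = np.arange(total) - np.repeat(
                    np.cumsum(c) - c, c)
                q_anchor = np.repeat(qpos[hit_idx], c)
                t_anchor = tpos[np.repeat(run_starts, c) + offsets]
                order = np.lexsort((q_anchor, t_anchor))
                chains = _chain_anchors(
                    q_anchor[order], t_anchor[order], k, cfg.chain_max_gap)
                for ch in chains:
                    if ch["n"] < cfg.chain_min_anchors:
                        continue
                    q0, q1 = ch["q0"], ch["q1"] + k
                    t0, t1 = ch["t0"], ch["t1"] + k
                    if strand == "-":
                        q0, q1 = len(query) - q1, len(query) - q0
                    block = max(ch["q1"] + k - ch["q0"], t1 - t0)
                    records.append(AlignmentRecord(
                        query_id=query.id, query_len=len(query),
                        query_start=int(q0), query_end=int(q1),
                        strand=strand, target_id=t.id, target_len=len(t),
                        target_start=int(t0), target_end=int(t1),
                        matches=int(ch["mbases"]), block_length=int(block),
                    ))
        records.sort(key=lambda r: (-r.matches, r.target_id, r.target_start,
                                    r.strand, r.query_start))
        return records


def _chain_anchors(qa: np.ndarray, ta: np.ndarray, k: int, max_gap: int
                   ) -> list[dict]:
    """Greedy colinear chaining of anchors sorted by (target, query).

    A chain records its query/target bounds, anchor count and the number
    of distinct matched query bases (union of anchor spans).
    """
    qa = qa.tolist()
    ta = ta.tolist()
    open_chains: list[dict] = []
    done: list[dict] = []
    for q, t in zip(qa, ta):
        # retire chains that can no longer be extended
        still = []
        for ch in open_chains:
            if t - ch["t1"] > max_gap:
                done.append(ch)
            else:
                still.append(ch)
        open_chains = still
        best = None
        for ch in open_chains:
            if ch["q1"] < q <= ch["q1"] + max_gap and t > ch["t1"]:
                if best is None or ch["q1"] > best["q1"]:
                    best = ch
        if best is not None:
            best["mbases"] += min(k, q - best["q1"])
            best["q1"] = q
            best["t1"] = t
            best["n"] += 1
        else:
            open_chains.append({"q0": q, "q1": q, "t0": t, "t1": t,
                                "mbases": k, "n": 1})
    done.extend(open_chains)
    return done


def map_query(query: SeqRecord, targets: Sequence[SeqRecord],
              cfg: Config | None = None) -> list[AlignmentRecord]:
    """Map one query against targets; convenience wrapper over
    TargetIndex for one-shot use."""
    cfg = cfg or Config()
    return TargetIndex(targets, cfg.kmer_k).map(query, cfg)


# ---------------------------------------------------------------------------
# PAF

def import_paf(path: Union[str, Path, io.TextIOBase]
               ) -> list[AlignmentRecord]:
    """Read the 12 mandatory PAF columns into AlignmentRecords."""
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    try:
        records: list[AlignmentRecord] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafError(
                    f"line {lineno}: expected >= 12 columns, got "
                    f"{len(fields)}")
            try:
                records.append(AlignmentRecord(
                    query_id=fields[0], query_len=int(fields[1]),
                    query_start=int(fields[2]), query_end=int(fields[3]),
                    strand=fields[4], target_id=fields[5],
                    target_len=int(fields[6]), target_start=int(fields[7]),
                    target_end=int(fields[8]), matches=int(fields[9]),
                    block_length=int(fields[10]),
                ))
            except ValueError as exc:
                raise PafError(f"line {lineno}: {exc}") from exc
        return records
    finally:
        if close:
            handle.close()


def write_paf(records: Iterable[AlignmentRecord],
              path: Union[str, Path, io.TextIOBase]) -> None:
    handle = path
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "w")
        close = True
    try:
        for r in records:
            handle.write("\t".join(str(x) for x in (
                r.query_id, r.query_len, r.query_start, r.query_end,
                r.strand, r.target_id, r.target_len, r.target_start,
                r.target_end, r.matches, r.block_length, 255,
            )) + "\n")
    finally:
        if close:
            handle.close()
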