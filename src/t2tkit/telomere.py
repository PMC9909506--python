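"""Terminal telomeric-repeat detection and T2T status summary.

The scan looks for exact occurrences of the configured 7-bp units and
their reverse complements inside a terminal window at each chromosome
end (default 50 kb), groups occurrences into runs whose consecutive
matches are at most ``telomere_max_gap`` bases apart, and calls the run
nearest the chromosome end once it reaches ``telomere_min_units``
matches.  A single isolated unit therefore never constitutes a
telomere.  Call polarity (five_prime / three_prime) comes from window
position, not from match strand: the plant telomere motif appears as
C-rich arrays on the 5' arm and G-rich arrays on the 3' arm, and the
default unit set covers both written forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pairwise import revcomp
from .seqio import Config, GenomicInterval, SeqRecord

__all__ = ["TelomereCall", "T2TSummary", "scan_telomeres", "summarize_t2t"]


@dataclass(frozen=True)
class TelomereCall:
    chrom: str
    chrom_end: str  # "five_prime" | "three_prime"
    interval: GenomicInterval
    unit_count: int
    offset_from_end: int

    @property
    def span(self) -> int:
        return self.interval.length


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _runs(positions: list[int], unit_len: int, max_gap: int
          ) -> list[tuple[int, int, int]]:
    """Group sorted match positions into runs; returns
    (start, end, n_matches) with end = last match start + unit_len."""
    if not positions:
        return []
    runs = []
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - (prev + unit_len) <= max_gap:
            count += 1
        else:
            runs.append((start, prev + unit_len, count))
            start, count = p, 1
        prev = p
    runs.append((start, prev + unit_len, count))
    return runs


def scan_telomeres(record: SeqRecord, cfg: Config | None = None
                   ) -> list[TelomereCall]:
    """Scan both terminal windows of a record; 0-2 calls."""
    cfg = cfg or Config()
    units = set()
    for u in cfg.telomere_units:
        units.add(u)
        units.add(revcomp(u))
    unit_len = len(next(iter(units)))
    if any(len(u) != unit_len for u in units):
        raise ValueError("telomere units must share one length")
    L = len(record)
    window = min(cfg.terminal_window, L)
    calls: list[TelomereCall] = []
    for end_name in ("five_prime", "three_prime"):
        if end_name == "five_prime":
            w_start = 0
            sub = record.sequence[:window]
        else:
            w_start = L - window
            sub = record.sequence[w_start:]
        positions = sorted(
            p for u in sorted(units) for p in _find_all(sub, u))
        # deduplicate (distinct units cannot share a start, but be safe)
        positions = sorted(set(positions))
        best = None
        for start, end, count in _runs(positions, unit_len,
                                       cfg.telomere_max_gap):
            if count < cfg.telomere_min_units:
                continue
            # nearest the chromosome end
            dist = start if end_name == "five_prime" else window - end
            if best is None or dist < best[0]:
                best = (dist, start, end, count)
        if best is not None:
            _, start, end, count = best
            iv = GenomicInterval(record.id, w_start + start, w_start + end)
            offset = iv.start if end_name == "five_prime" else L - iv.end
            calls.append(TelomereCall(record.id, end_name, iv, count,
                                      offset))
    return calls


@dataclass
class T2TSummary:
    table: pd.DataFrame
    total_telomeres: int
    t2t_count: int


def summarize_t2t(calls: list[TelomereCall], chroms: list[str]
                  ) -> T2TSummary:
    """Per-chromosome telomere counts and the telomere-to-telomere flag
    (both ends present)."""
    by_chrom: dict[str, set[str]] = {c: set() for c in chroms}
    for call in calls:
        if call.chrom in by_chrom:
            by_chrom[call.chrom].add(call.chrom_end)
    rows = []
    for c in chroms:
        ends = by_chrom[c]
        rows.append({
            "chrom": c,
            "five_prime": "five_prime" in ends,
            "three_prime": "three_prime" in ends,
            "n_telomeres": len(ends),
            "t2t": len(ends) == 2,
        })
    table = pd.DataFrame(rows)
    return T2TSummary(
        table=table,
        total_telomeres=int(table["n_telomeres"].sum()),
        t2t_count=int(table["t2t"].sum()),
    )
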