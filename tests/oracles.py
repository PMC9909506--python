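"""Independent brute-force oracles used only by the tests.

The global-alignment oracle is a plain tuple-DP over (score, matches),
with no traceback: given the optimal (score, matches) and the two
sequence lengths, all four column counts of the canonical optimal
alignment follow algebraically whenever mismatch != 2*gap, so the
oracle never shares code or strategy with the vectorized implementation
it checks.
"""

from __future__ import annotations


def nw_best_score_matches(a: str, b: str, match: int = 2,
                          mismatch: int = -7, gap: int = -7
                          ) -> tuple[int, int]:
    """Lexicographic max of (score, matches) over all global alignments."""
    n, m = len(a), len(b)
    prev = [(j * gap, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i * gap, 0)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            hit = ai == b[j - 1] and ai != "N"
            ds, dm = prev[j - 1]
            us, um = prev[j]
            ls, lm = cur[j - 1]
            cand = (ds + match, dm + 1) if hit else (ds + mismatch, dm)
            cur.append(max(cand, (us + gap, um), (ls + gap, lm)))
        prev = cur
    return prev[m]


def nw_oracle_stats(a: str, b: str, match: int = 2, mismatch: int = -7,
                    gap: int = -7) -> dict:
    """Full column counts of the canonical optimal alignment, derived
    algebraically from (score, matches)."""
    assert mismatch != 2 * gap, "counts not determined in this regime"
    n, m = len(a), len(b)
    score, matches = nw_best_score_matches(a, b, match, mismatch, gap)
    num = score - match * matches - gap * (n + m - 2 * matches)
    den = mismatch - 2 * gap
    assert num % den == 0
    mismatches = num // den
    deletions = n - matches - mismatches   # gaps in b
    insertions = m - matches - mismatches  # gaps in a
    block = matches + mismatches + insertions + deletions
    return {
        "score": score, "matches": matches, "mismatches": mismatches,
        "insertions": insertions, "deletions": deletions,
        "block_length": block, "identity": matches / block,
    }


def all_rotations_and_revcomp(seq: str) -> list[str]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    out = []
    for s in (seq, rc):
        for i in range(len(s)):
            out.append(s[i:] + s[:i])
    return out
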