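"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the implementation's data structures and
shortcuts: the fold oracle enumerates nested structures recursively with
no memoisation, and the matching oracle scores every (entry, strand,
offset) with a plain mismatch count and applies the documented tie-break
by sorting.
"""

from __future__ import annotations

_PAIR_OK = {"AT", "TA", "GC", "CG", "GT", "TG"}


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over all nested structures, by exhaustive recursion."""

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        m = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in _PAIR_OK:
                m = max(m, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return m

    return best(0, len(seq) - 1)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def brute_force_match(
    seq: str,
    entries,  # sequence of objects with .id and .sequence
    max_mismatch: int,
    strands: tuple[str, ...] = ("+", "-"),
) -> tuple[str, int, int, str] | None:
    """All-offsets scan returning (ref_id, mismatches, offset, strand) or None.

    Ties: fewer mismatches, earlier catalog entry, smaller offset, sense
    before antisense.
    """
    candidates = []
    for idx, entry in enumerate(entries):
        ref = entry.sequence
        for srank, strand in enumerate(("+", "-")):
            if strand not in strands:
                continue
            query = seq if strand == "+" else _revcomp(seq)
            for off in range(len(ref) - len(query) + 1):
                mm = sum(a != b for a, b in zip(query, ref[off : off + len(query)]))
                if mm <= max_mismatch:
                    candidates.append(((mm, idx, off, srank), (entry.id, mm, off, strand)))
    if not candidates:
        return None
    return min(candidates)[1]
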