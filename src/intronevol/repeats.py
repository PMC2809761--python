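"""Direct repeats linking the two splice junctions of an intron.

A dotplot-style search: exact word-length seeds between a window around
the 5' junction (copy A) and a window around the 3' junction (copy B) are
chained along their diagonal and extended outward through a bounded number
of mismatches.  A hit is reported as the two copy intervals with its
match/span identity (e.g. 16/18).  Repeats that span both junctions are
the signature of an insertion flanked by direct repeats, as produced by
non-homologous end joining after uneven double-strand breaks.

Only direct (same-strand) repeats are searched.  With ``max_mismatches=0``
the hit set is exactly the exact-match dotplot (window = word size,
mismatch = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

VALID = set("ACGT")


@dataclass(frozen=True)
class RepeatHit:
    """One direct repeat; coordinates index the sequence passed in."""

    copyA_start: int
    copyA_end: int
    copyB_start: int
    copyB_end: int
    matches: int
    span: int
    overlaps_5ss: bool
    overlaps_3ss: bool

    @property
    def identity(self) -> str:
        return f"{self.matches}/{self.span}"


def _maximal_segments(match: list[bool], word: int, k: int) -> list[tuple[int, int]]:
    """All maximal segments of a match bitmap with <= k mismatches that
    contain an exact run of >= word matches and start/end on a match.

    Each maximal exact run is extended left through ``a`` mismatches and
    right through ``k - a`` for every split ``a``; endpoints are trimmed to
    matches.  Containment-deduplication leaves exactly the maximal valid
    segments.
    """
    m = len(match)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < m:
        if match[i]:
            j = i
            while j < m and match[j]:
                j += 1
            if j - i >= word:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return []
    candidates: set[tuple[int, int]] = set()
    for s, e in runs:
        for a in range(k + 1):
            lo = s
            budget = a
            p = s - 1
            best_lo = s
            while p >= 0:
                if match[p]:
                    best_lo = p
                else:
                    if budget == 0:
                        break
                    budget -= 1
                p -= 1
            lo = best_lo
            budget = k - a
            q = e
            best_hi = e
            while q < m:
                if match[q]:
                    best_hi = q + 1
                else:
                    if budget == 0:
                        break
                    budget -= 1
                q += 1
            candidates.add((lo, best_hi))
    segs = sorted(candidates)
    maximal = [
        (lo, hi)
        for lo, hi in segs
        if not any((lo2 <= lo and hi <= hi2) and (lo2, hi2) != (lo, hi) for lo2, hi2 in segs)
    ]
    return maximal


def find_junction_repeats(
    sequence: str,
    intron_start: int,
    intron_end: int,
    flank: int = 50,
    word: int = 8,
    max_mismatches: int = 2,
) -> list[RepeatHit]:
    """Enumerate direct repeats between the 5' and 3' junction neighborhoods.

    Window A covers ``intron_start`` +/- ``flank`` and window B covers
    ``intron_end`` +/- ``flank``; when the intron is shorter than twice the
    flank the intronic parts are truncated at the intron midpoint so the
    windows never overlap.  Hits are sorted by matches descending, then
    span descending, then leftmost.  ``overlaps_5ss`` is true when copy A
    covers position ``intron_start`` (the first intron base); likewise
    ``overlaps_3ss`` for copy B and ``intron_end``.
    """
    if word < 4:
        raise ValueError("word size must be >= 4")
    if not 0 <= intron_start < intron_end <= len(sequence):
        raise ValueError("intron coordinates outside sequence")
    seq = sequence.upper()
    mid = (intron_start + intron_end) // 2
    a_lo = max(0, intron_start - flank)
    a_hi = min(intron_start + flank, mid)
    b_lo = max(intron_end - flank, mid)
    b_hi = min(len(seq), intron_end + flank)

    hits: list[RepeatHit] = []
    seen: set[tuple[int, int, int]] = set()
    for d in range(b_lo - a_hi + 1, b_hi - a_lo):
        lo = max(a_lo, b_lo - d)
        hi = min(a_hi, b_hi - d)
        if hi - lo < word:
            continue
        match = [
            seq[i] == seq[i + d] and seq[i] in VALID
            for i in range(lo, hi)
        ]
        for s, e in _maximal_segments(match, word, max_mismatches):
            key = (d, s, e)
            if key in seen:
                continue
            seen.add(key)
            span = e - s
            matches = sum(match[s:e])
            ca, cb = lo + s, lo + s + d
            hits.append(
                RepeatHit(
                    copyA_start=ca,
                    copyA_end=ca + span,
                    copyB_start=cb,
                    copyB_end=cb + span,
                    matches=matches,
                    span=span,
                    overlaps_5ss=ca <= intron_start < ca + span,
                    overlaps_3ss=cb <= intron_end < cb + span,
                )
            )
    hits.sort(key=lambda h: (-h.matches, -h.span, h.copyA_start, h.copyB_start))
    return hits


def junction_repeats_for_intron(
    contig_seq: str,
    gene_local_start: int,
    gene_local_end: int,
    gene_offset: int,
    **kwargs,
) -> list[RepeatHit]:
    """Convenience wrapper mapping gene-local intron coordinates into a
    contig: ``gene_offset`` is the contig position of the gene's 5' end on
    the coding strand (the caller handles strand orientation)."""
    return find_junction_repeats(
        contig_seq,
        gene_offset + gene_local_start,
        gene_offset + gene_local_end,
        **kwargs,
    )
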