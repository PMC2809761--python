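"""Independent brute-force oracles used to check the package's algorithms.

Each oracle implements the operation's definition directly (exhaustive
enumeration or direct translation) without sharing code with the
implementation under test.
"""

from __future__ import annotations

import itertools

STOPS = {"TAA", "TAG", "TGA"}


# --- Dollo parsimony ------------------------------------------------------

def _leaves_below(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def _count_losses_under(node, present: set[str]) -> int:
    """Number of maximal all-absent subtrees within node's clade."""
    total = 0
    for child in node.child_nodes():
        below = _leaves_below(child)
        if below & present:
            total += _count_losses_under(child, present)
        else:
            total += 1
    return total


def dollo_min_losses(tree, present: set[str]) -> int:
    """Exhaustive minimum loss count over all single-gain placements."""
    best = None
    for node in tree.preorder_node_iter():
        if not present <= _leaves_below(node):
            continue
        losses = _count_losses_under(node, present)
        if best is None or losses < best:
            best = losses
    assert best is not None
    return best


def maximal_absent_subtrees(node, present: set[str]) -> set[str]:
    """Branch labels of maximal all-absent subtrees within node's clade."""
    out: set[str] = set()

    def walk(n):
        for child in n.child_nodes():
            if _leaves_below(child) & present:
                walk(child)
            else:
                out.add(child.label)

    walk(node)
    return out


# --- PTC scanning ---------------------------------------------------------

def ptc_by_translation(
    flank5: str, intron: str, flank3: str, phase: int, include_boundary: bool
):
    """Scan the retained transcript in the exonic frame; classify each stop
    codon as internal (fully inside the intron) or junction-spanning.

    Returns (has_ptc, first_internal_offset_or_None).
    """
    whole = (flank5 + intron + flank3).upper()
    f5, L = len(flank5), len(intron)
    start = (f5 - phase) % 3
    first_internal = None
    boundary = False
    for p in range(start, len(whole) - 2, 3):
        if whole[p:p + 3] not in STOPS:
            continue
        inside = p >= f5 and p + 3 <= f5 + L
        overlaps = p + 3 > f5 and p < f5 + L
        if inside:
            if first_internal is None:
                first_internal = p - f5
        elif overlaps:
            boundary = True
    has = first_internal is not None or (include_boundary and boundary)
    return has, first_internal


# --- junction repeats -----------------------------------------------------

def brute_force_repeats(
    seq: str, intron_start: int, intron_end: int, flank: int, word: int, k: int
) -> set[tuple[int, int, int, int]]:
    """All maximal gapless repeat segments between the junction windows.

    Enumerates every (diagonal, start, end) segment, keeps those with <= k
    mismatches, match endpoints and an exact run >= word, then removes
    segments contained in a longer valid segment on the same diagonal.
    Returns {(copyA_start, copyB_start, span, matches)}.
    """
    seq = seq.upper()
    mid = (intron_start + intron_end) // 2
    a_lo, a_hi = max(0, intron_start - flank), min(intron_start + flank, mid)
    b_lo, b_hi = max(intron_end - flank, mid), min(len(seq), intron_end + flank)
    valid_by_diag: dict[int, list[tuple[int, int, int]]] = {}
    for i in range(a_lo, a_hi):
        for j in range(b_lo, b_hi):
            d = j - i
            # build segments starting at (i, j)
            max_len = min(a_hi - i, b_hi - j)
            mism = 0
            run = 0
            best_run = 0
            for s in range(max_len):
                x, y = seq[i + s], seq[j + s]
                ok = x == y and x in "ACGT"
                if ok:
                    run += 1
                else:
                    mism += 1
                    run = 0
                best_run = max(best_run, run)
                if mism > k:
                    break
                span = s + 1
                first_ok = seq[i] == seq[j] and seq[i] in "ACGT"
                if ok and first_ok and best_run >= word:
                    valid_by_diag.setdefault(d, []).append((i, span, span - mism))
    out: set[tuple[int, int, int, int]] = set()
    for d, segs in valid_by_diag.items():
        for i, span, matches in segs:
            contained = any(
                (i2 <= i and i + span <= i2 + span2) and (i2, span2) != (i, span)
                for i2, span2, _ in segs
            )
            if not contained:
                out.add((i, i + d, span, matches))
    return out
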