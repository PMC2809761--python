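"""Positional bias of intron classes and codon usage of intron sequence.

Relative position of an intron is its coding offset divided by the CDS
length, in [0, 1).  A 5' bias -- more introns in the first half of the
gene than the second -- is tested with a Pearson chi-square against the
uniform expectation; two classes are compared with a 2x2 chi-square on the
5'/3' half split.  The "codon" usage of intron sequence is read in the
retention frame (the frame in which retained-intron stops are scanned)
and compared with a reference exonic codon-usage table by Spearman rank
correlation: sequence that never passed through a coding stage should show
no correlation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import STOP_CODONS
from .nmd import retention_frame_offset
from .simulate import ALL_CODONS


def relative_position(cds_offset: int, cds_length: int) -> float:
    if not 0 <= cds_offset < cds_length:
        raise ValueError(f"cds_offset {cds_offset} outside [0, {cds_length})")
    return cds_offset / cds_length


def uniformity_chisq(
    positions: Sequence[float], n_bins: int = 2
) -> tuple[float, int, float]:
    """Pearson chi-square of relative positions against uniformity.

    Positions are binned into ``n_bins`` equal-width bins on [0, 1); the
    default two-bin test asks only whether the 5' half holds more introns
    than the 3' half.  Returns (chi2, df, p).  If any expected count drops
    below 5 a warning is raised and, for the two-bin case, an exact
    binomial test is used instead (chi2 reported as NaN).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("no positions")
    if np.any((pos < 0) | (pos >= 1)):
        raise ValueError("relative positions must lie in [0, 1)")
    counts, _ = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    expected = pos.size / n_bins
    if expected < 5:
        warnings.warn(f"expected count {expected:.1f} < 5; chi-square unreliable")
        if n_bins == 2:
            p = stats.binomtest(int(counts[0]), pos.size, 0.5).pvalue
            return float("nan"), 1, float(p)
    chi2, p = stats.chisquare(counts)
    return float(chi2), n_bins - 1, float(p)


def two_sample_chisq(
    positions_a: Sequence[float], positions_b: Sequence[float]
) -> tuple[float, int, float]:
    """2x2 Pearson chi-square (no continuity correction): class x 5'/3' half."""
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    table = np.array(
        [
            [np.sum(a < 0.5), np.sum(a >= 0.5)],
            [np.sum(b < 0.5), np.sum(b >= 0.5)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def intron_codon_usage(
    introns: pd.DataFrame, frame: str = "retention"
) -> pd.Series:
    """Codon usage (per 1,000 codons) of intron sequence.

    Codons are read starting at the retention-frame offset of each intron
    (``frame="zero"`` reads from the first base instead) and pooled over
    all introns; codons containing an ambiguous base are skipped and
    counted.  Expects columns ``seq`` and ``phase``.
    """
    if len(introns) == 0:
        raise ValueError("empty intron set")
    counts = pd.Series(0, index=ALL_CODONS, dtype=float)
    skipped = 0
    for seq, phase in zip(introns["seq"], introns["phase"]):
        s = seq.upper()
        start = retention_frame_offset(int(phase)) if frame == "retention" else 0
        for i in range(start, len(s) - 2, 3):
            codon = s[i:i + 3]
            if codon in counts.index:
                counts[codon] += 1
            else:
                skipped += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no complete codons in intron set")
    usage = counts / total * 1000.0
    usage.attrs["n_codons"] = int(total)
    usage.attrs["n_skipped"] = skipped
    return usage


def usage_correlation(
    usage: pd.Series, reference: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, two-sided p)
    between a 64-codon usage vector and a reference table."""
    if len(usage) != 64 or len(reference) != 64:
        raise ValueError("usage vectors must have 64 entries")
    ref = reference.reindex(usage.index)
    if ref.isna().any():
        raise ValueError("reference table missing codons")
    if usage.nunique() == 1 or ref.nunique() == 1:
        raise ValueError("constant usage vector: correlation undefined")
    rho, p = stats.spearmanr(usage.to_numpy(), ref.to_numpy())
    return float(rho), float(p)
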