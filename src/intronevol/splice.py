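"""Splice-site strength and motif diversity by bootstrap resampling.

Strength is the fraction of introns using the canonical donor GT(A/G)AGT
(intron positions +1..+6) or the canonical acceptor CAG (positions
-3..-1).  A focal set (e.g. novel introns) is compared against a large
reference pool by drawing B bootstrap samples of the focal size from the
reference and asking whether the focal value falls outside the percentile
95% interval of the resampled statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

CANONICAL_DONORS = frozenset({"GTAAGT", "GTGAGT"})
CANONICAL_ACCEPTOR = "CAG"


def donor_is_consensus(donor6: str) -> bool:
    """True iff the 6-mer is GT(A/G)AGT.  Any N disqualifies."""
    return donor6.upper() in CANONICAL_DONORS


def acceptor_is_consensus(acceptor3: str) -> bool:
    """True iff the -3..-1 trimer is CAG."""
    return acceptor3.upper() == CANONICAL_ACCEPTOR


def donor_consensus_frac(motifs: Sequence[str]) -> float:
    return sum(donor_is_consensus(m) for m in motifs) / len(motifs)


def acceptor_consensus_frac(motifs: Sequence[str]) -> float:
    return sum(acceptor_is_consensus(m) for m in motifs) / len(motifs)


def motif_diversity(motifs: Sequence[str]) -> int:
    """Number of distinct donor 6-mers in a sample (order-invariant)."""
    if len(motifs) == 0:
        raise ValueError("empty motif sample")
    return len(set(m.upper() for m in motifs))


STATISTICS: dict[str, Callable[[Sequence[str]], float]] = {
    "donor_consensus_frac": donor_consensus_frac,
    "acceptor_consensus_frac": acceptor_consensus_frac,
    "distinct_donor_motifs": motif_diversity,
}


def _resampled_statistic(
    motifs: Sequence[str],
    statistic: str,
    B: int,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """B bootstrap replicates of the statistic, vectorized over samples.

    Motifs are factorized to integer codes once; fraction statistics become
    a boolean lookup + row mean, the diversity statistic a row sort +
    distinct count.
    """
    pool = [m.upper() for m in motifs]
    uniq, codes = np.unique(pool, return_inverse=True)
    idx = rng.integers(0, len(codes), size=(B, n))
    sampled = codes[idx]
    if statistic == "distinct_donor_motifs":
        sampled.sort(axis=1)
        return (np.diff(sampled, axis=1) != 0).sum(axis=1) + 1.0
    fn = STATISTICS[statistic]
    per_code = np.array([fn([u]) for u in uniq])  # 0/1 per unique motif
    return per_code[sampled].mean(axis=1)


@dataclass(frozen=True)
class BootstrapSummary:
    statistic: str
    observed_focal: float
    observed_reference: float
    B: int
    focal_n: int
    ci_low: float
    ci_high: float
    significant: bool
    seed: int
    focal_ci_low: float | None = None
    focal_ci_high: float | None = None


def bootstrap_statistic(
    reference_motifs: Sequence[str],
    focal_motifs: Sequence[str],
    statistic: str,
    B: int = 10_000,
    focal_n: int | None = None,
    seed: int = 0,
    resample_focal: bool = False,
) -> BootstrapSummary:
    """Percentile-bootstrap comparison of a focal intron set vs a reference.

    Draws ``B`` samples of size ``focal_n`` (default: the focal set size)
    with replacement from the reference pool, computes the statistic on
    each, and takes the 2.5th/97.5th percentiles (linear interpolation
    between order statistics) as the 95% CI.  The focal set is significant
    when its observed value falls outside that interval.  Optionally the
    focal set is resampled the same way, which describes the variance
    within the focal set but is not needed for the significance call.
    """
    if len(reference_motifs) == 0:
        raise ValueError("reference set is empty")
    if len(focal_motifs) == 0:
        raise ValueError("focal set is empty")
    if B < 100:
        raise ValueError("B must be >= 100")
    fn = STATISTICS[statistic]
    n = focal_n if focal_n is not None else len(focal_motifs)
    if n < 1:
        raise ValueError("focal_n must be >= 1")
    rng = np.random.default_rng(seed)
    stats = _resampled_statistic(reference_motifs, statistic, B, n, rng)
    ci_low, ci_high = np.quantile(stats, [0.025, 0.975])
    observed_focal = fn(focal_motifs)
    focal_lo = focal_hi = None
    if resample_focal:
        fstats = _resampled_statistic(focal_motifs, statistic, B, n, rng)
        focal_lo, focal_hi = np.quantile(fstats, [0.025, 0.975])
    return BootstrapSummary(
        statistic=statistic,
        observed_focal=float(observed_focal),
        observed_reference=float(fn(reference_motifs)),
        B=B,
        focal_n=n,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=bool(observed_focal < ci_low or observed_focal > ci_high),
        seed=seed,
        focal_ci_low=None if focal_lo is None else float(focal_lo),
        focal_ci_high=None if focal_hi is None else float(focal_hi),
    )
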