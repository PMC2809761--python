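"""Positional-bias tests and intron codon usage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from intronevol.position import (
    intron_codon_usage,
    relative_position,
    two_sample_chisq,
    uniformity_chisq,
    usage_correlation,
)
from intronevol.simulate import draw_positions, synthetic_codon_usage


def test_all_5prime_closed_form():
    """100 positions all < 0.5 in two bins: chi2 = (50^2/50)*2 = 100."""
    chi2, df, p = uniformity_chisq([0.1] * 100, n_bins=2)
    assert chi2 == pytest.approx(100.0)
    assert df == 1
    assert p == pytest.approx(1.52e-23, rel=0.05)


def test_balanced_split_gives_zero():
    pos = [0.25] * 50 + [0.75] * 50
    chi2, _, p = uniformity_chisq(pos, n_bins=2)
    assert chi2 == 0.0 and p == 1.0


def test_two_bin_equals_closed_form_identity():
    rng = np.random.default_rng(0)
    pos = rng.random(200)
    chi2, _, _ = uniformity_chisq(pos, n_bins=2)
    n5 = np.sum(pos < 0.5)
    assert chi2 == pytest.approx((abs(n5 - 100) ** 2) * 4 / 200)


def test_small_sample_binomial_fallback():
    with pytest.warns(UserWarning, match="chi-square unreliable"):
        chi2, df, p = uniformity_chisq([0.1, 0.2, 0.3], n_bins=2)
    assert np.isnan(chi2) and 0 <= p <= 1


def test_two_sample_chisq_hand_computed():
    """(90,10) vs (50,50): Pearson chi2 on the 2x2 table = 800/21."""
    a = [0.1] * 90 + [0.9] * 10
    b = [0.1] * 50 + [0.9] * 50
    chi2, df, p = two_sample_chisq(a, b)
    assert df == 1
    assert chi2 == pytest.approx(800 / 21)  # = 38.095...


def test_two_sample_chisq_symmetry_and_identity():
    a = [0.1] * 30 + [0.9] * 10
    b = [0.2] * 60 + [0.8] * 20
    assert two_sample_chisq(a, b)[0] == pytest.approx(two_sample_chisq(b, a)[0])
    same = [0.1] * 20 + [0.9] * 20
    assert two_sample_chisq(same, same)[0] == pytest.approx(0.0)


def test_skewed_positions_dominate_uniform_ecdf():
    rng = np.random.default_rng(1)
    skewed = draw_positions(1.0, 2000, rng)
    chi2, _, p = uniformity_chisq(skewed)
    assert p < 1e-6 and np.mean(skewed < 0.5) > 0.5


def test_relative_position_bounds():
    assert relative_position(0, 30) == 0.0
    with pytest.raises(ValueError):
        relative_position(30, 30)


def test_codon_usage_single_intron_phase0():
    df = pd.DataFrame({"seq": ["GTAAGT"], "phase": [0]})
    usage = intron_codon_usage(df)
    assert usage["GTA"] == pytest.approx(500.0)
    assert usage["AGT"] == pytest.approx(500.0)
    assert usage.sum() == pytest.approx(1000.0)


def test_codon_usage_respects_retention_frame():
    df = pd.DataFrame({"seq": ["GTAAGTA"], "phase": [2]})  # offset 1: TAA, GTA
    usage = intron_codon_usage(df)
    assert usage["TAA"] == pytest.approx(500.0)
    assert usage["GTA"] == pytest.approx(500.0)


def test_codon_usage_empty_set_errors():
    with pytest.raises(ValueError, match="empty"):
        intron_codon_usage(pd.DataFrame({"seq": [], "phase": []}))


def test_codon_usage_pooling_invariance():
    rng = np.random.default_rng(2)
    seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]) for _ in range(20)]
    df = pd.DataFrame({"seq": seqs, "phase": [0] * 20})
    pooled = intron_codon_usage(df)
    counts = pooled * pooled.attrs["n_codons"] / 1000.0
    manual = pd.Series(0.0, index=pooled.index)
    for s in seqs:
        one = intron_codon_usage(pd.DataFrame({"seq": [s], "phase": [0]}))
        manual += one * one.attrs["n_codons"] / 1000.0
    assert np.allclose(counts.to_numpy(), manual.to_numpy())


def test_usage_correlation_extremes_and_errors():
    usage = synthetic_codon_usage(3)
    rho, p = usage_correlation(usage, usage)
    assert rho == pytest.approx(1.0)
    reversed_ref = pd.Series(
        usage.rank(ascending=False).to_numpy(), index=usage.index
    )
    rho_neg, _ = usage_correlation(usage, reversed_ref)
    assert rho_neg == pytest.approx(-1.0)
    const = pd.Series(1.0, index=usage.index)
    with pytest.raises(ValueError, match="constant"):
        usage_correlation(const, usage)


def test_usage_correlation_null_is_uniform_p():
    """Against random permutations of a reference, p-values are ~uniform."""
    rng = np.random.default_rng(4)
    usage = synthetic_codon_usage(5)
    pvals = []
    for _ in range(300):
        perm = pd.Series(
            rng.permutation(usage.to_numpy()), index=usage.index
        )
        _, p = usage_correlation(usage, perm)
        pvals.append(p)
    pvals = np.asarray(pvals)
    # coarse uniformity: roughly 10% below 0.1, 50% below 0.5
    assert abs(np.mean(pvals < 0.1) - 0.1) < 0.07
    assert abs(np.mean(pvals < 0.5) - 0.5) < 0.12
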