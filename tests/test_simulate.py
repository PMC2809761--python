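"""Properties of the synthetic-data generator."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from intronevol.simulate import (
    SimulationParams,
    draw_intron_sequence,
    draw_positions,
    simulate_turnover,
    synthetic_codon_usage,
    write_dataset,
)
from intronevol.splice import donor_is_consensus


RNG = lambda s=0: np.random.default_rng(s)


def test_zero_gain_rate_gives_identical_structures_and_empty_novel_truth():
    params = SimulationParams(
        n_genes=20, seed=2, gain_rate=0.0, loss_rate=0.0, insertion_rate=0.0
    )
    res = simulate_turnover(params)
    truth = res.truth.sites_frame()
    assert (truth["class"] == "ancestral").all()
    assert (truth["loss_branches"] == "").all()
    # every species carries the identical exon/intron structure
    by_gene = {}
    for sp, models in res.models.items():
        for m in models:
            by_gene.setdefault(m.gene_id, set()).add(
                (m.cds_seq, tuple(i.seq for i in m.introns))
            )
    assert all(len(v) == 1 for v in by_gene.values())


def test_seed_determinism_byte_identical(tmp_path):
    params = dict(n_genes=15, seed=42)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        d.mkdir()
        write_dataset(simulate_turnover(SimulationParams(**params)), d)
    files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    assert files
    for f in files:
        assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f"{f} differs"


def test_different_seed_changes_output():
    a = simulate_turnover(SimulationParams(n_genes=10, seed=1))
    b = simulate_turnover(SimulationParams(n_genes=10, seed=2))
    sa = a.truth.sites_frame()
    sb = b.truth.sites_frame()
    assert not sa.equals(sb)


def test_intron_sequence_contract():
    params = SimulationParams()
    rng = RNG(3)
    for phase in (0, 1, 2):
        for want_3n in (True, False):
            for _ in range(50):
                seq = draw_intron_sequence(params, phase, want_3n, rng)
                assert seq.startswith("GT") and seq.endswith("AG")
                assert len(seq) >= 45
                assert (len(seq) % 3 == 0) == want_3n


def test_forced_canonical_donor():
    params = SimulationParams(p_canonical_donor=1.0)
    rng = RNG(4)
    donors = {draw_intron_sequence(params, 0, False, rng)[:6] for _ in range(200)}
    assert donors <= {"GTAAGT", "GTGAGT"}


def test_canonical_donor_fraction_binomial():
    """10,000 draws at p=0.7: empirical fraction within 3 SE of 0.7."""
    params = SimulationParams(p_canonical_donor=0.7)
    rng = RNG(5)
    n = 10_000
    hits = sum(
        donor_is_consensus(draw_intron_sequence(params, 0, False, rng)[:6])
        for _ in range(n)
    )
    se = np.sqrt(0.7 * 0.3 / n)
    assert abs(hits / n - 0.7) < 3 * se


def test_phase2_canonical_donor_always_carries_stop_even_without_ptc_density():
    """The donor GT(A/G)A itself writes TAA/TGA into the first retained
    codon of a phase-2 intron; no planted stops are needed."""
    from intronevol.nmd import scan_ptc

    params = SimulationParams(ptc_density=0.0, p_canonical_donor=1.0)
    rng = RNG(6)
    for _ in range(100):
        seq = draw_intron_sequence(params, 2, False, rng)
        ann = scan_ptc(seq, 2)
        assert ann.first_ptc_offset == 1
        assert seq[1:4] in {"TAA", "TGA"}


def test_positional_law_uniform_at_beta_zero():
    pos = draw_positions(0.0, 10_000, RNG(7))
    counts, _ = np.histogram(pos, bins=10, range=(0, 1))
    _, p = stats.chisquare(counts)
    assert p > 0.01


def test_positional_law_5prime_skew_dominates_uniform():
    rng = RNG(8)
    skewed = draw_positions(1.5, 5_000, rng)
    uniform = draw_positions(0.0, 5_000, rng)
    # one-sided: skewed ECDF sits above the uniform one (values smaller)
    res = stats.ks_2samp(skewed, uniform, alternative="greater")
    assert res.pvalue < 1e-6
    assert skewed.mean() < uniform.mean()


def test_truth_is_dollo_consistent_single_origin(small_sim):
    truth = small_sim.truth.sites_frame()
    # one row per site; a site never appears with two origins
    assert truth["site_id"].is_unique
    # losses lie strictly below the origin: a lost branch never contains
    # a present species
    tree = small_sim.tree
    nodes = {n.label: n for n in tree.preorder_node_iter()}
    for _, row in truth.iterrows():
        present = set(row["present"].split(",")) if row["present"] else set()
        for b in filter(None, row["loss_branches"].split(",")):
            below = {lf.taxon.label for lf in nodes[b].leaf_iter()}
            assert not (below & present)


def test_annotations_contain_exactly_surviving_introns(small_sim):
    truth = small_sim.truth.sites_frame()
    expected = {}
    for _, row in truth.iterrows():
        for sp in filter(None, row["present"].split(",")):
            expected[(row["group"], sp)] = expected.get((row["group"], sp), 0) + 1
    for sp, models in small_sim.models.items():
        for m in models:
            assert len(m.introns) == expected.get((m.gene_id, sp), 0)


def test_planted_repeat_has_perfect_copy_at_both_junctions():
    res = simulate_turnover(
        SimulationParams(n_genes=40, seed=13, p_planted_repeat=1.0)
    )
    truth = res.truth.sites_frame()
    planted = truth[(truth["planted_repeat"] == 1) & (truth["present"] != "")]
    assert len(planted) > 0
    k = res.truth.params.planted_repeat_length
    checked = 0
    for _, row in planted.iterrows():
        sp = row["present"].split(",")[0]
        model = next(m for m in res.models[sp] if m.gene_id == row["group"])
        contig = res.contigs[sp][model.contig]
        gstart, gend = model.span
        gene_seq = contig[gstart:gend]
        if model.strand == "-":
            from Bio.Seq import Seq

            gene_seq = str(Seq(gene_seq).reverse_complement())
        for intron in model.introns:
            copyA = gene_seq[intron.start - 2: intron.start + k - 2]
            copyB = gene_seq[intron.end - (k - 2): intron.end + 2]
            if len(copyA) == k and copyA == copyB:
                checked += 1
                break
    assert checked >= len(planted) * 0.9  # rare multi-intron genes may shift coords


def test_synthetic_codon_usage_is_a_valid_table():
    usage = synthetic_codon_usage(1)
    assert len(usage) == 64
    assert usage.sum() == pytest.approx(1000.0)
    assert (usage >= 0).all()
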