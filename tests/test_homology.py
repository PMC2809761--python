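"""Intron homologization, coding-change classes and insertion detection."""

from __future__ import annotations

import pytest

from intronevol.homology import (
    HomologyError,
    IntronSite,
    build_sites,
    classify_coding_change,
    detect_unspliced_insertions,
    map_intron,
)
from intronevol.io_formats import GeneModel, Intron, ProteinAlignment


def _intron(gene="g", species="sp", cds_offset=6, cds_length=30, length=45):
    seq = "GT" + "C" * (length - 4) + "AG"
    return Intron(
        gene_id=gene,
        species=species,
        index=0,
        start=cds_offset,
        end=cds_offset + length,
        phase=cds_offset % 3,
        seq=seq,
        cds_offset=cds_offset,
        cds_length=cds_length,
    )


def test_map_intron_phase0_and_phase1():
    msa = ProteinAlignment(["sp"], ["MKVQWERTYL"])
    assert map_intron(_intron(cds_offset=6), msa, "sp") == (2, 0)
    assert map_intron(_intron(cds_offset=7), msa, "sp") == (2, 1)


def test_map_intron_with_gaps_matches_bruteforce_column_scan():
    row = "M--KV-QW"
    msa = ProteinAlignment(["sp", "other"], [row, "MAAKVAQW"])
    # brute force: walk columns, counting residues
    def brute(residue_index):
        seen = -1
        for col, ch in enumerate(row):
            if ch != "-":
                seen += 1
                if seen == residue_index:
                    return col
        raise AssertionError
    for cds_offset in range(0, 16):  # row has 5 residues = 15 coding nt
        col, phase = map_intron(
            _intron(cds_offset=cds_offset, cds_length=16), msa, "sp"
        )
        assert phase == cds_offset % 3
        assert col == brute(min(cds_offset // 3, 4))


def test_map_intron_offset_beyond_cds_is_error():
    msa = ProteinAlignment(["sp"], ["MKV"])
    with pytest.raises(HomologyError, match="beyond CDS"):
        map_intron(_intron(cds_offset=12, cds_length=12 + 3), msa, "sp")


def _model(species, gene, introns, n_codons=10):
    cds = "ATG" + "AAA" * (n_codons - 1)
    m = GeneModel.__new__(GeneModel)  # bypass exon bookkeeping for unit tests
    m.gene_id = gene
    m.species = species
    m.contig = "c"
    m.strand = "+"
    m.exons = [(0, 3 * n_codons)]
    m.cds_seq = cds
    m.introns = introns
    m.transcript_id = None
    return m


def test_build_sites_exact_match_merges_and_slack_separates():
    msa = ProteinAlignment(["sp1", "sp2"], ["M" * 20, "M" * 20])
    i1 = _intron("g", "sp1", cds_offset=31, cds_length=60)  # col 10, phase 1
    i2 = _intron("g", "sp2", cds_offset=31, cds_length=60)
    models = {
        "sp1": [_model("sp1", "g", [i1], 20)],
        "sp2": [_model("sp2", "g", [i2], 20)],
    }
    sites = build_sites(models, {"g": msa}, ["sp1", "sp2"], slack=0)
    assert len(sites) == 1
    assert sites[0].presence == {"sp1": True, "sp2": True}

    i3 = _intron("g", "sp2", cds_offset=34, cds_length=60)  # col 11, phase 1
    models["sp2"] = [_model("sp2", "g", [i3], 20)]
    two = build_sites(models, {"g": msa}, ["sp1", "sp2"], slack=0)
    assert len(two) == 2
    merged = build_sites(models, {"g": msa}, ["sp1", "sp2"], slack=1)
    assert len(merged) == 1 and merged[0].presence == {"sp1": True, "sp2": True}


def test_build_sites_drops_incomplete_groups(caplog):
    import logging

    msa = ProteinAlignment(["sp1", "sp2"], ["M" * 20, "M" * 20])
    models = {"sp1": [_model("sp1", "g", [], 20)], "sp2": []}
    with caplog.at_level(logging.WARNING):
        sites = build_sites(models, {"g": msa}, ["sp1", "sp2"])
    assert sites == []
    assert "incomplete" in caplog.text


def test_build_sites_duplicate_mapping_is_annotation_defect():
    msa = ProteinAlignment(["sp1", "sp2"], ["M" * 20, "M" * 20])
    i1 = _intron("g", "sp1", cds_offset=30, cds_length=60)
    i2 = _intron("g", "sp1", cds_offset=30, cds_length=60)
    i2 = Intron(**{**vars(i2), "index": 1})
    models = {
        "sp1": [_model("sp1", "g", [i1, i2], 20)],
        "sp2": [_model("sp2", "g", [], 20)],
    }
    with pytest.raises(HomologyError, match="annotation defect"):
        build_sites(models, {"g": msa}, ["sp1", "sp2"])


def test_site_recovery_equals_truth_on_clean_simulation(clean_sim):
    """With slack=0 and no coding-change variants, recovered sites equal
    the simulator truth 1:1 (columns, phases and presence vectors)."""
    species = sorted(clean_sim.models)
    sites = build_sites(clean_sim.models, clean_sim.msas, species, slack=0)
    truth = clean_sim.truth.sites_frame()
    visible = truth[truth["present"] != ""]
    got = {
        (s.group_id, s.column, s.phase,
         ",".join(sp for sp in species if s.presence[sp]))
        for s in sites
    }
    want = set(
        zip(visible["group"], visible["column"], visible["phase"], visible["present"])
    )
    assert got == want


def test_site_count_invariant_under_species_order(clean_sim):
    species = sorted(clean_sim.models)
    a = build_sites(clean_sim.models, clean_sim.msas, species)
    b = build_sites(clean_sim.models, clean_sim.msas, species[::-1])
    assert len(a) == len(b)
    assert {s.site_id for s in a} == {s.site_id for s in b}


def test_coding_change_classes():
    # 2 extra residues beside column 5 in carrier rows -> class "1-3"
    carrier = "MKVQWXXERTYL"
    absent_ = "MKVQW--ERTYL"
    msa = ProteinAlignment(["sp1", "sp2"], [carrier, absent_])
    site = IntronSite("g", column=5, phase=0, presence={"sp1": True, "sp2": False})
    cc = classify_coding_change(site, msa)
    assert cc.n_aa_delta == 2 and cc.change_class == "1-3"

    identical = ProteinAlignment(["sp1", "sp2"], ["MKVQWERTYL", "MKVQWERTYL"])
    cc0 = classify_coding_change(
        IntronSite("g", 5, 0, {"sp1": True, "sp2": False}), identical
    )
    assert cc0.n_aa_delta == 0 and cc0.change_class == "0"

    big_c = "MKVQW" + "X" * 5 + "ERTYL"
    big_a = "MKVQW" + "-" * 5 + "ERTYL"
    cc4 = classify_coding_change(
        IntronSite("g", 5, 0, {"sp1": True, "sp2": False}),
        ProteinAlignment(["sp1", "sp2"], [big_c, big_a]),
    )
    assert cc4.change_class == ">=4"


def test_coding_change_recovered_from_simulation(small_sim):
    species = sorted(small_sim.models)
    sites = build_sites(small_sim.models, small_sim.msas, species)
    truth = small_sim.truth.sites_frame()
    changed = truth[(truth["coding_change"] > 0) & (truth["present"] != "")]
    by_key = {(r["group"], r["column"], r["phase"]): r for _, r in changed.iterrows()}
    n_checked = 0
    for s in sites:
        key = (s.group_id, s.column, s.phase)
        if key not in by_key or all(s.presence.values()) or not any(s.presence.values()):
            continue
        cc = classify_coding_change(s, small_sim.msas[s.group_id])
        assert cc.n_aa_delta == by_key[key]["coding_change"]
        n_checked += 1
    assert n_checked > 0


def test_insertion_detection_thresholds():
    rows = {
        "sp1": "M" * 10 + "X" * 20 + "K" * 10,
        "sp2": "M" * 10 + "-" * 20 + "K" * 10,
        "sp3": "M" * 10 + "-" * 20 + "K" * 10,
    }
    msa = ProteinAlignment(list(rows), list(rows.values()))
    hits = detect_unspliced_insertions({"g": msa})
    assert len(hits) == 1
    assert hits.iloc[0]["length_aa"] == 20 and hits.iloc[0]["species"] == "sp1"

    short = {
        "sp1": "M" * 10 + "X" * 14 + "K" * 10,
        "sp2": "M" * 10 + "-" * 14 + "K" * 10,
    }
    msa2 = ProteinAlignment(list(short), list(short.values()))
    assert detect_unspliced_insertions({"g": msa2}).empty


def test_insertions_recovered_from_simulation_no_false_positives(clean_sim):
    species = sorted(clean_sim.models)
    sites = build_sites(clean_sim.models, clean_sim.msas, species)
    hits = detect_unspliced_insertions(clean_sim.msas, sites)
    want = {
        (i.group, ",".join(i.present), i.length_aa)
        for i in clean_sim.truth.insertions
    }
    got = set(zip(hits["group"], hits["species"], hits["length_aa"]))
    assert got == want
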