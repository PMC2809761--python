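"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive. Minus-strand genes are normalized to the coding strand at load,
so every downstream module is strand-agnostic: intron coordinates are
gene-local (offset from the transcription start on the coding strand) and
intron sequences read 5'->3' on the coding strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GeneModelError(ValueError):
    """Raised for malformed gene annotations that cannot be skipped."""


@dataclass(frozen=True)
class Intron:
    """One intron of a coding gene, in coding-strand orientation.

    ``start``/``end`` are gene-local 0-based half-open positions measured
    from the 5' end of the gene region (transcription start on the coding
    strand), so a plus-strand gene and its reverse-complemented twin yield
    identical introns.  ``phase`` counts the coding nucleotides of the
    interrupted codon that precede the intron (0, 1 or 2).
    """

    gene_id: str
    species: str
    index: int
    start: int
    end: int
    phase: int
    seq: str
    cds_offset: int
    cds_length: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor6(self) -> str:
        """6-mer at intron positions +1..+6 (5' splice site)."""
        return self.seq[:6]

    @property
    def acceptor3(self) -> str:
        """3-mer at intron positions -3..-1 (3' splice site)."""
        return self.seq[-3:]

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise GeneModelError(
                f"{self.gene_id} intron {self.index}: length {self.end - self.start} "
                f"!= sequence length {len(self.seq)}"
            )
        if not 0 <= self.cds_offset <= self.cds_length:
            raise GeneModelError(
                f"{self.gene_id} intron {self.index}: cds_offset {self.cds_offset} "
                f"outside [0, {self.cds_length}]"
            )
        if self.phase != self.cds_offset % 3:
            raise GeneModelError(
                f"{self.gene_id} intron {self.index}: phase {self.phase} inconsistent "
                f"with cds_offset {self.cds_offset}"
            )


@dataclass
class GeneModel:
    """One species' coding gene: exons on the contig plus the coding sequence.

    ``exons`` are (start, end) pairs in 0-based half-open *contig*
    coordinates, sorted ascending regardless of strand.  ``cds_seq`` is the
    spliced coding sequence on the coding strand.  ``introns`` is derived.
    """

    gene_id: str
    species: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    introns: list[Intron] = field(default_factory=list)
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: gene has no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise GeneModelError(f"{self.gene_id}: empty or inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if set(self.cds_seq) - DNA_ALPHABET:
            raise GeneModelError(f"{self.gene_id}: cds_seq has non-ACGTN characters")
        if len(self.cds_seq) != sum(e - s for s, e in self.exons):
            raise GeneModelError(f"{self.gene_id}: cds_seq length does not match exons")
        if len(self.cds_seq) % 3:
            raise GeneModelError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def span(self) -> tuple[int, int]:
        """Contig span of the gene, 0-based half-open."""
        return self.exons[0][0], self.exons[-1][1]

    def protein(self) -> str:
        return str(Seq(self.cds_seq).translate())


def derive_introns(model: GeneModel, contig_seq: str) -> list[Intron]:
    """Fill ``model.introns`` from the gaps between consecutive exons.

    ``contig_seq`` is the forward-strand contig sequence; intron sequences
    are reverse-complemented for minus-strand genes so they read 5'->3' on
    the coding strand.
    """
    gstart, gend = model.span
    gaps = [
        (model.exons[i][1], model.exons[i + 1][0]) for i in range(len(model.exons) - 1)
    ]
    if model.strand == "-":
        gaps = gaps[::-1]
    introns: list[Intron] = []
    cds_before = 0
    exon_lengths = [e - s for s, e in model.exons]
    if model.strand == "-":
        exon_lengths = exon_lengths[::-1]
    for i, (a, b) in enumerate(gaps):
        cds_before += exon_lengths[i]
        raw = contig_seq[a:b].upper()
        if model.strand == "+":
            local = (a - gstart, b - gstart)
            seq = raw
        else:
            local = (gend - b, gend - a)
            seq = str(Seq(raw).reverse_complement())
        introns.append(
            Intron(
                gene_id=model.gene_id,
                species=model.species,
                index=i,
                start=local[0],
                end=local[1],
                phase=cds_before % 3,
                seq=seq,
                cds_offset=cds_before,
                cds_length=model.cds_length,
            )
        )
    model.introns = introns
    return introns


# ---------------------------------------------------------------------------
# GFF3 + genome FASTA
# ---------------------------------------------------------------------------

def _spliced_cds(exons: Sequence[tuple[int, int]], strand: str, contig_seq: str) -> str:
    parts = [contig_seq[s:e] for s, e in exons]
    seq = "".join(parts).upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_gene_models(
    gff3_path: str | Path, fasta_path: str | Path, species: str
) -> list[GeneModel]:
    """Load one gene model per gene from a GFF3 annotation and genome FASTA.

    Keeps the longest isoform per gene (amino-acid length, ties broken
    lexicographically by transcript id).  Genes whose CDS length is not a
    multiple of 3, or whose translation contains an internal stop, are
    skipped with a logged warning (frameshift or pseudogene-like defects).
    A CDS coordinate outside its contig is a hard error.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates: list[tuple[int, str, GeneModel]] = []
        skip_reasons: list[str] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            if not cds_feats:
                continue
            if gene.seqid not in contigs:
                raise GeneModelError(
                    f"CDS of {mrna.id}: contig {gene.seqid!r} absent from FASTA"
                )
            contig_seq = contigs[gene.seqid]
            exons = [(f.start - 1, f.end) for f in cds_feats]  # 1-based incl -> 0-based half-open
            for f in cds_feats:
                if f.start < 1 or f.end > len(contig_seq):
                    raise GeneModelError(
                        f"CDS {f.id or mrna.id} at {gene.seqid}:{f.start}-{f.end} "
                        f"outside contig (length {len(contig_seq)})"
                    )
            strand = gene.strand if gene.strand in "+-" else mrna.strand
            cds_seq = _spliced_cds(exons, strand, contig_seq)
            if len(cds_seq) % 3:
                skip_reasons.append(f"{mrna.id}: CDS length {len(cds_seq)} not divisible by 3")
                continue
            prot = str(Seq(cds_seq).translate())
            body = prot[:-1] if prot.endswith("*") else prot
            if "*" in body:
                skip_reasons.append(f"{mrna.id}: internal stop codon in translation")
                continue
            model = GeneModel(
                gene_id=gene.id,
                species=species,
                contig=gene.seqid,
                strand=strand,
                exons=exons,
                cds_seq=cds_seq,
                transcript_id=mrna.id,
            )
            derive_introns(model, contig_seq)
            candidates.append((len(cds_seq) // 3, mrna.id, model))
        if candidates:
            # longest isoform; ties lexicographic by transcript id
            candidates.sort(key=lambda t: (-t[0], t[1]))
            models.append(candidates[0][2])
        elif skip_reasons:
            logger.warning("skipping gene %s: %s", gene.id, "; ".join(skip_reasons))
    return models


def write_gene_models(
    models: Iterable[GeneModel], gff3_path: str | Path, source: str = "intronevol"
) -> None:
    """Write gene/mRNA/CDS features as GFF3 (1-based inclusive on disk)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gstart, gend = m.span
            tid = m.transcript_id or f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.contig}\t{source}\tmRNA\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            exons = m.exons if m.strand == "+" else m.exons[::-1]
            cds_before = 0
            for j, (s, e) in enumerate(exons):
                frame = (3 - cds_before % 3) % 3
                fh.write(
                    f"{m.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{frame}\t"
                    f"ID={tid}.cds{j};Parent={tid}\n"
                )
                cds_before += e - s


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeError(ValueError):
    pass


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    """Give every unnamed internal node a deterministic label (preorder index)."""
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is not None and node.taxon.label:
            node.label = node.taxon.label
        elif not node.label:
            node.label = "ROOT" if node.parent_node is None else f"N{i}"


def read_tree(
    newick_path: str | Path, allow_root_polytomy: bool = False
) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths in millions of years.

    Every non-root edge must carry a branch length.  A root with more than
    two children is rejected unless ``allow_root_polytomy`` is set (the
    basal polytomy then stands for an unresolved root, not an unrooted
    tree).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(newick_path),
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"newick parse error in {newick_path}: {exc}") from exc
    return _validate_tree(tree, allow_root_polytomy)


def tree_from_string(newick: str, allow_root_polytomy: bool = False) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    return _validate_tree(tree, allow_root_polytomy)


def _validate_tree(tree: dendropy.Tree, allow_root_polytomy: bool) -> dendropy.Tree:
    root = tree.seed_node
    n_root_children = len(root.child_nodes())
    if n_root_children > 2 and not allow_root_polytomy:
        raise TreeError(
            f"root has {n_root_children} children; tree looks unrooted "
            "(pass allow_root_polytomy=True to accept)"
        )
    missing = [
        node for node in tree.preorder_node_iter()
        if node.parent_node is not None and node.edge.length is None
    ]
    if missing:
        raise TreeError(
            "missing branch length on node(s): "
            + ", ".join(str(n.taxon or n.label or "?") for n in missing)
        )
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise TreeError("negative branch length")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf names")
    _label_internal_nodes(tree)
    return tree


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Protein multiple alignments
# ---------------------------------------------------------------------------

class ProteinAlignment:
    """An aligned protein ortholog group with residue<->column maps.

    Rows are keyed by sequence id (species label in the synthetic pipeline).
    ``residue_to_column[row][k]`` is the 0-based alignment column of the
    k-th ungapped residue of that row.
    """

    GAP = "-"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
        self.ids = list(ids)
        self.rows = {i: r for i, r in zip(ids, rows)}
        self.n_columns = len(rows[0]) if rows else 0
        self.residue_to_column: dict[str, list[int]] = {
            rid: [c for c, ch in enumerate(row) if ch != self.GAP]
            for rid, row in self.rows.items()
        }

    def ungapped_length(self, row_id: str) -> int:
        return len(self.residue_to_column[row_id])

    def column_of_residue(self, row_id: str, residue_index: int) -> int:
        cols = self.residue_to_column[row_id]
        if not 0 <= residue_index < len(cols):
            raise IndexError(
                f"residue {residue_index} out of range for row {row_id!r} "
                f"({len(cols)} residues)"
            )
        return cols[residue_index]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid in self.ids:
                fh.write(f">{rid}\n{self.rows[rid]}\n")


def read_protein_msa(fasta_path: str | Path) -> ProteinAlignment:
    """Read one ortholog group's aligned FASTA (gap character '-')."""
    try:
        aln = AlignIO.read(str(fasta_path), "fasta")
    except ValueError as exc:
        raise ValueError(f"bad alignment {fasta_path}: {exc}") from exc
    return ProteinAlignment([rec.id for rec in aln], [str(rec.seq) for rec in aln])
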