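"""Synthetic intron-turnover data with known ground truth.

Generates per-species gene annotations, genome sequence, protein multiple
alignments, a dated species tree and a truth table of every simulated gain
and loss event, so the whole inference pipeline can be exercised against a
known answer.  The generator emulates the regime of a nine-species
*Drosophila* comparison: a rooted tree spanning ~40 My, per-branch intron
gains as a Poisson process, subsequent losses as a per-intron hazard
(each site gained exactly once -- Dollo-consistent by construction),
intron lengths >= 45 nt with a controllable 3n-class mix, canonical
GT(A/G)AGT / CAG splice motifs with tunable frequencies, retention-frame
stop codons at a tunable density, a 5'-skewed positional law, occasional
1-3 codon coding-sequence changes beside a new intron, large unspliced
coding insertions, and optionally planted direct repeats spanning both
splice junctions.

No substitution process runs on exons: orthologous residues are identical
across species, which makes the protein alignments exact statements of the
true homology.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    Intron,
    ProteinAlignment,
    STOP_CODONS,
    derive_introns,
    tree_from_string,
)
from .nmd import retention_frame_offset

# Nine-species fixture tree; branch lengths in millions of years, root ~40 My
# deep, melanogaster/yakuba split at 10 My.
DROSOPHILA_9_TAXON_NEWICK = (
    "(((((D_melanogaster:10,(D_erecta:8,D_yakuba:8):2):15,D_ananassae:25):5,"
    "D_pseudoobscura:30):5,D_willistoni:35):5,"
    "((D_virilis:25,D_mojavensis:25):5,D_grimshawi:30):10);"
)

BASES = np.array(list("ACGT"))
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
STOPS = sorted(STOP_CODONS)


@dataclass
class SimulationParams:
    """Knobs of the turnover simulator.

    Rates are per-branch and time is measured in Bya (1e9 years):
    ``gain_rate`` is expected gains per gene per Bya, ``loss_rate`` a
    per-intron loss hazard per Bya, ``insertion_rate`` expected large
    unspliced coding insertions per gene per Bya.  Either may be a single
    float or a mapping from branch id (child-node label) to a float.
    """

    n_genes: int = 500
    tree_newick: str = DROSOPHILA_9_TAXON_NEWICK
    gain_rate: float | Mapping[str, float] = 2.8
    loss_rate: float | Mapping[str, float] = 0.4
    insertion_rate: float = 1.6
    mean_ancestral_introns: float = 2.45
    mean_gene_codons: float = 450.0
    min_gene_codons: int = 120
    intron_length_min: int = 45
    intron_length_mean_extra: float = 25.0
    p_3n: float = 1 / 3
    p_canonical_donor: float = 0.30
    p_canonical_acceptor: float = 0.55
    p_canonical_donor_ancestral: float = 0.55
    p_canonical_acceptor_ancestral: float = 0.70
    ptc_density: float = 3 / 64
    position_bias: float = 0.5
    position_bias_ancestral: float = 0.17
    p_coding_change: float = 0.13
    p_coding_change_large: float = 0.01
    p_planted_repeat: float = 0.02
    planted_repeat_length: int = 10
    intergenic_pad: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_3n",
            "p_canonical_donor",
            "p_canonical_acceptor",
            "p_canonical_donor_ancestral",
            "p_canonical_acceptor_ancestral",
            "ptc_density",
            "p_coding_change",
            "p_coding_change_large",
            "p_planted_repeat",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.intron_length_min < 45:
            raise ValueError("intron_length_min must be >= 45")
        for name in ("insertion_rate", "position_bias", "position_bias_ancestral"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for r in (self.gain_rate, self.loss_rate):
            vals = r.values() if isinstance(r, Mapping) else [r]
            if any(v < 0 for v in vals):
                raise ValueError("rates must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def rate_for(self, which: str, branch: str) -> float:
        r = getattr(self, which)
        if isinstance(r, Mapping):
            return float(r[branch])
        return float(r)


@dataclass
class TrueSite:
    """Ground truth for one simulated intron site."""

    site_id: str
    group: str
    codon_index: int          # ancestral residue whose codon holds the insertion point
    phase: int
    origin: str               # branch id of the gain, or "root" for ancestral introns
    klass: str                # "novel" | "ancestral"
    loss_branches: list[str]
    present: list[str]        # leaf species carrying the intron
    seq: str = ""
    is_3n: bool = False
    first_ptc_offset: int | None = None
    coding_change: int = 0    # codons inserted beside the intron (0 = clean gain)
    planted_repeat: bool = False
    column: int = -1          # protein-MSA column, filled after alignment assembly


@dataclass
class TrueInsertion:
    group: str
    origin: str
    codon_index: int
    length_aa: int
    present: list[str]


@dataclass
class SyntheticTruth:
    sites: list[TrueSite]
    insertions: list[TrueInsertion]
    params: SimulationParams
    seed: int

    def sites_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "site_id": s.site_id,
                    "group": s.group,
                    "column": s.column,
                    "phase": s.phase,
                    "origin": s.origin,
                    "class": s.klass,
                    "loss_branches": ",".join(s.loss_branches),
                    "present": ",".join(s.present),
                    "length": len(s.seq),
                    "is_3n": int(s.is_3n),
                    "first_ptc_offset": -1 if s.first_ptc_offset is None else s.first_ptc_offset,
                    "coding_change": s.coding_change,
                    "planted_repeat": int(s.planted_repeat),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulationResult:
    models: dict[str, list[GeneModel]]        # species -> gene models
    contigs: dict[str, dict[str, str]]        # species -> contig id -> sequence
    msas: dict[str, ProteinAlignment]         # group -> alignment
    tree: dendropy.Tree
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence-level draws
# ---------------------------------------------------------------------------

def synthetic_codon_usage(seed: int = 7) -> pd.Series:
    """A biased 64-codon usage table (per 1,000 codons), Dirichlet-drawn.

    Serves as the reference table for codon-usage tests and as the source
    distribution for simulated exonic sequence, standing in for a published
    species table.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(64, 0.6))
    return pd.Series(freqs * 1000.0, index=ALL_CODONS, name="per_1000")


def _nonstop_probs(usage: pd.Series) -> np.ndarray:
    p = usage.reindex(NONSTOP_CODONS).to_numpy(dtype=float)
    return p / p.sum()


def draw_positions(beta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Relative positions on [0,1) with density proportional to (1-r)^beta.

    beta=0 is uniform; beta>0 skews draws toward the 5' end.
    """
    u = rng.random(n)
    return 1.0 - u ** (1.0 / (beta + 1.0))


def _rand_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def draw_intron_sequence(
    params: SimulationParams,
    phase: int,
    want_3n: bool,
    rng: np.random.Generator,
    ancestral: bool = False,
) -> str:
    """Draw one intron sequence under the motif/length/PTC model.

    Always begins "GT" and ends "AG".  The donor 6-mer matches GT(A/G)AGT
    with probability ``p_canonical_donor`` and the acceptor 3-mer equals
    CAG with probability ``p_canonical_acceptor`` (the ``*_ancestral``
    variants when ``ancestral``).  Length mod 3 == 0 iff ``want_3n``.
    Retention-frame codons strictly inside the intron (clear of the splice
    motifs) are stop codons with rate ``ptc_density``.
    """
    min_len = params.intron_length_min
    mean_extra = params.intron_length_mean_extra
    length = min_len - 1 + int(rng.geometric(1.0 / (mean_extra + 1.0)))
    if want_3n:
        down = length - length % 3
        length = down if down >= min_len else down + 3
    elif length % 3 == 0:
        length += 1 if (rng.random() < 0.5 or length - 1 < min_len) else -1

    p_don = params.p_canonical_donor_ancestral if ancestral else params.p_canonical_donor
    p_acc = params.p_canonical_acceptor_ancestral if ancestral else params.p_canonical_acceptor

    seq = [""] * length
    if rng.random() < p_don:
        donor = "GTAAGT" if rng.random() < 0.5 else "GTGAGT"
    else:
        while True:
            donor = "GT" + _rand_bases(4, rng)
            if donor not in ("GTAAGT", "GTGAGT"):
                break
    seq[0:6] = list(donor)
    if rng.random() < p_acc:
        acceptor = "CAG"
    else:
        acceptor = "AGT"[rng.integers(0, 3)] + "AG"
        while acceptor == "CAG":  # unreachable, first base never C
            acceptor = _rand_bases(1, rng) + "AG"
    seq[length - 3:] = list(acceptor)

    nonstop = NONSTOP_CODONS
    for i in range(retention_frame_offset(phase), length - 2, 3):
        if i < 6 or i + 3 > length - 3:
            continue  # codon touches a splice motif; leave it to the motif draw
        if rng.random() < params.ptc_density:
            codon = STOPS[rng.integers(0, 3)]
        else:
            codon = nonstop[rng.integers(0, len(nonstop))]
        seq[i:i + 3] = list(codon)
    for i, ch in enumerate(seq):
        if not ch:
            seq[i] = BASES[rng.integers(0, 4)]
    return "".join(seq)


def _first_frame_stop(seq: str, phase: int) -> int | None:
    """Generator-side truth scan: first retention-frame stop fully inside."""
    for i in range(retention_frame_offset(phase), len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i
    return None


# ---------------------------------------------------------------------------
# event-level simulation
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    n_codons: int
    strand: str
    pad5: str
    pad3: str
    codons: list[str] = field(default_factory=list)
    sites: list[TrueSite] = field(default_factory=list)
    blocks: list[tuple[int, int, list[str], frozenset]] = field(default_factory=list)
    # blocks: (codon position, serial, codon list, carrier leaf set)
    insertions: list[TrueInsertion] = field(default_factory=list)

    def occupied(self, c: int, phase: int) -> bool:
        return any(s.codon_index == c and s.phase == phase for s in self.sites)

    def near_event(self, c: int, slop: int = 1) -> bool:
        for s in self.sites:
            if abs(s.codon_index - c) <= slop:
                return True
        for pos, _, codons, _ in self.blocks:
            if pos - slop <= c <= pos + len(codons) + slop:
                return True
        return False


def _branches_preorder(tree: dendropy.Tree) -> list[dendropy.Node]:
    return [n for n in tree.preorder_node_iter() if n.parent_node is not None]


def _leaves_below(node: dendropy.Node) -> list[str]:
    return sorted(lf.taxon.label for lf in node.leaf_iter())


def _thin_losses(
    origin: dendropy.Node,
    loss_hazard,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Drop the intron along descendant branches; returns (loss branch ids,
    surviving leaf species).  Once lost on a branch the whole subtree below
    is silent, so each maximal absent subtree maps to exactly one recorded
    loss branch (standard Dollo geometry)."""
    losses: list[str] = []
    survivors: list[str] = []

    def descend(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            p = 1.0 - np.exp(-loss_hazard(child.label) * child.edge.length / 1000.0)
            if rng.random() < p:
                losses.append(child.label)
            else:
                if child.is_leaf():
                    survivors.append(child.taxon.label)
                descend(child)

    if origin.is_leaf():
        survivors.append(origin.taxon.label)
    else:
        descend(origin)
    return losses, sorted(survivors)


def simulate_turnover(params: SimulationParams) -> SimulationResult:
    """Run the full generator; identical params (including seed) give
    identical output, byte-for-byte once written."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tree = tree_from_string(params.tree_newick)
    branches = _branches_preorder(tree)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    for b in branches:
        exp_gains = params.rate_for("gain_rate", b.label) * b.edge.length / 1000.0
        if exp_gains > 1:
            warnings.warn(
                f"branch {b.label}: {exp_gains:.2f} expected gains per gene; "
                "homoplasy-risk regime, colliding sites are re-drawn"
            )

    usage = synthetic_codon_usage(params.seed % (2**31))
    nonstop_p = _nonstop_probs(usage)

    width = len(str(params.n_genes))
    genes: list[_Gene] = []
    for gi in range(params.n_genes):
        n_codons = params.min_gene_codons + int(
            rng.geometric(1.0 / (params.mean_gene_codons - params.min_gene_codons + 1.0))
        ) - 1
        g = _Gene(
            gene_id=f"g{gi:0{width}d}",
            n_codons=n_codons,
            strand="+" if rng.random() < 0.5 else "-",
            pad5=_rand_bases(params.intergenic_pad, rng),
            pad3=_rand_bases(params.intergenic_pad, rng),
        )
        idx = rng.choice(len(NONSTOP_CODONS), size=n_codons, p=nonstop_p)
        g.codons = [NONSTOP_CODONS[i] for i in idx]
        genes.append(g)

    serial = itertools.count()
    site_count = itertools.count()

    def place_site(g: _Gene, beta: float, origin_label: str, klass: str) -> TrueSite:
        for _ in range(100):
            r = draw_positions(beta, 1, rng)[0]
            c = min(g.n_codons - 1, max(1, int(r * g.n_codons)))
            phase = int(rng.integers(0, 3))
            if not g.occupied(c, phase):
                break
        else:
            raise RuntimeError("could not place intron site without collision")
        site = TrueSite(
            site_id=f"s{next(site_count):06d}",
            group=g.gene_id,
            codon_index=c,
            phase=phase,
            origin=origin_label,
            klass=klass,
            loss_branches=[],
            present=[],
        )
        g.sites.append(site)
        return site

    # ancestral introns: present at the root
    for g in genes:
        for _ in range(int(rng.poisson(params.mean_ancestral_introns))):
            place_site(g, params.position_bias_ancestral, "root", "ancestral")

    # gains along branches, preorder
    for b in branches:
        lam = params.rate_for("gain_rate", b.label) * params.n_genes * b.edge.length / 1000.0
        for _ in range(int(rng.poisson(lam))):
            g = genes[int(rng.integers(0, params.n_genes))]
            site = place_site(g, params.position_bias, b.label, "novel")
            if rng.random() < params.p_coding_change:
                if rng.random() < params.p_coding_change_large / max(params.p_coding_change, 1e-9):
                    delta = int(rng.integers(4, 6))
                else:
                    delta = int(rng.integers(1, 4))
                site.coding_change = delta
            if rng.random() < params.p_planted_repeat:
                site.planted_repeat = True

    # large unspliced insertions (coding indels that are not introns)
    for b in branches:
        lam = params.insertion_rate * params.n_genes * b.edge.length / 1000.0
        for _ in range(int(rng.poisson(lam))):
            g = genes[int(rng.integers(0, params.n_genes))]
            for _ in range(100):
                c = int(rng.integers(1, g.n_codons))
                if not g.near_event(c, slop=2):
                    break
            else:
                continue
            length_aa = min(165, 15 + int(rng.geometric(1.0 / 21.0)) - 1)
            idx = rng.choice(len(NONSTOP_CODONS), size=length_aa, p=nonstop_p)
            carriers = frozenset(_leaves_below(b))
            g.blocks.append((c, next(serial), [NONSTOP_CODONS[i] for i in idx], carriers))
            g.insertions.append(
                TrueInsertion(
                    group=g.gene_id,
                    origin=b.label,
                    codon_index=c,
                    length_aa=length_aa,
                    present=sorted(carriers),
                )
            )

    # losses + carrier sets, then sequences (junction context now known)
    label_to_node = {n.label: n for n in tree.preorder_node_iter()}
    loss_hazard = lambda branch: params.rate_for("loss_rate", branch)
    for g in genes:
        g.sites.sort(key=lambda s: (s.codon_index, s.phase, s.site_id))
        for site in g.sites:
            origin_node = tree.seed_node if site.origin == "root" else label_to_node[site.origin]
            losses, survivors = _thin_losses(origin_node, loss_hazard, rng)
            site.loss_branches = losses
            site.present = survivors
            if site.coding_change:
                idx = rng.choice(len(NONSTOP_CODONS), size=site.coding_change, p=nonstop_p)
                g.blocks.append(
                    (
                        site.codon_index,
                        next(serial),
                        [NONSTOP_CODONS[i] for i in idx],
                        frozenset(site.present),
                    )
                )
            want_3n = rng.random() < params.p_3n
            seq = draw_intron_sequence(
                params, site.phase, want_3n, rng, ancestral=site.klass == "ancestral"
            )
            if site.planted_repeat:
                planted = _plant_repeat(g, site, seq, params.planted_repeat_length)
                if planted is None:
                    site.planted_repeat = False
                else:
                    seq = planted
            site.seq = seq
            site.is_3n = len(seq) % 3 == 0
            site.first_ptc_offset = _first_frame_stop(seq, site.phase)
        g.blocks.sort(key=lambda t: (t[0], t[1]))

    models, contigs, msas = _assemble(genes, leaves, params)
    truth = SyntheticTruth(
        sites=[s for g in genes for s in g.sites],
        insertions=[ins for g in genes for ins in g.insertions],
        params=params,
        seed=params.seed,
    )
    _fill_truth_columns(truth, genes, msas)
    return SimulationResult(models=models, contigs=contigs, msas=msas, tree=tree, truth=truth)


def _plant_repeat(g: _Gene, site: TrueSite, seq: str, k: int) -> str | None:
    """Overwrite the intron ends so a perfect k-mer direct repeat spans both
    splice junctions without touching the coding sequence.

    The repeat R is pinned by its context: R[0:2] = the 2 exonic nt 5' of
    the intron, R[-2:] = the 2 exonic nt 3' of it, the donor GT and the
    terminal AG fix four internal positions, and the remainder comes from
    the drawn sequence.  copyA = exon tail + intron head, copyB = intron
    tail + exon head, both of length k.  Returns None (no plant) when the
    geometry does not fit or the junction context is ambiguous because
    another simulated event sits in the same codon.
    """
    if k < 8 or len(seq) < 2 * (k - 2):
        return None
    c = site.codon_index
    own = [
        b for b in g.blocks
        if b[0] == c and site.present and set(b[3]) == set(site.present)
    ]
    foreign = [b for b in g.blocks if b[0] == c and b not in own]
    neighbours = [
        s for s in g.sites
        if s is not site and abs(s.codon_index - c) <= 1
    ]
    if foreign or neighbours or c < 1:
        return None
    prefix = "".join(g.codons[:c])
    for _, _, codons, _ in own:
        prefix += "".join(codons)
    prefix += g.codons[c][: site.phase]
    suffix = (g.codons[c][site.phase:] + (g.codons[c + 1] if c + 1 < g.n_codons else "TAA"))[:2]
    if len(prefix) < 2:
        return None
    R = prefix[-2:] + "GT" + seq[4: k - 4] + "AG" + suffix
    assert len(R) == k
    head = R[2:]        # k-2 nt: overwrite intron start (keeps GT)
    tail = R[: k - 2]   # k-2 nt: overwrite intron end (keeps terminal AG)
    body = seq[len(head): len(seq) - len(tail)]
    return head + body + tail


# ---------------------------------------------------------------------------
# assembly of per-species models and alignments
# ---------------------------------------------------------------------------

def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _assemble(
    genes: list[_Gene], leaves: list[str], params: SimulationParams
) -> tuple[dict[str, list[GeneModel]], dict[str, dict[str, str]], dict[str, ProteinAlignment]]:
    models: dict[str, list[GeneModel]] = {sp: [] for sp in leaves}
    contigs: dict[str, dict[str, str]] = {sp: {} for sp in leaves}
    msas: dict[str, ProteinAlignment] = {}

    for g in genes:
        blocks_at: dict[int, list[tuple[int, list[str], frozenset]]] = {}
        for pos, ser, codons, carriers in g.blocks:
            blocks_at.setdefault(pos, []).append((ser, codons, carriers))
        for pos in blocks_at:
            blocks_at[pos].sort()

        # alignment columns: per ancestral position, insertion blocks first
        aln_rows = {sp: [] for sp in leaves}
        anc_column: dict[int, int] = {}
        col = 0
        for c in range(g.n_codons + 1):
            for ser, codons, carriers in blocks_at.get(c, []):
                aa = "".join(_translate_codon(cd) for cd in codons)
                for sp in leaves:
                    aln_rows[sp].append(aa if sp in carriers else "-" * len(aa))
                col += len(codons)
            if c < g.n_codons:
                anc_column[c] = col
                aa = _translate_codon(g.codons[c])
                for sp in leaves:
                    aln_rows[sp].append(aa)
                col += 1
        g.anc_column = anc_column  # type: ignore[attr-defined]
        msas[g.gene_id] = ProteinAlignment(leaves, ["".join(aln_rows[sp]) for sp in leaves])

        for sp in leaves:
            codon_list: list[str] = []
            insert_points: dict[str, int] = {}  # site_id -> codon index in this species
            for c in range(g.n_codons + 1):
                for ser, codons, carriers in blocks_at.get(c, []):
                    if sp in carriers:
                        codon_list.extend(codons)
                for site in g.sites:
                    if site.codon_index == c and sp in site.present:
                        insert_points[site.site_id] = len(codon_list)
                if c < g.n_codons:
                    codon_list.append(g.codons[c])
            cds = "".join(codon_list)
            site_offsets = sorted(
                (3 * insert_points[s.site_id] + s.phase, s.seq)
                for s in g.sites
                if s.site_id in insert_points
            )
            # splice the gene sequence together
            parts: list[str] = []
            exons_local: list[tuple[int, int]] = []
            prev = 0
            pos_local = 0
            for off, iseq in site_offsets:
                parts.append(cds[prev:off])
                exons_local.append((pos_local, pos_local + (off - prev)))
                pos_local += off - prev
                parts.append(iseq)
                pos_local += len(iseq)
                prev = off
            parts.append(cds[prev:])
            exons_local.append((pos_local, pos_local + (len(cds) - prev)))
            gene_seq = "".join(parts)

            pad = params.intergenic_pad
            if g.strand == "+":
                contig_seq = g.pad5 + gene_seq + g.pad3
                exons = [(pad + s, pad + e) for s, e in exons_local]
            else:
                from Bio.Seq import Seq

                contig_seq = g.pad5 + str(Seq(gene_seq).reverse_complement()) + g.pad3
                L = len(gene_seq)
                exons = [(pad + L - e, pad + L - s) for s, e in exons_local]
            contig_id = f"ctg_{g.gene_id}"
            contigs[sp][contig_id] = contig_seq
            model = GeneModel(
                gene_id=g.gene_id,
                species=sp,
                contig=contig_id,
                strand=g.strand,
                exons=exons,
                cds_seq=cds,
                transcript_id=f"{g.gene_id}.t1",
            )
            derive_introns(model, contig_seq)
            models[sp].append(model)
    return models, contigs, msas


def _fill_truth_columns(
    truth: SyntheticTruth, genes: list[_Gene], msas: dict[str, ProteinAlignment]
) -> None:
    by_id = {g.gene_id: g for g in genes}
    for site in truth.sites:
        g = by_id[site.group]
        site.column = g.anc_column[site.codon_index]  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(result: SimulationResult, outdir: str | Path) -> None:
    """Write per-species GFF3+FASTA, per-group MSAs, the tree, truth tables
    and a params echo under ``outdir``."""
    from .io_formats import write_gene_models

    outdir = Path(outdir)
    (outdir / "msa").mkdir(parents=True, exist_ok=True)
    for sp in sorted(result.models):
        write_gene_models(result.models[sp], outdir / f"{sp}.gff3")
        with open(outdir / f"{sp}.fa", "w") as fh:
            for cid in sorted(result.contigs[sp]):
                fh.write(f">{cid}\n{result.contigs[sp][cid]}\n")
    for group in sorted(result.msas):
        result.msas[group].write(outdir / "msa" / f"{group}.fa")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(result.truth.params.tree_newick.strip() + "\n")
    result.truth.sites_frame().to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "group": i.group,
                "origin": i.origin,
                "codon_index": i.codon_index,
                "length_aa": i.length_aa,
                "present": ",".join(i.present),
            }
            for i in result.truth.insertions
        ],
        columns=["group", "origin", "codon_index", "length_aa", "present"],
    ).to_csv(outdir / "truth_insertions.tsv", sep="\t", index=False)
    params = asdict(result.truth.params)
    with open(outdir / "params.json", "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_codon_usage(usage: pd.Series, path: str | Path) -> None:
    usage.rename_axis("codon").to_frame().to_csv(path, sep="\t")


def read_codon_usage(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="codon")
    return df.iloc[:, 0]


# ---------------------------------------------------------------------------
# stand-alone annotation table for regression recovery studies
# ---------------------------------------------------------------------------

def simulate_ptc_table(
    n_novel: int = 307,
    n_conserved: int = 8810,
    or_novel: float = 3.0,
    or_conserved: float = 1.6,
    seed: int = 0,
    length_effect: float = 0.02,
    phase_effects: tuple[float, float, float] = (0.0, 0.3, 2.0),
    intercept: float = 0.3,
) -> pd.DataFrame:
    """Annotation table with designed within-group 3n odds ratios.

    Lengths follow the simulator's shifted-geometric law (floor 45 nt),
    phases the rough genomic mix 0.4/0.3/0.3, and the 3n class is Bernoulli
     1/3.  The linear predictor of PTC occurrence adds log(or_novel) for
    novel 3n introns and log(or_conserved) for conserved 3n introns on top
    of length and phase effects, so a correctly specified logistic fit
    should recover the two odds ratios within its confidence intervals.
    """
    rng = np.random.default_rng(seed)
    n = n_novel + n_conserved
    group = np.array(["novel"] * n_novel + ["conserved"] * n_conserved)
    length = 44 + rng.geometric(1.0 / 26.0, size=n)
    is_3n = rng.random(n) < 1 / 3
    # force the length's mod-3 class to match the drawn 3n class
    rem = length % 3
    length = np.where(is_3n, length - rem, np.where(rem == 0, length + 1, length))
    length = np.maximum(length, 45)
    phase = rng.choice([0, 1, 2], size=n, p=[0.4, 0.3, 0.3])
    eta = (
        intercept
        + length_effect * (length - 70.0)
        + np.asarray(phase_effects)[phase]
        + np.where(is_3n & (group == "novel"), np.log(or_novel), 0.0)
        + np.where(is_3n & (group == "conserved"), np.log(or_conserved), 0.0)
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    has_ptc = rng.random(n) < p
    return pd.DataFrame(
        {
            "length": length.astype(int),
            "phase": phase.astype(int),
            "group": group,
            "is_3n": is_3n,
            "has_ptc": has_ptc,
        }
    )
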