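"""Homologize introns across species into presence/absence sites.

An intron position is identified by the protein-alignment column of the
residue whose codon contains (or follows) the insertion point, together
with the intron phase.  Introns from different species that land on the
same (column, phase) are the same site; a complete presence/absence vector
over all species of the tree is attached to each site, which is the input
Dollo parsimony needs.  Ortholog groups missing any species are dropped:
only fully represented groups give unambiguous presence vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, Intron, ProteinAlignment

logger = logging.getLogger(__name__)


class HomologyError(ValueError):
    pass


@dataclass
class IntronSite:
    """A homologized intron position within one ortholog group."""

    group_id: str
    column: int
    phase: int
    presence: dict[str, bool]
    member_introns: list[Intron] = field(default_factory=list)

    @property
    def site_id(self) -> str:
        return f"{self.group_id}:{self.column}:{self.phase}"

    def presence_string(self, species_order: Sequence[str]) -> str:
        return "".join("1" if self.presence[sp] else "0" for sp in species_order)


@dataclass(frozen=True)
class CodingChange:
    site_id: str
    n_aa_delta: int
    change_class: str  # "0" | "1-3" | ">=4"
    truncated_window: bool = False


def map_intron(intron: Intron, msa: ProteinAlignment, row_id: str) -> tuple[int, int]:
    """(alignment column, phase) of an intron via its coding offset.

    The residue containing/preceding the insertion point is residue
    floor(cds_offset / 3) of the ungapped row; its alignment column plus
    the phase (cds_offset mod 3) pins the site.
    """
    n_res = msa.ungapped_length(row_id)
    if intron.cds_offset > 3 * n_res:
        raise HomologyError(
            f"{intron.gene_id}: cds_offset {intron.cds_offset} beyond CDS "
            f"({n_res} residues in row {row_id!r})"
        )
    residue = intron.cds_offset // 3
    if residue == n_res:  # insertion point right after the last residue
        residue -= 1
    return msa.column_of_residue(row_id, residue), intron.cds_offset % 3


def build_sites(
    gene_models_by_species: Mapping[str, Sequence[GeneModel]],
    msas: Mapping[str, ProteinAlignment],
    species: Sequence[str],
    slack: int = 0,
) -> list[IntronSite]:
    """Cluster introns of complete ortholog groups into sites.

    Exact (column, phase) matches always merge; with ``slack`` > 0,
    equal-phase clusters whose columns differ by at most ``slack`` are
    merged as well (single linkage along the column axis).  Groups lacking
    a gene in any species are dropped with a logged count.
    """
    species = list(species)
    by_group: dict[str, dict[str, GeneModel]] = {}
    for sp, models in gene_models_by_species.items():
        for m in models:
            by_group.setdefault(m.gene_id, {})[sp] = m

    dropped = 0
    sites: list[IntronSite] = []
    for group_id in sorted(by_group):
        members = by_group[group_id]
        if set(members) != set(species) or group_id not in msas:
            dropped += 1
            continue
        msa = msas[group_id]
        placed: dict[tuple[int, int], IntronSite] = {}
        for sp in species:
            seen: set[tuple[int, int]] = set()
            for intron in members[sp].introns:
                key = map_intron(intron, msa, sp)
                if key in seen:
                    raise HomologyError(
                        f"gene {group_id}/{sp}: two introns map to column "
                        f"{key[0]} phase {key[1]} (annotation defect)"
                    )
                seen.add(key)
                if key not in placed:
                    placed[key] = IntronSite(
                        group_id=group_id,
                        column=key[0],
                        phase=key[1],
                        presence={s: False for s in species},
                    )
                placed[key].presence[sp] = True
                placed[key].member_introns.append(intron)
        clusters = _merge_slack(list(placed.values()), slack) if slack > 0 else list(placed.values())
        clusters.sort(key=lambda s: (s.column, s.phase))
        sites.extend(clusters)
    if dropped:
        logger.warning("dropped %d incomplete ortholog group(s)", dropped)
    return sites


def _merge_slack(sites: list[IntronSite], slack: int) -> list[IntronSite]:
    merged: list[IntronSite] = []
    for phase in (0, 1, 2):
        chain: list[IntronSite] = []
        for s in sorted(
            (x for x in sites if x.phase == phase), key=lambda x: x.column
        ):
            if chain and s.column - chain[-1].column <= slack:
                chain.append(s)
            else:
                if chain:
                    merged.append(_fuse(chain))
                chain = [s]
        if chain:
            merged.append(_fuse(chain))
    return merged


def _fuse(chain: list[IntronSite]) -> IntronSite:
    if len(chain) == 1:
        return chain[0]
    head = chain[0]
    fused = IntronSite(
        group_id=head.group_id,
        column=head.column,
        phase=head.phase,
        presence=dict(head.presence),
    )
    for s in chain:
        for sp, pres in s.presence.items():
            fused.presence[sp] = fused.presence[sp] or pres
        fused.member_introns.extend(s.member_introns)
    return fused


def classify_coding_change(
    site: IntronSite, msa: ProteinAlignment, window: int = 10
) -> CodingChange:
    """Net amino-acid change beside a site between carrier and non-carrier
    species, binned as 0, 1-3 or >=4 residues.

    Counts residues (non-gap characters) within ``window`` columns either
    side of the site column in carrier vs. non-carrier rows; the rounded
    difference of the means is the signed delta.
    """
    present = [sp for sp, p in site.presence.items() if p]
    absent = [sp for sp, p in site.presence.items() if not p]
    if not present or not absent:
        raise HomologyError(f"site {site.site_id}: needs both carrier and non-carrier species")
    lo = max(0, site.column - window)
    hi = min(msa.n_columns, site.column + window + 1)
    truncated = lo != site.column - window or hi != site.column + window + 1

    def mean_residues(rows: list[str]) -> float:
        return sum(
            sum(1 for ch in msa.rows[sp][lo:hi] if ch != msa.GAP) for sp in rows
        ) / len(rows)

    delta = round(mean_residues(present) - mean_residues(absent))
    mag = abs(delta)
    change_class = "0" if mag == 0 else ("1-3" if mag <= 3 else ">=4")
    return CodingChange(site.site_id, int(delta), change_class, truncated)


def detect_unspliced_insertions(
    msas: Mapping[str, ProteinAlignment],
    sites: Iterable[IntronSite] = (),
    min_aa: int = 15,
) -> pd.DataFrame:
    """Find large coding insertions that did not become introns.

    A hit is a maximal run of alignment columns in which one fixed,
    non-empty proper subset of rows has residues while all other rows are
    gapped, of length >= ``min_aa`` (15 aa = 45 nt, the shortest insertion
    long enough to be spliced as an intron), and whose columns contain no
    homologized intron site.  Returns a frame with group, species
    (comma-joined carriers) and length_aa.
    """
    site_cols: dict[str, set[int]] = {}
    for s in sites:
        site_cols.setdefault(s.group_id, set()).add(s.column)
    records = []
    for group_id in sorted(msas):
        msa = msas[group_id]
        ids = msa.ids
        runs: list[tuple[int, int, frozenset]] = []
        cur_set: frozenset | None = None
        cur_start = 0
        for col in range(msa.n_columns):
            have = frozenset(rid for rid in ids if msa.rows[rid][col] != msa.GAP)
            key = have if 0 < len(have) < len(ids) else None
            if key != cur_set:
                if cur_set is not None:
                    runs.append((cur_start, col, cur_set))
                cur_set = key
                cur_start = col
        if cur_set is not None:
            runs.append((cur_start, msa.n_columns, cur_set))
        for start, end, carriers in runs:
            if end - start < min_aa:
                continue
            if any(start <= c < end for c in site_cols.get(group_id, ())):
                continue
            records.append(
                {
                    "group": group_id,
                    "species": ",".join(sorted(carriers)),
                    "length_aa": end - start,
                    "column_start": start,
                }
            )
    return pd.DataFrame(records, columns=["group", "species", "length_aa", "column_start"])
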