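"""Dollo-parsimony reconstruction of intron gain and loss.

Under Dollo parsimony each intron site is gained exactly once; any pattern
of absence below the gain node is explained by losses.  The most
parsimonious single-gain placement is the MRCA of the species carrying the
intron, and the losses are the root edges of the maximal all-absent
subtrees inside that clade.  A site whose carrier MRCA is the tree root
cannot be polarized -- it may be an ancestral intron or a gain on the root
-- so its gain is reported as ROOT_AMBIGUOUS and counted separately; its
losses below the root are still well defined and are counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .homology import IntronSite

logger = logging.getLogger(__name__)

ROOT_AMBIGUOUS = "ROOT_AMBIGUOUS"


class DolloError(ValueError):
    pass


@dataclass
class SiteEvents:
    site_id: str
    group_id: str
    gain_branch: str          # branch id (child-node label) or ROOT_AMBIGUOUS
    loss_branches: list[str]

    @property
    def is_root_ambiguous(self) -> bool:
        return self.gain_branch == ROOT_AMBIGUOUS


@dataclass
class EventReconstruction:
    sites: list[SiteEvents]
    tree: dendropy.Tree

    @property
    def n_root_ambiguous(self) -> int:
        return sum(1 for s in self.sites if s.is_root_ambiguous)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "group": s.group_id,
                    "gain_branch": s.gain_branch,
                    "loss_branches": ",".join(s.loss_branches),
                }
                for s in self.sites
            ],
            columns=["site_id", "group", "gain_branch", "loss_branches"],
        )


def _leaf_index(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def infer_site(
    presence: Mapping[str, bool], tree: dendropy.Tree
) -> tuple[str, list[str]]:
    """Most parsimonious single-gain placement for one presence vector.

    Returns (gain branch id or ROOT_AMBIGUOUS, loss branch ids).  The gain
    branch is named by its child node; losses are the topmost edges of the
    maximal absent subtrees within the gain clade.
    """
    leaves = _leaf_index(tree)
    unknown = set(presence) - set(leaves)
    if unknown:
        raise DolloError(f"presence vector names unknown species: {sorted(unknown)}")
    missing = set(leaves) - set(presence)
    if missing:
        raise DolloError(f"presence vector incomplete, missing: {sorted(missing)}")
    present_nodes = [leaves[sp] for sp, p in presence.items() if p]
    if not present_nodes:
        raise DolloError("all-absent presence vector: no site to reconstruct")

    if len(present_nodes) == 1:
        mrca = present_nodes[0]
    else:
        mrca = tree.mrca(taxa=[n.taxon for n in present_nodes])

    present_set = {n.taxon.label for n in present_nodes}
    losses: list[str] = []

    def descend(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            below = {lf.taxon.label for lf in child.leaf_iter()}
            if below & present_set:
                descend(child)
            else:
                losses.append(child.label)

    descend(mrca)
    gain = ROOT_AMBIGUOUS if mrca.parent_node is None else mrca.label
    return gain, losses


def reconstruct(sites: Sequence[IntronSite], tree: dendropy.Tree) -> EventReconstruction:
    events = []
    for site in sites:
        gain, losses = infer_site(site.presence, tree)
        events.append(SiteEvents(site.site_id, site.group_id, gain, losses))
    return EventReconstruction(events, tree)


def summarize(
    recon: EventReconstruction, n_genes: int, tree: dendropy.Tree | None = None
) -> pd.DataFrame:
    """Per-branch event counts and rates in events/gene/Bya.

    The denominator is the fixed analyzed-gene count, not a per-branch
    ancestral gene number.  A totals row (branch id "TOTAL") is appended;
    the count of root-ambiguous sites is attached as frame attrs.
    """
    if n_genes <= 0:
        raise DolloError("n_genes must be positive")
    tree = tree or recon.tree
    branches = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    gains = {b.label: 0 for b in branches}
    losses = {b.label: 0 for b in branches}
    for s in recon.sites:
        if not s.is_root_ambiguous:
            gains[s.gain_branch] += 1
        for b in s.loss_branches:
            losses[b] += 1
    rows = []
    for b in branches:
        t_bya = b.edge.length / 1000.0
        if t_bya == 0 and (gains[b.label] or losses[b.label]):
            warnings.warn(f"branch {b.label}: events on zero-length branch, rate is inf")
        g_rate = gains[b.label] / n_genes / t_bya if t_bya > 0 else (
            np.inf if gains[b.label] else 0.0
        )
        l_rate = losses[b.label] / n_genes / t_bya if t_bya > 0 else (
            np.inf if losses[b.label] else 0.0
        )
        rows.append(
            {
                "branch": b.label,
                "branch_length_my": b.edge.length,
                "n_gains": gains[b.label],
                "n_losses": losses[b.label],
                "gain_rate": g_rate,
                "loss_rate": l_rate,
            }
        )
    total_my = sum(b.edge.length for b in branches)
    rows.append(
        {
            "branch": "TOTAL",
            "branch_length_my": total_my,
            "n_gains": sum(gains.values()),
            "n_losses": sum(losses.values()),
            "gain_rate": sum(gains.values()) / n_genes / (total_my / 1000.0),
            "loss_rate": sum(losses.values()) / n_genes / (total_my / 1000.0),
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["n_root_ambiguous"] = recon.n_root_ambiguous
    return out


def genes_with_both(recon: EventReconstruction) -> list[str]:
    """Ortholog groups that underwent both intron gain and intron loss."""
    gained: set[str] = set()
    lost: set[str] = set()
    for s in recon.sites:
        if not s.is_root_ambiguous:
            gained.add(s.group_id)
        if s.loss_branches:
            lost.add(s.group_id)
    return sorted(gained & lost)


def site_class(events: SiteEvents) -> str:
    """'novel' for a polarized gain, 'conserved' for a root-level site."""
    return "conserved" if events.is_root_ambiguous else "novel"
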