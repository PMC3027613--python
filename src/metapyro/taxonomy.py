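"""Rank-aware taxonomy trees, LCA merging and abundance profiles.

Marker-gene (16S rRNA) fragments and protein-coding environmental gene
tags (EGTs) arrive as per-read lineage assignments with per-rank
confidences, produced by external classifiers.  This module applies the
length/confidence filters, merges multi-assignment reads by lowest
common ancestor, and turns the surviving assignments into rank-wise
abundance profiles whose percentages are taken over the full normalized
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Canonical ranks from broadest to most specific.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed trees or lineages not on the tree."""


@dataclass(frozen=True)
class TaxNode:
    node_id: str
    name: str
    rank: str  # one of RANKS, or "root"
    parent_id: str | None


class TaxonomyTree:
    """A rooted tree over the canonical ranks.

    Missing intermediate ranks are allowed; a node's rank must be
    strictly deeper than its parent's, so ranks never repeat or invert
    along a root-to-leaf path and absent ranks act as pass-through.
    """

    ROOT_ID = "root"

    def __init__(self) -> None:
        self.nodes: dict[str, TaxNode] = {
            self.ROOT_ID: TaxNode(self.ROOT_ID, "root", "root", None)
        }
        self._children: dict[str, list[str]] = {self.ROOT_ID: []}

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, name: str, rank: str, parent_id: str) -> TaxNode:
        if node_id in self.nodes:
            raise TaxonomyError(f"duplicate node id {node_id!r}")
        if parent_id not in self.nodes:
            raise TaxonomyError(f"parent {parent_id!r} of {node_id!r} not in tree")
        if rank not in RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {rank!r} for node {node_id!r}")
        parent = self.nodes[parent_id]
        if parent.rank != "root" and RANK_DEPTH[rank] <= RANK_DEPTH[parent.rank]:
            raise TaxonomyError(
                f"rank {rank!r} of {node_id!r} not below parent rank {parent.rank!r}"
            )
        node = TaxNode(node_id, name, rank, parent_id)
        self.nodes[node_id] = node
        self._children[node_id] = []
        self._children[parent_id].append(node_id)
        return node

    @classmethod
    def from_lineages(cls, lineages: Iterable[Sequence[tuple[str, str]]]) -> "TaxonomyTree":
        """Build a tree from lineage paths of (rank, name) pairs.

        Node ids are the '/'-joined name path, so identical names under
        different parents stay distinct.
        """
        tree = cls()
        for lineage in lineages:
            parent = cls.ROOT_ID
            path: list[str] = []
            for rank, name in lineage:
                path.append(name)
                node_id = "/".join(path)
                if node_id not in tree.nodes:
                    tree.add_node(node_id, name, rank, parent)
                parent = node_id
        return tree

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TaxonomyTree":
        """Build from a headered table (node_id, name, rank, parent_id).

        Rows may appear in any order; parents are resolved iteratively.
        """
        required = {"node_id", "name", "rank", "parent_id"}
        missing = required - set(table.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns {sorted(missing)}")
        tree = cls()
        pending = list(table.itertuples(index=False))
        while pending:
            still: list = []
            progressed = False
            for row in pending:
                if row.parent_id in tree.nodes:
                    tree.add_node(row.node_id, row.name, row.rank, row.parent_id)
                    progressed = True
                else:
                    still.append(row)
            if not progressed:
                orphans = sorted(r.node_id for r in still)
                raise TaxonomyError(f"unresolvable parents for nodes {orphans}")
            pending = still
        return tree

    # -- queries ------------------------------------------------------

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        if node_id not in self.nodes:
            raise TaxonomyError(f"node {node_id!r} not on tree")
        path = [node_id]
        while (parent := self.nodes[path[-1]].parent_id) is not None:
            path.append(parent)
        return path

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        """The node's ancestor-or-self at ``rank``, or None if the
        lineage ends above that rank."""
        target = RANK_DEPTH[rank]
        for nid in self.path_to_root(node_id):
            node = self.nodes[nid]
            if node.rank != "root" and RANK_DEPTH[node.rank] == target:
                return nid
            if node.rank != "root" and RANK_DEPTH[node.rank] < target:
                return None
        return None

    def lca(self, node_ids: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not node_ids:
            raise TaxonomyError("lca of empty node set")
        paths = [list(reversed(self.path_to_root(n))) for n in node_ids]
        anc = self.ROOT_ID
        for column in zip(*paths):
            if all(c == column[0] for c in column):
                anc = column[0]
            else:
                break
        return anc


def lca_merge(classifications: Sequence[str], tree: TaxonomyTree) -> str:
    """Merge multiple classifications of one read into a single node.

    Reads carrying more than one gene fragment can receive several,
    possibly contradicting, taxonomic calls; collapsing them to the
    deepest node that is an ancestor-or-self of every call trades rank
    resolution for consistency.
    """
    for node in classifications:
        if node not in tree.nodes:
            raise TaxonomyError(f"node {node!r} not on tree")
    return tree.lca(classifications)


# -- filters ----------------------------------------------------------


def filter_marker_candidates(
    hits: pd.DataFrame, min_len: int = 50, max_evalue: float = 1e-5
) -> set[str]:
    """Reads whose marker-gene alignment passes the length/E-value gate.

    ``hits`` needs columns read_id, align_length, evalue.  Both
    boundaries are inclusive (alignment length >= min_len, E-value
    <= max_evalue).
    """
    if hits.empty:
        return set()
    keep = (hits["align_length"] >= min_len) & (hits["evalue"] <= max_evalue)
    return set(hits.loc[keep, "read_id"])


def apply_confidence_threshold(
    assignments: pd.DataFrame, rank: str, min_conf: float = 0.80
) -> pd.DataFrame:
    """Keep assignments with confidence at ``rank`` of at least min_conf.

    ``assignments`` is long-form (read_id, rank, taxon, confidence[,
    source]); the filter selects the rows *at* the requested rank and
    applies the inclusive threshold to them.
    """
    if rank not in RANK_DEPTH:
        raise TaxonomyError(f"unknown rank {rank!r}")
    at_rank = assignments[assignments["rank"] == rank]
    return at_rank[at_rank["confidence"] >= min_conf].copy()


# -- profiles ---------------------------------------------------------

UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceProfile:
    """Taxon counts at one rank, with the normalized-dataset size as the
    denominator for percentages."""

    rank: str
    counts: dict[str, int]
    total_reads: int
    unclassified: int = 0

    def percentage(self, taxon: str) -> float:
        return 100.0 * self.counts.get(taxon, 0) / self.total_reads

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int).sort_values(ascending=False)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative taxon count")
        if sum(self.counts.values()) + self.unclassified > self.total_reads:
            raise ValueError("profile counts exceed total reads")


def build_profile(
    assignments: Mapping[str, str],
    tree: TaxonomyTree,
    rank: str,
    total_reads: int,
) -> AbundanceProfile:
    """Count reads at-or-below each taxon of ``rank``.

    ``assignments`` maps read_id -> (merged) tree node.  Reads whose
    node ends above the requested rank go into an explicit
    unclassified-at-rank bucket rather than being dropped silently.
    """
    counts: dict[str, int] = {}
    unclassified = 0
    for node in assignments.values():
        anc = tree.ancestor_at_rank(node, rank)
        if anc is None:
            unclassified += 1
        else:
            name = tree.nodes[anc].name
            counts[name] = counts.get(name, 0) + 1
    return AbundanceProfile(rank=rank, counts=counts, total_reads=total_reads,
                            unclassified=unclassified)


def lineage_table_to_nodes(
    tax_table: pd.DataFrame, tree: TaxonomyTree | None = None
) -> pd.DataFrame:
    """Collapse a long-form assignment table to one tree node per read.

    Rows (read_id, rank, taxon, ...) are ordered by rank depth and the
    name path is joined into the '/'-separated node id convention of
    :meth:`TaxonomyTree.from_lineages`.  When a tree is given, each
    node is checked against it.
    """
    frames = []
    for read_id, group in tax_table.groupby("read_id", sort=False):
        ordered = group.sort_values("rank", key=lambda s: s.map(RANK_DEPTH))
        node = "/".join(ordered["taxon"])
        frames.append((read_id, node))
    out = pd.DataFrame(frames, columns=["read_id", "node"])
    if tree is not None:
        unknown = sorted(set(out["node"]) - set(tree.nodes))
        if unknown:
            raise TaxonomyError(f"nodes not on tree: {unknown[:5]}")
    return out


def compare_genus_sets(
    profile_a: AbundanceProfile, profile_b: AbundanceProfile
) -> tuple[set[str], set[str], set[str]]:
    """Partition observed taxa into (specific to A, shared, specific to B)."""
    taxa_a = {t for t, c in profile_a.counts.items() if c > 0}
    taxa_b = {t for t, c in profile_b.counts.items() if c > 0}
    return taxa_a - taxa_b, taxa_a & taxa_b, taxa_b - taxa_a
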