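"""Function x taxonomy cross-tabulation for fermentation pathways.

Per-read orthologous-group (COG) assignments are joined with the
per-read taxonomic lineages, grouped into fermentation-relevant
pathway contexts (polysaccharide degradation, acetogenesis via the
Wood-Ljungdahl pathway, methanogenesis), and aggregated over the
taxonomy tree: every node carries the number of pathway reads assigned
at or below it, and the bracketed residual — reads that could not be
classified to any child — makes the per-node accounting explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .taxonomy import TaxonomyTree


class FunctionError(ValueError):
    pass


PATHWAYS = ("polysaccharide_degradation", "acetogenesis", "methanogenesis")


@dataclass
class PathwayGroupMap:
    """COG id -> (pathway, subcategory); each id maps to exactly one pair."""

    mapping: dict[str, tuple[str, str]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayGroupMap":
        if frame["cog_id"].duplicated().any():
            dups = sorted(frame.loc[frame["cog_id"].duplicated(), "cog_id"])
            raise FunctionError(f"COG ids mapped more than once: {dups}")
        return cls(
            {
                str(r.cog_id): (str(r.pathway), str(r.subcategory))
                for r in frame.itertuples(index=False)
            }
        )

    @classmethod
    def default(cls) -> "PathwayGroupMap":
        """The shipped map: a small curated stand-in covering cellulose,
        hemicellulose and lignin degradation, the Wood-Ljungdahl pathway
        and methanogenesis marker groups (synthetic-community scale, not
        the full published COG lists)."""
        with resources.files("metapyro.data").joinpath("cog_pathways.tsv").open() as fh:
            return cls.from_frame(pd.read_csv(fh, sep="\t"))

    def pathway_of(self, cog_id: str) -> tuple[str, str] | None:
        return self.mapping.get(cog_id)

    def cogs_for(self, pathway: str) -> list[str]:
        return sorted(c for c, (p, _) in self.mapping.items() if p == pathway)


def join_function_taxonomy(
    cog_table: pd.DataFrame, tax_assignments: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Inner join of functional and taxonomic annotation on read id.

    ``cog_table`` has (read_id, cog_id, evalue); reads with several COG
    hits are reduced to their best E-value hit first (ties broken by
    lexicographic COG id, deterministically).  ``tax_assignments`` needs
    (read_id, node) where node is a taxonomy-tree node id.  Returns the
    joined frame plus a report counting reads lacking either annotation.
    """
    if cog_table.empty or tax_assignments.empty:
        joined = pd.DataFrame(columns=["read_id", "cog_id", "evalue", "node"])
    else:
        best = (
            cog_table.sort_values(["read_id", "evalue", "cog_id"])
            .drop_duplicates("read_id", keep="first")
        )
        joined = best.merge(tax_assignments[["read_id", "node"]], on="read_id", how="inner")
    cog_ids = set(cog_table["read_id"]) if not cog_table.empty else set()
    tax_ids = set(tax_assignments["read_id"]) if not tax_assignments.empty else set()
    report = {
        "n_function_only": len(cog_ids - tax_ids),
        "n_taxonomy_only": len(tax_ids - cog_ids),
        "n_joined": len(joined),
    }
    return joined, report


@dataclass
class FunctionTaxonNode:
    node_id: str
    count: int
    residual: int  # reads not classified at any lower rank (bracketed)
    subcategory_counts: dict[str, int] = field(default_factory=dict)

    def subcategory_fractions(self) -> dict[str, float]:
        total = sum(self.subcategory_counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.subcategory_counts.items()}


@dataclass
class FunctionTaxonTree:
    """Taxonomy tree annotated with per-pathway read counts."""

    pathway: str
    nodes: dict[str, FunctionTaxonNode]
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": n.node_id,
                "count": n.count,
                "residual": n.residual,
                **{f"frac_{k}": v for k, v in n.subcategory_fractions().items()},
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows)


def aggregate_pathway_tree(
    joined: pd.DataFrame,
    tree: TaxonomyTree,
    group_map: PathwayGroupMap,
    pathway: str,
) -> FunctionTaxonTree:
    """Aggregate pathway reads over the taxonomy tree.

    Each joined read whose COG belongs to ``pathway`` adds one to its
    assigned node and to every ancestor, so a node's count is the
    number of pathway reads at or below it; the residual (count − sum
    of child counts) is the bracketed number of reads that stay
    unresolved at that node.  Subcategory tallies (e.g. cellulose /
    hemicellulose / lignin) accumulate the same way and normalize to
    pie fractions per node.
    """
    if pathway not in PATHWAYS:
        raise FunctionError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    counts: dict[str, int] = {}
    subcats: dict[str, dict[str, int]] = {}
    n_pathway = 0
    for row in joined.itertuples(index=False):
        hit = group_map.pathway_of(row.cog_id)
        if hit is None or hit[0] != pathway:
            continue
        n_pathway += 1
        subcat = hit[1]
        for nid in tree.path_to_root(row.node):
            counts[nid] = counts.get(nid, 0) + 1
            subcats.setdefault(nid, {}).setdefault(subcat, 0)
            subcats[nid][subcat] += 1
    nodes: dict[str, FunctionTaxonNode] = {}
    for nid, count in counts.items():
        child_sum = sum(counts.get(c, 0) for c in tree.children(nid))
        nodes[nid] = FunctionTaxonNode(
            node_id=nid,
            count=count,
            residual=count - child_sum,
            subcategory_counts=subcats.get(nid, {}),
        )
    return FunctionTaxonTree(pathway=pathway, nodes=nodes, total_reads=n_pathway)


def pathway_percentage(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """100 * numerator / denominator, rounded to the reported precision."""
    if denominator <= 0:
        raise FunctionError("denominator must be positive")
    if numerator < 0:
        raise FunctionError("numerator must be >= 0")
    return round(100.0 * numerator / denominator, ndigits)


def tally_best_hits(best_hits: Mapping[str, str] | pd.DataFrame) -> pd.Series:
    """Per-locus read counts from a best-hit table (read -> locus).

    Each read contributes to exactly one locus, so the counts sum to
    the number of reads with hits.
    """
    if isinstance(best_hits, pd.DataFrame):
        if best_hits["read_id"].duplicated().any():
            raise FunctionError("best-hit table assigns a read to more than one locus")
        loci = best_hits["locus"]
    else:
        loci = pd.Series(list(best_hits.values()), dtype=object)
    counts = loci.value_counts().sort_index()
    counts.name = "n_reads"
    return counts
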