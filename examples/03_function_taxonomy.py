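"""Function x taxonomy cross-tabulation over fermentation pathways.

Joins per-read orthologous-group hits with taxonomic assignments and
aggregates the methanogenesis-context reads over the taxonomy tree.
"""

from metapyro import (
    PathwayGroupMap,
    aggregate_pathway_tree,
    default_community,
    generate_assignment_tables,
    generate_reads,
    join_function_taxonomy,
    pathway_percentage,
)
from metapyro.taxonomy import TaxonomyTree, lineage_table_to_nodes

spec = default_community(n_reads=10_000, duplicate_rate=0.0,
                         backfold_breakpoint=None, seed=3)
reads, truth = generate_reads(spec)
tax, cog = generate_assignment_tables(reads, truth, spec, seed=4)

tree = TaxonomyTree.from_lineages([t.lineage for t in spec.taxa])
nodes = lineage_table_to_nodes(tax, tree)
joined, report = join_function_taxonomy(cog, nodes)
print(f"reads with both annotations: {report['n_joined']}")

ftree = aggregate_pathway_tree(joined, tree, PathwayGroupMap.default(),
                               "methanogenesis")
print(f"methanogenesis-context reads: {ftree.total_reads}")
for node_id, node in sorted(ftree.nodes.items()):
    name = node_id.split("/")[-1]
    if name in {"Archaea", "Methanomicrobiales", "Methanosarcinales", "root"}:
        print(f"  {name:<20} count={node.count:>5}  unresolved-below={node.residual}")

archaea = next(n for i, n in ftree.nodes.items() if i.endswith("Archaea"))
mm = next(n for i, n in ftree.nodes.items() if i.endswith("Methanomicrobiales"))
share = pathway_percentage(mm.count, archaea.count)
print(f"\nMethanomicrobiales share of archaeal methanogenesis hits: {share:.0f}%")
# Counts accumulate up the tree; a node's bracketed residual is the
# number of reads that could not be placed in any of its children.
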