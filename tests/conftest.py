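"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use different algorithms from the library code
they check: exhaustive scans, brute-force enumeration and per-base
bitmaps instead of the sequential/analytic/interval implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from metapyro.readqc import GCLengthProfile
from metapyro.taxonomy import RANKS, TaxonomyTree

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# -- oracle: exhaustive two-segment least-squares breakpoint scan ------


def two_segment_breakpoint(lengths: np.ndarray, values: np.ndarray,
                           min_points: int = 10) -> int:
    """Length at the split minimizing total SSE of two independent OLS
    fits (left/right of the split).  O(n) per candidate via prefix sums."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)

    def sse(i, j):  # fit on x[i:j]
        xs, ys = x[i:j], y[i:j]
        m = len(xs)
        xbar, ybar = xs.mean(), ys.mean()
        sxx = ((xs - xbar) ** 2).sum()
        sxy = ((xs - xbar) * (ys - ybar)).sum()
        syy = ((ys - ybar) ** 2).sum()
        if sxx == 0:
            return syy
        return syy - sxy * sxy / sxx

    best, best_k = np.inf, None
    for k in range(min_points, n - min_points):
        total = sse(0, k) + sse(k, n)
        if total < best:
            best, best_k = total, k
    return int(x[best_k])


# -- oracle: brute-force LCA via ancestor-set intersection -------------


def lca_bruteforce(tree: TaxonomyTree, node_ids) -> str:
    """Deepest member of the intersection of all ancestor-or-self sets."""
    common = None
    for nid in node_ids:
        anc = set(tree.path_to_root(nid))
        common = anc if common is None else common & anc
    return max(common, key=tree.depth)


def random_toy_tree(rng: np.random.Generator, max_children: int = 3):
    """A random taxonomy tree over all seven ranks; returns (tree, leaves)."""
    tree = TaxonomyTree()
    frontier = [TaxonomyTree.ROOT_ID]
    counter = itertools.count()
    nodes = []
    for rank in RANKS:
        nxt = []
        for parent in frontier:
            for _ in range(int(rng.integers(1, max_children + 1))):
                nid = f"n{next(counter)}"
                tree.add_node(nid, nid, rank, parent)
                nxt.append(nid)
                nodes.append(nid)
        # keep the tree small: cap the frontier
        if len(nxt) > 6:
            nxt = [nxt[int(i)] for i in rng.choice(len(nxt), size=6, replace=False)]
        frontier = nxt
    return tree, nodes


# -- oracle: rarefaction by exhaustive subset enumeration --------------


def rarefaction_enumeration(counts, n: int) -> float:
    """Mean richness over every C(N, n) subset, enumerated explicitly."""
    items = [i for i, c in enumerate(counts) for _ in range(c)]
    total = 0
    count = 0
    for subset in itertools.combinations(range(len(items)), n):
        total += len({items[i] for i in subset})
        count += 1
    return total / count


def rarefaction_exact_rational(counts, n: int) -> float:
    """E[S_n] with exact integer binomial coefficients (math.comb)."""
    total = sum(counts)
    denom = math.comb(total, n)
    acc = 0.0
    for c in counts:
        acc += 1.0 - math.comb(total - c, n) / denom
    return acc


# -- oracle: per-base bitmap coverage ----------------------------------


def covered_fraction_bitmap(intervals, genome_length: int) -> float:
    mask = np.zeros(genome_length, dtype=bool)
    for lo, hi in intervals:
        mask[max(lo, 0):min(hi, genome_length)] = True
    return mask.sum() / genome_length


# -- oracle: naive KDE double loop -------------------------------------


def epanechnikov_naive(values, bandwidth, grid):
    out = []
    for x in grid:
        acc = 0.0
        for v in values:
            u = (x - v) / bandwidth
            if abs(u) <= 1.0:
                acc += 0.75 * (1.0 - u * u)
        out.append(acc / (len(values) * bandwidth))
    return np.array(out)


# -- oracle: minimal compatible partition of SNP signatures ------------


def min_compatible_partition(sigs) -> int:
    """Smallest number of groups such that within each group all reads
    agree wherever their covered intervals both observe a position.

    ``sigs`` is a list of (snps: dict, interval: (lo, hi)).  A pair
    conflicts when one carries a SNP at a position the other covers
    with a different (possibly reference) base.  Brute force over
    assignments; feasible for <= 8 reads.
    """

    def pair_ok(a, b):
        (snps_a, (lo_a, hi_a)), (snps_b, (lo_b, hi_b)) = a, b
        for pos, base in snps_a.items():
            if lo_b <= pos < hi_b and snps_b.get(pos) != base:
                return False
        for pos, base in snps_b.items():
            if lo_a <= pos < hi_a and snps_a.get(pos) != base:
                return False
        return True

    n = len(sigs)
    best = n

    def search(i, groups):
        nonlocal best
        if len(groups) >= best:
            return
        if i == n:
            best = min(best, len(groups))
            return
        for g in groups:
            if all(pair_ok(sigs[i], sigs[j]) for j in g):
                g.append(i)
                search(i + 1, groups)
                g.pop()
        groups.append([i])
        search(i + 1, groups)
        groups.pop()

    search(0, [])
    return best


# -- shared fixtures ---------------------------------------------------


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """Firmicutes toy taxonomy used across LCA and profile tests."""
    tree = TaxonomyTree()
    tree.add_node("Bacteria", "Bacteria", "superkingdom", "root")
    tree.add_node("Firmicutes", "Firmicutes", "phylum", "Bacteria")
    tree.add_node("Clostridia", "Clostridia", "class", "Firmicutes")
    tree.add_node("Bacilli", "Bacilli", "class", "Firmicutes")
    tree.add_node("Clostridiales", "Clostridiales", "order", "Clostridia")
    tree.add_node("Clostridiaceae", "Clostridiaceae", "family", "Clostridiales")
    tree.add_node("Clostridium", "Clostridium", "genus", "Clostridiaceae")
    tree.add_node("Bacillales", "Bacillales", "order", "Bacilli")
    tree.add_node("Bacillaceae", "Bacillaceae", "family", "Bacillales")
    tree.add_node("Bacillus", "Bacillus", "genus", "Bacillaceae")
    return tree
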