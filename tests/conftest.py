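"""Shared fixtures: the packaged 13-species benchmark (simulated once per
session) and small independent oracles used by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ciliate_rdna.clone_align import CloneLibrary, trim_primers
from ciliate_rdna.io_formats import NamedSequence
from ciliate_rdna.phylo_check import TreeNode, haplotype_congruence_report
from ciliate_rdna.polymorphism import summarize_species
from ciliate_rdna.synthetic_data import simulate_clone_library, table2_benchmark

BENCH_SEED = 316


@pytest.fixture(scope="session")
def benchmark():
    return table2_benchmark(BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_libraries(benchmark):
    """Primer-trimmed clone libraries per species, provenance preserved."""
    out = {}
    for spec in benchmark.species_specs:
        libs = []
        for lib in simulate_clone_library(spec):
            trimmed = [
                trim_primers(c, spec.primer_fwd, spec.primer_rev) for c in lib.clones
            ]
            libs.append(
                CloneLibrary(lib.species_id, lib.individual_id, trimmed, lib.provenance)
            )
        out[spec.species_id] = libs
    return out


@pytest.fixture(scope="session")
def benchmark_summaries(benchmark_libraries):
    return {sp: summarize_species(libs) for sp, libs in benchmark_libraries.items()}


@pytest.fixture(scope="session")
def benchmark_congruence(benchmark, benchmark_summaries):
    species_haps = {
        sp: [
            NamedSequence(f"{u.unit_id}_hap{h.haplotype_id}", h.sequence)
            for u in s.units
            for h in u.haplotypes
        ]
        for sp, s in benchmark_summaries.items()
    }
    return haplotype_congruence_report(species_haps, benchmark.outgroups)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the code paths they check)

def enumeration_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Exhaustive recursion over every global alignment of two short strings."""
    if not a and not b:
        return 0
    scores = []
    if a and b:
        scores.append(
            enumeration_alignment_score(a[1:], b[1:], match, mismatch, gap)
            + (match if a[0] == b[0] else mismatch)
        )
    if a:
        scores.append(enumeration_alignment_score(a[1:], b, match, mismatch, gap) + gap)
    if b:
        scores.append(enumeration_alignment_score(a, b[1:], match, mismatch, gap) + gap)
    return max(scores)


def random_additive_tree(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    """Random unrooted binary tree with positive branch lengths."""
    leaves = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(3)
    ]
    root = TreeNode(children=list(leaves))
    for i in range(3, n_taxa):
        # collect (parent, child) edges and subdivide one at random
        edges = []

        def walk(node):
            for c in node.children:
                edges.append((node, c))
                walk(c)

        walk(root)
        parent, child = edges[rng.integers(len(edges))]
        newleaf = TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0)))
        joint = TreeNode(children=[child, newleaf], length=float(rng.uniform(0.1, 1.0)))
        parent.children[parent.children.index(child)] = joint
    return root


def tree_path_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix by BFS on the tree's adjacency graph."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}

    def walk(node):
        adj.setdefault(id(node), [])
        if node.is_leaf():
            names[id(node)] = node.name
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((id(c), c.length))
            adj[id(c)].append((id(node), c.length))
            walk(c)

    walk(tree)
    leaf_ids = sorted(names, key=lambda k: names[k])
    taxa = [names[k] for k in leaf_ids]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(leaf_ids):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaf_ids):
            d[i, j] = dist[dst]
    return taxa, d
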