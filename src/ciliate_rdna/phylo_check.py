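"""Desk-scale phylogenetic checks: NJ trees, monophyly, topology congruence.

The question answered here is narrow: do the haplotypes of each species form
a monophyletic group, and does the answer depend on how gapped/ambiguous
columns are handled?  Monophyly is a topological property, so a distance
method (neighbour joining on p-distances) suffices at this scale; likelihood
or Bayesian inference and node supports are deliberately out of scope.

Gap handling mirrors the two-alignment practice of marker-gene studies as a
mode flag: ``complete`` deletion drops every column containing a gap in any
row before distances are computed, ``pairwise`` deletion drops gapped
columns per sequence pair.

Neighbour joining is implemented with deterministic tie-breaking (first
minimal Q-matrix entry in row-major taxon order) so trees are reproducible;
it recovers the generating topology exactly for any additive matrix.
Robinson–Foulds distance counts the nontrivial bipartitions present in
exactly one of two trees on the same leaf set.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import NamedSequence, read_fasta, write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "CongruenceReport",
    "p_distance",
    "build_distance_matrix",
    "nj_tree",
    "newick",
    "tree_splits",
    "is_monophyletic",
    "rf_distance",
    "align_with_mafft",
    "haplotype_congruence_report",
]

GapMode = Literal["pairwise", "complete"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal over ordered taxa."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("need a symmetric nonnegative matrix with zero diagonal")
        object.__setattr__(self, "values", v)


@dataclass
class TreeNode:
    """Unrooted tree stored as a rooted structure; the root is the final
    trifurcation, so every internal node of the unrooted tree has degree 3."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among columns where neither sequence
    has a gap; raises if no column is comparable."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    compared = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) sites")
    return diffs / compared


def build_distance_matrix(
    seqs: Sequence[NamedSequence], mode: GapMode = "pairwise"
) -> DistanceMatrix:
    """Pairwise p-distances from aligned sequences under a gap-deletion mode."""
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("duplicate taxon ids")
    rows = [s.seq for s in seqs]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences must share one aligned length")
    if mode == "complete":
        keep = [c for c in range(len(rows[0])) if all(r[c] != "-" for r in rows)]
        if not keep:
            raise ValueError("complete deletion removed every column")
        rows = ["".join(r[c] for c in keep) for r in rows]
    elif mode != "pairwise":
        raise ValueError(f"unknown gap mode {mode!r}")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(rows[i], rows[j])
    return DistanceMatrix(tuple(s.id for s in seqs), d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbour-joining agglomeration.

    Ties in the Q matrix resolve to the first (row-major) minimal entry in
    the current taxon order; negative branch-length estimates are clipped to
    zero.  For three taxa the unique unrooted topology is returned directly.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        left, right = nodes[i], nodes[j]
        left.length = max(vi, 0.0)
        right.length = max(vj, 0.0)
        parent = TreeNode(children=[left, right])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    # terminal trifurcation
    (a, b, c) = nodes
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.5 * (da + db - dc), 0.0)
    b.length = max(0.5 * (da + dc - db), 0.0)
    c.length = max(0.5 * (db + dc - da), 0.0)
    return TreeNode(children=[a, b, c])


def newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{node.length:.6f}"

    inner = ",".join(fmt(c) for c in tree.children)
    return f"({inner});"


def _canonical(split: frozenset[str], leafset: frozenset[str]) -> frozenset[str]:
    other = leafset - split
    return min(split, other, key=lambda s: (len(s), tuple(sorted(s))))


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Canonicalised nontrivial bipartitions induced by the internal edges."""
    leafset = frozenset(tree.leaves())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(leafset) - 1:
            splits.add(_canonical(below, leafset))
        return below

    walk(tree)
    return splits


def is_monophyletic(tree: TreeNode, leafset: Iterable[str]) -> bool:
    """True iff some edge separates exactly ``leafset`` from the rest."""
    target = frozenset(leafset)
    leaves = frozenset(tree.leaves())
    if not target:
        raise ValueError("empty leaf set")
    unknown = target - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(target) in (1, len(leaves)):
        return True  # a leaf edge / the trivial split
    return _canonical(target, leaves) in tree_splits(tree)


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the two
    trees' nontrivial split sets (leaf sets must match)."""
    if frozenset(t1.leaves()) != frozenset(t2.leaves()):
        raise ValueError("trees must share one leaf set")
    return len(tree_splits(t1) ^ tree_splits(t2))


def align_with_mafft(seqs: Sequence[NamedSequence]) -> list[NamedSequence]:
    """Cross-species multiple alignment via the MAFFT command-line tool."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(seqs, inp)
        proc = subprocess.run(
            ["mafft", "--retree", "2", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(tmp) / "out.fasta"
        out.write_text(proc.stdout)
        aligned = read_fasta(out)
    by_id = {s.id: s for s in aligned}
    return [by_id[s.id] for s in seqs]  # restore input order


@dataclass
class CongruenceReport:
    """Monophyly flags per species and topology agreement between gap modes."""

    trees: dict[str, TreeNode]
    newicks: dict[str, str]
    monophyly: dict[str, dict[str, bool]]  # species -> mode -> flag
    rf_between_modes: int

    def as_frame(self) -> pd.DataFrame:
        records = [
            {"species": sp, **{f"monophyletic_{m}": v for m, v in modes.items()}}
            for sp, modes in self.monophyly.items()
        ]
        return pd.DataFrame.from_records(records)


def haplotype_congruence_report(
    species_haplotypes: dict[str, list[NamedSequence]],
    outgroups: Sequence[NamedSequence] = (),
    modes: Sequence[GapMode] = ("pairwise", "complete"),
    aligned: bool = False,
) -> CongruenceReport:
    """NJ trees over all species' haplotypes (plus outgroups) under each gap
    mode, with per-species monophyly flags and the RF distance between the
    mode trees.

    Haplotype ids must be unique across species.  Set ``aligned`` when the
    inputs are already one alignment; otherwise MAFFT aligns them.
    """
    if len(species_haplotypes) < 2:
        raise ValueError("need at least 2 species")
    members = {
        sp: [s.id for s in seqs] for sp, seqs in species_haplotypes.items()
    }
    allseqs = [s for seqs in species_haplotypes.values() for s in seqs] + list(outgroups)
    if not aligned:
        allseqs = align_with_mafft(allseqs)
    trees: dict[str, TreeNode] = {}
    newicks: dict[str, str] = {}
    monophyly: dict[str, dict[str, bool]] = {sp: {} for sp in species_haplotypes}
    for mode in modes:
        dm = build_distance_matrix(allseqs, mode=mode)
        tree = nj_tree(dm)
        trees[mode] = tree
        newicks[mode] = newick(tree)
        for sp, ids in members.items():
            monophyly[sp][mode] = is_monophyletic(tree, ids)
    rf = rf_distance(trees[modes[0]], trees[modes[1]]) if len(modes) > 1 else 0
    logger.info(
        "haplotype_congruence_report: %d species, %d sequences, RF(modes)=%d",
        len(species_haplotypes),
        len(allseqs),
        rf,
    )
    return CongruenceReport(
        trees=trees, newicks=newicks, monophyly=monophyly, rf_between_modes=rf
    )
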