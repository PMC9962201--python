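"""Independent oracles shared by the unit and acceptance tests.

Everything here deliberately avoids the code paths it checks: alignment
scores come from a plain affine-gap recursion (and, for tiny inputs, full
path enumeration), operon segmentation from a direct rule walk, and
phylogeny inputs from trees built by random joining with path-length
distances.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from skbio.tree import TreeNode

_SUB = substitution_matrices.load("BLOSUM62")


def affine_dp_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_ends: bool = True,
) -> float:
    """Optimal global affine-gap score by memoized recursion.

    A gap run of length L costs ``gap_open + gap_extend * L``; runs sitting
    at either boundary of the sequence they interrupt are free when
    ``free_ends``.  Exhausts the alignment space via memoization.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: str) -> float:
        if i == n and j == m:
            return 0.0
        best = -math.inf
        if i < n and j < m:
            best = max(best, _SUB[a[i], b[j]] + go(i + 1, j + 1, "M"))
        if j < m:  # gap in a, consuming b[j]
            if free_ends and (i == 0 or i == n):
                cost = 0.0
            else:
                cost = gap_extend if prev == "GA" else gap_open + gap_extend
            best = max(best, -cost + go(i, j + 1, "GA"))
        if i < n:  # gap in b, consuming a[i]
            if free_ends and (j == 0 or j == m):
                cost = 0.0
            else:
                cost = gap_extend if prev == "GB" else gap_open + gap_extend
            best = max(best, -cost + go(i + 1, j, "GB"))
        return best

    return go(0, 0, "M")


def affine_enum_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_ends: bool = True,
) -> float:
    """Optimal score by literally enumerating every alignment path (tiny inputs)."""

    def score_moves(moves: str) -> float:
        total, i, j = 0.0, 0, 0
        k = 0
        while k < len(moves):
            move = moves[k]
            if move == "M":
                total += _SUB[a[i], b[j]]
                i, j, k = i + 1, j + 1, k + 1
                continue
            run = 0
            while k < len(moves) and moves[k] == move:
                run += 1
                k += 1
            if move == "A":  # gap in a at point i
                free = free_ends and (i == 0 or i == len(a))
                j += run
            else:  # gap in b at point j
                free = free_ends and (j == 0 or j == len(b))
                i += run
            if not free:
                total -= gap_open + gap_extend * run
        return total

    best = -math.inf
    stack = [(0, 0, "")]
    while stack:
        i, j, moves = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score_moves(moves))
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, moves + "M"))
        if j < len(b):
            stack.append((i, j + 1, moves + "A"))
        if i < len(a):
            stack.append((i + 1, j, moves + "B"))
    return best


def brute_force_operon_blocks(
    genes: list[tuple[str, int, int, str]], max_gap_bp: int
) -> list[tuple[str, ...]]:
    """Direct application of the segmentation rule to one replicon.

    ``genes`` are (gene_id, start, end, strand) sorted by start.  A new
    block starts whenever the strand flips or the intergenic gap exceeds
    the threshold (negative gaps count as 0).
    """
    blocks: list[list[tuple[str, int, int, str]]] = []
    for gene in genes:
        gid, start, end, strand = gene
        if blocks:
            prev = blocks[-1][-1]
            same_strand = strand == prev[3]
            gap = max(start - prev[2] - 1, 0)
            if same_strand and gap <= max_gap_bp:
                blocks[-1].append(gene)
                continue
        blocks.append([gene])
    return [tuple(g[0] for g in block) for block in blocks]


def random_binary_tree(rng: np.random.Generator, n_taxa: int) -> TreeNode:
    """Random rooted binary tree with branch lengths in [0.1, 1.0]."""
    nodes = [TreeNode(name=f"t{i}", length=None) for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(int(j))
        left = nodes.pop(int(i))
        left.length = float(rng.uniform(0.1, 1.0))
        right.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    return nodes[0]


def additive_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (an additive matrix)."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return ids, np.asarray(dm.data, dtype=float)


def splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of a tree's leaf set."""
    leaves = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        under = frozenset(t.name for t in node.tips())
        rest = leaves - under
        if len(under) >= 2 and len(rest) >= 2:
            out.add(frozenset((under, rest)))
    return out
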