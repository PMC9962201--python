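"""Distance-based phylogeny: identity matrix -> NJ tree -> Newick.

The distance between two proteins is ``1 - identity/100``.  Trees are
inferred with classical neighbor-joining, which recovers additive distance
matrices exactly; negative branch-length estimates are clamped to zero
(the common convention).  The resulting topologies are illustrative
companions to the comparative tables, not model-based inferences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from .identity import IdentityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, non-negative, zero diagonal


def identity_to_distance(matrix: IdentityMatrix) -> DistanceMatrix:
    """d = 1 - identity/100; raises on identities outside [0, 100]."""
    values = np.asarray(matrix.values, dtype=float)
    if (values < 0).any() or (values > 100).any():
        raise ValueError("identities must lie in [0, 100]")
    dist = 1.0 - values / 100.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ids=tuple(matrix.ids), values=dist)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (>= 3 taxa).

    Negative branch-length estimates are clamped to zero.  Returns an
    unrooted tree represented with a trifurcating root.
    """
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = _SkbioDistanceMatrix(matrix.values, ids=list(matrix.ids))
    tree = _skbio_nj(dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.warning("clamping negative branch length %.4g at %s", node.length, node.name)
            node.length = 0.0
    return tree
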