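"""Distance-based phylogeny: p-distances and neighbour joining.

Distances are uncorrected p-distances (fraction of differing positions
among mutually ungapped columns, i.e. pairwise deletion) with an optional
Kimura-style protein correction ``d = -ln(1 - p - p^2/5)``.  Trees are
built with the classic Saitou–Nei neighbour-joining algorithm, which is
exact on additive distance matrices, and are serialised to Newick via
scikit-bio's ``TreeNode``.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
from skbio import DistanceMatrix, TreeNode

from cidkit.alignment import GAP, AlignedSequenceSet

#: Cap applied to saturated Kimura-corrected distances (ClustalW-style).
SATURATION_CAP = 10.0


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share no mutually ungapped column."""


def p_distance(aln: AlignedSequenceSet, i: int | str, j: int | str) -> float:
    """Fraction of differing mutually non-gap columns between two rows.

    ``i``/``j`` may be sequence indices (0-based) or sequence ids.
    Columns where either sequence is gapped are excluded (pairwise
    deletion).
    """
    def resolve(x: int | str) -> str:
        return aln.records[x].residues if isinstance(x, int) else aln.record(x).residues

    a, b = resolve(i), resolve(j)
    comparable = 0
    diffs = 0
    for ca, cb in zip(a, b):
        if ca != GAP and cb != GAP:
            comparable += 1
            if ca != cb:
                diffs += 1
    if comparable == 0:
        raise UndefinedDistanceError(
            f"sequences {i!r} and {j!r} share no ungapped column"
        )
    return diffs / comparable


def kimura_correction(p: float, *, cap: float = SATURATION_CAP) -> float:
    """Kimura's protein-distance correction ``d = -ln(1 - p - p^2/5)``.

    For p near saturation (argument of the log <= 0, p >= ~0.854) the
    distance is capped at ``cap`` with a warning, mirroring common
    practice in distance programs.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0.0:
        warnings.warn(
            f"p-distance {p:.4f} saturated; capping corrected distance at "
            f"{cap}",
            stacklevel=2,
        )
        return cap
    return min(cap, -math.log(arg))


def distance_matrix(
    aln: AlignedSequenceSet,
    correction: Literal["none", "kimura"] = "none",
) -> DistanceMatrix:
    """All-pairs distance matrix of an alignment as a skbio DistanceMatrix."""
    n = aln.N
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln, i, j)
            d[i, j] = d[j, i] = (
                kimura_correction(p) if correction == "kimura" else p
            )
    return DistanceMatrix(d, ids=aln.seq_ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree (Saitou & Nei) from a distance matrix.

    Repeatedly joins the pair minimising
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (``r_i = sum_k d(i,k)``), with
    branch lengths from the standard split formula and
    ``d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2`` to the new node.  Ties
    are broken on the lexicographically smallest active index pair, so
    the output is deterministic.  Negative branch lengths are clamped to
    zero (a ``clamped`` attribute is set on the returned root when this
    happened).  The result is returned as a rooted-at-trifurcation
    ``TreeNode`` representing the unrooted binary NJ tree; for an
    additive matrix, leaf-to-leaf path lengths equal the input distances.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped = True
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    if n == 2:
        half = dm[0, 1] / 2.0
        for node in nodes:
            node.length = clamp(half)
        root = TreeNode(children=nodes)
        root.clamped = clamped
        return root

    d = np.array(dm.data, dtype=float)
    active = list(range(n))  # indices into `nodes`/rows of d
    # d grows as new internal nodes are appended
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) position pair
        best = np.unravel_index(np.argmin(q), q.shape)
        ai, aj = sorted((int(best[0]), int(best[1])))
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (na - 2))
        vj = dij - vi
        nodes[i].length = clamp(vi)
        nodes[j].length = clamp(vj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(new)
        new_idx = len(nodes) - 1
        new_row = np.zeros(new_idx + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_idx, k] = d[k, new_idx] = duk
        active = [k for k in active if k not in (i, j)] + [new_idx]
    # final trifurcation: v_i = (d_ij + d_ik - d_jk) / 2
    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = clamp(vi)
    nodes[j].length = clamp(vj)
    nodes[k].length = clamp(vk)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    root.clamped = clamped
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise a tree to a Newick file at full float precision."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> float:
    """Unrooted Robinson–Foulds distance (shared-bipartition count)."""
    return float(t1.compare_rfd(t2))


def distance_matrix_to_tsv(dm: DistanceMatrix) -> str:
    """Square TSV with a header row of taxa."""
    lines = ["\t" + "\t".join(dm.ids)]
    for i, name in enumerate(dm.ids):
        lines.append(
            name + "\t" + "\t".join(f"{dm.data[i, j]:.6g}" for j in range(len(dm.ids)))
        )
    return "\n".join(lines) + "\n"
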