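"""Alignment curation, neighbor-joining, support collapsing and
phylogeny-guided family nomenclature.

Naming follows the reference-anchored rules: a target leaf that is the
reciprocal unique nearest neighbour of a single reference gene inherits
that gene's number; co-equidistant targets share the number with letter
suffixes; targets tied between several references, and all remaining
targets, receive fresh numbers above the reference maximum, issued in a
fixed tree-traversal order.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "AlignmentBlockFilter",
    "NameAssignment",
    "assign_names",
    "filter_alignment_blocks",
    "nj_tree",
    "parse_reference_number",
    "patristic_distances",
    "support_collapse",
]

REFERENCE_RE = re.compile(r"^At\D*?(\d+)[a-z]?$")


@dataclass(frozen=True)
class AlignmentBlockFilter:
    """Column filter in the spirit of relaxed Gblocks curation."""

    max_gap_fraction: float = 0.5
    min_block_length: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")


@dataclass(frozen=True)
class NameAssignment:
    target: str
    name: str
    rule: str  # same_number | lettered | new_number_multi_ref | new_number
    references: tuple[str, ...] = ()


def filter_alignment_blocks(
    alignment: dict[str, str], block_filter: AlignmentBlockFilter | None = None
) -> dict[str, str]:
    """Keep maximal runs of columns whose gap fraction is acceptable and
    whose run length reaches ``min_block_length``; order preserved."""
    if block_filter is None:
        block_filter = AlignmentBlockFilter()
    if not alignment:
        raise ValueError("empty alignment")
    seqs = list(alignment.values())
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    n = len(seqs)
    good = [
        sum(1 for s in seqs if s[c] in "-.") / n <= block_filter.max_gap_fraction
        for c in range(length)
    ]
    keep: list[int] = []
    c = 0
    while c < length:
        if not good[c]:
            c += 1
            continue
        j = c
        while j < length and good[j]:
            j += 1
        if j - c >= block_filter.min_block_length:
            keep.extend(range(c, j))
        c = j
    if not keep:
        raise ValueError(
            "no alignment columns survived curation; relax max_gap_fraction "
            "or min_block_length"
        )
    return {k: "".join(s[c] for c in keep) for k, s in alignment.items()}


def nj_tree(distance_matrix: DistanceMatrix | np.ndarray, ids=None) -> TreeNode:
    """Neighbor-joining tree with negative branch lengths clamped to 0."""
    if not isinstance(distance_matrix, DistanceMatrix):
        arr = np.asarray(distance_matrix, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        distance_matrix = DistanceMatrix(arr, ids=ids)
    if distance_matrix.shape[0] < 3:
        raise ValueError("at least 3 taxa required")
    tree = _skbio_nj(distance_matrix)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def support_collapse(tree: TreeNode, threshold: float = 70.0) -> TreeNode:
    """Collapse internal edges whose support is below ``threshold``.

    Supports are read from internal-node names (newick convention).
    Nodes without a parseable support are kept.  The leaf set is
    unchanged; collapsing merges a node's children into its parent.
    """
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse(include_self=False)):
            if node.is_tip() or node.parent is None:
                continue
            try:
                support = float(node.name) if node.name is not None else None
            except (TypeError, ValueError):
                support = None
            if support is not None and support < threshold:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True
    return tree


def patristic_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the matrix of path-length distances between them."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data


def parse_reference_number(label: str) -> int | None:
    m = REFERENCE_RE.match(label)
    return int(m.group(1)) if m else None


def _traversal_order(tree: TreeNode) -> dict[str, int]:
    """Deterministic leaf order: depth-first walk of the unrooted tree
    anchored at the lexicographically smallest leaf, taking each node's
    children in stored order and the parent edge last."""
    anchor_name = min((t.name for t in tree.tips()), key=str)
    anchor = next(t for t in tree.tips() if t.name == anchor_name)
    order: dict[str, int] = {}
    seen: set[int] = set()

    def walk(node: TreeNode) -> None:
        if id(node) in seen:
            return
        seen.add(id(node))
        if node.is_tip() and node.name not in order:
            order[node.name] = len(order)
        for nb in list(node.children) + ([node.parent] if node.parent else []):
            walk(nb)

    walk(anchor)
    return order


def assign_names(
    tree: TreeNode,
    reference_numbers: dict[str, int] | None = None,
    prefix: str = "ATL",
    rel_tol: float = 1e-6,
) -> list[NameAssignment]:
    """Name every non-reference leaf from its phylogenetic placement.

    ``reference_numbers`` maps reference leaf labels to their numbers;
    when omitted, labels matching ``At...<number>`` are parsed.  Rules,
    in order: (i) reciprocal unique nearest reference -> same number;
    (ii) several targets equidistant from one reference -> shared number
    with letters in traversal order; (iii) a target tied between two or
    more references -> next unused number above the reference maximum;
    (iv) everything else -> progressive new numbers along the traversal.
    """
    leaves = [t.name for t in tree.tips()]
    if reference_numbers is None:
        reference_numbers = {
            lf: num
            for lf in leaves
            if (num := parse_reference_number(lf)) is not None
        }
    refs = [lf for lf in leaves if lf in reference_numbers]
    targets = [lf for lf in leaves if lf not in reference_numbers]
    if not refs or not targets:
        raise ValueError("tree must contain both reference and target leaves")
    numbers = list(reference_numbers.values())
    if len(set(numbers)) != len(numbers):
        raise ValueError("duplicate reference numbers")

    ids, dmat = patristic_distances(tree)
    idx = {lf: i for i, lf in enumerate(ids)}
    order = _traversal_order(tree)

    def tied_min(row_of: str, candidates: list[str]) -> list[str]:
        dists = {c: dmat[idx[row_of], idx[c]] for c in candidates}
        dmin = min(dists.values())
        tol = rel_tol * max(dmin, 1e-300)
        return sorted(
            (c for c, d in dists.items() if d <= dmin + tol), key=order.__getitem__
        )

    nearest_refs = {t: tied_min(t, refs) for t in targets}
    nearest_targets = {r: tied_min(r, targets) for r in refs}

    assignments: dict[str, NameAssignment] = {}
    # rules (i) and (ii): targets anchored to a single reference
    for r in refs:
        claimants = [
            t
            for t in nearest_targets[r]
            if len(nearest_refs[t]) == 1 and nearest_refs[t][0] == r
        ]
        if not claimants:
            continue
        num = reference_numbers[r]
        if len(claimants) == 1:
            t = claimants[0]
            assignments[t] = NameAssignment(t, f"{prefix}{num}", "same_number", (r,))
        else:
            for letter, t in zip(_letters(), sorted(claimants, key=order.__getitem__)):
                assignments[t] = NameAssignment(
                    t, f"{prefix}{num}{letter}", "lettered", (r,)
                )

    # rules (iii) and (iv): fresh numbers in traversal order
    next_number = max(numbers) + 1
    unnamed = sorted((t for t in targets if t not in assignments), key=order.__getitem__)
    for t in unnamed:
        near = tuple(nearest_refs[t])
        rule = "new_number_multi_ref" if len(near) >= 2 else "new_number"
        assignments[t] = NameAssignment(t, f"{prefix}{next_number}", rule, near)
        next_number += 1

    result = sorted(assignments.values(), key=lambda a: order[a.target])
    names = [a.name for a in result]
    if len(set(names)) != len(names):  # pragma: no cover - defensive
        raise AssertionError("duplicate names assigned")
    return result


def _letters():
    for size in itertools.count(1):
        for combo in itertools.product("abcdefghijklmnopqrstuvwxyz", repeat=size):
            yield "".join(combo)
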