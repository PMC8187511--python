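"""Paralog-cluster assignment by distance trees and bootstrap support.

Verified receptor proteins are assigned to paralog clusters (SREB1, SREB2,
SREB3A, SREB3B) from a labelled multiple alignment: p-distances feed a
neighbor-joining tree; bootstrap replicates over alignment columns measure,
for each candidate cluster, how often its members form a clade in the tree
rooted on a designated outgroup.  Sequences whose cluster is not supported —
typically deep outgroups such as agnathan or shark sreb-like genes — are
labelled UNASSIGNED rather than forced into a clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .conserve import GAP, MSA

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "pairwise_distances",
    "nj_tree",
    "bootstrap_clusters",
    "clusters_from_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")


@dataclass(frozen=True)
class ClusterAssignment:
    #: gene_id -> cluster label or "UNASSIGNED"
    labels: dict
    #: cluster -> bootstrap support (fraction of replicates monophyletic)
    support: dict


def _encoded_rows(msa: MSA) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype="S1") for r in msa.rows])


def _p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise p-distance: mismatches over aligned non-gap residue pairs."""
    n = mat.shape[0]
    gap = GAP.encode()
    nongap = mat != gap
    d = np.zeros((n, n))
    # broadcast in row blocks to bound memory on large families
    block = max(1, int(4e7 // max(1, n * mat.shape[1])))
    none_comparable = False
    for lo in range(0, n, block):
        hi = min(n, lo + block)
        comp = nongap[lo:hi, None, :] & nongap[None, :, :]
        mism = comp & (mat[lo:hi, None, :] != mat[None, :, :])
        m = comp.sum(axis=2)
        none_comparable = none_comparable or bool((m == 0).any())
        d[lo:hi] = np.where(m > 0, mism.sum(axis=2) / np.maximum(m, 1), 1.0)
    np.fill_diagonal(d, 0.0)  # an all-gap row still matches itself
    if none_comparable:
        warnings.warn(
            "sequence pair with no comparable columns; distance set to 1.0"
        )
    return d


def pairwise_distances(msa: MSA, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """p-distances between all sequences of ``msa`` (optionally a subset)."""
    sub = msa.subset(ids) if ids is not None else msa
    return DistanceMatrix(labels=tuple(sub.ids), d=_p_distance_matrix(_encoded_rows(sub)))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero.

    Deterministic for a fixed input order.  For an exactly additive distance
    matrix the reconstructed tree reproduces every split of the generating
    tree.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(_SkbioDM(dm.d, ids=list(dm.labels)))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _clades(tree: TreeNode, root_tip: Optional[str]) -> set[frozenset]:
    """Tip-sets of every internal node after rooting at ``root_tip``."""
    if root_tip is not None:
        rooted = tree.root_at(tree.find(root_tip).parent)
    else:
        rooted = tree.root_at_midpoint()
    out = set()
    for node in rooted.non_tips(include_self=True):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def _monophyletic(clades: set[frozenset], members: frozenset) -> bool:
    return len(members) == 1 or members in clades


def bootstrap_clusters(
    msa: MSA,
    hints: dict[str, Optional[str]],
    n_boot: int = 100,
    seed: int = 0,
    outgroup: Optional[str] = None,
    support_threshold: float = 0.7,
) -> ClusterAssignment:
    """Assign sequences to hinted clusters with bootstrap clade support.

    Alignment columns are resampled with replacement ``n_boot`` times; each
    replicate's NJ tree is rooted on ``outgroup`` (midpoint without one) and
    scored for whether each hinted cluster's members are monophyletic.  A
    sequence keeps its hinted label when that cluster's support reaches
    ``support_threshold``; sequences without a hint, or in unsupported
    clusters, are UNASSIGNED.
    """
    if msa.n_cols < 10:
        raise ValueError("alignment too short to bootstrap (need >= 10 columns)")
    rng = np.random.default_rng(seed)
    mat = _encoded_rows(msa)
    members: dict[str, frozenset] = {}
    for gid in msa.ids:
        hint = hints.get(gid)
        if hint is not None:
            members.setdefault(hint, set())
    members = {
        c: frozenset(g for g in msa.ids if hints.get(g) == c) for c in members
    }
    hits = {c: 0 for c in members}
    ids = list(msa.ids)
    for _ in range(n_boot):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        boot = mat[:, cols]
        d = _p_distance_matrix(boot)
        tree = _skbio_nj(_SkbioDM(d, ids=ids))
        clades = _clades(tree, outgroup)
        for c, mem in members.items():
            if mem and _monophyletic(clades, mem):
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in members}
    labels = {}
    for gid in msa.ids:
        hint = hints.get(gid)
        if hint is not None and support.get(hint, 0.0) >= support_threshold:
            labels[gid] = hint
        else:
            labels[gid] = "UNASSIGNED"
    return ClusterAssignment(labels=labels, support=support)


def clusters_from_tree(
    tree: TreeNode,
    hints: dict[str, Optional[str]],
    outgroup: Optional[str] = None,
    support_threshold: float = 0.7,
) -> ClusterAssignment:
    """Assignment from an externally computed tree with support labels.

    Internal node names are interpreted as bootstrap fractions (or
    percentages when > 1).  Each hinted cluster is accepted when its members
    are monophyletic after rooting and the subtending node's support, if
    annotated, reaches the threshold.
    """
    if outgroup is not None:
        rooted = tree.root_at(tree.find(outgroup).parent)
    else:
        rooted = tree.root_at_midpoint()
    tips = {t.name for t in rooted.tips()}
    clusters = sorted({h for h in hints.values() if h is not None})
    support: dict[str, float] = {}
    for c in clusters:
        mem = frozenset(g for g, h in hints.items() if h == c) & tips
        support[c] = 0.0
        for node in rooted.non_tips(include_self=True):
            if frozenset(t.name for t in node.tips()) == mem:
                raw = node.name
                if raw is None:
                    support[c] = 1.0
                else:
                    val = float(raw)
                    support[c] = val / 100.0 if val > 1.0 else val
                break
    labels = {}
    for gid in tips:
        hint = hints.get(gid)
        if hint is not None and support.get(hint, 0.0) >= support_threshold:
            labels[gid] = hint
        else:
            labels[gid] = "UNASSIGNED"
    return ClusterAssignment(labels=labels, support=support)
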