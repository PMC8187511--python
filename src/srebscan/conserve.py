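"""Alignment-column conservation profiling for a paralog family.

Given a protein multiple alignment with per-sequence cluster labels, this
module answers three questions in reference-sequence numbering:

* which columns are "highly conserved" within each cluster, under the rule
  that a column is conserved when at most ``max_divergent`` (default 3)
  sequences deviate from the cluster's modal residue;
* which reference positions are *cluster-specific*: conserved in every
  cluster, with the three background clusters sharing one modal residue and
  the target cluster fixed on a different one — the signature of a conserved
  functional divergence after gene duplication;
* how the family deviates from the canonical class-A GPCR motifs (DRY in
  TM3, CWxP in TM6, NPxxY in TM7) at supplied anchor positions.

Columns before the reference's first transmembrane helix can be masked out,
since N-terminal regions are hypervariable and often carry ambiguous start
sites.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from Bio.Align import substitution_matrices

from .screen import TMAnnotation

__all__ = [
    "MSA",
    "ColumnProfile",
    "ClusterSpecificSite",
    "MotifPosition",
    "MotifReport",
    "align_or_import",
    "pairwise_align",
    "mask_nterminal",
    "profile_columns",
    "min_conservation_pct",
    "find_cluster_specific_sites",
    "scan_motifs",
]

GAP = "-"


# ---------------------------------------------------------------------------
# MSA container

@dataclass(frozen=True)
class MSA:
    """A labelled protein multiple alignment with a designated reference.

    ``reference_id`` fixes the coordinate system: reference position *r*
    (1-based, ungapped) corresponds to the alignment column holding the
    reference's *r*-th non-gap character.  ``masked_before`` columns at the
    start of the alignment are excluded from conservation statistics.
    """

    ids: tuple[str, ...]
    clusters: tuple[Optional[str], ...]
    rows: tuple[str, ...]
    reference_id: str
    masked_before: int = 0

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged alignment")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i, c in Counter(self.ids).items() if c > 1]
            raise ValueError(f"duplicate sequence ids: {dup}")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def ref_to_col(self, ref_position: int) -> int:
        """0-based column of the reference's ``ref_position``-th residue."""
        seen = 0
        for col, ch in enumerate(self.reference_row):
            if ch != GAP:
                seen += 1
                if seen == ref_position:
                    return col
        raise IndexError(f"reference position {ref_position} beyond sequence")

    def col_to_ref(self, col: int) -> Optional[int]:
        """1-based reference position of column ``col`` (None at a ref gap)."""
        row = self.reference_row
        if row[col] == GAP:
            return None
        return sum(1 for ch in row[: col + 1] if ch != GAP)

    def subset(self, keep_ids: Iterable[str]) -> "MSA":
        keep = set(keep_ids)
        if self.reference_id not in keep:
            keep = keep | {self.reference_id}
        idx = [i for i, gid in enumerate(self.ids) if gid in keep]
        return replace(
            self,
            ids=tuple(self.ids[i] for i in idx),
            clusters=tuple(self.clusters[i] for i in idx),
            rows=tuple(self.rows[i] for i in idx),
        )


# ---------------------------------------------------------------------------
# pairwise / progressive alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _column_score(col_a: str, col_b: str) -> float:
    """Mean BLOSUM62 score over residue pairs; gap characters score 0."""
    total = 0.0
    for a in col_a:
        if a == GAP:
            continue
        for b in col_b:
            if b == GAP:
                continue
            total += _BLOSUM62[a][b]
    return total / (len(col_a) * len(col_b))


def _align_profiles(
    prof_a: Sequence[str], prof_b: Sequence[str],
    gap_open: float = -10.0, gap_extend: float = -1.0,
) -> tuple[list[str], list[str], float]:
    """Gotoh affine-gap alignment of two profiles (lists of rows).

    The first residue of a gap run costs ``gap_open``, each further residue
    ``gap_extend``; terminal gaps are charged like internal ones.  Ties are
    broken deterministically: match over a gap in the second profile over a
    gap in the first.
    """
    cols_a = ["".join(r[i] for r in prof_a) for i in range(len(prof_a[0]))]
    cols_b = ["".join(r[i] for r in prof_b) for i in range(len(prof_b[0]))]
    n, m = len(cols_a), len(cols_b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in B (consumes A)
    Y = np.full((n + 1, m + 1), neg)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _column_score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                          Y[i, j - 1] + gap_extend)
    # traceback, preferring M (match) then X (gap in B) then Y (gap in A)
    mats = {"M": M, "X": X, "Y": Y}
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: mats[s][i, j])
    score = mats[state][i, j]
    out_a: list[str] = []
    out_b: list[str] = []
    ga = GAP * len(prof_a)
    gb = GAP * len(prof_b)
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            s = _column_score(cols_a[i - 1], cols_b[j - 1])
            prev = M[i, j] - s
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
            for cand in ("M", "X", "Y"):
                if np.isclose(mats[cand][i, j], prev):
                    state = cand
                    break
        elif state == "X":
            out_a.append(cols_a[i - 1])
            out_b.append(gb)
            val = X[i, j]
            i = i - 1
            if np.isclose(M[i, j] + gap_open, val):
                state = "M"
            elif np.isclose(X[i, j] + gap_extend, val):
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append(ga)
            out_b.append(cols_b[j - 1])
            val = Y[i, j]
            j = j - 1
            if np.isclose(M[i, j] + gap_open, val):
                state = "M"
            elif np.isclose(X[i, j] + gap_open, val):
                state = "X"
            else:
                state = "Y"
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(prof_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(prof_b))]
    return new_a, new_b, float(score)


def pairwise_align(a: str, b: str, gap_open: float = -10.0,
                   gap_extend: float = -1.0) -> tuple[str, str, float]:
    """Affine-gap global alignment of two sequences (BLOSUM62)."""
    ra, rb, score = _align_profiles([a], [b], gap_open, gap_extend)
    return ra[0], rb[0], score


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(max(1, len(a) - k + 1))}
    kb = {b[i:i + k] for i in range(max(1, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - 2.0 * len(ka & kb) / (len(ka) + len(kb))


def align_or_import(
    proteins: Sequence[tuple[str, str]],
    mode: str = "import",
    clusters: Optional[dict] = None,
    reference_id: Optional[str] = None,
) -> MSA:
    """Build an :class:`MSA` by validating an import or aligning progressively.

    ``import`` requires equal-length (already aligned) sequences.
    ``progressive`` builds a UPGMA guide tree on k-mer distances and merges
    profiles bottom-up with BLOSUM62 and affine gaps (open -10, extend -1).
    """
    ids = [gid for gid, _ in proteins]
    seqs = [s for _, s in proteins]
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    clusters = clusters or {}
    reference_id = reference_id or ids[0]

    if mode == "import":
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("ragged import: sequences differ in length")
        rows = list(seqs)
    elif mode == "progressive":
        if len(proteins) == 2:
            ra, rb, _ = pairwise_align(seqs[0], seqs[1])
            order, rows = [0, 1], [ra, rb]
            return MSA(
                ids=tuple(ids[i] for i in order),
                clusters=tuple(clusters.get(ids[i]) for i in order),
                rows=tuple(rows), reference_id=reference_id,
            )
        n = len(seqs)
        cond = []
        for i in range(n):
            for j in range(i + 1, n):
                cond.append(_kmer_distance(seqs[i], seqs[j]))
        Z = linkage(np.array(cond), method="average")
        profiles: dict[int, tuple[list[int], list[str]]] = {
            i: ([i], [seqs[i]]) for i in range(n)
        }
        for step, (a, b, _, _) in enumerate(Z):
            ia, ib = int(a), int(b)
            ids_a, prof_a = profiles.pop(ia)
            ids_b, prof_b = profiles.pop(ib)
            new_a, new_b, _ = _align_profiles(prof_a, prof_b)
            profiles[n + step] = (ids_a + ids_b, new_a + new_b)
        order, rows = profiles[n + len(Z) - 1]
        return MSA(
            ids=tuple(ids[i] for i in order),
            clusters=tuple(clusters.get(ids[i]) for i in order),
            rows=tuple(rows), reference_id=reference_id,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MSA(
        ids=tuple(ids),
        clusters=tuple(clusters.get(gid) for gid in ids),
        rows=tuple(rows), reference_id=reference_id,
    )


# ---------------------------------------------------------------------------
# masking

def mask_nterminal(msa: MSA, tm: dict[str, TMAnnotation]) -> MSA:
    """Mask alignment columns before the reference's first TM helix."""
    ann = tm.get(msa.reference_id)
    if ann is None or not ann.segments:
        raise ValueError("reference sequence lacks a TM annotation")
    tm1_start = ann.segments[0][0]
    col = msa.ref_to_col(tm1_start)
    return replace(msa, masked_before=col)


# ---------------------------------------------------------------------------
# column profiling

@dataclass(frozen=True)
class ColumnProfile:
    column: int                      # 1-based alignment column
    ref_position: Optional[int]      # None where the reference has a gap
    masked: bool
    counts: dict                     # cluster -> {residue/gap -> n}
    modal: dict                      # cluster -> modal residue (None if all-gap)
    divergent: dict                  # cluster -> count deviating from modal
    conserved: dict                  # cluster -> divergent <= max_divergent
    cluster_sizes: dict
    pooled_modal: Optional[str]
    pooled_divergent: int
    pooled_conserved: bool

    def conservation(self, cluster: Optional[str] = None) -> float:
        """Fraction of sequences carrying the modal residue."""
        if cluster is None:
            n = sum(self.cluster_sizes.values())
            return (n - self.pooled_divergent) / n if n else 0.0
        n = self.cluster_sizes[cluster]
        return (n - self.divergent[cluster]) / n if n else 0.0


def _column_stats(column: Sequence[str], gap_policy: str) -> tuple[Optional[str], int, Counter]:
    counts = Counter(column)
    residues = {r: c for r, c in counts.items() if r != GAP}
    if not residues:
        return None, (len(column) if gap_policy == "divergent" else 0), counts
    top = max(residues.values())
    modal = min(r for r, c in residues.items() if c == top)  # alphabetical tie
    if gap_policy == "divergent":
        divergent = len(column) - residues[modal]
    else:
        divergent = sum(residues.values()) - residues[modal]
    return modal, divergent, counts


def profile_columns(
    msa: MSA, max_divergent: int = 3, gap_policy: str = "divergent"
) -> list[ColumnProfile]:
    """Per-column, per-cluster conservation statistics.

    The modal residue is the most frequent non-gap residue (alphabetical on
    ties); the divergent count is the number of cluster members not carrying
    it, with gaps counted as divergent under the default policy.  A column is
    conserved in a cluster when its divergent count is <= ``max_divergent``.
    """
    if gap_policy not in ("divergent", "ignore"):
        raise ValueError("gap_policy must be 'divergent' or 'ignore'")
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(msa.clusters):
        if label is not None:
            groups.setdefault(label, []).append(i)
    empty = [c for c, idx in groups.items() if not idx]
    for c in empty:
        warnings.warn(f"cluster {c} is empty; omitted")
        groups.pop(c)
    labelled = sorted(groups)
    all_rows = [i for idx in groups.values() for i in idx]

    profiles: list[ColumnProfile] = []
    for col in range(msa.n_cols):
        column_chars = {i: msa.rows[i][col] for i in all_rows}
        counts, modal, divergent, conserved = {}, {}, {}, {}
        for c in labelled:
            chars = [column_chars[i] for i in groups[c]]
            m, d, cnt = _column_stats(chars, gap_policy)
            counts[c], modal[c], divergent[c] = dict(cnt), m, d
            conserved[c] = d <= max_divergent
        pm, pd, _ = _column_stats([column_chars[i] for i in all_rows], gap_policy)
        profiles.append(ColumnProfile(
            column=col + 1,
            ref_position=msa.col_to_ref(col),
            masked=col < msa.masked_before,
            counts=counts, modal=modal, divergent=divergent,
            conserved=conserved,
            cluster_sizes={c: len(groups[c]) for c in labelled},
            pooled_modal=pm, pooled_divergent=pd,
            pooled_conserved=pd <= max_divergent,
        ))
    return profiles


def min_conservation_pct(n: int, max_divergent: int = 3) -> float:
    """Lowest conservation percentage a conserved column can have.

    With at most ``max_divergent`` deviating members in a cluster of ``n``,
    conservation is at least 100*(n - max_divergent)/n, rounded half-up to
    one decimal place.
    """
    if n <= max_divergent:
        raise ValueError(f"cluster size {n} must exceed max_divergent {max_divergent}")
    pct = Decimal(100) * (Decimal(n) - Decimal(max_divergent)) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# cluster-specific sites

@dataclass(frozen=True)
class ClusterSpecificSite:
    ref_position: int
    consensus_target: str
    consensus_other: str
    #: cluster -> conservation fraction at this column (plus "pooled")
    conservation: dict


def find_cluster_specific_sites(
    profiles: Sequence[ColumnProfile],
    target_cluster: str,
    background_clusters: Sequence[str],
    strict: bool = True,
) -> list[ClusterSpecificSite]:
    """Reference positions conserved everywhere but divergent in the target.

    A site qualifies when (a) every background cluster is conserved — and,
    in strict mode, all backgrounds share one modal residue, (b) the target
    cluster is conserved, and (c) the target modal differs from every
    background modal.  Masked columns and columns where the reference is
    gapped are never reported.
    """
    if target_cluster in background_clusters:
        raise ValueError("target cluster cannot be its own background")
    sites = []
    for p in profiles:
        if p.masked or p.ref_position is None:
            continue
        if target_cluster not in p.modal:
            continue
        bg_modals = [p.modal.get(c) for c in background_clusters]
        if any(m is None for m in bg_modals):
            continue
        if not all(p.conserved.get(c, False) for c in background_clusters):
            continue
        if not p.conserved.get(target_cluster, False):
            continue
        t = p.modal[target_cluster]
        if t is None:
            continue
        if strict:
            if len(set(bg_modals)) != 1 or bg_modals[0] == t:
                continue
            other = bg_modals[0]
        else:
            if any(m == t for m in bg_modals):
                continue
            other = "".join(sorted(set(bg_modals)))
        cons = {c: p.conservation(c) for c in [*background_clusters, target_cluster]}
        cons["pooled"] = p.conservation()
        sites.append(ClusterSpecificSite(
            ref_position=p.ref_position, consensus_target=t,
            consensus_other=other, conservation=cons,
        ))
    return sorted(sites, key=lambda s: s.ref_position)


# ---------------------------------------------------------------------------
# motif scan

@dataclass(frozen=True)
class MotifPosition:
    ref_position: int
    canonical: str                  # canonical residue, 'x' = wildcard
    modal: dict                     # cluster -> modal residue
    conservation: dict              # cluster -> fraction carrying its modal
    pooled_modal: Optional[str]
    pooled_conservation: float
    deviation: Optional[str]        # e.g. "D->T"; None when matching or 'x'


@dataclass(frozen=True)
class MotifReport:
    motif: str
    canonical: str
    anchor: int
    positions: tuple[MotifPosition, ...]


def scan_motifs(
    msa: MSA,
    motif_anchors: dict[str, int],
    canonical: Optional[dict[str, str]] = None,
    profiles: Optional[Sequence[ColumnProfile]] = None,
    subset: Optional[Iterable[str]] = None,
) -> list[MotifReport]:
    """Report modal residues and deviations at canonical GPCR motif anchors.

    ``motif_anchors`` maps a motif name to the reference position of its
    first residue.  Wildcard positions ('x') are reported but never flagged
    as deviations.  ``subset`` restricts the scan to a clade of sequences
    (for lineage-restricted substitutions).
    """
    canonical = canonical or {m: m for m in motif_anchors}
    scan_msa = msa.subset(subset) if subset is not None else msa
    if profiles is None or subset is not None:
        profiles = profile_columns(scan_msa)
    by_ref = {p.ref_position: p for p in profiles if p.ref_position is not None}
    reports = []
    for motif, anchor in motif_anchors.items():
        canon = canonical[motif]
        positions = []
        for off, ch in enumerate(canon):
            ref_pos = anchor + off
            p = by_ref.get(ref_pos)
            if p is None:
                raise ValueError(
                    f"motif {motif} position {ref_pos} outside the alignment"
                )
            cons = {c: p.conservation(c) for c in p.modal}
            deviation = None
            if ch not in "xX" and p.pooled_modal is not None \
                    and p.pooled_modal != ch:
                deviation = f"{ch}->{p.pooled_modal}"
            positions.append(MotifPosition(
                ref_position=ref_pos, canonical=ch, modal=dict(p.modal),
                conservation=cons, pooled_modal=p.pooled_modal,
                pooled_conservation=p.conservation(), deviation=deviation,
            ))
        reports.append(MotifReport(
            motif=motif, canonical=canon, anchor=anchor,
            positions=tuple(positions),
        ))
    return reports
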