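"""Candidate-gene verification: ORF extraction, transmembrane counting, filters.

Putative receptor genes pulled from genome assemblies are often incomplete.
Before any comparative analysis each nucleotide sequence is (1) translated at
its longest ATG-initiated open reading frame, (2) scanned for transmembrane
(TM) helices with a Kyte-Doolittle sliding-window hydropathy detector, and
(3) filtered on expected protein length (~370 aa for an SREB receptor) and TM
count.  Two nested datasets result:

* dataset 1 ("presence/absence grade"): length OK and >= 5 of 7 TM helices —
  good enough to say the gene exists at a locus;
* dataset 2 ("analysis grade"): length OK and exactly 7 TM helices — good
  enough for column-level conservation statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "ProteinRecord",
    "TMAnnotation",
    "ScreenResult",
    "KYTE_DOOLITTLE",
    "find_longest_orf",
    "predict_tm",
    "apply_filters",
    "screen_gene",
    "screen_genes",
]

DNA_ALPHABET = set("ACGTN")

#: Kyte & Doolittle hydropathy index, kcal/mol-free-energy-like scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class GeneRecord:
    """A nucleotide gene sequence with optional genomic coordinates."""

    gene_id: str
    species: str
    sequence: str
    cluster_hint: Optional[str] = None
    #: (contig, start, end, strand); 1-based inclusive coordinates.
    locus: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-DNA characters {sorted(bad)}")
        if self.locus is not None and self.locus[1] > self.locus[2]:
            raise ValueError(f"{self.gene_id}: locus start > end")


@dataclass(frozen=True)
class ProteinRecord:
    """Translation of a gene's longest ATG-initiated open reading frame."""

    gene_id: str
    aa_sequence: str
    #: reading frame 0/1/2 on the reported strand
    orf_frame: int
    #: '+' or '-'
    strand: str
    #: 1-based inclusive nucleotide span on the *input* sequence, stop included
    orf_span: tuple[int, int]


@dataclass(frozen=True)
class TMAnnotation:
    """Predicted transmembrane segments, 1-based inclusive residue spans."""

    segments: tuple[tuple[int, int], ...]
    reason: str = ""

    @property
    def count(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class ScreenResult:
    gene_id: str
    species: str
    length_ok: bool
    tm_count: int
    aa_length: int
    dataset1_pass: bool
    dataset2_pass: bool
    reason: str = ""
    cluster_hint: Optional[str] = None


def _orf_candidates(seq: str, min_codons: int):
    """Yield (aa, frame, strand, start, end) for every ATG..stop ORF.

    Coordinates are 1-based inclusive on the forward input sequence and
    include the stop codon.
    """
    n = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                if s[i:i + 3] == "ATG":
                    j = i
                    while j + 3 <= n:
                        codon = s[j:j + 3]
                        if codon in ("TAA", "TAG", "TGA"):
                            aa = str(Seq(s[i:j]).translate())
                            if len(aa) >= min_codons and "*" not in aa:
                                if strand == "+":
                                    start, end = i + 1, j + 3
                                else:
                                    start, end = n - (j + 3) + 1, n - i
                                yield aa, frame, strand, start, end
                            # restart the scan after this ORF
                            break
                        j += 3
                    i = j + 3 if j + 3 <= n else n
                else:
                    i += 3


def find_longest_orf(gene: GeneRecord, min_codons: int = 50) -> Optional[ProteinRecord]:
    """Return the translation of the longest ATG-initiated ORF on either strand.

    Ties are broken by earlier start coordinate on the input, then by strand
    ('+' preferred).  Returns ``None`` when no ORF reaches ``min_codons``
    codons; callers record this as a screening failure ("no_orf"), not an
    exception, because assembly fragments routinely lack a full reading frame.
    """
    seq = gene.sequence.upper()
    best = None
    for aa, frame, strand, start, end in _orf_candidates(seq, min_codons):
        key = (-len(aa), start, 0 if strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, aa, frame, strand, start, end)
    if best is None:
        return None
    _, aa, frame, strand, start, end = best
    return ProteinRecord(gene.gene_id, aa, frame, strand, (start, end))


def predict_tm(
    protein: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 3,
) -> TMAnnotation:
    """Detect transmembrane helices by sliding-window Kyte-Doolittle hydropathy.

    Mean hydropathy is computed over a centred window of ``window`` residues;
    maximal runs of above-threshold window centres, expanded to the window
    edges, are candidate segments.  Segments shorter than ``min_length``
    residues are discarded and segments separated by <= ``merge_gap`` residues
    are merged.  A classical seven-helix receptor yields seven segments.
    """
    aa = protein.aa_sequence
    n = len(aa)
    if n < window:
        return TMAnnotation((), reason="too_short")
    half = window // 2
    scores = [KYTE_DOOLITTLE.get(c, 0.0) for c in aa]
    # rolling mean over the window; centre index runs half .. n-half-1 (0-based)
    total = sum(scores[:window])
    centers = []
    for c in range(half, n - half):
        if total / window > threshold:
            centers.append(c)
        left = c - half
        if left + window < n:
            total += scores[left + window] - scores[left]
    # maximal runs of consecutive centres -> spans expanded to window edges
    raw: list[list[int]] = []
    for c in centers:
        if raw and c == raw[-1][1] + 1:
            raw[-1][1] = c
        else:
            raw.append([c, c])
    spans = [
        (max(0, a - half), min(n - 1, b + half)) for a, b in raw
    ]
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    segments = tuple(
        (a + 1, b + 1) for a, b in merged if b - a + 1 >= min_length
    )
    return TMAnnotation(segments)


def apply_filters(
    protein: Optional[ProteinRecord],
    tm: Optional[TMAnnotation],
    *,
    species: str = "",
    cluster_hint: Optional[str] = None,
    len_target: int = 370,
    len_tol: float = 0.15,
    tm_min: int = 5,
    tm_full: int = 7,
) -> ScreenResult:
    """Apply the inclusion filters and report dataset membership.

    ``length_ok`` requires the protein length within ``len_tol`` (fractional)
    of ``len_target``; dataset 1 additionally requires >= ``tm_min`` TM
    segments and dataset 2 exactly ``tm_full``.
    """
    if protein is None:
        return ScreenResult(
            gene_id="", species=species, length_ok=False, tm_count=0,
            aa_length=0, dataset1_pass=False, dataset2_pass=False,
            reason="no_orf", cluster_hint=cluster_hint,
        )
    n = len(protein.aa_sequence)
    tm_count = tm.count if tm is not None else 0
    # fractional window rounded outward: 370 +/- 15% accepts 314-426 aa
    lo = math.floor(len_target * (1 - len_tol))
    hi = math.ceil(len_target * (1 + len_tol))
    length_ok = lo <= n <= hi
    d1 = length_ok and tm_count >= tm_min
    d2 = length_ok and tm_count == tm_full
    reasons = []
    if not length_ok:
        reasons.append(f"length_{n}")
    if tm is not None and tm.reason:
        reasons.append(tm.reason)
    if tm_count != tm_full:
        reasons.append(f"tm_{tm_count}")
    return ScreenResult(
        gene_id=protein.gene_id, species=species, length_ok=length_ok,
        tm_count=tm_count, aa_length=n, dataset1_pass=d1, dataset2_pass=d2,
        reason=";".join(reasons), cluster_hint=cluster_hint,
    )


def screen_gene(gene: GeneRecord, **filter_kwargs) -> tuple[ScreenResult, Optional[ProteinRecord], Optional[TMAnnotation]]:
    """Run the full verification chain for one gene."""
    protein = find_longest_orf(gene)
    tm = predict_tm(protein) if protein is not None else None
    result = apply_filters(
        protein, tm, species=gene.species, cluster_hint=gene.cluster_hint,
        **filter_kwargs,
    )
    if protein is not None and not result.gene_id:
        result = ScreenResult(**{**result.__dict__, "gene_id": gene.gene_id})
    elif protein is None:
        result = ScreenResult(**{**result.__dict__, "gene_id": gene.gene_id})
    return result, protein, tm


def screen_genes(genes: Sequence[GeneRecord], **filter_kwargs):
    """Screen a collection; returns (results, proteins, tms) keyed by gene_id."""
    results: list[ScreenResult] = []
    proteins: dict[str, ProteinRecord] = {}
    tms: dict[str, TMAnnotation] = {}
    for g in genes:
        res, prot, tm = screen_gene(g, **filter_kwargs)
        results.append(res)
        if prot is not None:
            proteins[g.gene_id] = prot
        if tm is not None:
            tms[g.gene_id] = tm
    return results, proteins, tms
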