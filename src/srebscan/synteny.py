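"""Microsynteny: presence/absence matrices and gene-loss vs assembly-gap calls.

An apparent gene absence in a genome assembly has two very different
explanations: the gene was truly lost in that lineage, or the assembly simply
lacks usable sequence at the locus.  Conserved flanking genes discriminate
the two — if both neighbours of the expected locus are present and contiguous
but the target gene is not between them, the gene was lost; if a flanker
itself is missing, the locus may sit in an assembly gap and no loss can be
claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .screen import ScreenResult

__all__ = [
    "GeneFeature",
    "GenomeAnnotation",
    "PresenceCall",
    "SyntenyCall",
    "LocusConfig",
    "normalize_symbol",
    "symbols_match",
    "presence_matrix",
    "call_synteny",
    "call_locus",
    "locus_diagram",
]


@dataclass(frozen=True)
class GeneFeature:
    symbol: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class GenomeAnnotation:
    species: str
    records: tuple[GeneFeature, ...]

    def on_contig(self, contig: str) -> list[GeneFeature]:
        return sorted(
            (r for r in self.records if r.contig == contig),
            key=lambda r: r.start,
        )


@dataclass(frozen=True)
class PresenceCall:
    species: str
    gene: str
    status: str  # present | incomplete | absent


@dataclass(frozen=True)
class SyntenyCall:
    species: str
    target: str
    upstream_flank_status: str    # found | missing
    downstream_flank_status: str  # found | missing
    interval_genes: tuple[str, ...]
    call: str                     # present | lost | assembly_gap | inconclusive
    note: str = ""


@dataclass
class LocusConfig:
    """Flanker configuration for one family-gene locus."""

    target: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]
    max_span_genes: int = 50
    max_span_bp: int = 2_000_000
    synonyms: dict[str, str] = field(default_factory=dict)


def normalize_symbol(symbol: str, synonyms: Optional[dict] = None) -> str:
    """Case-fold a gene symbol and strip a '-like' suffix."""
    s = symbol.strip().casefold()
    if s.endswith("-like"):
        s = s[: -len("-like")]
    if synonyms:
        s = synonyms.get(s, s)
    return s


def symbols_match(genome_symbol: str, query: str,
                  synonyms: Optional[dict] = None) -> bool:
    """True when an annotation symbol matches a configured query symbol.

    Matching is exact after case-folding and '-like' stripping; additionally
    a trailing paralog letter on the *annotation* symbol is ignored when the
    remaining stem ends in a digit (suv39h1a matches suv39h1).  Stripping is
    one-sided so that sibling paralogs in a query (sreb3a vs sreb3b) are
    never conflated.
    """
    g = normalize_symbol(genome_symbol, synonyms)
    q = normalize_symbol(query, synonyms)
    if g == q:
        return True
    if len(g) > 1 and g[-1].isalpha() and g[:-1] == q and q[-1:].isdigit():
        return True
    return False


# ---------------------------------------------------------------------------
# presence/absence matrix

def presence_matrix(
    screens: Iterable[ScreenResult],
    genes: Sequence[str],
    species: Sequence[str],
    gene_of=None,
) -> tuple[pd.DataFrame, list[PresenceCall]]:
    """Species x gene presence matrix from screening results.

    A gene is ``present`` in a species when any hit passes the
    presence/absence filters (dataset 1), ``incomplete`` when hits exist but
    all fail (a fragment still witnesses the locus), and ``absent`` when no
    hit exists at all.  Returns the matrix (values P/I/A) and the calls.
    """
    if gene_of is None:
        gene_of = lambda r: r.cluster_hint  # noqa: E731
    status: dict[tuple[str, str], str] = {}
    for res in screens:
        key = (res.species, gene_of(res))
        if key[1] is None:
            continue
        if res.dataset1_pass:
            status[key] = "present"
        else:
            status.setdefault(key, "incomplete")
    calls = [
        PresenceCall(sp, g, status.get((sp, g), "absent"))
        for sp in species for g in genes
    ]
    df = pd.DataFrame(
        [[status.get((sp, g), "absent")[0].upper() for g in genes] for sp in species],
        index=list(species), columns=list(genes),
    )
    return df, calls


# ---------------------------------------------------------------------------
# synteny calls

def _find_matches(feats: Sequence[GeneFeature], queries: Sequence[str],
                  synonyms) -> list[int]:
    return [
        i for i, f in enumerate(feats)
        if any(symbols_match(f.symbol, q, synonyms) for q in queries)
    ]


def call_synteny(
    genome: GenomeAnnotation,
    target: str,
    upstream: Sequence[str],
    downstream: Sequence[str],
    max_span_genes: int = 50,
    max_span_bp: int = 2_000_000,
    synonyms: Optional[dict] = None,
) -> SyntenyCall:
    """Classify a species' target-gene status from its flanking genes.

    The nearest valid upstream/downstream flanker pair on a shared contig
    (within ``max_span_genes`` intervening genes and ``max_span_bp``) defines
    the locus interval.  ``lost`` requires both flankers found with the
    target absent from the interval *and* absent genome-wide; a missing
    flanker yields ``assembly_gap``; an unordered or over-long flanker pair
    is ``inconclusive``.
    """
    for q in list(upstream) + list(downstream):
        if symbols_match(q, target, synonyms) or symbols_match(target, q, synonyms):
            raise ValueError(f"flanker symbol {q!r} collides with target {target!r}")

    feats = list(genome.records)
    target_anywhere = bool(_find_matches(feats, [target], synonyms))

    contigs = sorted({f.contig for f in feats})
    up_found = down_found = False
    best: Optional[tuple[GeneFeature, GeneFeature, list[GeneFeature]]] = None
    unordered = False
    for contig in contigs:
        on = genome.on_contig(contig)
        ups = _find_matches(on, upstream, synonyms)
        downs = _find_matches(on, downstream, synonyms)
        up_found = up_found or bool(ups)
        down_found = down_found or bool(downs)
        for ui in ups:
            for di in downs:
                lo, hi = (ui, di) if ui < di else (di, ui)
                a, b = on[lo], on[hi]
                if a.end >= b.start:
                    unordered = True
                    continue
                between = on[lo + 1:hi]
                if len(between) > max_span_genes:
                    continue
                if b.start - a.end > max_span_bp:
                    continue
                if best is None or len(between) < len(best[2]):
                    best = (a, b, between)
    # genome-wide flanker presence (any contig, even unpaired)
    if not up_found:
        up_found = bool(_find_matches(feats, upstream, synonyms))
    if not down_found:
        down_found = bool(_find_matches(feats, downstream, synonyms))

    up_status = "found" if up_found else "missing"
    down_status = "found" if down_found else "missing"

    if not up_found or not down_found:
        call = "present" if target_anywhere else "assembly_gap"
        note = "flanker missing"
        interval: tuple[str, ...] = ()
    elif best is None:
        call = "present" if target_anywhere else (
            "inconclusive" if unordered else "assembly_gap"
        )
        note = "flankers unordered or overlapping" if unordered else \
            "flankers on different contigs"
        interval = ()
    else:
        a, b, between = best
        interval = tuple(f.symbol for f in between)
        in_interval = any(symbols_match(f.symbol, target, synonyms) for f in between)
        if in_interval:
            call, note = "present", ""
        elif target_anywhere:
            call, note = "present", "target outside flanked interval"
        else:
            call, note = "lost", ""
    return SyntenyCall(
        species=genome.species, target=target,
        upstream_flank_status=up_status, downstream_flank_status=down_status,
        interval_genes=interval, call=call, note=note,
    )


def call_locus(
    genomes: Iterable[GenomeAnnotation], locus: LocusConfig
) -> list[SyntenyCall]:
    """Run :func:`call_synteny` for one locus across many genomes."""
    return [
        call_synteny(
            g, locus.target, locus.upstream, locus.downstream,
            locus.max_span_genes, locus.max_span_bp, locus.synonyms,
        )
        for g in genomes
    ]


def locus_diagram(genome: GenomeAnnotation, contig: str, width: int = 78) -> str:
    """Plain-text gene-order diagram for one contig."""
    feats = genome.on_contig(contig)
    arrows = [
        f"{f.symbol}{'>' if f.strand == '+' else '<'}" for f in feats
    ]
    line = " - ".join(arrows)
    return f"{genome.species} {contig}: {line}"
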