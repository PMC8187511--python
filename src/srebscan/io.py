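"""File formats: FASTA, GFF3/BED-like gene orders, Ct CSV, result TSVs.

Gene FASTA headers follow ``species|gene_id|cluster_hint``; gene orders are
readable either from GFF3 (``gene`` features with a ``Name`` or ``ID``
attribute) or from a five-column TSV (symbol, contig, start, end, strand).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conserve import MSA
from .qpcr import CtRecord
from .screen import GeneRecord, ScreenResult
from .synteny import GeneFeature, GenomeAnnotation

__all__ = [
    "read_gene_fasta", "write_gene_fasta",
    "read_aligned_fasta", "write_aligned_fasta",
    "read_genome_tsv", "write_genome_tsv", "write_genome_gff3", "read_genome_gff3",
    "read_ct_csv", "write_ct_csv", "write_dilutions_csv", "read_dilutions_csv",
    "write_screen_tsv", "write_truth_manifest",
]


# ---------------------------------------------------------------------------
# FASTA

def write_gene_fasta(genes: Iterable[GeneRecord], path) -> None:
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=f"{g.species}|{g.gene_id}|{g.cluster_hint or '.'}",
            description="",
        )
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_fasta(path) -> list[GeneRecord]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3:
            species, gene_id, hint = parts
            hint = None if hint in (".", "") else hint
        else:
            species, gene_id, hint = "", rec.id, None
        genes.append(GeneRecord(
            gene_id=gene_id, species=species, sequence=str(rec.seq).upper(),
            cluster_hint=hint,
        ))
    return genes


def write_aligned_fasta(msa: MSA, path) -> None:
    records = [
        SeqRecord(Seq(row), id=gid, description=cluster or "")
        for gid, cluster, row in zip(msa.ids, msa.clusters, msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_aligned_fasta(path, clusters: Optional[dict] = None,
                       reference_id: Optional[str] = None) -> MSA:
    ids, labels, rows = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        desc = rec.description.split(None, 1)
        labels.append(
            (clusters or {}).get(rec.id) or (desc[1] if len(desc) > 1 else None)
        )
        rows.append(str(rec.seq).upper())
    return MSA(
        ids=tuple(ids), clusters=tuple(labels), rows=tuple(rows),
        reference_id=reference_id or ids[0],
    )


# ---------------------------------------------------------------------------
# gene orders

_GENOME_COLS = ["symbol", "contig", "start", "end", "strand"]


def write_genome_tsv(genome: GenomeAnnotation, path) -> None:
    df = pd.DataFrame(
        [(r.symbol, r.contig, r.start, r.end, r.strand) for r in genome.records],
        columns=_GENOME_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genome_tsv(path, species: Optional[str] = None) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t")
    records = tuple(
        GeneFeature(str(r.symbol), str(r.contig), int(r.start), int(r.end),
                    str(r.strand))
        for r in df.itertuples()
    )
    return GenomeAnnotation(species=species or Path(path).stem, records=records)


def write_genome_gff3(genome: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(genome.records, 1):
            fh.write(
                f"{r.contig}\tsrebscan\tgene\t{r.start}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID=gene{i};Name={r.symbol}\n"
            )


def read_genome_gff3(path, species: Optional[str] = None) -> GenomeAnnotation:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            symbol = attrs.get("Name") or attrs.get("ID") or "."
            records.append(GeneFeature(symbol, f[0], int(f[3]), int(f[4]), f[6]))
    return GenomeAnnotation(species=species or Path(path).stem,
                            records=tuple(records))


# ---------------------------------------------------------------------------
# qPCR tables

def write_ct_csv(rows, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group", "gene", "replicate", "ct", "input_rna_ug"])
        for r in rows:
            w.writerow([r.sample_id, r.group, r.gene, r.replicate,
                        f"{r.ct:.6f}", r.input_rna_ug])


def read_ct_csv(path) -> list[CtRecord]:
    """Read a Ct CSV, collapsing replicate rows into one record each."""
    df = pd.read_csv(path)
    records = []
    for (sample, group, gene), sub in df.groupby(
        ["sample_id", "group", "gene"], sort=False
    ):
        ug = sub["input_rna_ug"].iloc[0]
        records.append(CtRecord(
            sample_id=str(sample), group=str(group), gene=str(gene),
            cts=tuple(float(c) for c in sub["ct"]),
            input_rna_ug=None if pd.isna(ug) else float(ug),
        ))
    return records


def write_dilutions_csv(dilutions: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "quantity", "ct"])
        for gene, pts in dilutions.items():
            for q, ct in pts:
                w.writerow([gene, q, f"{ct:.6f}"])


def read_dilutions_csv(path) -> dict:
    df = pd.read_csv(path)
    return {
        str(g): [(float(r.quantity), float(r.ct)) for r in sub.itertuples()]
        for g, sub in df.groupby("gene", sort=False)
    }


# ---------------------------------------------------------------------------
# results

def write_screen_tsv(results: Sequence[ScreenResult], path) -> None:
    df = pd.DataFrame([
        {
            "gene_id": r.gene_id, "species": r.species,
            "aa_length": r.aa_length, "length_ok": r.length_ok,
            "tm_count": r.tm_count, "dataset1_pass": r.dataset1_pass,
            "dataset2_pass": r.dataset2_pass, "reason": r.reason,
            "cluster_hint": r.cluster_hint or ".",
        }
        for r in results
    ])
    df.to_csv(path, sep="\t", index=False)


def write_truth_manifest(truth, path) -> None:
    """Machine-readable planted-truth manifest (JSON)."""
    payload = {
        "specific_sites": {k: list(v) for k, v in truth.specific_sites.items()},
        "losses": [list(x) for x in truth.losses],
        "fold_changes": {
            f"{gene}:{group}": ratio
            for (gene, group), ratio in truth.fold_changes.items()
        },
        "motif_anchors": truth.motif_anchors,
        "motif_canonical": truth.motif_canonical,
        "reference_id": truth.reference_id,
        "tm_spans": [list(s) for s in truth.tm_spans],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
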