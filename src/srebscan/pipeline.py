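"""High-level orchestration: family FASTA in, family analysis out.

Chains the screening, clustering and conservation stages the way the full
survey is meant to be run: verify every candidate, build the analysis-grade
alignment, assign paralog clusters with bootstrap support, then profile
conservation, scan for target-cluster-specific sites and report motif
deviations — all in reference numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cluster import ClusterAssignment, bootstrap_clusters
from .conserve import (
    MSA,
    ClusterSpecificSite,
    ColumnProfile,
    MotifReport,
    align_or_import,
    find_cluster_specific_sites,
    mask_nterminal,
    profile_columns,
    scan_motifs,
)
from .screen import GeneRecord, ProteinRecord, ScreenResult, TMAnnotation, screen_genes

__all__ = ["FamilyAnalysis", "analyze_family"]

CLUSTER_NAMES = ("SREB1", "SREB2", "SREB3A", "SREB3B")


@dataclass
class FamilyAnalysis:
    screens: list[ScreenResult]
    proteins: dict[str, ProteinRecord]
    tms: dict[str, TMAnnotation]
    assignment: ClusterAssignment
    msa: MSA                       # analysis-grade, cluster-labelled, masked
    profiles: list[ColumnProfile]
    specific_sites: list[ClusterSpecificSite]
    motifs: list[MotifReport]

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.msa.clusters:
            if label is not None:
                sizes[label] = sizes.get(label, 0) + 1
        return sizes


def analyze_family(
    genes: Sequence[GeneRecord],
    reference_id: str,
    target_cluster: str = "SREB3B",
    motif_anchors: Optional[dict[str, int]] = None,
    motif_canonical: Optional[dict[str, str]] = None,
    outgroup: Optional[str] = None,
    n_boot: int = 100,
    seed: int = 0,
    max_divergent: int = 3,
) -> FamilyAnalysis:
    """Run screen -> cluster -> conserve on a candidate gene collection.

    Cluster hints are taken from each gene record; sequences failing the
    analysis-grade screen, and sequences whose hinted cluster lacks
    bootstrap support (including un-hinted outgroups), are excluded from the
    conservation alignment.
    """
    screens, proteins, tms = screen_genes(genes)
    hints = {g.gene_id: g.cluster_hint for g in genes}
    dataset2 = [s.gene_id for s in screens if s.dataset2_pass]
    full_msa = align_or_import(
        [(gid, proteins[gid].aa_sequence) for gid in dataset2],
        "import", {gid: hints.get(gid) for gid in dataset2}, reference_id,
    )
    assignment = bootstrap_clusters(
        full_msa, {gid: hints.get(gid) for gid in dataset2},
        n_boot=n_boot, seed=seed, outgroup=outgroup,
    )
    assigned = [
        gid for gid in dataset2 if assignment.labels[gid] != "UNASSIGNED"
    ]
    msa = align_or_import(
        [(gid, proteins[gid].aa_sequence) for gid in assigned],
        "import", {gid: assignment.labels[gid] for gid in assigned},
        reference_id,
    )
    msa = mask_nterminal(msa, tms)
    profiles = profile_columns(msa, max_divergent=max_divergent)
    background = [c for c in CLUSTER_NAMES if c != target_cluster
                  and c in set(msa.clusters)]
    sites = find_cluster_specific_sites(profiles, target_cluster, background)
    motifs = []
    if motif_anchors:
        motifs = scan_motifs(msa, motif_anchors, motif_canonical, profiles)
    return FamilyAnalysis(
        screens=screens, proteins=proteins, tms=tms, assignment=assignment,
        msa=msa, profiles=profiles, specific_sites=sites, motifs=motifs,
    )
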