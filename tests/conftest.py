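"""Shared fixtures: a scaled-down synthetic family exercising every stage."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from srebscan.conserve import align_or_import, mask_nterminal, profile_columns
from srebscan.screen import screen_genes
from srebscan.simulate import SimConfig, compact_config, simulate_family

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CLUSTERS = ("SREB1", "SREB2", "SREB3A", "SREB3B")


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """16 species, four clusters, planted sites/losses, one outgroup."""
    base = compact_config(seed)
    return dataclasses.replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def family():
    cfg = small_config(1)
    genes, truth = simulate_family(cfg)
    return cfg, genes, truth


@pytest.fixture(scope="session")
def screened(family):
    _, genes, truth = family
    results, proteins, tms = screen_genes(genes)
    return results, proteins, tms, truth


@pytest.fixture(scope="session")
def family_msa(screened):
    results, proteins, tms, truth = screened
    keep = [
        r.gene_id for r in results
        if r.dataset2_pass and truth.cluster_of[r.gene_id] in CLUSTERS
    ]
    clusters = {gid: truth.cluster_of[gid] for gid in keep}
    msa = align_or_import(
        [(gid, proteins[gid].aa_sequence) for gid in keep],
        "import", clusters, reference_id=truth.reference_id,
    )
    return mask_nterminal(msa, tms)


@pytest.fixture(scope="session")
def family_profiles(family_msa):
    return profile_columns(family_msa)
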