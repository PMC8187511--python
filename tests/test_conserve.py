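"""Conservation profiling, specific-site detection, motif scans, alignment."""

import random
from collections import Counter

import pytest
from Bio.Align import substitution_matrices

from srebscan.conserve import (
    MSA,
    align_or_import,
    find_cluster_specific_sites,
    mask_nterminal,
    min_conservation_pct,
    pairwise_align,
    profile_columns,
    scan_motifs,
)
from srebscan.screen import TMAnnotation

BL62 = substitution_matrices.load("BLOSUM62")
BACKGROUND = ["SREB1", "SREB2", "SREB3A"]


# ---------------------------------------------------------------------------
# independent oracles

def nw_affine_oracle(a: str, b: str, go: float = -10.0, ge: float = -1.0) -> float:
    """Plain three-state dynamic program, written independently of the
    package's profile aligner: first gap residue costs ``go``, later ones
    ``ge``; terminal gaps charged."""
    INF = float("-inf")
    n, m = len(a), len(b)
    M = [[INF] * (m + 1) for _ in range(n + 1)]
    X = [[INF] * (m + 1) for _ in range(n + 1)]
    Y = [[INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(BL62[a[i - 1]][b[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


def specific_sites_oracle(msa: MSA, target: str, background, max_div: int = 3):
    """Literal reading of the site rules: loop over columns, count residues
    per cluster with a Counter, apply conditions (a)-(c) verbatim."""
    found = []
    groups = {}
    for gid, cl, row in zip(msa.ids, msa.clusters, msa.rows):
        groups.setdefault(cl, []).append(row)
    for col in range(msa.n_cols):
        if col < msa.masked_before:
            continue
        ref = msa.col_to_ref(col)
        if ref is None:
            continue
        modal = {}
        ok = True
        for cl in [*background, target]:
            chars = [row[col] for row in groups[cl]]
            res = Counter(c for c in chars if c != "-")
            if not res:
                ok = False
                break
            top = max(res.values())
            m = min(r for r, c in res.items() if c == top)
            if len(chars) - res[m] > max_div:
                ok = False
                break
            modal[cl] = m
        if not ok:
            continue
        bg = {modal[c] for c in background}
        if len(bg) == 1 and modal[target] not in bg:
            found.append(ref)
    return found


def random_labelled_msa(rng: random.Random, n_rows: int, n_cols: int) -> MSA:
    alphabet = "ACDEFGHIKLMNPQRSTVWY-"
    labels = ["SREB1", "SREB2", "SREB3A", "SREB3B"]
    ids, clusters, rows = [], [], []
    for i in range(n_rows):
        ids.append(f"g{i}")
        clusters.append(labels[i % 4])
        rows.append("".join(rng.choice(alphabet) for _ in range(n_cols)))
    # reference must have at least one residue
    rows[0] = rows[0].replace("-", "A") or "A" * n_cols
    return MSA(tuple(ids), tuple(clusters), tuple(rows), "g0")


# ---------------------------------------------------------------------------
# alignment

class TestAlignOrImport:
    def test_import_passthrough(self):
        msa = align_or_import([("a", "MKT"), ("b", "MRT")], "import")
        assert msa.rows == ("MKT", "MRT")

    def test_ragged_import_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            align_or_import([("a", "MKT"), ("b", "MK")], "import")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            align_or_import([("a", "MKT"), ("a", "MRT")], "import")

    def test_identical_sequences_align_gap_free(self):
        seq = "MKTAYIAKQR"
        ra, rb, score = pairwise_align(seq, seq)
        assert ra == rb == seq
        assert score == pytest.approx(sum(float(BL62[c][c]) for c in seq))

    @pytest.mark.parametrize(
        "a,b",
        [
            ("HEAGAWGHEE", "PAWHEAE"),
            ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKTAYIAKQR"),
            ("GATTACA", "GCATGCG"),
            ("WWWWKKKK", "WWKK"),
        ],
    )
    def test_pairwise_score_matches_dp_oracle(self, a, b):
        _, _, score = pairwise_align(a, b)
        assert score == pytest.approx(nw_affine_oracle(a, b))

    def test_pairwise_alignment_is_consistent_with_score(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        ra, rb, score = pairwise_align(a, b)
        assert ra.replace("-", "") == a and rb.replace("-", "") == b
        # re-score the emitted alignment column by column
        total, in_gap_a, in_gap_b = 0.0, False, False
        for ca, cb in zip(ra, rb):
            if ca == "-":
                total += -1.0 if in_gap_a else -10.0
                in_gap_a, in_gap_b = True, False
            elif cb == "-":
                total += -1.0 if in_gap_b else -10.0
                in_gap_b, in_gap_a = True, False
            else:
                total += float(BL62[ca][cb])
                in_gap_a = in_gap_b = False
        assert total == pytest.approx(score)

    def test_progressive_on_family_recovers_equal_length(self):
        seqs = [("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR"), ("c", "MKTAYLAKQR")]
        msa = align_or_import(seqs, "progressive")
        assert msa.n_cols == 10
        assert all("-" not in r for r in msa.rows)


# ---------------------------------------------------------------------------
# masking and numbering

class TestMaskAndNumbering:
    def test_reference_numbering_skips_gaps(self):
        msa = MSA(("r", "x"), (None, None), ("M-KT", "MAKT"), "r")
        assert msa.ref_to_col(2) == 2  # K sits in column 3 (0-based 2)
        assert msa.col_to_ref(1) is None

    def test_tm1_at_position_one_masks_nothing(self):
        msa = MSA(("r", "x"), ("A", "A"), ("MKT", "MRT"), "r")
        out = mask_nterminal(msa, {"r": TMAnnotation(((1, 3),))})
        assert out.masked_before == 0

    def test_mask_tracks_detected_tm1_start(self, family_msa, screened):
        # the mask column equals the detected TM1 start - 1; the hydropathy
        # segment may begin a few residues before the planted helix (31)
        _, _, tms, truth = screened
        detected = tms[family_msa.reference_id].segments[0][0]
        assert family_msa.masked_before == detected - 1
        assert 31 - 6 <= detected <= 31

    def test_missing_reference_annotation_raises(self):
        msa = MSA(("r", "x"), ("A", "A"), ("MKT", "MRT"), "r")
        with pytest.raises(ValueError):
            mask_nterminal(msa, {})


# ---------------------------------------------------------------------------
# column profiles

class TestProfileColumns:
    def test_monomorphic_column(self):
        msa = MSA(
            ("a", "b", "c", "d"), ("C1",) * 4,
            ("A", "A", "A", "A"), "a",
        )
        p = profile_columns(msa)[0]
        assert p.modal["C1"] == "A"
        assert p.divergent["C1"] == 0
        assert p.conservation("C1") == 1.0

    def test_gap_counts_as_divergent(self):
        rows = tuple(["A"] * 40 + ["T"] * 2 + ["-"])
        msa = MSA(
            tuple(f"g{i}" for i in range(43)), ("C1",) * 43, rows, "g0",
        )
        p = profile_columns(msa)[0]
        assert p.modal["C1"] == "A"
        assert p.divergent["C1"] == 3
        assert p.conserved["C1"]

    def test_gap_policy_ignore(self):
        rows = tuple(["A"] * 40 + ["T"] * 2 + ["-"])
        msa = MSA(
            tuple(f"g{i}" for i in range(43)), ("C1",) * 43, rows, "g0",
        )
        p = profile_columns(msa, gap_policy="ignore")[0]
        assert p.divergent["C1"] == 2

    def test_modal_tie_alphabetical(self):
        msa = MSA(("a", "b"), ("C1", "C1"), ("T", "A"), "a")
        assert profile_columns(msa)[0].modal["C1"] == "A"

    def test_counts_conserve_cluster_size(self, family_profiles, family_msa):
        sizes = Counter(c for c in family_msa.clusters)
        for p in family_profiles[:50]:
            for cl, cnt in p.counts.items():
                assert sum(cnt.values()) == sizes[cl] == p.cluster_sizes[cl]

    def test_conservation_fraction_bounds(self, family_profiles):
        for p in family_profiles:
            for cl in p.cluster_sizes:
                assert 0.0 <= p.conservation(cl) <= 1.0


class TestMinConservationPct:
    @pytest.mark.parametrize(
        "n,expected",
        [(75, 96.0), (80, 96.3), (69, 95.7), (54, 94.4), (4, 25.0)],
    )
    def test_threshold_values(self, n, expected):
        assert min_conservation_pct(n) == expected

    def test_requires_n_above_max_divergent(self):
        with pytest.raises(ValueError):
            min_conservation_pct(3)

    def test_round_half_up(self):
        # 77/80 = 96.25 -> 96.3 under half-up (banker's rounding would say 96.2)
        assert min_conservation_pct(80) == 96.3


# ---------------------------------------------------------------------------
# cluster-specific sites

class TestSpecificSites:
    def test_planted_sites_recovered_exactly(self, family_profiles, family):
        _, _, truth = family
        sites = find_cluster_specific_sites(family_profiles, "SREB3B", BACKGROUND)
        assert tuple(s.ref_position for s in sites) == truth.specific_sites["SREB3B"]

    def test_no_planted_sites_empty(self):
        from srebscan.simulate import simulate_family
        from srebscan.screen import screen_genes
        from conftest import small_config
        import dataclasses

        cfg = small_config(3)
        clusters = tuple(
            dataclasses.replace(c, n_planted_specific_sites=0,
                                planted_positions=None)
            for c in cfg.clusters
        )
        cfg = dataclasses.replace(cfg, clusters=clusters)
        genes, truth = simulate_family(cfg)
        results, proteins, tms = screen_genes(genes)
        keep = [r.gene_id for r in results
                if r.dataset2_pass and truth.cluster_of[r.gene_id] != "sreb_like"]
        msa = align_or_import(
            [(g, proteins[g].aa_sequence) for g in keep], "import",
            {g: truth.cluster_of[g] for g in keep}, truth.reference_id,
        )
        msa = mask_nterminal(msa, tms)
        sites = find_cluster_specific_sites(
            profile_columns(msa), "SREB3B", BACKGROUND
        )
        assert sites == []

    def test_matches_brute_force_oracle_on_family(self, family_msa, family_profiles):
        got = [s.ref_position for s in
               find_cluster_specific_sites(family_profiles, "SREB3B", BACKGROUND)]
        assert got == specific_sites_oracle(family_msa, "SREB3B", BACKGROUND)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_alignments(self, seed):
        rng = random.Random(seed)
        msa = random_labelled_msa(rng, rng.randint(8, 50), rng.randint(20, 500))
        profiles = profile_columns(msa)
        got = [s.ref_position for s in
               find_cluster_specific_sites(profiles, "SREB3B", BACKGROUND)]
        assert got == specific_sites_oracle(msa, "SREB3B", BACKGROUND)

    def test_row_permutation_invariance(self, family_msa):
        rng = random.Random(11)
        idx = list(range(len(family_msa.ids)))
        rng.shuffle(idx)
        shuffled = MSA(
            tuple(family_msa.ids[i] for i in idx),
            tuple(family_msa.clusters[i] for i in idx),
            tuple(family_msa.rows[i] for i in idx),
            family_msa.reference_id, family_msa.masked_before,
        )
        a = find_cluster_specific_sites(profile_columns(family_msa),
                                        "SREB3B", BACKGROUND)
        b = find_cluster_specific_sites(profile_columns(shuffled),
                                        "SREB3B", BACKGROUND)
        assert a == b

    def test_target_in_background_rejected(self, family_profiles):
        with pytest.raises(ValueError):
            find_cluster_specific_sites(
                family_profiles, "SREB3B", ["SREB3B", "SREB1", "SREB2"]
            )

    def test_masked_nterminal_sites_never_reported(self, family_profiles):
        sites = find_cluster_specific_sites(family_profiles, "SREB3B", BACKGROUND)
        assert all(s.ref_position >= 31 for s in sites)  # TM1 starts at 31


# ---------------------------------------------------------------------------
# motif scan

class TestScanMotifs:
    def test_planted_deviation_flagged_pooled(self, family_msa, family):
        _, _, truth = family
        reports = {
            r.motif: r for r in scan_motifs(
                family_msa, truth.motif_anchors, truth.motif_canonical
            )
        }
        dry_d = reports["DRY"].positions[0]
        assert dry_d.deviation == "D->T"
        assert dry_d.pooled_conservation == 1.0

    def test_wildcards_never_flagged(self, family_msa, family):
        _, _, truth = family
        for rep in scan_motifs(family_msa, truth.motif_anchors,
                               truth.motif_canonical):
            for pos in rep.positions:
                if pos.canonical in "xX":
                    assert pos.deviation is None

    def test_per_cluster_modal_for_cwxp(self, family_msa, family):
        # C of CWxP kept in SREB1 but L elsewhere, at full conservation
        _, _, truth = family
        rep = {r.motif: r for r in scan_motifs(
            family_msa, truth.motif_anchors, truth.motif_canonical
        )}["CWxP"]
        c_pos = rep.positions[0]
        assert c_pos.modal["SREB1"] == "C"
        for cl in ("SREB2", "SREB3A", "SREB3B"):
            assert c_pos.modal[cl] == "L"
            assert c_pos.conservation[cl] == 1.0

    def test_subclade_restricted_scan(self, family_msa, family):
        # restricting the scan to SREB1 members shows C, not the pooled L
        _, _, truth = family
        sreb1_ids = [g for g, c in zip(family_msa.ids, family_msa.clusters)
                     if c == "SREB1"]
        rep = {r.motif: r for r in scan_motifs(
            family_msa, truth.motif_anchors, truth.motif_canonical,
            subset=sreb1_ids,
        )}["CWxP"]
        assert rep.positions[0].pooled_modal == "C"

    def test_anchor_outside_alignment_raises(self, family_msa):
        with pytest.raises(ValueError, match="outside"):
            scan_motifs(family_msa, {"DRY": 10_000}, {"DRY": "DRY"})
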