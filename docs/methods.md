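# Methods

This note documents the models, rules and numerical conventions implemented
in `srebscan`, the design choices made where several readings were possible,
and what the synthetic data generator does and does not emulate.

## Candidate verification (screen)

Genome-assembly candidates are verified in three steps.

**ORF extraction.** The longest ATG-initiated open reading frame ending at a
stop codon is taken over both strands and all three frames; ties go to the
earlier start coordinate on the input, then to the forward strand. ORFs
shorter than 50 codons are treated as "no ORF" — a screening failure, not an
exception, because assembly fragments routinely lack a full reading frame.
Multiple plausible start sites are thereby resolved by the longest-ORF
convention.

**TM detection.** Transmembrane helices are called with a deterministic
Kyte–Doolittle detector: mean hydropathy over a 19-residue window; maximal
runs of window centres above 1.6, expanded to the window edges, form
candidate segments; segments under 15 residues are dropped and segments
within 3 residues merged. The contract is the *count* (≥ 5 or = 7), not a
posterior probability, which is why a windowed hydropathy rule suffices in
place of an HMM. All four constants are keyword arguments. Detected segment
boundaries are approximate (± a few residues around a true helix edge);
nothing downstream depends on exact boundaries except the N-terminal mask,
which only ever errs by masking a few residues fewer.

**Filters.** `length_ok` accepts proteins within 15% of 370 aa with outward
integer rounding, i.e. 314–426 aa. Dataset 1 (presence/absence evidence)
requires `length_ok` and ≥ 5 TMs; dataset 2 (analysis grade) requires
exactly 7. Dataset 2 is a subset of dataset 1 by construction.

## Paralog clustering (cluster)

Distances are p-distances: mismatches over aligned non-gap pairs; a pair
with no comparable columns gets distance 1.0 with a warning. Trees are
neighbor joining (scikit-bio) with negative branch lengths clamped to zero;
on an additive metric NJ reproduces the generating topology exactly, which
the tests verify by quartet enumeration. Bootstrap support for a candidate
cluster is the fraction of column-resampled replicates in which its members
form a clade after rooting on a user-designated outgroup (midpoint without
one). A sequence keeps its hinted cluster when that cluster's support
reaches 0.7 (configurable); un-hinted sequences and members of unsupported
clusters are `UNASSIGNED`. The default of 100 replicates is a desk-scale
compromise; support in the synthetic regime saturates at 1.0 well below
that. An externally computed tree with support labels can be imported
instead (`clusters_from_tree`).

## Conservation profiling (conserve)

The alignment container fixes a reference sequence whose ungapped 1-based
positions define the coordinate system for all reports. Columns before the
reference's first TM helix are masked from statistics (N-terminal regions
are hypervariable and carry ambiguous start sites) but retained in the
matrix.

A column is **conserved** in a cluster when at most 3 members deviate from
the modal residue. Gaps count as deviations by default (`--gap-policy
divergent`; rationale: a deletion does not conserve the modal residue), with
an `ignore` alternative. Modal ties break alphabetically. The implied
per-cluster thresholds are `round_half_up(100·(n−3)/n, 1)` — half-up
rounding is part of the contract (77/80 → 96.3, not banker's 96.2).

A reference position is **cluster-specific** for a target when (a) every
background cluster is conserved and — in the default strict mode — all
three share one modal residue, (b) the target cluster is conserved, and
(c) the target modal differs. A relaxed mode (each background conserved,
any residues, all different from the target) is available behind a flag.
The implementation is checked against a literal brute-force oracle on
random alignments up to 50 × 500.

**Motifs.** DRY/CWxP/NPxxY anchors are supplied as reference positions
(canonical GPCR knowledge, not computed from structure). Each motif position
reports per-cluster modal residues and conservation fractions plus pooled
values; deviations from the canonical letter are flagged, never at `x`
wildcards. A `subset` argument restricts the scan to a clade for
lineage-restricted substitutions. Whether a deviation is quantified pooled
or per cluster is ambiguous in general, so both are always reported.

**Aligner.** Equal-length inputs (the synthetic regime, or any pre-aligned
FASTA) pass through `import` mode. `progressive` mode builds a UPGMA guide
tree on 3-mer distances and merges profiles with BLOSUM62 column means and
affine gaps: the first gap residue costs −10, each further −1, terminal
gaps charged, ties broken match > gap-in-second > gap-in-first. It is
adequate for a conserved single-length family; it is not a general-purpose
aligner (no iterative refinement, no terminal-gap discounting).

## Microsynteny (synteny)

Presence calls come from screening: `present` needs a dataset-1 hit,
`incomplete` means only failing hits (a fragment still witnesses the
locus), `absent` means none. Loss calls use configured upstream/downstream
flanker symbols per locus: the nearest valid flanker pair on one contig
(≤ 50 intervening genes and ≤ 2 Mb; both configurable — no window is
canonical) defines the interval. `lost` requires both flankers found, the
target absent from the interval *and absent genome-wide* (the rescue rule:
a gene found anywhere is never called lost). A missing flanker — or a
flanker pair found only on different contigs — yields `assembly_gap`;
overlapping/unordered flankers are `inconclusive`. Note the different-contig
case reports both flank statuses as `found` with an explanatory note; the
call expresses that the locus cannot be confirmed intact. Symbol matching is
exact after case-folding and `-like` stripping, plus one-sided stripping of
a trailing paralog letter when the stem ends in a digit (`suv39h1a` matches
query `suv39h1`, but `sreb3a` never matches `sreb3b`), plus a user synonym
table. Strand is recorded, not used.

## qPCR quantification (qpcr)

Standard curves are ordinary least squares of mean Ct on log10 relative
quantity over ≥ 4 distinct dilution points (replicates averaged before the
fit; 4–6 points expected, more warns). Efficiency is E = 10^(−1/slope) − 1;
QC passes in [0.90, 1.00] ± 0.02 ("approximately 90–100%"). Quantities are
interpolated as Q = 10^((Ct − b)/m) after averaging duplicate Cts.

Three normalization modes: `ref_gene` divides by the same sample's
reference-gene quantity (from the reference's own curve); `fixed_input`
uses the quantity directly and asserts equal RNA input; `per_ug_input`
divides by input RNA in µg. All modes then divide by the calibrator-group
mean, so the calibrator averages exactly 1.0. With every input at 2.5 µg,
`fixed_input` and `per_ug_input` quantities differ by the constant 2.5 and
produce identical calibrated values — the cross-validation property.

The reference-gene screen runs one-way ANOVA on natural-log quantities
across groups; p < 0.05 marks a candidate unstable, and the pipeline
refuses `ref_gene` mode with an unstable reference unless overridden.
Group tests use natural-log transformed values (the choice of log base does
not affect any test statistic used): Welch's t-test for two groups, one-way
ANOVA plus Tukey HSD at α = 0.05 otherwise, with a compact letter display
built from maximal cliques of the not-significantly-different graph (shared
letter ⇔ pairwise p ≥ 0.05). Noiseless data (zero within-group variance)
short-circuits: distinct means are reported significant, identical means
not, avoiding 0/0 statistics. Non-positive values are rejected before the
log; non-detects should be omitted upstream rather than imputed.

## Synthetic data (simulate)

The generator emulates the statistical structure the analyses assume, with
planted, exactly recoverable truth.

**Protein architecture.** Every simulated receptor follows a fixed layout:
Met + 29-residue hydrophilic N-pad, seven 21-residue hydrophobic helices
(residues from I/L/V/F/A/M) separated by 20-residue hydrophilic loops, and
a hydrophilic C-tail (375 aa total by default). The TM detector finds
exactly 7 helices by construction; `tm_count(k)` failures dissolve helices
into loop sequence (k < 7) or plant extra helices deep in the tail (k > 7,
far enough that hydropathy windows cannot bridge); `truncated_orf` cuts the
protein at ~40%.

**Evolution.** One family-ancestral sequence is drawn. Each cluster's root
copy differs at three kinds of planted, *immutable* positions:
cluster-diagnostic columns (a configurable fraction, default 0.30, of
mutable columns fixed to distinct residues per cluster — this is what
separates clusters by ≥ 3× between/within distance and provably prevents
accidental cluster-specific-site calls), target-specific sites (one residue
inside the target cluster, a different shared residue outside; hydrophobic
pairs inside helices, hydrophilic in loops), and motif strings. Everything
else mutable evolves i.i.d. per site down a balanced ultrametric species
tree (depth 1): substitution probability per unit depth is the cluster's
rate, replacements uniform over a hydrophilic alphabet. Substitutions are
confined to loop/pad/tail columns so helix architecture — and hence
screening — is invariant under evolution. Outgroup sreb-like sequences take
a fifth residue at every diagnostic column plus heavy loop divergence,
making them roughly equidistant from all clusters. Proteins are
reverse-translated with a fixed most-frequent-codon table plus a stop.

Default rates (per site per unit depth): SREB2 0.010 < SREB1 0.020 <
SREB3A 0.025 < SREB3B 0.030, encoding the family's observed conservation
ranking; at survey scale (80+ sequences per cluster) almost all columns are
conserved under the ≤ 3 rule, as in the real family. The monotonicity of
identity in the rate is a statistical property; at desk scale (16 species)
it is only testable for clearly separated rates, and the property tests use
0.005/0.02/0.06/0.15.

**Survey composition.** `default_config` (82 species) prunes clusters to
memberships 76/82/72/55 (SREB3B absent from the 27 earliest-branching
species; SREB3A lost in a 10-species live-bearer-like clade; SREB1 lost in
5 plus one assembly gap). `study_config` adds the seven TM-deviant
sequences (counts 5, 6, 8, 8, 8, 6, 5), three outgroups and a single DRY-D
deviant, so the analysis-grade clusters come out at 75/80/69/54 and the
pooled DRY-D conservation at 277/278 = 99.6%. `compact_config` (16 species)
keeps all event types for fast many-seed property checks.
`simulate_genomes` places each family gene between its locus flankers
(foxp3b/suv39h1; tspy + ppp1r3f/wdr13; invented symbols for the other two
loci) with filler genes; `gene_loss` removes only the family gene,
`assembly_gap` also removes the downstream flanker; half the species carry
an `a`-suffixed flanker name to exercise symbol normalisation.
`simulate_ct` draws Ct = b + m·log10(Q) + N(0, σ) with m = −1/log10(1+E),
encodes fold changes exactly in starting quantities, and emits triplicate
4–6-point dilution series; at σ = 0 every closed form is exact (E = 1 ⇒
slope −3.3219; 8-fold ⇒ ΔCt = 3).

All randomness flows from one seeded NumPy generator per entry point
(family/genomes share the config seed; Ct uses a derived stream), so equal
configs give byte-identical FASTA/TSV/CSV output. Stream order is: ancestral
draw, site planting, per-cluster evolution in config order, duplications,
outgroups.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: indels and alignment uncertainty (sequences
are colinear; `import` mode alignment is exact), rate heterogeneity beyond
the planted/mutable dichotomy, codon usage and nucleotide-level processes,
convergent or back substitutions at planted sites, annotation errors in
gene order, and qPCR artefacts (inhibition, non-detects, between-plate
effects). Results on real families depend on alignment quality and on how
sharply paralog clusters separate, neither of which this generator
stresses.

## Problem sizes used in the shipped checks

The test suite runs the survey-scale family (≈ 280 sequences × 375 aa)
once end-to-end and uses the 16-species configuration for many-seed
properties: 50 seeds for planted-site recovery (survey scale), 50 for
synteny classification, 50 for cluster recovery at 100 bootstrap
replicates, 20 random alignments against the brute-force oracle. The
acceptance script repeats these from scratch at the same sizes (survey
bootstrap at 50 replicates) in about a minute on one CPU.

## Known limitations

The progressive aligner is quadratic and intended for small imports;
real-world alignments should be imported from a dedicated aligner. The NJ
stand-in recovers cluster labels, not publication-grade phylogenies — no
model selection, no ML optimisation. Synteny works at symbol level and
inherits any annotation naming noise not covered by the synonym table.
Sub-cluster outliers (a cluster member divergent within its own clade) are
not flagged separately: they either keep support or drop the whole cluster
below threshold.
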