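"""Relative-expression quantification from qPCR Ct tables.

Quantification follows the relative-standard-curve method: each assay's
dilution series is fitted by ordinary least squares of mean Ct on log10
relative quantity, giving an amplification efficiency E = 10^(-1/slope) - 1
that must fall in the 90-100% window for the assay to pass QC.  Sample
quantities interpolated from the curve are then normalised in one of three
modes used for different tissue panels:

* ``ref_gene``    — divided by the quantity of a stable reference gene
  (e.g. 18S rRNA) measured in the same sample;
* ``fixed_input`` — used as-is, valid when every sample received the same
  quantity of input RNA;
* ``per_ug_input`` — divided by the sample's input RNA in micrograms, for
  panels where equal loading was impossible.

All modes finally divide by the calibrator-group mean so the calibrator
(e.g. spermiating testis) averages exactly 1.0.  Group comparisons are run
on natural-log-transformed values: Welch's t-test for two groups, one-way
ANOVA with Tukey's HSD and a compact letter display for more.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CtRecord",
    "StandardCurve",
    "RelExpression",
    "GroupStats",
    "fit_standard_curve",
    "quantity_from_ct",
    "quantify",
    "relative_expression",
    "reference_gene_screen",
    "group_tests",
    "compact_letter_display",
]


@dataclass(frozen=True)
class CtRecord:
    """Ct measurements for one sample x gene, replicates kept together."""

    sample_id: str
    group: str
    gene: str
    cts: tuple[float, ...]
    input_rna_ug: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.cts:
            raise ValueError("at least one Ct replicate required")
        if any(c <= 0 for c in self.cts):
            raise ValueError("Ct values must be positive")

    @property
    def ct(self) -> float:
        """Replicate-mean Ct (duplicates are averaged before quantification)."""
        return float(np.mean(self.cts))


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    #: (log10 relative quantity, mean Ct) per dilution point
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    qc_pass: bool
    qc_note: str = ""

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class RelExpression:
    sample_id: str
    group: str
    gene: str
    value: float
    mode: str
    calibrator: str


@dataclass(frozen=True)
class GroupStats:
    gene: str
    groups: tuple[str, ...]
    means: dict
    sems: dict
    test: str       # "t_test" or "anova"
    p_value: float
    tukey_letters: dict


# ---------------------------------------------------------------------------
# standard curves

def fit_standard_curve(
    dilutions: Sequence[tuple[float, float]],
    gene: str = "",
    efficiency_window: tuple[float, float] = (0.90, 1.00),
    efficiency_tolerance: float = 0.02,
) -> StandardCurve:
    """Fit Ct = intercept + slope * log10(quantity) to a dilution series.

    ``dilutions`` holds (relative quantity, Ct) pairs; replicate Cts at the
    same quantity are averaged before the fit.  Requires at least four
    distinct quantities.  QC passes when the efficiency falls inside
    ``efficiency_window`` widened by ``efficiency_tolerance`` on each side.
    """
    by_q: dict[float, list[float]] = {}
    for q, ct in dilutions:
        if q <= 0:
            raise ValueError("dilution quantities must be positive")
        by_q.setdefault(float(q), []).append(float(ct))
    if len(by_q) < 4:
        raise ValueError(f"standard curve needs >= 4 distinct points, got {len(by_q)}")
    notes = []
    if len(by_q) > 6:
        notes.append(f"{len(by_q)} points (expected 4-6)")
    qs = sorted(by_q, reverse=True)
    points = tuple((math.log10(q), float(np.mean(by_q[q]))) for q in qs)
    mean_cts = [ct for _, ct in points]
    if any(b <= a for a, b in zip(mean_cts, mean_cts[1:])):
        notes.append("non-monotone Ct vs dilution")
        warnings.warn(f"{gene or 'curve'}: non-monotone Ct vs dilution")
    x = np.array([lq for lq, _ in points])
    y = np.array(mean_cts)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    lo, hi = efficiency_window
    qc = (lo - efficiency_tolerance) <= eff <= (hi + efficiency_tolerance)
    if not qc:
        notes.append(f"efficiency {eff * 100:.1f}% outside QC window")
    return StandardCurve(
        gene=gene, points=points, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2),
        qc_pass=qc, qc_note="; ".join(notes),
    )


def quantity_from_ct(ct: float, curve: StandardCurve) -> float:
    """Relative quantity interpolated from the standard curve."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


# ---------------------------------------------------------------------------
# quantification

def quantify(
    ct: CtRecord,
    curve: StandardCurve,
    mode: str,
    ref: Optional[CtRecord] = None,
    ref_curve: Optional[StandardCurve] = None,
    calibrator_mean: float = 1.0,
    calibrator: str = "",
    fixed_input_ug: Optional[float] = None,
) -> RelExpression:
    """Normalise one sample's quantity under the chosen mode.

    ``calibrator_mean`` is the mean un-calibrated value of the calibrator
    group for this gene; dividing by it sets the calibrator to 1.0.
    """
    q = quantity_from_ct(ct.ct, curve)
    if mode == "ref_gene":
        if ref is None:
            raise ValueError("ref_gene mode requires a reference-gene record")
        rq = quantity_from_ct(ref.ct, ref_curve if ref_curve is not None else curve)
        value = q / rq
    elif mode == "fixed_input":
        if fixed_input_ug is not None and ct.input_rna_ug is not None \
                and not math.isclose(ct.input_rna_ug, fixed_input_ug):
            raise ValueError(
                f"{ct.sample_id}: input RNA {ct.input_rna_ug} ug differs from "
                f"the fixed input {fixed_input_ug} ug"
            )
        value = q
    elif mode == "per_ug_input":
        if ct.input_rna_ug is None:
            raise ValueError("per_ug_input mode requires input_rna_ug")
        value = q / ct.input_rna_ug
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return RelExpression(
        sample_id=ct.sample_id, group=ct.group, gene=ct.gene,
        value=value / calibrator_mean, mode=mode, calibrator=calibrator,
    )


def relative_expression(
    records: Iterable[CtRecord],
    curves: dict[str, StandardCurve],
    mode: str,
    calibrator_group: str,
    reference_gene: Optional[str] = None,
    allow_unstable_reference: bool = False,
    unstable: Optional[dict[str, float]] = None,
) -> list[RelExpression]:
    """Full quantification pipeline over a Ct table.

    Quantifies every non-reference gene, then rescales within each gene so
    the calibrator-group mean is exactly 1.0.  In ``ref_gene`` mode the
    reference gene must not appear unstable (see
    :func:`reference_gene_screen`) unless explicitly overridden.
    """
    records = list(records)
    if mode == "ref_gene":
        if reference_gene is None:
            raise ValueError("ref_gene mode requires reference_gene")
        if unstable and reference_gene in unstable and not allow_unstable_reference:
            raise ValueError(
                f"reference gene {reference_gene} is unstable across groups "
                f"(p = {unstable[reference_gene]:.3g}); refusing ref_gene mode"
            )
    refs = {
        (r.sample_id): r for r in records if r.gene == reference_gene
    } if reference_gene else {}

    raw: list[RelExpression] = []
    for r in records:
        if reference_gene is not None and r.gene == reference_gene:
            continue
        curve = curves[r.gene]
        ref = refs.get(r.sample_id) if mode == "ref_gene" else None
        if mode == "ref_gene" and ref is None:
            raise ValueError(f"missing reference gene for sample {r.sample_id}")
        raw.append(quantify(
            r, curve, mode, ref=ref,
            ref_curve=curves.get(reference_gene) if reference_gene else None,
            calibrator=calibrator_group,
        ))
    out: list[RelExpression] = []
    for gene in sorted({v.gene for v in raw}):
        vals = [v for v in raw if v.gene == gene]
        cal = [v.value for v in vals if v.group == calibrator_group]
        if not cal:
            raise ValueError(f"{gene}: no samples in calibrator group "
                             f"{calibrator_group!r}")
        mean = float(np.mean(cal))
        out.extend(
            RelExpression(v.sample_id, v.group, v.gene, v.value / mean,
                          mode, calibrator_group)
            for v in vals
        )
    return out


# ---------------------------------------------------------------------------
# reference-gene screen

def reference_gene_screen(
    records: Iterable[CtRecord],
    candidates: Sequence[str],
    curves: Optional[dict[str, StandardCurve]] = None,
    alpha: float = 0.05,
) -> dict[str, tuple[bool, float]]:
    """One-way ANOVA of each candidate reference gene across groups.

    Quantities (from the gene's standard curve, or assuming perfect doubling
    without one) are natural-log transformed; a candidate is unstable when
    group means differ at ``alpha``.  Returns gene -> (stable, p).
    """
    records = list(records)
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("reference screen needs >= 2 groups")
    report: dict[str, tuple[bool, float]] = {}
    for gene in candidates:
        per_group = []
        for g in groups:
            vals = []
            for r in records:
                if r.gene != gene or r.group != g:
                    continue
                q = (quantity_from_ct(r.ct, curves[gene])
                     if curves and gene in curves else 2.0 ** (-r.ct))
                vals.append(math.log(q))
            if vals:
                per_group.append(vals)
        if len(per_group) < 2:
            raise ValueError(f"{gene}: fewer than 2 groups with data")
        if all(np.allclose(v, per_group[0][0]) for v in per_group):
            report[gene] = (True, 1.0)
            continue
        _, p = stats.f_oneway(*per_group)
        report[gene] = (bool(p >= alpha), float(p))
    return report


# ---------------------------------------------------------------------------
# group statistics

def compact_letter_display(
    groups: Sequence[str], significant: set[frozenset]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    ``significant`` holds unordered pairs that differ.  Maximal cliques of
    the complement ("not different") graph each receive one letter; a
    group's display is the sorted letters of the cliques containing it.
    """
    groups = list(groups)
    ns_edge = {
        frozenset((a, b))
        for a, b in itertools.combinations(groups, 2)
        if frozenset((a, b)) not in significant
    }
    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(frozenset(p) in ns_edge
                   for p in itertools.combinations(combo, 2)):
                cliques.append(combo)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for li, clique in enumerate(cliques):
        for g in clique:
            out[g] += letters[li]
    return {g: "".join(sorted(s)) for g, s in out.items()}


def group_tests(values: Iterable[RelExpression], alpha: float = 0.05) -> GroupStats:
    """Compare relative expression across groups for one gene.

    Values are natural-log transformed; two groups use Welch's t-test, more
    use one-way ANOVA with Tukey's HSD at ``alpha`` and a compact letter
    display.  Means and standard errors are reported on the relative scale.
    """
    values = list(values)
    genes = {v.gene for v in values}
    if len(genes) != 1:
        raise ValueError(f"group_tests expects one gene, got {sorted(genes)}")
    gene = genes.pop()
    if any(v.value <= 0 for v in values):
        raise ValueError("relative expression must be positive before log transform")
    groups = sorted({v.group for v in values})
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: [v.value for v in values if v.group == g] for g in groups}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need >= 2 samples per group")
    logs = {g: np.log(v) for g, v in by_group.items()}
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    sems = {g: float(stats.sem(v)) for g, v in by_group.items()}

    # degenerate noiseless data: zero within-group variance makes any mean
    # difference certain and identical means indistinguishable
    if all(np.allclose(v, v.mean()) for v in logs.values()):
        group_means = {g: v.mean() for g, v in logs.items()}
        sig = {
            frozenset((a, b))
            for a, b in itertools.combinations(groups, 2)
            if not math.isclose(group_means[a], group_means[b], abs_tol=1e-12)
        }
        p = 0.0 if sig else 1.0
        return GroupStats(
            gene, tuple(groups), means, sems,
            "t_test" if len(groups) == 2 else "anova", p,
            compact_letter_display(groups, sig),
        )

    if len(groups) == 2:
        a, b = (logs[g] for g in groups)
        _, p = stats.ttest_ind(a, b, equal_var=False)
        sig = {frozenset(groups)} if p < alpha else set()
        letters = compact_letter_display(groups, sig)
        return GroupStats(gene, tuple(groups), means, sems, "t_test",
                          float(p), letters)

    samples = [logs[g] for g in groups]
    _, p = stats.f_oneway(*samples)
    flat = np.concatenate(samples)
    labels = np.concatenate([[g] * len(logs[g]) for g in groups])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    sig = set()
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if reject:
            sig.add(frozenset((g1, g2)))
    letters = compact_letter_display(groups, sig)
    return GroupStats(gene, tuple(groups), means, sems, "anova",
                      float(p), letters)
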