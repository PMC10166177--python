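"""Differential intron retention between two conditions.

Replicate junction counts are pooled per condition and each intron is
tested with a two-sided pooled two-proportion z-test on intronic
junction reads versus total junction reads at both splice sites
combined.  This is a deliberately simple count-based substitute for a
GLM with per-bin dispersion: replicate overdispersion is not modelled,
which makes the p-values anti-conservative when biological replicates
disagree.  The fold change is the ratio of pooled IRIs (condition B over
A).  Confidence tiers follow the fold-change/FDR convention used for IR
scatter comparisons: ``high`` = FC > 1.2 and BH-adjusted p < 0.1,
``low`` = FC > 1.2 and adjusted p >= 0.1, else ``none``.

Only events whose IRI exceeds a floor (default 0.1) are tested; the floor
is applied to the larger of the two condition IRIs by default
(``floor_mode='max'``), or to both (``'both'``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .junctions import JunctionCounts, compute_iri

Tier = Literal["high", "low", "none"]


@dataclass
class DifferentialIRRecord:
    intron_id: str
    iri_a: float
    iri_b: float
    fc: float
    p: float
    padj: float
    tier: Tier
    excluded: Optional[str] = None  # reason code when not tested


def pool_counts(replicates: Sequence[JunctionCounts]) -> JunctionCounts:
    """Sum junction counts over replicates of one condition."""
    if not replicates:
        raise ValueError("at least one replicate required")
    ids = {c.intron_id for c in replicates}
    if len(ids) > 1:
        raise ValueError(f"mixed introns in one pool: {sorted(ids)}")
    return JunctionCounts(
        intron_id=replicates[0].intron_id,
        ei5=sum(c.ei5 for c in replicates),
        ei3=sum(c.ei3 for c in replicates),
        ee=sum(c.ee for c in replicates),
        flanking_exons_covered=all(c.flanking_exons_covered for c in replicates),
        flanking_exon_reads=sum(c.flanking_exon_reads for c in replicates),
    )


def two_proportion_z(x1, n1, x2, n2):
    """Vectorized two-sided pooled-variance two-proportion z-test.

    Returns ``(z, p)``; degenerate strata (pooled proportion 0 or 1, or
    an empty margin) give z = 0, p = 1.
    """
    from scipy.stats import norm

    x1, n1, x2, n2 = (np.asarray(v, dtype=float) for v in (x1, n1, x2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (x2 / n2 - x1 / n1) / se
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2 * norm.sf(np.abs(z))
    return z, p


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_differential_ir(
    counts_a: Sequence[Sequence[JunctionCounts]],
    counts_b: Sequence[Sequence[JunctionCounts]],
    iri_floor: float = 0.1,
    fc_min: float = 1.2,
    alpha: float = 0.1,
    floor_mode: Literal["max", "both"] = "max",
) -> list[DifferentialIRRecord]:
    """Per-intron differential IR between conditions A and B.

    ``counts_a``/``counts_b`` are replicate lists (one inner sequence per
    replicate) matched by intron id.  Introns absent from either
    condition, or below the IRI floor, are returned untested with an
    ``excluded`` reason.
    """
    pooled_a = _pool_by_intron(counts_a)
    pooled_b = _pool_by_intron(counts_b)
    records: list[DifferentialIRRecord] = []
    testable: list[tuple[int, JunctionCounts, JunctionCounts, float, float]] = []
    for intron_id in list(pooled_a) + [k for k in pooled_b if k not in pooled_a]:
        if intron_id not in pooled_a or intron_id not in pooled_b:
            records.append(
                DifferentialIRRecord(intron_id, math.nan, math.nan, math.nan,
                                     math.nan, math.nan, "none", excluded="missing_condition")
            )
            continue
        ca, cb = pooled_a[intron_id], pooled_b[intron_id]
        iri_a, iri_b = compute_iri(ca).iri, compute_iri(cb).iri
        if math.isnan(iri_a) or math.isnan(iri_b):
            records.append(
                DifferentialIRRecord(intron_id, iri_a, iri_b, math.nan, math.nan,
                                     math.nan, "none", excluded="undefined_iri")
            )
            continue
        passes_floor = (
            max(iri_a, iri_b) > iri_floor
            if floor_mode == "max"
            else min(iri_a, iri_b) > iri_floor
        )
        if not passes_floor:
            records.append(
                DifferentialIRRecord(intron_id, iri_a, iri_b, _fold_change(iri_a, iri_b),
                                     math.nan, math.nan, "none", excluded="iri_floor")
            )
            continue
        records.append(
            DifferentialIRRecord(intron_id, iri_a, iri_b, _fold_change(iri_a, iri_b),
                                 math.nan, math.nan, "none")
        )
        testable.append((len(records) - 1, ca, cb, iri_a, iri_b))
    if testable:
        xa = np.array([c.ei5 + c.ei3 for _, c, _, _, _ in testable])
        na = np.array([c.ei5 + c.ei3 + 2 * c.ee for _, c, _, _, _ in testable])
        xb = np.array([c.ei5 + c.ei3 for _, _, c, _, _ in testable])
        nb = np.array([c.ei5 + c.ei3 + 2 * c.ee for _, _, c, _, _ in testable])
        _, p = two_proportion_z(xa, na, xb, nb)
        padj = bh_adjust(p)
        for (idx, _, _, _, _), pi, qi in zip(testable, p, padj):
            rec = records[idx]
            rec.p = float(pi)
            rec.padj = float(qi)
            rec.tier = _tier(rec.fc, rec.padj, fc_min, alpha)
    return records


def _fold_change(iri_a: float, iri_b: float) -> float:
    if iri_a == 0:
        return math.inf if iri_b > 0 else 1.0
    return iri_b / iri_a


def _tier(fc: float, padj: float, fc_min: float, alpha: float) -> Tier:
    if fc > fc_min:
        return "high" if padj < alpha else "low"
    return "none"


def _pool_by_intron(
    replicates: Sequence[Sequence[JunctionCounts]],
) -> dict[str, JunctionCounts]:
    if not replicates:
        raise ValueError("at least one replicate required")
    by_id: dict[str, list[JunctionCounts]] = {}
    for rep in replicates:
        for c in rep:
            by_id.setdefault(c.intron_id, []).append(c)
    return {k: pool_counts(v) for k, v in by_id.items()}


def zscore_rows(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-score (population sd) of an introns x samples matrix.

    Returns ``(z, constant)`` where constant rows (sd = 0) are mapped to
    all-zero and flagged.  Single-column input is rejected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must have >= 2 columns per row")
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (m - mean) / safe_sd
    z[constant, :] = 0.0
    return z, constant
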