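"""Consensus-tier characterisation and purity-retention curves.

Regions detected by many independent methods tend to be compositionally
extreme: dominant-motif class shifts toward homopolymers, Shannon entropy
drops and purity rises with the consensus level k.  This module quantifies
those trends (per-tier motif proportions and entropy/purity quartiles) and
computes, per method, the fraction of its regions retained at increasing
purity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .complexity_metrics import dominant_repeat_unit, purity, shannon_entropy
from .interval_consensus import ConsensusSegment
from .io_formats import Proteome, RegionSet, extract_subsequence, RegionRecord

__all__ = [
    "MotifAnnotation",
    "dominant_motif",
    "tier_summaries",
    "purity_retention",
]

CATEGORY_BY_LENGTH = {1: "Monopeptide", 2: "Dipeptide", 3: "Tripeptide"}


@dataclass(frozen=True)
class MotifAnnotation:
    """Dominant tandem motif of a region and its category."""

    motif: str
    category: str
    coverage: float


def primitive_unit(unit: str) -> str:
    """Smallest unit whose tandem repetition yields ``unit`` ("ABAB" -> "AB")."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return unit[:p]
    return unit


def dominant_motif(seq: str, threshold: float = 0.5) -> MotifAnnotation:
    """Classify a region by its dominant tandem motif.

    The best tandem unit of length <= 3 is reduced to its primitive form
    (so "AA" counts as the monopeptide "A"); if its tandem coverage reaches
    ``threshold`` the region is a Mono-/Di-/Tripeptide by unit length,
    otherwise Other with an empty motif.
    """
    unit, coverage = dominant_repeat_unit(seq, kmax=3)
    unit = primitive_unit(unit)
    if coverage >= threshold:
        return MotifAnnotation(unit, CATEGORY_BY_LENGTH[len(unit)], coverage)
    return MotifAnnotation("", "Other", coverage)


def tier_summaries(
    segments: Sequence[ConsensusSegment],
    proteome: Proteome,
    n_methods: int | None = None,
    motif_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-consensus-level summary table.

    One row per k in 1..n_methods (default: the largest k observed), with the
    segment count, motif-category proportions, and quartiles of Shannon
    entropy and purity.  Tiers with no segments are reported with zero count
    and NaN statistics, not dropped.  Outlying segments are retained.
    """
    if n_methods is None:
        n_methods = max((s.k for s in segments), default=1)
    by_k: dict[int, list[ConsensusSegment]] = {k: [] for k in range(1, n_methods + 1)}
    for s in segments:
        by_k.setdefault(s.k, []).append(s)
    rows = []
    for k in range(1, n_methods + 1):
        segs = by_k.get(k, [])
        cats = {"Monopeptide": 0, "Dipeptide": 0, "Tripeptide": 0, "Other": 0}
        entropies, purities = [], []
        for s in segs:
            seq = extract_subsequence(
                proteome[s.protein_id], RegionRecord(s.protein_id, s.start, s.end)
            )
            cats[dominant_motif(seq, motif_threshold).category] += 1
            entropies.append(shannon_entropy(seq))
            purities.append(purity(seq))
        n = len(segs)
        row: dict[str, float] = {"k": k, "n_segments": n}
        for cat, c in cats.items():
            row[f"prop_{cat.lower()}"] = c / n if n else np.nan
        for name, vals in (("entropy", entropies), ("purity", purities)):
            q = np.percentile(vals, [25, 50, 75]) if vals else [np.nan] * 3
            row[f"{name}_q1"], row[f"{name}_median"], row[f"{name}_q3"] = q
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def purity_retention(
    region_sets: Sequence[RegionSet],
    proteome: Proteome,
    thresholds: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Fraction of each method's regions with purity >= threshold.

    Rows are purity thresholds in percent (default 0..100 step 5), columns
    methods.  retained(0) = 1 for any non-empty set and every column is
    non-increasing.  A method with no regions is an error.
    """
    ts = np.asarray(list(thresholds) if thresholds is not None else range(0, 101, 5), dtype=float)
    data = {}
    for rs in region_sets:
        if len(rs) == 0:
            raise ValueError(f"method {rs.method!r} has no regions")
        purities = np.array(
            [100.0 * purity(extract_subsequence(proteome[r.protein_id], r)) for r in rs]
        )
        data[rs.method] = [(purities >= t).mean() for t in ts]
    return pd.DataFrame(data, index=pd.Index(ts, name="purity_pct"))
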