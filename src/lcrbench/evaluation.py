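"""Residue-level confusion-matrix evaluation against the reference annotation.

Each residue of each protein gets a binary reference label (inside/outside a
reference LCR) and a binary prediction label per method; pooling residues
gives TP/FP/FN/TN counts, hence TPR = TP/(TP+FN) and FPR = FP/(FP+TN).  These
rates measure agreement with the operational reference definition, not
biological truth.  Four protein-level stratifications mirror the benchmark's
comparison axes: gene length deciles, reference-LCR count per protein,
reference coverage percentage, and the LCR-to-gene entropy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .complexity_metrics import shannon_entropy
from .interval_consensus import merge_intervals
from .io_formats import Proteome, ProteinRecord, RegionSet, validate_regions

__all__ = [
    "ConfusionCounts",
    "residue_confusion",
    "tpr",
    "fpr",
    "stratify_gene_length",
    "entropy_ratio",
    "entropy_ratio_bin",
    "evaluate_stratified",
    "STRATIFIERS",
]

STRATIFIERS = ("gene_length_decile", "lcr_count", "coverage_bin", "entropy_ratio_bin")


@dataclass(frozen=True)
class ConfusionCounts:
    """Residue-level confusion counts; tp+fp+fn+tn = residues evaluated."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _coverage_mask(protein: ProteinRecord, recs) -> np.ndarray:
    mask = np.zeros(protein.length, dtype=bool)
    for r in recs:
        mask[r.start - 1 : r.end] = True
    return mask


def residue_confusion(
    reference: RegionSet, predicted: RegionSet, proteome: Proteome
) -> ConfusionCounts:
    """Pooled residue-level confusion counts over the whole proteome.

    TP: residue in both reference and prediction; FN: reference only;
    FP: prediction only; TN: neither.  Predictions (or references) on
    proteins absent from the proteome are an error.
    """
    validate_regions(reference, proteome)
    validate_regions(predicted, proteome)
    ref_by = merge_intervals(reference).by_protein()
    pred_by = merge_intervals(predicted).by_protein()
    tp = fp = fn = tn = 0
    for pid, prot in proteome.items():
        ref_mask = _coverage_mask(prot, ref_by.get(pid, []))
        pred_mask = _coverage_mask(prot, pred_by.get(pid, []))
        tp += int(np.sum(ref_mask & pred_mask))
        fp += int(np.sum(~ref_mask & pred_mask))
        fn += int(np.sum(ref_mask & ~pred_mask))
        tn += int(np.sum(~ref_mask & ~pred_mask))
    return ConfusionCounts(tp, fp, fn, tn)


def tpr(c: ConfusionCounts) -> float | None:
    """True-positive rate TP/(TP+FN); None when undefined (no positives)."""
    d = c.tp + c.fn
    return c.tp / d if d else None


def fpr(c: ConfusionCounts) -> float | None:
    """False-positive rate FP/(FP+TN); None when undefined (no negatives)."""
    d = c.fp + c.tn
    return c.fp / d if d else None


def stratify_gene_length(proteome: Proteome, n_bins: int = 10) -> dict[str, int]:
    """Assign each protein a length-decile bin 1..n_bins.

    Proteins are stably sorted by (length, id) ascending and split into
    contiguous groups whose sizes differ by at most one, with the larger
    groups first.
    """
    ids = sorted(proteome, key=lambda pid: (proteome[pid].length, pid))
    n = len(ids)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} proteins, got {n}")
    q, r = divmod(n, n_bins)
    sizes = [q + 1] * r + [q] * (n_bins - r)
    out: dict[str, int] = {}
    i = 0
    for b, size in enumerate(sizes, start=1):
        for pid in ids[i : i + size]:
            out[pid] = b
        i += size
    return out


def entropy_ratio(protein: ProteinRecord, reference_regions: RegionSet) -> float | None:
    """Entropy of concatenated reference-LCR residues over whole-protein entropy.

    None when the whole-protein entropy is zero (ratio undefined) or the
    protein has no reference region.
    """
    recs = [r for r in reference_regions if r.protein_id == protein.id]
    if not recs:
        return None
    whole = shannon_entropy(protein.sequence)
    if whole == 0.0:
        return None
    lcr_seq = "".join(protein.sequence[r.start - 1 : r.end] for r in recs)
    return shannon_entropy(lcr_seq) / whole


def entropy_ratio_bin(ratio: float) -> float:
    """Right-closed ordered bins 0.2, 0.4, 0.6, 0.8, 1.0 (ratios > 1 clamp to 1.0)."""
    for edge in (0.2, 0.4, 0.6, 0.8):
        if ratio <= edge:
            return edge
    return 1.0


def _coverage_stratum(pct: float) -> str:
    for edge, label in ((5, "5"), (10, "10"), (15, "15"), (20, "20")):
        if pct <= edge:
            return label
    return ">20"


def _strata_map(
    stratifier: str, reference: RegionSet, proteome: Proteome
) -> dict[str, object]:
    """Protein -> stratum label; proteins with no defined stratum are omitted."""
    if stratifier == "gene_length_decile":
        return dict(stratify_gene_length(proteome))
    ref_by = merge_intervals(reference).by_protein()
    raw_by = reference.by_protein()
    out: dict[str, object] = {}
    if stratifier == "lcr_count":
        # counts 1..6, >=6 pooled into 6; proteins without reference LCRs excluded
        for pid, recs in raw_by.items():
            out[pid] = min(len(recs), 6)
    elif stratifier == "coverage_bin":
        for pid, recs in ref_by.items():
            pct = 100.0 * sum(r.length for r in recs) / proteome[pid].length
            out[pid] = _coverage_stratum(pct)
    elif stratifier == "entropy_ratio_bin":
        for pid in ref_by:
            ratio = entropy_ratio(proteome[pid], reference)
            if ratio is not None:
                out[pid] = entropy_ratio_bin(ratio)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")
    return out


def _restrict(regions: RegionSet, proteins: Mapping[str, object]) -> RegionSet:
    """Keep only regions on the given proteins."""
    return RegionSet(
        [r for r in regions if r.protein_id in proteins], method=regions.method
    )


def evaluate_stratified(
    reference: RegionSet,
    predictions: Mapping[str, RegionSet],
    proteome: Proteome,
    stratifier: str = "gene_length_decile",
    per_protein: bool = False,
) -> pd.DataFrame:
    """Per-stratum TPR/FPR per method, plus unweighted means across strata.

    By default residues are pooled within each stratum before computing rates;
    ``per_protein=True`` instead averages per-protein rates within the
    stratum.  Returns a long-format DataFrame with columns (stratum, method,
    tpr, fpr); the mean rows carry stratum label "mean".  Strata where a rate
    is undefined report NaN; means skip NaN strata.
    """
    strata = _strata_map(stratifier, reference, proteome)
    labels = sorted(set(strata.values()), key=lambda v: (isinstance(v, str), v))
    rows = []
    for method, pred in predictions.items():
        per_stratum_tpr, per_stratum_fpr = [], []
        for label in labels:
            sub = {pid: proteome[pid] for pid, s in strata.items() if s == label}
            ref_sub = _restrict(reference, sub)
            pred_sub = _restrict(pred, sub)
            if per_protein:
                t_vals, f_vals = [], []
                for pid, prot in sub.items():
                    c = residue_confusion(
                        _restrict(reference, {pid: None}), _restrict(pred, {pid: None}), {pid: prot}
                    )
                    t, f = tpr(c), fpr(c)
                    if t is not None:
                        t_vals.append(t)
                    if f is not None:
                        f_vals.append(f)
                t = float(np.mean(t_vals)) if t_vals else None
                f = float(np.mean(f_vals)) if f_vals else None
            else:
                c = residue_confusion(ref_sub, pred_sub, sub)
                t, f = tpr(c), fpr(c)
            per_stratum_tpr.append(t)
            per_stratum_fpr.append(f)
            rows.append(
                {"stratum": label, "method": method,
                 "tpr": np.nan if t is None else t,
                 "fpr": np.nan if f is None else f}
            )
        rows.append(
            {
                "stratum": "mean",
                "method": method,
                "tpr": float(np.mean([v for v in per_stratum_tpr if v is not None]))
                if any(v is not None for v in per_stratum_tpr) else np.nan,
                "fpr": float(np.mean([v for v in per_stratum_fpr if v is not None]))
                if any(v is not None for v in per_stratum_fpr) else np.nan,
            }
        )
    return pd.DataFrame(rows)
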