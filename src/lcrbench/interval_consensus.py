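"""Residue-level interval algebra: merge, multi-method consensus, Jaccard.

This is the framework's replacement for genome-arithmetic toolkits on protein
coordinates: interval union, a multi-way intersection that partitions covered
residues into maximal runs of constant method-membership (each with its
consensus level k), residue-level Jaccard similarity, and the fixed binned
summaries used to compare detection methods (region length, per-protein
coverage, per-protein region count, pooled amino-acid composition).

Bin-boundary ownership: interval labels like "0-10, 10-20" are left-open /
right-closed, (0,10], (10,20], ...; count labels "1-5, 5-10" own their upper
edge, [1,5], [6,10], [11,15], [16,inf).  This makes the printed labels a
partition; it changes which bin edge values fall in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import Proteome, RegionRecord, RegionSet, extract_subsequence

__all__ = [
    "ConsensusSegment",
    "LENGTH_BINS",
    "COVERAGE_BINS",
    "COUNT_LABELS",
    "merge_intervals",
    "multi_intersect",
    "jaccard",
    "jaccard_matrix",
    "summarize_lengths",
    "summarize_coverage",
    "summarize_counts",
    "aa_composition",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Region-length bins in residues, left-open right-closed, last open-ended.
LENGTH_BINS = ((0, 10), (10, 20), (20, 50), (50, 100), (100, 200), (200, None))
LENGTH_LABELS = ("0-10", "10-20", "20-50", "50-100", "100-200", ">200")

#: Per-protein LCR coverage bins in percent.
COVERAGE_BINS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))
COVERAGE_LABELS = ("0-20", "20-40", "40-60", "60-80", "80-100")

#: Per-protein region-count bins.
COUNT_LABELS = ("0", "1-5", "5-10", "10-15", "15+")


@dataclass(frozen=True)
class ConsensusSegment:
    """A maximal run of residues covered by a constant set of methods."""

    protein_id: str
    start: int
    end: int
    k: int
    methods: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_intervals(regions: RegionSet) -> RegionSet:
    """Union of intervals: overlapping or bookended (end+1 = next start)
    records on the same protein are merged.  Residue coverage is preserved
    exactly."""
    merged: list[RegionRecord] = []
    for pid, recs in regions.by_protein().items():
        cur_start, cur_end = recs[0].start, recs[0].end
        for r in recs[1:]:
            if r.start <= cur_end + 1:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(RegionRecord(pid, cur_start, cur_end, regions.method))
                cur_start, cur_end = r.start, r.end
        merged.append(RegionRecord(pid, cur_start, cur_end, regions.method))
    return RegionSet(merged, method=regions.method)


def multi_intersect(region_sets: Sequence[RegionSet]) -> list[ConsensusSegment]:
    """Partition covered residues into consensus segments.

    For each protein, residues covered by at least one method are split into
    maximal runs over which the set of covering methods is constant; each run
    becomes one segment with consensus level k = number of covering methods.
    Analogous to a multi-way interval intersection report.
    """
    if not region_sets:
        raise ValueError("need at least one region set")
    methods = [rs.method for rs in region_sets]
    if len(set(methods)) != len(methods):
        raise ValueError(f"method labels must be distinct, got {methods}")
    merged = [merge_intervals(rs) for rs in region_sets]
    by_protein: dict[str, list[tuple[int, RegionRecord]]] = {}
    for mi, rs in enumerate(merged):
        for pid, recs in rs.by_protein().items():
            by_protein.setdefault(pid, []).extend((mi, r) for r in recs)

    segments: list[ConsensusSegment] = []
    for pid in sorted(by_protein):
        entries = by_protein[pid]
        max_end = max(r.end for _, r in entries)
        # membership[i, m]: residue i+1 covered by method m
        membership = np.zeros((max_end, len(methods)), dtype=bool)
        for mi, r in entries:
            membership[r.start - 1 : r.end, mi] = True
        covered = membership.any(axis=1)
        # boundaries where the membership row changes
        change = np.ones(max_end, dtype=bool)
        change[1:] = (membership[1:] != membership[:-1]).any(axis=1)
        starts = np.flatnonzero(change)
        ends = np.append(starts[1:], max_end)
        for s, e in zip(starts, ends):
            if not covered[s]:
                continue
            row = membership[s]
            segments.append(
                ConsensusSegment(
                    protein_id=pid,
                    start=int(s) + 1,
                    end=int(e),
                    k=int(row.sum()),
                    methods=tuple(m for m, on in zip(methods, row) if on),
                )
            )
    return segments


def _intersection_length(a: list[RegionRecord], b: list[RegionRecord]) -> int:
    """Total overlap between two sorted merged interval lists (two-pointer sweep)."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo <= hi:
            total += hi - lo + 1
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return total


def jaccard(a: RegionSet, b: RegionSet) -> float:
    """Residue-level Jaccard similarity |A & B| / |A | B| across all proteins.

    Defined as 0 when both sets are empty.
    """
    am, bm = merge_intervals(a), merge_intervals(b)
    a_by, b_by = am.by_protein(), bm.by_protein()
    inter = sum(
        _intersection_length(a_by[pid], b_by[pid]) for pid in a_by.keys() & b_by.keys()
    )
    union = am.total_length() + bm.total_length() - inter
    return inter / union if union else 0.0


def jaccard_matrix(region_sets: Sequence[RegionSet]) -> pd.DataFrame:
    """Symmetric methods x methods Jaccard matrix (diagonal 1.0 for non-empty sets)."""
    methods = [rs.method for rs in region_sets]
    n = len(region_sets)
    mat = np.ones((n, n))
    for i in range(n):
        mat[i, i] = 1.0 if len(region_sets[i]) else 0.0
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(region_sets[i], region_sets[j])
    return pd.DataFrame(mat, index=methods, columns=methods)


def _bin_value(v: float, bins) -> int:
    """Index of the left-open right-closed bin containing v (0 goes to bin 0)."""
    for idx, (lo, hi) in enumerate(bins):
        if hi is None or v <= hi:
            if v > lo or (idx == 0 and v >= 0):
                return idx
    raise ValueError(f"value {v} outside bins {bins}")


def summarize_lengths(regions: RegionSet) -> pd.Series:
    """Histogram of region lengths over the fixed length bins."""
    counts = np.zeros(len(LENGTH_BINS), dtype=int)
    for r in regions:
        counts[_bin_value(r.length, LENGTH_BINS)] += 1
    return pd.Series(counts, index=list(LENGTH_LABELS), name="n_regions")


def summarize_coverage(regions: RegionSet, proteome: Proteome) -> pd.Series:
    """Histogram of per-protein LCR coverage percentages.

    Coverage = 100 * merged covered residues / protein length, computed for
    every protein in the proteome (uncovered proteins count in the 0-20 bin).
    """
    merged_by = merge_intervals(regions).by_protein()
    counts = np.zeros(len(COVERAGE_BINS), dtype=int)
    for pid, prot in proteome.items():
        covered = sum(r.length for r in merged_by.get(pid, []))
        pct = 100.0 * covered / prot.length
        counts[_bin_value(pct, COVERAGE_BINS)] += 1
    return pd.Series(counts, index=list(COVERAGE_LABELS), name="n_proteins")


def summarize_counts(regions: RegionSet, proteome: Proteome) -> pd.Series:
    """Histogram of raw (unmerged) region counts per protein."""
    per_protein = {pid: len(recs) for pid, recs in regions.by_protein().items()}
    counts = np.zeros(len(COUNT_LABELS), dtype=int)
    for pid in proteome:
        c = per_protein.get(pid, 0)
        if c == 0:
            counts[0] += 1
        elif c <= 5:
            counts[1] += 1
        elif c <= 10:
            counts[2] += 1
        elif c <= 15:
            counts[3] += 1
        else:
            counts[4] += 1
    return pd.Series(counts, index=list(COUNT_LABELS), name="n_proteins")


def aa_composition(regions: RegionSet, proteome: Proteome) -> pd.Series:
    """Pooled amino-acid composition of all region residues.

    Counts over the 20 standard amino acids, normalised to the total residue
    count; sums to 1 for sequences free of ambiguity codes.
    """
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for r in regions:
        seq = extract_subsequence(proteome[r.protein_id], r)
        total += len(seq)
        for c in seq:
            if c in counts:
                counts[c] += 1
    if total == 0:
        raise ValueError("no residues to normalise: region set is empty")
    return pd.Series(
        {aa: counts[aa] / total for aa in AMINO_ACIDS}, name="fraction"
    )
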