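"""Operational reference LCR annotation by sliding-window scanning.

Every protein is scanned with overlapping windows (default 20 residues,
step 10).  Each window is profiled in the two-axis complexity space and kept
when it satisfies the operational low-complexity rule

    mutation % < 50   and   most-frequent-amino-acid % > 50

(strict inequalities).  Kept windows are merged into maximal regions; the
result is the reference annotation that predictions are benchmarked against.
The reference is an operational definition grounded in compositional
constraints, not experimentally validated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .complexity_metrics import profile_segment
from .interval_consensus import merge_intervals
from .io_formats import ProteinRecord, RegionRecord, RegionSet

__all__ = [
    "WindowScheme",
    "ReferenceThresholds",
    "sliding_windows",
    "annotate_protein",
    "annotate_proteome",
]


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window geometry: window length and step, in residues."""

    window: int = 20
    step: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window):
            raise ValueError(
                f"require 1 <= step <= window, got step={self.step}, window={self.window}"
            )


@dataclass(frozen=True)
class ReferenceThresholds:
    """Strict thresholds of the operational LCR rule, in percent."""

    max_mutation_pct: float = 50.0
    min_dominance_pct: float = 50.0

    def __post_init__(self) -> None:
        for v in (self.max_mutation_pct, self.min_dominance_pct):
            if not (0.0 < v < 100.0):
                raise ValueError(f"thresholds must lie in (0, 100), got {v}")


def sliding_windows(length: int, scheme: WindowScheme = WindowScheme()) -> list[tuple[int, int]]:
    """1-based inclusive window coordinates covering a protein of given length.

    Windows start at 1, 1+step, 1+2*step, ... while they fit; if the final
    residue would be uncovered, one right-anchored full-length window is
    appended.  Proteins shorter than the window get a single whole-protein
    window.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length < scheme.window:
        return [(1, length)]
    windows = []
    start = 1
    while start + scheme.window - 1 <= length:
        windows.append((start, start + scheme.window - 1))
        start += scheme.step
    if windows[-1][1] < length:
        windows.append((length - scheme.window + 1, length))
    return windows


def annotate_protein(
    protein: ProteinRecord,
    scheme: WindowScheme = WindowScheme(),
    thresholds: ReferenceThresholds = ReferenceThresholds(),
    x_metric: str = "minperiod",
    method: str = "reference",
) -> RegionSet:
    """Reference LCR regions of one protein.

    Each window is profiled; windows passing the strict thresholds are merged
    (union of overlapping/adjacent intervals) into maximal regions.
    """
    kept = []
    for start, end in sliding_windows(protein.length, scheme):
        prof = profile_segment(protein.sequence[start - 1 : end], x_metric=x_metric)
        if (
            prof.mutation_pct < thresholds.max_mutation_pct
            and prof.dominance_pct > thresholds.min_dominance_pct
        ):
            kept.append(RegionRecord(protein.id, start, end, method))
    return merge_intervals(RegionSet(kept, method=method))


def annotate_proteome(
    proteome: Iterable[ProteinRecord],
    scheme: WindowScheme = WindowScheme(),
    thresholds: ReferenceThresholds = ReferenceThresholds(),
    x_metric: str = "minperiod",
    method: str = "reference",
) -> RegionSet:
    """Map :func:`annotate_protein` over a proteome; deterministic ordering."""
    records: list[RegionRecord] = []
    for protein in proteome:
        records.extend(
            annotate_protein(protein, scheme, thresholds, x_metric, method).records
        )
    return RegionSet(records, method=method)
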