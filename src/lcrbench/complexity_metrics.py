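"""Per-segment complexity descriptors for the LC diagram.

A sequence segment is placed in a two-axis complexity space:

* **y — compositional dominance**: the percentage of the segment accounted for
  by its most frequent amino acid.
* **x — mutational distance to a perfect repeat**: the minimal percentage of
  residues that must change so the segment becomes an exact periodic repeat.

Because the period-1 repeat (a homorepeat of the dominant residue) is always
admitted, x <= 100 - y: every segment lives inside the "complexity triangle".
Homorepeats sit at the top-left corner, perfect tandem repeats along the left
edge, and compositionally diverse (globular-like) sequence at the lower right.
Segments are classified by the operational 50%/50% thresholds into LCR
(low-complexity), LTR (long tandem repeat) and HCR (high-complexity) zones.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

__all__ = [
    "ComplexityProfile",
    "shannon_entropy",
    "dominance",
    "purity",
    "mutation_to_homorepeat",
    "min_mutation_over_periods",
    "dominant_repeat_unit",
    "classify_point",
    "profile_segment",
    "MAX_ENTROPY_BITS",
]

#: Entropy ceiling for the standard 20-letter amino-acid alphabet (bits).
MAX_ENTROPY_BITS = math.log2(20)

X_METRICS = ("minperiod", "homorepeat")


@dataclass(frozen=True)
class ComplexityProfile:
    """All complexity descriptors of one sequence segment."""

    mutation_pct: float
    dominance_pct: float
    dominant_residue: str
    entropy_bits: float
    purity: float
    best_period: int
    homorepeat_mutation_pct: float
    segment_class: str


def _require_nonempty(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")


def shannon_entropy(seq: str) -> float:
    """Shannon entropy of the residue composition, in bits.

    0 for a homorepeat; log2(20) ~= 4.32 for uniform usage of all 20 amino
    acids.  Frequencies are taken from the segment itself, no pseudocounts.
    """
    _require_nonempty(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in Counter(seq).values()) + 0.0


def dominance(seq: str) -> tuple[str, float]:
    """Most frequent residue and its percentage; ties broken lexicographically."""
    _require_nonempty(seq)
    counts = Counter(seq)
    best = max(counts, key=lambda a: (counts[a], _neg_lex(a)))
    return best, 100.0 * counts[best] / len(seq)


def _neg_lex(symbol: str) -> tuple[int, ...]:
    # max() helper: prefer lexicographically smaller symbols on count ties
    return tuple(-ord(c) for c in symbol)


def purity(seq: str) -> float:
    """Fraction of residues equal to the primary amino acid (= dominance/100)."""
    return dominance(seq)[1] / 100.0


def mutation_to_homorepeat(seq: str) -> float:
    """Percentage of residues differing from the dominant residue.

    The mutational distance to the period-1 perfect repeat; equals
    100 - dominance percentage exactly.
    """
    _require_nonempty(seq)
    return 100.0 - dominance(seq)[1]


def min_mutation_over_periods(
    seq: str, max_period: int | None = None
) -> tuple[float, int]:
    """Minimal mutation percentage to reach a perfect repeat of any period.

    For each candidate period p, positions are partitioned into phase classes
    by (position - 1) mod p; the consensus of each class is its most frequent
    symbol (ties lexicographic) and mismatches are residues differing from
    their phase consensus.  A partial terminal repeat unit is allowed.  The
    default search space is p = 1..floor(L/2), so every admitted period yields
    at least two (possibly partial) copies.

    Returns (percentage, smallest period achieving it).  A single residue is
    already a perfect repeat: (0.0, 1).
    """
    _require_nonempty(seq)
    n = len(seq)
    if n < 2:
        return 0.0, 1
    limit = n // 2
    if max_period is None:
        max_period = limit
    if not (1 <= max_period <= limit):
        raise ValueError(f"max_period must be in 1..{limit}, got {max_period}")
    best_mm = n + 1
    best_p = 1
    for p in range(1, max_period + 1):
        mismatches = 0
        for phase in range(p):
            cls = seq[phase::p]
            mismatches += len(cls) - Counter(cls).most_common(1)[0][1]
        if mismatches < best_mm:
            best_mm, best_p = mismatches, p
    return 100.0 * best_mm / n, best_p


def dominant_repeat_unit(seq: str, kmax: int = 3) -> tuple[str, float]:
    """Best exact tandem-repeat unit of length <= kmax and its coverage.

    Scans all units of length 1..kmax; the winner is the unit whose maximal
    run of exact tandem copies (at least two consecutive copies — a lone
    k-mer is not a tandem) covers the largest fraction of the sequence.
    Ties go to the shorter unit, then the lexicographically smaller one.
    If no unit repeats anywhere, falls back to the dominant residue with the
    coverage of its longest (length-1) run.
    """
    _require_nonempty(seq)
    if kmax < 1:
        raise ValueError(f"kmax must be >= 1, got {kmax}")
    n = len(seq)
    best_unit, best_run = "", 0
    for k in range(1, min(kmax, n) + 1):
        i = 0
        while i + k <= n:
            unit = seq[i : i + k]
            j = i + k
            while j + k <= n and seq[j : j + k] == unit:
                j += k
            run = j - i
            if run >= 2 * k:  # require >= 2 tandem copies
                if run > best_run or (
                    run == best_run
                    and (len(unit), unit) < (len(best_unit), best_unit)
                ):
                    best_unit, best_run = unit, run
            i += 1
    if not best_unit:
        return dominance(seq)[0], 1 / n
    return best_unit, best_run / n


def classify_point(mutation_pct: float, dominance_pct: float) -> str:
    """Triangle-segment class under the operational 50%/50% thresholds.

    LCR if x < 50 and y > 50; LTR if x < 50 and y < 50; HCR if x > 50 and
    y < 50; UNDEFINED for exact-50 boundaries (and the unreachable upper-right
    corner).
    """
    if not (0.0 <= mutation_pct <= 100.0 and 0.0 <= dominance_pct <= 100.0):
        raise ValueError(
            f"coordinates out of range: ({mutation_pct}, {dominance_pct})"
        )
    x, y = mutation_pct, dominance_pct
    if x < 50 and y > 50:
        return "LCR"
    if x < 50 and y < 50:
        return "LTR"
    if x > 50 and y < 50:
        return "HCR"
    return "UNDEFINED"


def profile_segment(seq: str, x_metric: str = "minperiod") -> ComplexityProfile:
    """Compute the full complexity profile of a segment.

    ``x_metric`` selects the diagram's x-axis: ``"minperiod"`` (default) uses
    the minimum mutational distance over all periods, ``"homorepeat"`` the
    distance to the period-1 homorepeat only.
    """
    if x_metric not in X_METRICS:
        raise ValueError(f"unknown x_metric {x_metric!r}; expected one of {X_METRICS}")
    _require_nonempty(seq)
    residue, dom_pct = dominance(seq)
    homo_pct = 100.0 - dom_pct
    min_pct, best_p = min_mutation_over_periods(seq)
    if x_metric == "homorepeat":
        mutation_pct, period = homo_pct, 1
    else:
        mutation_pct, period = min_pct, best_p
    return ComplexityProfile(
        mutation_pct=mutation_pct,
        dominance_pct=dom_pct,
        dominant_residue=residue,
        entropy_bits=shannon_entropy(seq),
        purity=dom_pct / 100.0,
        best_period=period,
        homorepeat_mutation_pct=homo_pct,
        segment_class=classify_point(mutation_pct, dom_pct),
    )
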