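"""FASTA and BED-like region I/O with explicit coordinate dialects.

All coordinates inside the package are 1-based inclusive ("native1"), the
convention of the BED-like TSV files the framework standardises tool outputs
into.  The standard 0-based half-open BED convention ("bed0") is supported at
the I/O boundary only, for interoperability with interval toolkits such as
bedtools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "RegionRecord",
    "RegionSet",
    "Proteome",
    "as_proteome",
    "validate_regions",
    "read_fasta",
    "read_regions",
    "write_regions",
    "extract_subsequence",
]

DIALECTS = ("native1", "bed0")


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    The id is the first whitespace-delimited token of the FASTA header and
    must be unique within a proteome.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id {self.id!r} is empty or contains whitespace")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class RegionRecord:
    """A 1-based inclusive interval on a protein, tagged with its source method."""

    protein_id: str
    start: int
    end: int
    method: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.protein_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class RegionSet:
    """An ordered, deduplicated collection of regions sharing a method label.

    Records are kept sorted by (protein_id, start, end).  Overlapping records
    are allowed — merging is an explicit operation (see
    :func:`lcrbench.interval_consensus.merge_intervals`).
    """

    def __init__(self, records: Iterable[RegionRecord] = (), method: str = ""):
        recs = sorted(set(records))
        if method:
            recs = [
                RegionRecord(r.protein_id, r.start, r.end, method) for r in recs
            ]
        self.records: list[RegionRecord] = recs
        self.method = method or (recs[0].method if recs else "")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RegionRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return [(r.protein_id, r.start, r.end) for r in self.records] == [
            (r.protein_id, r.start, r.end) for r in other.records
        ]

    def __repr__(self) -> str:
        return f"RegionSet(method={self.method!r}, n={len(self.records)})"

    def by_protein(self) -> dict[str, list[RegionRecord]]:
        out: dict[str, list[RegionRecord]] = {}
        for r in self.records:
            out.setdefault(r.protein_id, []).append(r)
        return out

    def total_length(self) -> int:
        return sum(r.length for r in self.records)


Proteome = dict[str, ProteinRecord]


def as_proteome(proteins: Iterable[ProteinRecord]) -> Proteome:
    """Index proteins by id, preserving order."""
    return {p.id: p for p in proteins}


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record protein FASTA file.

    Sequences are uppercased; input order is preserved.  Raises ``ValueError``
    on an empty file, duplicate ids, or non-letter sequence characters, naming
    the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        if not seq:
            raise ValueError(f"protein {rec.id!r} in {path} has an empty sequence")
        bad = sorted({c for c in seq if not c.isalpha()})
        if bad:
            raise ValueError(
                f"protein {rec.id!r} in {path} contains non-letter characters {bad}"
            )
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _to_native1(start_s: str, end_s: str, dialect: str, lineno: int, path) -> tuple[int, int]:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates {start_s!r}, {end_s!r}") from exc
    if dialect == "bed0":
        start, end = start + 1, end
    if not (1 <= start <= end):
        raise ValueError(
            f"{path}:{lineno}: invalid interval {start}-{end} after conversion to 1-based inclusive"
        )
    return start, end


def read_regions(
    path: str | os.PathLike,
    dialect: str = "native1",
    method: str | None = None,
) -> RegionSet:
    """Read a BED-like TSV of regions (protein_id, start, end[, method]).

    ``dialect="native1"`` is 1-based inclusive; ``dialect="bed0"`` is standard
    0-based half-open BED.  Method label precedence: explicit ``method``
    argument > 4th column > filename stem.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    records: list[RegionRecord] = []
    col4: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            start, end = _to_native1(fields[1], fields[2], dialect, lineno, path)
            label = fields[3] if len(fields) > 3 and fields[3] else ""
            if label:
                col4.add(label)
            records.append(RegionRecord(fields[0], start, end, label))
    if method is None:
        if len(col4) == 1:
            method = col4.pop()
        else:
            method = Path(path).stem
    return RegionSet(records, method=method)


def write_regions(
    regions: RegionSet, path: str | os.PathLike, dialect: str = "native1"
) -> None:
    """Write regions as BED-like TSV; round-trips with :func:`read_regions`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for r in regions:
            if dialect == "bed0":
                start, end = r.start - 1, r.end
            else:
                start, end = r.start, r.end
            method = r.method or regions.method
            if method:
                fh.write(f"{r.protein_id}\t{start}\t{end}\t{method}\n")
            else:
                fh.write(f"{r.protein_id}\t{start}\t{end}\n")


def extract_subsequence(protein: ProteinRecord, region: RegionRecord) -> str:
    """Return the region's amino-acid subsequence (1-based inclusive slice)."""
    if region.protein_id != protein.id:
        raise ValueError(
            f"region protein id {region.protein_id!r} does not match protein {protein.id!r}"
        )
    if region.end > protein.length:
        raise ValueError(
            f"region {region.protein_id}:{region.start}-{region.end} exceeds "
            f"protein length {protein.length}"
        )
    return protein.sequence[region.start - 1 : region.end]


def validate_regions(regions: RegionSet, proteome: Proteome) -> None:
    """Check every region resolves against the proteome; raise on the first failure."""
    for r in regions:
        if r.protein_id not in proteome:
            raise KeyError(f"region references unknown protein {r.protein_id!r}")
        if r.end > proteome[r.protein_id].length:
            raise ValueError(
                f"region {r.protein_id}:{r.start}-{r.end} exceeds protein length "
                f"{proteome[r.protein_id].length}"
            )
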