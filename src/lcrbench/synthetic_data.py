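"""Synthetic proteomes with planted low-complexity structure.

Generates test proteomes in which homorepeats and (optionally degenerate)
tandem repeats are planted at known coordinates inside random background
sequence, plus pseudo-method predictions with controlled sensitivity,
false-discovery rate and boundary jitter.  Every analytic module can thereby
be closed against planted parameters without any external data.

All randomness flows from one integer seed through independently spawned
child streams, so adding one feature never perturbs unrelated draws and
outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ProteinRecord, RegionRecord, RegionSet

__all__ = [
    "PlantedFeature",
    "SyntheticSpec",
    "GroundTruth",
    "PredictorSpec",
    "generate_proteome",
    "simulate_predictions",
    "make_tiered_consensus_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Rough human-like background amino-acid frequencies (order of AMINO_ACIDS).
#: A realism preset only; the default background is uniform.
HUMAN_LIKE_FREQS = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
     2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.4, 6.0, 1.2, 2.7]
) / 100.0


@dataclass(frozen=True)
class PlantedFeature:
    """One kind of repeat to plant: ``kind`` is "homorepeat" or "tandem".

    For homorepeats ``unit`` is a single residue and ``copies`` the run
    length; for tandems the planted segment is ``copies`` exact copies of
    ``unit`` before substitution noise.  Each residue is independently
    replaced by a uniformly random different residue with probability
    ``substitution_rate``.  ``n_instances`` segments are planted in total.
    """

    kind: str
    unit: str
    copies: int
    substitution_rate: float = 0.0
    n_instances: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("homorepeat", "tandem"):
            raise ValueError(f"kind must be 'homorepeat' or 'tandem', got {self.kind!r}")
        if self.kind == "homorepeat" and len(self.unit) != 1:
            raise ValueError("homorepeat unit must be a single residue")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.copies < 1 or self.n_instances < 1:
            raise ValueError("copies and n_instances must be >= 1")

    @property
    def length(self) -> int:
        return self.copies * len(self.unit)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for a synthetic proteome."""

    n_proteins: int = 50
    min_length: int = 100
    max_length: int = 400
    features: tuple[PlantedFeature, ...] = ()
    background_freqs: tuple[float, ...] | None = None  # None = uniform over 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or not (1 <= self.min_length <= self.max_length):
            raise ValueError("invalid proteome dimensions")


@dataclass
class GroundTruth:
    """Planted regions with per-region metadata."""

    regions: RegionSet
    meta: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class PredictorSpec:
    """A simulated detection method.

    ``sensitivity``: probability each true region is emitted;
    ``fdr_rate``: expected fraction of emitted regions that are background
    decoys; ``boundary_jitter``: maximal uniform shift of emitted endpoints.
    """

    name: str = "pseudo"
    sensitivity: float = 1.0
    fdr_rate: float = 0.0
    boundary_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.fdr_rate < 1.0):
            raise ValueError("sensitivity in [0,1] and fdr_rate in [0,1) required")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


def _random_background(rng: np.random.Generator, length: int, freqs) -> np.ndarray:
    if freqs is None:
        return rng.integers(0, 20, size=length)
    cum = np.cumsum(np.asarray(freqs) / np.sum(freqs))
    return np.searchsorted(cum, rng.random(length), side="right").clip(0, 19)


def _feature_residues(feature: PlantedFeature, rng: np.random.Generator) -> np.ndarray:
    unit_idx = np.array([AMINO_ACIDS.index(c) for c in feature.unit])
    seg = np.tile(unit_idx, feature.copies)
    if feature.substitution_rate > 0:
        hit = rng.random(len(seg)) < feature.substitution_rate
        # replace by a uniformly random *different* residue
        offsets = rng.integers(1, 20, size=len(seg))
        seg = np.where(hit, (seg + offsets) % 20, seg)
    return seg


def generate_proteome(spec: SyntheticSpec) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate a proteome and the ground-truth coordinates of planted repeats.

    Planted segments are placed at uniformly random non-overlapping positions
    across randomly chosen proteins (bounded retries; an error if a feature
    cannot be placed).  Deterministic for a given spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    bg_rng, place_rng, feat_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    lengths = [
        int(bg_rng.integers(spec.min_length, spec.max_length + 1))
        for _ in range(spec.n_proteins)
    ]
    seqs = [_random_background(bg_rng, L, spec.background_freqs) for L in lengths]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_proteins)]
    truth_records: list[RegionRecord] = []
    meta: list[dict] = []

    for feature in spec.features:
        for _ in range(feature.n_instances):
            placed = False
            for _try in range(1000):
                pi = int(place_rng.integers(0, spec.n_proteins))
                L = lengths[pi]
                if feature.length > L:
                    continue
                start0 = int(place_rng.integers(0, L - feature.length + 1))
                end0 = start0 + feature.length  # half-open, 0-based
                if any(not (end0 <= s or start0 >= e) for s, e in occupied[pi]):
                    continue
                seqs[pi][start0:end0] = _feature_residues(feature, feat_rng)
                occupied[pi].append((start0, end0))
                truth_records.append(
                    RegionRecord(f"prot{pi + 1}", start0 + 1, end0, "truth")
                )
                meta.append(
                    {
                        "protein_id": f"prot{pi + 1}",
                        "start": start0 + 1,
                        "end": end0,
                        "kind": feature.kind,
                        "unit": feature.unit,
                        "substitution_rate": feature.substitution_rate,
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place feature {feature} without overlap after 1000 tries"
                )

    proteins = [
        ProteinRecord(f"prot{i + 1}", "".join(AMINO_ACIDS[j] for j in seq))
        for i, seq in enumerate(seqs)
    ]
    return proteins, GroundTruth(RegionSet(truth_records, method="truth"), meta)


def simulate_predictions(
    truth: GroundTruth,
    predictor: PredictorSpec,
    proteome: Sequence[ProteinRecord],
) -> RegionSet:
    """Emit a pseudo-method's predictions from the ground truth.

    Each true region is emitted with probability ``sensitivity``; emitted
    endpoints are shifted by independent uniform jitter in
    [-boundary_jitter, +boundary_jitter], clamped to the protein.  Decoy
    regions (lengths resampled from the truth lengths) are placed uniformly
    in background, avoiding the truth, at the rate implied by ``fdr_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(predictor.seed))
    by_id = {p.id: p for p in proteome}
    truth_by = truth.regions.by_protein()
    records: list[RegionRecord] = []
    emitted = 0
    for r in truth.regions:
        if rng.random() >= predictor.sensitivity:
            continue
        emitted += 1
        L = by_id[r.protein_id].length
        j = predictor.boundary_jitter
        start = r.start + int(rng.integers(-j, j + 1)) if j else r.start
        end = r.end + int(rng.integers(-j, j + 1)) if j else r.end
        start = max(1, min(start, L))
        end = max(start, min(end, L))
        records.append(RegionRecord(r.protein_id, start, end, predictor.name))

    if predictor.fdr_rate > 0 and emitted:
        n_decoys = int(round(emitted * predictor.fdr_rate / (1 - predictor.fdr_rate)))
        lengths = [r.length for r in truth.regions] or [10]
        for _ in range(n_decoys):
            placed = False
            for _try in range(1000):
                prot = proteome[int(rng.integers(0, len(proteome)))]
                dlen = int(lengths[int(rng.integers(0, len(lengths)))])
                if dlen > prot.length:
                    continue
                start = int(rng.integers(1, prot.length - dlen + 2))
                end = start + dlen - 1
                overlaps = any(
                    not (end < t.start or start > t.end)
                    for t in truth_by.get(prot.id, [])
                )
                if overlaps:
                    continue
                records.append(RegionRecord(prot.id, start, end, predictor.name))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place decoy region after 1000 tries")
    return RegionSet(records, method=predictor.name)


def make_tiered_consensus_fixture(
    k_max: int,
    n_regions_per_tier: int = 10,
    region_length: int = 30,
    flank: int = 30,
    purities: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[RegionSet]]:
    """Proteome plus k_max pseudo-method region sets with planted tier structure.

    Tier t hosts regions covered by methods 1..t, so after multi-way
    intersection they surface at consensus level k = t.  Planted purity
    increases with the tier (default: evenly spaced from 0.5 to 0.95), giving
    consensus-tier analyses a known monotone signal.  Each region sits on its
    own protein between random background flanks.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if purities is None:
        purities = np.linspace(0.5, 0.95, k_max)
    if len(purities) != k_max:
        raise ValueError("need one planted purity per tier")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    proteins: list[ProteinRecord] = []
    per_method: list[list[RegionRecord]] = [[] for _ in range(k_max)]
    pidx = 0
    for tier, p in enumerate(purities, start=1):
        for _ in range(n_regions_per_tier):
            pidx += 1
            pid = f"tierprot{pidx}"
            dominant = int(rng.integers(0, 20))
            core = np.full(region_length, dominant)
            miss = rng.random(region_length) >= p
            core[miss] = (dominant + rng.integers(1, 20, size=region_length))[miss] % 20
            left = _random_background(rng, flank, None)
            right = _random_background(rng, flank, None)
            seq = np.concatenate([left, core, right])
            proteins.append(
                ProteinRecord(pid, "".join(AMINO_ACIDS[j] for j in seq))
            )
            region = (pid, flank + 1, flank + region_length)
            for m in range(tier):
                per_method[m].append(RegionRecord(*region, f"method{m + 1}"))
    sets = [
        RegionSet(recs, method=f"method{m + 1}") for m, recs in enumerate(per_method)
    ]
    return proteins, sets
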