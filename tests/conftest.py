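import numpy as np
import pytest

from lcrbench.io_formats import ProteinRecord, RegionRecord, RegionSet, as_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def small_proteome():
    """Three hand-written proteins: one homorepeat, one diverse, one mixed."""
    proteins = [
        ProteinRecord("homo", "E" * 40),
        ProteinRecord("diverse", AA * 2),
        ProteinRecord("mixed", "E" * 20 + AA),
    ]
    return as_proteome(proteins)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_region_sets(rng, n_sets=2, n_proteins=3, max_regions=8, max_coord=60):
    """Random interval collections for oracle tests."""
    sets = []
    for m in range(n_sets):
        records = []
        for p in range(n_proteins):
            for _ in range(rng.integers(0, max_regions + 1)):
                start = int(rng.integers(1, max_coord))
                end = int(rng.integers(start, min(start + 20, max_coord) + 1))
                records.append(RegionRecord(f"p{p}", start, end))
        sets.append(RegionSet(records, method=f"m{m}"))
    return sets


def residue_set(region_set):
    """Explicit residue-set oracle representation of a RegionSet."""
    out = set()
    for r in region_set:
        for i in range(r.start, r.end + 1):
            out.add((r.protein_id, i))
    return out
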