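import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from xenocds.model import TaxonomyMap, Thresholds


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def taxonomy() -> TaxonomyMap:
    """Three species per group, ids like EUBACTERIA:1."""
    pairs = []
    for group in ("eubacteria", "archaea", "fungi", "viridiplantae",
                  "protists", "arthropoda", "other_metazoa"):
        for i in range(1, 4):
            pairs.append((f"{group}:{i}", group))
    return TaxonomyMap.from_pairs(pairs)


def make_hit(query="q1", species="arthropoda:1", identity=80.0, aln_len=200,
             evalue=1e-50, bitscore=300.0, subject=None):
    from xenocds.io_formats import HitRecord
    return HitRecord(query_id=query, subject_id=subject or f"{species}|p0",
                     subject_species=species, identity_pct=identity,
                     aln_len=aln_len, evalue=evalue, bitscore=bitscore)


@pytest.fixture(scope="session")
def hit_factory():
    return make_hit
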