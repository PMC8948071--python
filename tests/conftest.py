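"""Shared fixtures: small aligned datasets and random additive trees."""

from __future__ import annotations

import numpy as np
import pytest

from barcode_associate.records import Dataset, SpecimenRecord
from barcode_associate.tree import PhyloTree

# Codons with no stops under the invertebrate mitochondrial code (table 5).
_SAFE_CODONS = [
    "GCT", "GCC", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT",
    "AAA", "TTA", "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT",
    "GTT", "TGA", "TAT",  # TGA is Trp in table 5, not a stop
]


def coding_fragment(n_codons: int, seed: int = 0) -> str:
    """An in-frame, stop-free coding fragment under the invertebrate
    mitochondrial code."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons))


def make_record(sid: str, seq: str, species: str = "X", stage: str = "male",
                region: str = "east") -> SpecimenRecord:
    return SpecimenRecord(
        specimen_id=sid, species_label=species, life_stage=stage,
        region=region, sequence=seq,
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    base = coding_fragment(120, seed=11)
    return Dataset(
        [
            make_record("a1", base, species="A"),
            make_record("a2", base[:-3] + "GCT", species="A", stage="larva"),
            make_record("b1", base[:180] + coding_fragment(60, seed=12), species="B"),
        ]
    )


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_len: float = 0.05, max_len: float = 1.0
) -> PhyloTree:
    """Random unrooted binary tree with branch lengths well above zero,
    so the four-point condition strictly separates topologies."""
    t = PhyloTree()
    names = [f"t{i:02d}" for i in range(n_taxa)]
    nodes = [t.add_node(nm) for nm in names]
    # start from a 3-star, then attach remaining leaves to random edges
    center = t.add_node()
    for nd in nodes[:3]:
        t.add_edge(center, nd, float(rng.uniform(min_len, max_len)))
    for nd in nodes[3:]:
        a, b, ln = t.edges()[rng.integers(0, len(t.edges()))]
        split = float(rng.uniform(0.2, 0.8)) * ln
        mid = t.add_node()
        t.remove_edge(a, b)
        t.add_edge(a, mid, split)
        t.add_edge(mid, b, ln - split)
        t.add_edge(mid, nd, float(rng.uniform(min_len, max_len)))
    return t
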