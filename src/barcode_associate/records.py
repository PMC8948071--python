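"""Specimen records and aligned datasets.

A :class:`SpecimenRecord` is one sequenced individual: a specimen identifier,
a species label (or the ``UNKNOWN`` sentinel for unidentified larvae and
females), life stage, biogeographic region, and its aligned mtCOI sequence.
A :class:`Dataset` is a rectangular alignment of such records plus a tier tag
(pooled / east / west) used by the two-tier association workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

#: Sentinel species label for specimens awaiting association.
UNKNOWN = "UNKNOWN"

LIFE_STAGES = frozenset({"male", "female", "larva", "pupa", "adult_unsexed"})
REGIONS = frozenset({"east", "west", "unassigned"})
TIERS = frozenset({"pooled", "east", "west"})

# Nucleotide codes used throughout: A=0, C=1, G=2, T=3, everything else
# (gaps, N, IUPAC ambiguity codes) = 4 and is treated as missing, matching
# pairwise deletion of missing sites.
MISSING = 4

_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("U")] = 3
_ENCODE[ord("u")] = 3

_DECODE = np.frombuffer(b"ACGT?", dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, missing=4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced specimen in an aligned barcode dataset."""

    specimen_id: str
    species_label: str
    life_stage: str
    region: str
    sequence: str
    sex: str = ""
    locality: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise DatasetError(
                f"{self.specimen_id}: unknown life stage {self.life_stage!r}"
            )
        if self.region not in REGIONS:
            raise DatasetError(f"{self.specimen_id}: unknown region {self.region!r}")

    @property
    def is_unknown(self) -> bool:
        return self.species_label == UNKNOWN

    @property
    def ungapped_length(self) -> int:
        """Number of unambiguous A/C/G/T sites (gaps, N, ambiguities excluded)."""
        return int(np.count_nonzero(encode_sequence(self.sequence) != MISSING))

    def with_species(self, species_label: str) -> "SpecimenRecord":
        return replace(self, species_label=species_label)


@dataclass
class Dataset:
    """An aligned set of specimen records sharing one alignment length."""

    records: list[SpecimenRecord]
    tier_tag: str = "pooled"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tier_tag not in TIERS:
            raise DatasetError(f"unknown tier tag {self.tier_tag!r}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise DatasetError(
                f"ragged alignment: sequence lengths {sorted(lengths)} differ"
            )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen IDs: {dupes}")
        if self.tier_tag in ("east", "west"):
            off = [r.specimen_id for r in self.records if r.region != self.tier_tag]
            if off:
                raise DatasetError(
                    f"tier {self.tier_tag!r} contains out-of-region records: {off}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def species(self) -> list[str]:
        """Distinct non-UNKNOWN species labels, sorted."""
        return sorted({r.species_label for r in self.records if not r.is_unknown})

    @property
    def unknowns(self) -> list[SpecimenRecord]:
        return [r for r in self.records if r.is_unknown]

    def labels(self) -> dict[str, str]:
        """specimen_id -> species label (including UNKNOWN)."""
        return {r.specimen_id: r.species_label for r in self.records}

    def encoded(self) -> np.ndarray:
        """(n_records, alignment_length) uint8 matrix of nucleotide codes."""
        if not self.records:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.stack([encode_sequence(r.sequence) for r in self.records])

    def subset(self, specimen_ids: Iterable[str], tier_tag: str | None = None) -> "Dataset":
        wanted = set(specimen_ids)
        recs = [r for r in self.records if r.specimen_id in wanted]
        missing = wanted - {r.specimen_id for r in recs}
        if missing:
            raise KeyError(f"specimen IDs not in dataset: {sorted(missing)}")
        return Dataset(recs, tier_tag=tier_tag or self.tier_tag)
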