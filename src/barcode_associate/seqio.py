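"""Reading, writing, filtering, and reading-frame QC of aligned barcode data.

Input is an aligned FASTA (gaps as ``-``) plus a tab-separated metadata table
with columns ``specimen_id``, ``species_label``, ``life_stage``, ``sex``,
``region``, ``locality``, ``source`` (the last three optional). Records whose
ungapped, unambiguous length falls below the active minimum-length filter
(default 325 sites) are removed before analysis. Reading-frame QC translates
each fragment in all three frames under the invertebrate mitochondrial code
and flags fragments that cannot avoid internal stop codons or that sit in a
different frame from the dataset consensus — the automated equivalent of
checking an alignment for stop codons and translation frame shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import IO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from barcode_associate.records import Dataset, SpecimenRecord

logger = logging.getLogger(__name__)

PathOrHandle = Union[str, PathLike, IO[str]]

#: NCBI translation table for the invertebrate mitochondrial code.
INVERTEBRATE_MITO = 5

#: Minimum ungapped length for analyzed datasets.
DEFAULT_MIN_LENGTH = 325

#: Looser inclusion threshold applied when assembling candidate specimens.
INCLUSION_MIN_LENGTH = 300

REQUIRED_METADATA_COLUMNS = ("specimen_id", "species_label", "life_stage", "region")
OPTIONAL_METADATA_COLUMNS = ("sex", "locality", "source")


class AlignmentIOError(ValueError):
    """Raised on malformed or inconsistent alignment/metadata input."""


def read_alignment(
    fasta_source: PathOrHandle,
    metadata_source: PathOrHandle,
    tier_tag: str = "pooled",
) -> Dataset:
    """Read an aligned FASTA and its metadata table into a :class:`Dataset`.

    FASTA IDs and metadata ``specimen_id`` values must match one-to-one;
    records are returned in metadata order. Ragged alignments, duplicate IDs
    and missing metadata columns are fatal.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id in seqs:
            raise AlignmentIOError(f"duplicate FASTA ID: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AlignmentIOError("no sequences found in FASTA input")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AlignmentIOError(
            f"ragged alignment: sequence lengths {sorted(lengths)} differ"
        )

    meta = pd.read_csv(metadata_source, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise AlignmentIOError(f"metadata missing required columns: {missing_cols}")
    for col in OPTIONAL_METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = ""

    meta_ids = list(meta["specimen_id"])
    if len(set(meta_ids)) != len(meta_ids):
        dupes = sorted({i for i in meta_ids if meta_ids.count(i) > 1})
        raise AlignmentIOError(f"duplicate metadata specimen IDs: {dupes}")
    orphan_meta = [i for i in meta_ids if i not in seqs]
    orphan_fasta = [i for i in seqs if i not in set(meta_ids)]
    if orphan_meta or orphan_fasta:
        raise AlignmentIOError(
            "FASTA and metadata IDs do not match one-to-one; "
            f"metadata-only IDs: {orphan_meta}; FASTA-only IDs: {orphan_fasta}"
        )

    records = [
        SpecimenRecord(
            specimen_id=row.specimen_id,
            species_label=row.species_label,
            life_stage=row.life_stage,
            region=row.region,
            sequence=seqs[row.specimen_id],
            sex=row.sex,
            locality=row.locality,
            source=row.source,
        )
        for row in meta.itertuples(index=False)
    ]
    return Dataset(records, tier_tag=tier_tag)


def write_alignment(
    ds: Dataset, fasta_target: PathOrHandle, metadata_target: PathOrHandle
) -> None:
    """Write a dataset back out as aligned FASTA + metadata TSV."""

    def _write_fasta(handle: IO[str]) -> None:
        for r in ds.records:
            handle.write(f">{r.specimen_id}\n{r.sequence}\n")

    if hasattr(fasta_target, "write"):
        _write_fasta(fasta_target)  # type: ignore[arg-type]
    else:
        with open(fasta_target, "w") as handle:
            _write_fasta(handle)

    meta = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in ds.records],
            "species_label": [r.species_label for r in ds.records],
            "life_stage": [r.life_stage for r in ds.records],
            "sex": [r.sex for r in ds.records],
            "region": [r.region for r in ds.records],
            "locality": [r.locality for r in ds.records],
            "source": [r.source for r in ds.records],
        }
    )
    meta.to_csv(metadata_target, sep="\t", index=False)


def filter_by_length(ds: Dataset, min_ungapped: int = DEFAULT_MIN_LENGTH) -> Dataset:
    """Retain records with at least ``min_ungapped`` unambiguous A/C/G/T sites.

    Gaps, Ns and IUPAC ambiguity codes do not count toward the length, the
    same convention as pairwise deletion in the distance computations.
    Removed IDs are logged; an empty result is a warning, not an error.
    """
    if min_ungapped <= 0:
        raise ValueError("min_ungapped must be positive")
    kept, removed = [], []
    for r in ds.records:
        (kept if r.ungapped_length >= min_ungapped else removed).append(r)
    if removed:
        logger.info(
            "length filter (min %d) removed %d of %d records: %s",
            min_ungapped,
            len(removed),
            len(ds),
            [r.specimen_id for r in removed],
        )
    if not kept:
        logger.warning("length filter removed every record")
    return Dataset(list(kept), tier_tag=ds.tier_tag)


@dataclass(frozen=True)
class FrameReport:
    """Reading-frame QC verdict for one record."""

    specimen_id: str
    frame: int  # offset 0/1/2 into the ungapped sequence minimizing stops
    alignment_frame: int  # (first ungapped column + frame) mod 3
    stop_count: int  # internal stops in the chosen frame
    stop_flag: bool  # no frame avoids internal stop codons
    frame_shift_flag: bool  # chosen frame differs from the dataset consensus

    @property
    def passed(self) -> bool:
        return not (self.stop_flag or self.frame_shift_flag)


def _count_stops(ungapped: str, offset: int, table: int) -> int:
    coding = ungapped[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return 0
    aa = str(Seq(coding).translate(table=table))
    # A terminal stop is legitimate; only internal stops indicate trouble.
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.count("*")


def frame_qc(ds: Dataset, genetic_code: int = INVERTEBRATE_MITO) -> list[FrameReport]:
    """Per-record reading-frame QC against the dataset consensus frame.

    For each record the frame (of three) minimizing internal stop codons over
    its ungapped sites is selected; ties resolve to the smallest offset. A
    record is stop-flagged when even its best frame contains internal stops
    (e.g. after an uncorrected 1-base deletion) and frame-shift-flagged when
    its best frame, expressed in alignment coordinates, deviates from the
    majority frame across records.
    """
    chosen: list[tuple[SpecimenRecord, int, int, int]] = []
    for r in ds.records:
        seq = r.sequence.upper()
        first = next((i for i, c in enumerate(seq) if c not in "-."), 0)
        ungapped = seq.replace("-", "").replace(".", "")
        stops = [_count_stops(ungapped, f, genetic_code) for f in range(3)]
        frame = int(min(range(3), key=lambda f: stops[f]))
        chosen.append((r, frame, (first + frame) % 3, stops[frame]))

    frames = [af for (_, _, af, _) in chosen]
    consensus = min(set(frames), key=lambda f: (-frames.count(f), f)) if frames else 0

    return [
        FrameReport(
            specimen_id=r.specimen_id,
            frame=frame,
            alignment_frame=af,
            stop_count=nstop,
            stop_flag=nstop > 0,
            frame_shift_flag=af != consensus,
        )
        for (r, frame, af, nstop) in chosen
    ]


def frame_qc_table(reports: list[FrameReport]) -> pd.DataFrame:
    """QC reports as a tidy table (TSV-ready)."""
    return pd.DataFrame([vars(r) for r in reports])


def apply_frame_qc(ds: Dataset, reports: list[FrameReport]) -> Dataset:
    """Drop records flagged by frame QC (the strict policy)."""
    flagged = {r.specimen_id for r in reports if not r.passed}
    if flagged:
        logger.info("frame QC dropped %d records: %s", len(flagged), sorted(flagged))
    return Dataset(
        [r for r in ds.records if r.specimen_id not in flagged], tier_tag=ds.tier_tag
    )
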