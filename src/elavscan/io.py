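"""Reading and writing the formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention); 1-based
coordinates appear only in human-readable reports. ``U`` and ``T`` are kept
distinct on disk — files are never rewritten with a substituted alphabet;
T/U equivalence is applied at match time only (see :mod:`elavscan.motifs`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, CoordinateError, FormatError, SpeciesLookupError

_SEQ_ALPHABET = set("ACGTUNacgtun")
_GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA or RNA, case preserved)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters outside A/C/G/T/U/N: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based, half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"{self.seq_id}: negative start {self.start}")
        if self.end <= self.start:
            raise CoordinateError(
                f"{self.seq_id}: end {self.end} must exceed start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MultipleAlignment:
    """Gapped rows of equal width; one row is the designated reference.

    ``score`` carries the optimal alignment score when the object was
    produced by the bundled pairwise aligner; it is ``None`` for
    alignments read from disk.
    """

    rows: list[tuple[str, str]]
    ref_species: str
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        widths = {len(g) for _, g in self.rows}
        if len(widths) != 1:
            raise AlignmentFormatError(f"rows have unequal widths: {sorted(widths)}")
        ids = [s for s, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise AlignmentFormatError("duplicate species ids in alignment")
        if self.ref_species not in ids:
            raise SpeciesLookupError(self.ref_species)
        for sp, g in self.rows:
            if set(g) - _SEQ_ALPHABET - {_GAP}:
                raise AlignmentFormatError(f"row {sp!r}: invalid characters")
            if not g.replace(_GAP, ""):
                raise AlignmentFormatError(f"row {sp!r}: all-gap row")
            SequenceRecord(sp, g.replace(_GAP, ""))  # ungapped row must be valid

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def species_ids(self) -> list[str]:
        return [s for s, _ in self.rows]

    def gapped(self, species_id: str) -> str:
        for sp, g in self.rows:
            if sp == species_id:
                return g
        raise SpeciesLookupError(species_id)

    def ungapped_record(self, species_id: str) -> SequenceRecord:
        return SequenceRecord(species_id, self.gapped(species_id).replace(_GAP, ""))


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a plain FASTA file; order and case are preserved.

    Raises :class:`FormatError` on an empty file, duplicate ids, or
    characters outside the nucleotide alphabet, naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_aligned_fasta(path: str | os.PathLike, ref_species: str) -> MultipleAlignment:
    """Read an aligned FASTA ('-' gaps, equal-width rows) with a stated reference."""
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise AlignmentFormatError(f"duplicate species id {rec.id!r} in {path}")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq)))
    if not rows:
        raise AlignmentFormatError(f"no alignment rows found in {path}")
    return MultipleAlignment(rows=rows, ref_species=ref_species)


def write_aligned_fasta(aln: MultipleAlignment, path: str | os.PathLike, width: int = 60) -> None:
    recs = [SeqRecord(Seq(g), id=sp, description="") for sp, g in aln.rows]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_bed(entries: list[tuple[Interval, str, float]], path: str | os.PathLike) -> None:
    """Write BED6 lines (0-based half-open). Strand is fixed to '+': the scan
    is sense-strand only, since ELAV binds the transcript itself."""
    with open(path, "w") as fh:
        for iv, name, score in entries:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t+\n")


def read_bed(path: str | os.PathLike) -> list[tuple[Interval, str, float]]:
    out: list[tuple[Interval, str, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >=4 BED columns")
            iv = Interval(parts[0], int(parts[1]), int(parts[2]))
            score = float(parts[4]) if len(parts) > 4 else 0.0
            out.append((iv, parts[3], score))
    return out


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with a mandatory header row; 'NA' means missing."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tiff_stack(path: str | os.PathLike):
    """Read a (multi-page) TIFF as a numpy array, one page per z-plane."""
    return tifffile.imread(os.fspath(path))


def write_tiff_stack(arr, path: str | os.PathLike) -> None:
    tifffile.imwrite(os.fspath(path), arr)
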