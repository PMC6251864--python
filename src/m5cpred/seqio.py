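"""Transcript and site-table I/O, plus candidate-window extraction.

Coordinate conventions used throughout the package
--------------------------------------------------
* Positions are **1-based, fully closed, on the transcript** — never on the
  genome. A :class:`SiteRecord` with ``position=1`` refers to the first base.
* RNA input is normalised to the DNA alphabet on read (``U`` becomes ``T``);
  the internal alphabet is ``{A, C, G, T, N}``.
* A prediction candidate is always a cytosine. Extracting a window centred
  on a non-C base is an error (it signals a corrupt site table), not a
  silent skip.
* Windows that overhang a transcript end are padded with ``N`` rather than
  discarded, so sites near transcript ends stay in the evaluation sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    BoundsError,
    DuplicateIdError,
    FastaParseError,
    NotACandidateError,
    SchemaError,
    SiteValidationError,
)

ALPHABET = frozenset("ACGTN")
VALID_LABELS = ("positive", "negative")

SITE_TABLE_COLUMNS = ("transcript_id", "position", "label", "tissue")


@dataclass(frozen=True)
class Transcript:
    """A nucleotide sequence with identity and gene linkage.

    ``sequence`` is stored uppercase over ``{A,C,G,T,N}`` with U already
    normalised to T.
    """

    id: str
    sequence: str
    gene_id: str = ""
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A labelled candidate-C position on a transcript, with tissue provenance."""

    transcript_id: str
    position: int  # 1-based transcript coordinate
    label: str  # "positive" | "negative"
    tissue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SiteValidationError(
                f"position must be >= 1 (1-based), got {self.position} "
                f"on {self.transcript_id!r}"
            )
        if self.label not in VALID_LABELS:
            raise SiteValidationError(
                f"unknown label {self.label!r}; expected one of {VALID_LABELS}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-width context of ``2w+1`` bases centred on a candidate C.

    ``pad_count`` records how many ``N`` characters were added because the
    window overhangs a transcript end.
    """

    bases: str
    w: int
    center_index: int  # 1-based coordinate of the central C on its transcript
    pad_count: int = 0
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != 2 * self.w + 1:
            raise ValueError(
                f"window length {len(self.bases)} != 2w+1 = {2 * self.w + 1}"
            )
        if self.bases[self.w] != "C":
            raise ValueError(
                f"window centre must be C, got {self.bases[self.w]!r}"
            )
        if self.pad_count > 2 * self.w:
            raise ValueError("pad_count cannot exceed 2w")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, biotype: str = "mRNA") -> list[Transcript]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The header token before the first whitespace becomes the transcript id.
    A second whitespace-separated token of the form ``gene=<id>`` (or the
    second token itself when it carries no ``=``) is taken as the gene id.

    Raises
    ------
    FastaParseError
        If sequence data precedes any ``>`` header (with the line number).
    DuplicateIdError
        If two records share an id.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break

    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateIdError(f"{path}: duplicate transcript id {record.id!r}")
        seen.add(record.id)
        gene_id = ""
        desc_tokens = record.description.split()
        for token in desc_tokens[1:]:
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
                break
        transcripts.append(
            Transcript(
                id=record.id,
                sequence=normalize_sequence(str(record.seq)),
                gene_id=gene_id,
                biotype=biotype,
            )
        )
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path,
                width: int = 70) -> None:
    """Write transcripts as FASTA; ``gene=`` is carried in the description."""
    with open(path, "w") as out:
        for t in transcripts:
            header = f">{t.id}"
            if t.gene_id:
                header += f" gene={t.gene_id}"
            out.write(header + "\n")
            for i in range(0, len(t.sequence), width):
                out.write(t.sequence[i:i + width] + "\n")


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the 4-column TSV site table (header required).

    Columns: ``transcript_id  position  label  tissue``; positions 1-based.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in SITE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[SiteRecord] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            position = int(getattr(row, "position"))
        except ValueError as exc:
            raise SiteValidationError(
                f"{path}: row {row_number}: position "
                f"{getattr(row, 'position')!r} is not an integer"
            ) from exc
        try:
            records.append(
                SiteRecord(
                    transcript_id=getattr(row, "transcript_id"),
                    position=position,
                    label=getattr(row, "label"),
                    tissue=getattr(row, "tissue"),
                )
            )
        except SiteValidationError as exc:
            raise SiteValidationError(f"{path}: row {row_number}: {exc}") from exc
    return records


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(s.transcript_id, s.position, s.label, s.tissue) for s in sites],
        columns=list(SITE_TABLE_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def extract_window(transcript: Transcript, position: int, w: int) -> SequenceWindow:
    """Extract the ``2w+1`` window centred on a candidate C.

    Out-of-range flanks are filled with ``N``; ``pad_count`` reports how many.
    """
    n = len(transcript.sequence)
    if not 1 <= position <= n:
        raise BoundsError(
            f"position {position} outside transcript {transcript.id!r} "
            f"(length {n})"
        )
    center = transcript.sequence[position - 1]
    if center != "C":
        raise NotACandidateError(
            f"base at {transcript.id!r}:{position} is {center!r}, not C; "
            "site table may be corrupt"
        )
    lo = position - 1 - w
    hi = position + w  # exclusive, 0-based
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    core = transcript.sequence[max(lo, 0):min(hi, n)]
    return SequenceWindow(
        bases="N" * left_pad + core + "N" * right_pad,
        w=w,
        center_index=position,
        pad_count=left_pad + right_pad,
        transcript_id=transcript.id,
    )


def select_representative_transcript(
    transcripts_of_gene: Sequence[tuple[Transcript, int]],
) -> Transcript:
    """Pick one transcript per gene: the mRNA carrying the most sites.

    Ties are broken by longer sequence, then lexicographically smaller id,
    so selection is deterministic. When the gene has no mRNA-biotype
    transcript at all, selection falls back to every biotype and logs a
    warning instead of failing.
    """
    if not transcripts_of_gene:
        raise ValueError("cannot select a representative from an empty collection")
    mrna = [(t, c) for t, c in transcripts_of_gene if t.biotype == "mRNA"]
    pool = mrna
    if not pool:
        gene = transcripts_of_gene[0][0].gene_id or "<unknown gene>"
        warnings.warn(
            f"gene {gene}: no mRNA-biotype transcript; "
            "falling back to all biotypes",
            stacklevel=2,
        )
        pool = list(transcripts_of_gene)
    return min(pool, key=lambda tc: (-tc[1], -len(tc[0].sequence), tc[0].id))[0]
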