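"""Sequence I/O for phage-display insert amplicons.

Reads FASTA/FASTQ (or plain DNA lines), locates the 21-nt random insert
between fixed vector anchors on either strand, and translates NNK codons
to heptapeptides.  The amber codon TAG is translated as glutamine by
default because commercial display libraries are propagated in supE
suppressor hosts (e.g. ER2738), where TAG reads as Gln.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SequenceRead",
    "InsertRecord",
    "Strand",
    "InsertStatus",
    "ParseError",
    "SequenceError",
    "FrameError",
    "PrematureStopError",
    "AmbiguityError",
    "read_sequences",
    "reverse_complement",
    "extract_insert",
    "translate_codons",
    "write_insert_table",
]

NUCLEOTIDES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Stop codons that terminate translation even in a supE host.
HARD_STOPS = frozenset({"TAA", "TGA"})
AMBER = "TAG"


class ParseError(ValueError):
    """A sequence file could not be parsed in the requested format."""


class SequenceError(ValueError):
    """A sequence string contains characters outside the DNA alphabet."""


class FrameError(ValueError):
    """A coding sequence whose length is not a multiple of three."""


class PrematureStopError(ValueError):
    """A hard stop codon (TAA/TGA) inside the random region."""


class AmbiguityError(ValueError):
    """An N base inside a codon prevents unambiguous translation."""


class Strand(str, Enum):
    AS_READ = "as-read"
    REVCOMP = "reverse-complemented"


class InsertStatus(str, Enum):
    OK = "ok"
    ANCHORS_NOT_FOUND = "anchors-not-found"
    LENGTH_MISMATCH = "length-mismatch"
    AMBIGUOUS_BASE = "ambiguous-base"


@dataclass
class SequenceRead:
    """One raw read: id, DNA over {A,C,G,T,N}, optional Phred qualities."""

    read_id: str
    dna: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.dna:
            raise SequenceError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.dna) - NUCLEOTIDES
        if bad:
            raise SequenceError(
                f"read {self.read_id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if self.quality is not None:
            if len(self.quality) != len(self.dna):
                raise SequenceError(
                    f"read {self.read_id!r}: {len(self.quality)} quality values "
                    f"for {len(self.dna)} bases"
                )
            if any(q < 0 or q > 60 for q in self.quality):
                raise SequenceError(
                    f"read {self.read_id!r}: Phred values outside [0, 60]"
                )


@dataclass
class InsertRecord:
    """The random-region insert recovered from one clone's read.

    ``valid``/``failed_codons`` are left unset here; the library QC stage
    decides them against the NNK design rule.  Codon indices are 1-based.
    """

    clone_id: str
    raw_dna: str
    insert_dna: Optional[str] = None
    strand: Optional[Strand] = None
    status: InsertStatus = InsertStatus.OK
    valid: Optional[bool] = None
    failed_codons: list[int] = field(default_factory=list)

    @property
    def extraction_ok(self) -> bool:
        return self.status is InsertStatus.OK


def reverse_complement(dna: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N; involutive."""
    bad = set(dna) - NUCLEOTIDES
    if bad:
        raise SequenceError(f"non-nucleotide characters {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRead]:
    """Read sequences from ``path`` as FASTA, FASTQ (Phred+33) or raw lines.

    Order is preserved and N bases are retained.  An empty file yields an
    empty list.  Malformed records raise :class:`ParseError`.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "raw-lines":
        reads = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                seq = line.strip().upper()
                if not seq:
                    continue
                bad = set(seq) - NUCLEOTIDES
                if bad:
                    raise ParseError(
                        f"{path}: line {lineno}: non-nucleotide characters "
                        f"{sorted(bad)}"
                    )
                reads.append(SequenceRead(read_id=f"line{lineno}", dna=seq))
        return reads
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    reads = []
    n = 0
    try:
        for n, rec in enumerate(SeqIO.parse(str(path), fmt), start=1):
            quality = None
            if fmt == "fastq":
                quality = list(rec.letter_annotations["phred_quality"])
            reads.append(
                SequenceRead(read_id=rec.id, dna=str(rec.seq).upper(), quality=quality)
            )
    except ValueError as err:
        lines_per_rec = 4 if fmt == "fastq" else 2
        raise ParseError(
            f"{path}: malformed {fmt} near line {n * lines_per_rec + 1}: {err}"
        ) from err
    return reads


def extract_insert(
    read: SequenceRead,
    flank5: str,
    flank3: str,
    expect_len: int = 21,
) -> InsertRecord:
    """Locate ``flank5…flank3`` on either strand and return the enclosed insert.

    The as-read strand is tried first, then the reverse complement; the
    first exact anchor match wins (no mismatches are tolerated in the fixed
    vector anchors).  Failures are flagged on the record, never raised:
    anchors absent on both strands, a region whose length differs from
    ``expect_len``, or an N inside the region.
    """
    if not flank5 or not flank3:
        raise ValueError("flank anchors must be non-empty")
    for seq, strand in (
        (read.dna, Strand.AS_READ),
        (reverse_complement(read.dna), Strand.REVCOMP),
    ):
        i = seq.find(flank5)
        if i < 0:
            continue
        j = seq.find(flank3, i + len(flank5))
        if j < 0:
            continue
        insert = seq[i + len(flank5) : j]
        if len(insert) != expect_len:
            return InsertRecord(
                clone_id=read.read_id,
                raw_dna=read.dna,
                insert_dna=insert,
                strand=strand,
                status=InsertStatus.LENGTH_MISMATCH,
            )
        if "N" in insert:
            return InsertRecord(
                clone_id=read.read_id,
                raw_dna=read.dna,
                insert_dna=insert,
                strand=strand,
                status=InsertStatus.AMBIGUOUS_BASE,
            )
        return InsertRecord(
            clone_id=read.read_id,
            raw_dna=read.dna,
            insert_dna=insert,
            strand=strand,
            status=InsertStatus.OK,
        )
    return InsertRecord(
        clone_id=read.read_id,
        raw_dna=read.dna,
        status=InsertStatus.ANCHORS_NOT_FOUND,
    )


def translate_codons(dna: str, amber_as: str = "Q") -> str:
    """Translate a coding DNA string with the standard genetic code.

    TAG is read as ``amber_as`` (supE amber suppression); TAA/TGA raise
    :class:`PrematureStopError`.  The input length must be a multiple of
    three and may not contain N.
    """
    if len(dna) % 3 != 0:
        raise FrameError(f"length {len(dna)} is not a multiple of 3")
    bad = set(dna) - NUCLEOTIDES
    if bad:
        raise SequenceError(f"non-nucleotide characters {sorted(bad)}")
    peptide = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            raise AmbiguityError(f"ambiguous base in codon {i // 3 + 1} ({codon})")
        if codon == AMBER:
            peptide.append(amber_as)
        elif codon in HARD_STOPS:
            raise PrematureStopError(
                f"stop codon {codon} at codon {i // 3 + 1}"
            )
        else:
            peptide.append(standard_dna_table.forward_table[codon])
    return "".join(peptide)


def write_insert_table(records: Iterable[InsertRecord], path: str | Path) -> None:
    """Write extracted inserts as TSV: clone_id, strand, insert_dna, status."""
    rows = [
        {
            "clone_id": r.clone_id,
            "strand": r.strand.value if r.strand else "",
            "insert_dna": r.insert_dna or "",
            "status": r.status.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["clone_id", "strand", "insert_dna", "status"]).to_csv(
        path, sep="\t", index=False
    )
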