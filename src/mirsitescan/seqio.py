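"""Sequence, alignment and tabular I/O, and the coordinate conventions.

All genomic intervals in this package are 1-based and inclusive on both ends
(``length = end - start + 1``), matching the convention of transcript
annotation browsers; BED export converts to 0-based half-open.  miRNAs are
stored as RNA (U), UTRs are normalized to DNA (T) internally; pairing logic
elsewhere treats U and T as equivalent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "GenomicInterval",
    "UTRRecord",
    "AlignmentSet",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "local_to_genomic",
    "genomic_to_local",
    "interval_to_bed",
]

_VALID = set("ACGUTN")
_INTERVAL_RE = re.compile(r"(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)(?::(?P<strand>[+-]))?")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase nucleotide string tagged as RNA or DNA.

    T and U never co-occur: RNA sequences carry U, DNA sequences carry T.
    """

    residues: str
    alphabet: str  # "RNA" | "DNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        if self.alphabet not in ("RNA", "DNA"):
            raise ValueError(f"alphabet must be RNA or DNA, got {self.alphabet!r}")
        res = self.residues.upper()
        bad = set(res) - _VALID
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")
        res = res.replace("T", "U") if self.alphabet == "RNA" else res.replace("U", "T")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def as_rna(self) -> str:
        return self.residues.replace("T", "U")

    def as_dna(self) -> str:
        return self.residues.replace("U", "T")

    def reverse_complement(self) -> "NucleotideSequence":
        rc = str(Seq(self.as_dna()).reverse_complement())
        if self.alphabet == "RNA":
            rc = rc.replace("T", "U")
        return NucleotideSequence(rc, self.alphabet)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval; ``len = end - start + 1``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence anchored to a genomic interval.

    The sequence is given 5'->3' along the transcript; for minus-strand
    records local position 1 therefore corresponds to ``interval.end``.
    """

    id: str
    seq: NucleotideSequence
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.interval is not None and len(self.seq) != len(self.interval):
            raise ValueError(
                f"{self.id}: sequence length {len(self.seq)} != "
                f"interval length {len(self.interval)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentSet:
    """A gapped multiple alignment of orthologous UTRs keyed by species."""

    sequences: dict[str, str]
    reference: str
    columns: int = field(init=False)

    def __post_init__(self) -> None:
        if self.reference not in self.sequences:
            raise ValueError(f"reference species {self.reference!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ParseError("aligned sequences have unequal lengths")
        self.columns = lengths.pop()

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def reference_length(self) -> int:
        """Ungapped length of the reference row."""
        return sum(1 for c in self.sequences[self.reference] if c != "-")


def _parse_interval(description: str) -> GenomicInterval | None:
    m = _INTERVAL_RE.search(description)
    if m is None:
        return None
    return GenomicInterval(
        m["chrom"], int(m["start"]), int(m["end"]), m["strand"] or "+"
    )


def read_fasta(path: str | Path, alphabet: str = "DNA", with_intervals: bool = True):
    """Read FASTA records, normalizing case and U/T per *alphabet*.

    With ``with_intervals=True`` returns ``list[UTRRecord]``, parsing an
    optional ``chrom:start-end[:strand]`` token from each header; otherwise
    returns ``list[tuple[str, NucleotideSequence]]`` of (id, sequence).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = NucleotideSequence(str(rec.seq), alphabet)
        except ValueError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
        if with_intervals:
            interval = _parse_interval(rec.description)
            try:
                records.append(UTRRecord(rec.id, seq, interval))
            except ValueError as exc:
                raise ParseError(f"record {rec.id!r}: {exc}") from exc
        else:
            records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[UTRRecord]) -> None:
    """Write UTRRecords with their interval metadata in the header."""
    out = []
    for r in records:
        desc = ""
        if r.interval is not None:
            desc = f"{r.interval}:{r.interval.strand}"
        out.append(SeqRecord(Seq(r.seq.residues), id=r.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


def read_msa(path: str | Path, reference: str, fmt: str = "fasta") -> AlignmentSet:
    """Read a multiple alignment (``fasta`` = aligned-FASTA, or ``clustal``)."""
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    return AlignmentSet(seqs, reference)


def local_to_genomic(local_pos: int, utr: UTRRecord) -> int:
    """Map a 1-based position on the UTR sequence to its genomic position."""
    if utr.interval is None:
        raise ValueError(f"{utr.id}: no genomic interval attached")
    if not 1 <= local_pos <= len(utr):
        raise IndexError(f"local position {local_pos} outside 1..{len(utr)}")
    if utr.interval.strand == "+":
        return utr.interval.start + local_pos - 1
    return utr.interval.end - local_pos + 1


def genomic_to_local(genomic_pos: int, utr: UTRRecord) -> int:
    """Inverse of :func:`local_to_genomic`; exact round-trip."""
    if utr.interval is None:
        raise ValueError(f"{utr.id}: no genomic interval attached")
    if not utr.interval.start <= genomic_pos <= utr.interval.end:
        raise IndexError(f"genomic position {genomic_pos} outside {utr.interval}")
    if utr.interval.strand == "+":
        return genomic_pos - utr.interval.start + 1
    return utr.interval.end - genomic_pos + 1


def interval_to_bed(interval: GenomicInterval, name: str = ".", score: float = 0) -> str:
    """One BED line (0-based half-open) for a 1-based inclusive interval."""
    return "\t".join(
        [interval.chrom, str(interval.start - 1), str(interval.end), name,
         str(score), interval.strand]
    )
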