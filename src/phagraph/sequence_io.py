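"""Reading, windowing and translating DNA sequences.

Contigs are plain DNA strings over ``{A, C, G, T, N}``.  The encoder
consumes fixed-length windows ("segments"), and the gene-sharing side of
the pipeline consumes six-frame translations split at stop codons, with
short fragments discarded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

__all__ = [
    "Contig",
    "Segment",
    "ProteinRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "segment_contig",
    "six_frame_translate",
]

DNA_ALPHABET = frozenset("ACGTN")


class FastaError(ValueError):
    """Raised for malformed FASTA input or duplicate record identifiers."""


@dataclass(frozen=True)
class Contig:
    """An assembled DNA sequence to classify (or a reference genome)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> str:
        return str(Seq(self.seq).reverse_complement())


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of a contig (0-based offset, half-open)."""

    parent_id: str
    offset: int
    seq: str


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein, either a reference gene or a six-frame fragment.

    ``frame`` is 0-2 for the forward strand and 3-5 for the reverse
    complement; reference proteins use frame 0 by convention.
    """

    id: str
    parent_id: str
    frame: int
    aa_seq: str
    source: str = "contig"  # "contig" | "reference"

    def __post_init__(self) -> None:
        if "*" in self.aa_seq:
            raise ValueError(f"protein {self.id!r}: internal stop symbol")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzip-compressed) FASTA file.

    Returns ``(id, sequence)`` tuples in file order, sequences uppercased.
    Raises :class:`FastaError` naming the offending line for malformed
    input, and for duplicate identifiers.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FastaError(f"{path}: empty FASTA header at line {lineno}")
                if header in seen:
                    raise FastaError(
                        f"{path}: duplicate record id {header!r} at line {lineno}"
                    )
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise FastaError(
                        f"{path}: expected '>' header before sequence at line {lineno}"
                    )
                chunks.append(line.upper())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def segment_contig(contig: Contig, window: int = 2000, stride: int = 50) -> list[Segment]:
    """Cut a contig into windows of ``window`` nt every ``stride`` nt.

    Offsets run 0, stride, 2*stride, ... while the full window fits; a
    trailing residue shorter than the window is dropped.  A contig shorter
    than the window yields an empty list.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    out = []
    for off in range(0, contig.length - window + 1, stride):
        out.append(Segment(contig.id, off, contig.seq[off : off + window]))
    return out


def _translate_frame(dna: str) -> str:
    # trim to a whole number of codons; codons containing N become X
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate())


def six_frame_translate(contig: Contig, min_len: int = 12) -> list[ProteinRecord]:
    """Translate a contig in all six reading frames.

    Each frame is translated codon-by-codon with the standard genetic
    code, split at stop codons, and every stop-free fragment of at least
    ``min_len`` amino acids becomes one :class:`ProteinRecord`.  Frames
    0-2 read the forward strand with offsets 0-2; frames 3-5 read the
    reverse complement with offsets 0-2.
    """
    bad = set(contig.seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"contig {contig.id!r}: invalid characters {sorted(bad)}")
    out: list[ProteinRecord] = []
    rc = contig.reverse_complement()
    for frame in range(6):
        strand_seq = contig.seq if frame < 3 else rc
        aa = _translate_frame(strand_seq[frame % 3 :])
        for i, fragment in enumerate(aa.split("*")):
            if len(fragment) >= min_len:
                out.append(
                    ProteinRecord(
                        id=f"{contig.id}|f{frame}|{i}",
                        parent_id=contig.id,
                        frame=frame,
                        aa_seq=fragment,
                        source="contig",
                    )
                )
    return out
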