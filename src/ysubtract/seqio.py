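"""Sequence containers and FASTA/FASTQ I/O.

Thin wrappers around Biopython's parsers plus a handful of small sequence
utilities (reverse complement, ORF scanning, translation) used throughout
the package. Sequences are handled as plain upper-case strings internally.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code, '*' for stops)."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


@dataclass(frozen=True)
class Read:
    """A single sequencing read (FASTQ record)."""

    id: str
    seq: str
    qual: str = ""


ReadPair = tuple[Read, Read]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 keeps gzip output byte-identical across reruns
            import io

            return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: Iterable[tuple[str, str]] | dict[str, str]) -> None:
    if isinstance(records, dict):
        records = records.items()
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> list[Read]:
    """Read a (possibly gzipped) FASTQ file; Phred+33 qualities kept verbatim."""
    reads: list[Read] = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            reads.append(
                Read(
                    rec.id,
                    str(rec.seq).upper(),
                    "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                )
            )
    return reads


def write_fastq(path, reads: Iterable[Read]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in length: {len(r1)} vs {len(r2)}")
    return list(zip(r1, r2))


def flatten_pairs(pairs: Iterable[ReadPair]) -> Iterator[Read]:
    for a, b in pairs:
        yield a
        yield b


@dataclass(frozen=True)
class Orf:
    """An open reading frame: ATG..stop on the given strand of a transcript.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    *forward* strand sequence; ``aa_len`` excludes the stop codon.
    """

    start: int
    end: int
    strand: str
    aa_len: int


def _forward_orfs(seq: str) -> Iterator[tuple[int, int]]:
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                yield start, i + 3
                start = None


def find_orfs(seq: str, both_strands: bool = True) -> list[Orf]:
    """All complete ORFs (ATG to stop) in the sequence."""
    seq = seq.upper()
    n = len(seq)
    orfs = [Orf(s, e, "+", (e - s) // 3 - 1) for s, e in _forward_orfs(seq)]
    if both_strands:
        for s, e in _forward_orfs(revcomp(seq)):
            orfs.append(Orf(n - e, n - s, "-", (e - s) // 3 - 1))
    return orfs


def longest_orf(seq: str, both_strands: bool = True) -> Orf | None:
    orfs = find_orfs(seq, both_strands)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.aa_len, o.strand == "+", -o.start))


def orf_nucleotides(seq: str, orf: Orf, include_stop: bool = False) -> str:
    """Extract ORF nucleotide sequence in coding orientation."""
    sub = seq[orf.start : orf.end]
    if orf.strand == "-":
        sub = revcomp(sub)
    return sub if include_stop else sub[:-3]


def orf_peptide(seq: str, orf: Orf) -> str:
    return translate(orf_nucleotides(seq, orf))
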