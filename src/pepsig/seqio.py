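"""Sequence I/O and nucleotide-to-peptide transformations.

FASTA reading/writing is delegated to Biopython; the transformations the
annotation stage needs — fixed-window genome fragmentation, six-frame
translation and stop-free ORF extraction — live here.  Coordinates are
0-based half-open everywhere inside the package; conversion to 1-based
inclusive happens only when gene calls are written out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the package's record contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq or any(c.isspace() for c in self.seq):
            raise ValueError(f"protein {self.id!r}: empty sequence or whitespace")


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence over {A,C,G,T,N}, normalised to upper case."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - _NT_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: non-nucleotide characters {sorted(bad)}")


@dataclass(frozen=True)
class GenomeFragment:
    """A window of a genome; ``start`` is the 0-based offset of ``seq``."""

    genome_id: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading-frame translation of a nucleotide sequence.

    ``frame`` is +1/+2/+3 for offsets 0/1/2 on the forward strand and
    -1/-2/-3 for offsets 0/1/2 on the reverse complement.  ``source_len``
    is the nucleotide length of the translated sequence, kept so that
    amino-acid coordinates can be mapped back to the forward strand.
    """

    source_id: str
    frame: int
    aa_seq: str
    source_len: int


@dataclass(frozen=True)
class Orf:
    """A maximal stop-free run in one reading frame.

    ``aa_start``/``aa_end`` are half-open coordinates within the frame's
    amino-acid sequence; ``nt_start``/``nt_end`` are the corresponding
    half-open coordinates on the forward strand of the source sequence.
    """

    source_id: str
    frame: int
    aa_seq: str
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int


def read_fasta(
    path: str | Path, kind: Literal["protein", "nucleotide"] = "protein"
) -> list[ProteinRecord] | list[GenomeRecord]:
    """Read a FASTA file into protein or genome records.

    Sequence lines are concatenated, record order is preserved and
    duplicate identifiers are rejected.  Nucleotide sequences are
    upper-cased on input.
    """
    path = Path(path)
    records: list = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            if kind == "nucleotide":
                records.append(GenomeRecord(id=rec.id, seq=seq.upper()))
            else:
                records.append(ProteinRecord(id=rec.id, seq=seq.upper()))
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord | GenomeRecord], path: str | Path) -> None:
    """Write records to FASTA, 60-column wrapped."""
    seqrecords = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    _BioSeqIO.write(seqrecords, str(path), "fasta")


def fragment_genome(
    genome: GenomeRecord, window: int = 2000, overlap: int = 100
) -> list[GenomeFragment]:
    """Split a genome into overlapping windows.

    Fragments start at multiples of ``window - overlap`` so that
    consecutive fragments share ``overlap`` bases; the final fragment may
    be shorter than ``window``.  A genome shorter than one window yields
    a single fragment spanning the whole genome.
    """
    if not window > overlap >= 0:
        raise ValueError(f"require window > overlap >= 0, got {window}/{overlap}")
    step = window - overlap
    n = len(genome.seq)
    fragments = []
    start = 0
    while True:
        fragments.append(GenomeFragment(genome.id, start, genome.seq[start : start + window]))
        if start + window >= n:
            break
        start += step
    return fragments


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON_TABLE = _codon_table()


def _translate(nt: str) -> str:
    # standard genetic code; stops emit '*'; any codon containing N emits
    # 'X' so ambiguity can never create a peptide match
    usable = len(nt) - len(nt) % 3
    get = _CODON_TABLE.get
    return "".join(get(nt[i : i + 3], "X") for i in range(0, usable, 3))


def six_frame_translate(nt_seq: str, source_id: str = "") -> list[TranslatedFrame]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 translate at offsets 0, 1, 2 of the forward strand;
    frames -1..-3 at offsets 0, 1, 2 of the reverse complement.  Stop
    codons emit '*'.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(nt_seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    rc = str(Seq(nt_seq).reverse_complement())
    frames = []
    for offset in range(3):
        frames.append(
            TranslatedFrame(source_id, offset + 1, _translate(nt_seq[offset:]), len(nt_seq))
        )
    for offset in range(3):
        frames.append(
            TranslatedFrame(source_id, -(offset + 1), _translate(rc[offset:]), len(nt_seq))
        )
    return frames


def _orf_nt_interval(frame: int, aa_start: int, aa_end: int, source_len: int) -> tuple[int, int]:
    offset = abs(frame) - 1
    lo, hi = offset + 3 * aa_start, offset + 3 * aa_end
    if frame > 0:
        return lo, hi
    # reverse-complement coordinates mapped back to the forward strand
    return source_len - hi, source_len - lo


def extract_orfs(frames: Iterable[TranslatedFrame], min_len: int = 50) -> list[Orf]:
    """Extract maximal stop-free runs strictly longer than ``min_len``.

    No start codon is required: an ORF is any run of residues bounded by
    stop codons or the ends of the frame.
    """
    orfs: list[Orf] = []
    for fr in frames:
        pos = 0
        for run in fr.aa_seq.split("*"):
            if len(run) > min_len:
                nt_start, nt_end = _orf_nt_interval(fr.frame, pos, pos + len(run), fr.source_len)
                orfs.append(
                    Orf(fr.source_id, fr.frame, run, pos, pos + len(run), nt_start, nt_end)
                )
            pos += len(run) + 1
    return orfs
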