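"""Genome input and open-reading-frame identification.

Coordinates are 0-based half-open on the forward strand throughout the
package; GenBank's 1-based inclusive convention is converted once, at the
parse boundary.  The ORF caller is deliberately minimal — the longest
start-to-stop frame per reading frame on both strands — because gene
calling is not the scientific contribution here; when a GenBank record
carries CDS features those can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_BACTERIAL_TABLE.stop_codons)
_CODON_MAP = dict(_BACTERIAL_TABLE.forward_table)

VALID = set("ACGTN")


class ParseError(ValueError):
    """Malformed sequence record."""


class TranslationError(ValueError):
    """Raised for untranslatable coding sequence."""


@dataclass
class Orf:
    contig_id: str
    start: int          # 0-based, forward strand
    end: int            # half-open
    strand: str         # '+' or '-'
    aa_sequence: str

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


@dataclass
class Contig:
    id: str
    sequence: str
    source_format: str = "fasta"
    cds_orfs: list[Orf] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")


def _normalize(seq: str) -> str:
    """Uppercase and map non-ACGT IUPAC codes to N."""
    seq = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in seq)


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def translate(dna: str) -> str:
    """Standard bacterial-table translation of an in-frame sequence.

    A trailing stop codon is dropped; an internal stop is an error.
    Codons containing N translate to X.
    """
    if len(dna) % 3 != 0:
        raise TranslationError(
            f"sequence length {len(dna)} not divisible by 3")
    dna = dna.upper()
    aas: list[str] = []
    n_codons = len(dna) // 3
    for k in range(n_codons):
        codon = dna[3 * k: 3 * k + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOPS:
            if k != n_codons - 1:
                raise TranslationError(
                    f"internal stop codon at position {3 * k}")
        else:
            aa = _CODON_MAP.get(codon)
            if aa is None:
                raise TranslationError(f"unknown codon {codon!r}")
            aas.append(aa)
    return "".join(aas)


def read_sequences(path, fmt: str | None = None) -> list[Contig]:
    """Read FASTA or GenBank records into :class:`Contig` objects.

    GenBank CDS features, when present, are retained as precomputed ORFs
    (coordinates converted to 0-based half-open).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = ("genbank" if path.suffix.lower() in
               (".gb", ".gbk", ".genbank") else "fasta")
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {fmt!r}")
    contigs: list[Contig] = []
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    for rec in records:   # a record-less file is valid (no contigs)
        seq = _normalize(str(rec.seq))
        if not seq:
            raise ParseError(f"record {rec.id!r} has an empty sequence")
        contig = Contig(id=rec.id, sequence=seq, source_format=fmt)
        if fmt == "genbank":
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                start = int(feat.location.start)
                end = int(feat.location.end)
                strand = "-" if feat.location.strand == -1 else "+"
                aa = feat.qualifiers.get("translation", [None])[0]
                if aa is None:
                    sub = seq[start:end]
                    if strand == "-":
                        sub = reverse_complement(sub)
                    try:
                        aa = translate(sub)
                    except TranslationError:
                        continue
                contig.cds_orfs.append(
                    Orf(contig_id=contig.id, start=start, end=end,
                        strand=strand, aa_sequence=aa))
        contigs.append(contig)
    return contigs


def _frame_orfs(seq: str, frame: int, contig_id: str, strand: str,
                seqlen: int, min_length_aa: int) -> list[Orf]:
    """Maximal start-to-stop ORFs in one frame of ``seq`` (already
    oriented); coordinates reported on the forward strand."""
    orfs: list[Orf] = []
    start_codon: int | None = None
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if start_codon is None:
            if codon == "ATG":
                start_codon = i
        elif codon in _STOPS:
            aa_len = (i - start_codon) // 3
            if aa_len >= min_length_aa:
                if strand == "+":
                    s, e = start_codon, i + 3
                else:
                    s, e = seqlen - (i + 3), seqlen - start_codon
                orfs.append(Orf(
                    contig_id=contig_id, start=s, end=e, strand=strand,
                    aa_sequence=translate(seq[start_codon:i + 3])))
            start_codon = None
        i += 3
    return orfs


def find_orfs(contig: Contig, min_length_aa: int = 60) -> list[Orf]:
    """All maximal ATG-to-stop frames on both strands, length-filtered.

    Returns ORFs sorted by forward-strand start coordinate.
    """
    if min_length_aa < 1:
        raise ValueError("min_length_aa must be >= 1")
    seq = contig.sequence
    rc = reverse_complement(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        orfs += _frame_orfs(seq, frame, contig.id, "+", len(seq),
                            min_length_aa)
        orfs += _frame_orfs(rc, frame, contig.id, "-", len(seq),
                            min_length_aa)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orf_nucleotides(contig: Contig, orf: Orf) -> str:
    """The coding-strand nucleotide sequence of an ORF."""
    sub = contig.sequence[orf.start:orf.end]
    return reverse_complement(sub) if orf.strand == "-" else sub
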