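"""Sequence I/O, six-frame translation and the GYG exhaustiveness scan.

Protein and genome records are small frozen containers validated on
construction.  FASTA reading/writing is delegated to Biopython; a thin
pre-scan provides line-numbered errors for malformed files.

The GYG scan reproduces a whole-genome exhaustiveness check for K+
channels: every open reading frame (stop-to-stop, in all six reading
frames) is searched for the canonical selectivity-filter tripeptide
G-Y-G, and each hit is reported with forward-strand DNA coordinates and
a peptide context window for human inspection.  No automated channel
call is made from DNA hits.

Coordinates are 0-based half-open throughout the library; report
writers convert to 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
DNA_ALPHABET = set("ACGTN")

#: codon -> amino acid, standard genetic code (translation table 1)
_CODON_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _CODON_TABLE[_stop] = "*"

FRAMES = (1, 2, 3, -1, -2, -3)


class FastaParseError(ValueError):
    pass


class SequenceValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A named, species-tagged amino-acid sequence."""

    id: str
    species: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise SequenceValidationError(f"protein {self.id!r}: empty sequence")
        for pos, letter in enumerate(self.sequence):
            if letter not in PROTEIN_ALPHABET:
                raise SequenceValidationError(
                    f"protein {self.id!r}: disallowed character {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """A genomic DNA sequence over {A, C, G, T, N}."""

    id: str
    species: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise SequenceValidationError(f"genome {self.id!r}: empty sequence")
        for pos, letter in enumerate(self.sequence):
            if letter not in DNA_ALPHABET:
                raise SequenceValidationError(
                    f"genome {self.id!r}: disallowed character {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GygCandidate:
    """One G-Y-G occurrence inside an ORF of a six-frame translation.

    ``orf_start``/``orf_end`` are peptide coordinates within the frame
    translation; ``gyg_offset`` is the offset of the tripeptide within
    the ORF; ``dna_start``/``dna_end`` delimit the context peptide on
    the forward strand.
    """

    genome_id: str
    frame: int
    orf_start: int
    orf_end: int
    gyg_offset: int
    dna_start: int
    dna_end: int
    context: str


def _check_fasta_shape(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"line {lineno}: sequence data before any FASTA header ('>')"
            )
        return


def read_fasta(path, species_tag: str, kind: str = "protein"):
    """Read a FASTA file into ProteinRecord or GenomeRecord objects.

    Record ids are the first whitespace-delimited token of each header;
    duplicate ids raise an error.  ``kind`` selects the record type
    ("protein" or "genome").
    """
    with open(path) as handle:
        text = handle.read()
    _check_fasta_shape(text)
    cls = ProteinRecord if kind == "protein" else GenomeRecord
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if kind == "protein":
            records.append(
                ProteinRecord(
                    id=rec.id,
                    species=species_tag,
                    sequence=str(rec.seq),
                    description=rec.description[len(rec.id):].strip(),
                )
            )
        else:
            records.append(GenomeRecord(id=rec.id, species=species_tag, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write records as FASTA, 60-column wrapped."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=getattr(r, "description", "") or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def _translate(dna: str) -> str:
    """Translate a forward-oriented DNA string; trailing 1-2 nt ignored.

    Codons containing any non-ACGT letter translate to X (conservative:
    no ambiguity resolution), stop codons to '*'.
    """
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_RC)[::-1]


def six_frame_translate(genome: GenomeRecord) -> dict:
    """Translate all six reading frames; keys +1,+2,+3,-1,-2,-3.

    Frames +k translate the forward strand from offset k-1; frames -k
    translate the reverse complement from offset k-1 (standard code,
    stops as '*').
    """
    if len(genome) < 3:
        raise ValueError("genome shorter than one codon")
    fwd = genome.sequence
    rev = reverse_complement(fwd)
    return {
        1: _translate(fwd),
        2: _translate(fwd[1:]),
        3: _translate(fwd[2:]),
        -1: _translate(rev),
        -2: _translate(rev[1:]),
        -3: _translate(rev[2:]),
    }


def find_orfs(frame_peptide: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal stop-free runs (stop-to-stop ORFs, no ATG requirement).

    Returns 0-based half-open (start, end) segments of length >= min_len,
    sorted by start.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs = []
    start = 0
    for i, aa in enumerate(frame_peptide):
        if aa == "*":
            if i - start >= min_len:
                orfs.append((start, i))
            start = i + 1
    if len(frame_peptide) - start >= min_len:
        orfs.append((start, len(frame_peptide)))
    return orfs


def _peptide_to_dna(frame: int, pep_start: int, pep_end: int, genome_len: int) -> tuple[int, int]:
    """Forward-strand DNA span of a peptide slice in the given frame."""
    offset = abs(frame) - 1
    if frame > 0:
        return offset + 3 * pep_start, offset + 3 * pep_end
    # peptide lives on the reverse complement; map back to forward strand
    rc_start = offset + 3 * pep_start
    rc_end = offset + 3 * pep_end
    return genome_len - rc_end, genome_len - rc_start


def scan_gyg(
    genome: GenomeRecord, min_orf_len: int = 50, context_window: int = 40
) -> list[GygCandidate]:
    """Report every GYG tripeptide inside every qualifying ORF, all frames.

    Output order is deterministic: frame (+1,+2,+3,-1,-2,-3), then
    position.  The context is up to ``context_window`` residues on each
    side of the tripeptide, truncated at the ORF bounds; dna coordinates
    delimit the context peptide on the forward strand.
    """
    if context_window < 0:
        raise ValueError("context_window must be >= 0")
    frames = six_frame_translate(genome)
    candidates = []
    for frame in FRAMES:
        peptide = frames[frame]
        for orf_start, orf_end in find_orfs(peptide, min_orf_len):
            orf = peptide[orf_start:orf_end]
            pos = orf.find("GYG")
            while pos != -1:
                ctx_start = orf_start + max(0, pos - context_window)
                ctx_end = orf_start + min(len(orf), pos + 3 + context_window)
                dna_start, dna_end = _peptide_to_dna(frame, ctx_start, ctx_end, len(genome))
                candidates.append(
                    GygCandidate(
                        genome_id=genome.id,
                        frame=frame,
                        orf_start=orf_start,
                        orf_end=orf_end,
                        gyg_offset=pos,
                        dna_start=dna_start,
                        dna_end=dna_end,
                        context=peptide[ctx_start:ctx_end],
                    )
                )
                pos = orf.find("GYG", pos + 1)
    return candidates


def retranslate_candidate(genome: GenomeRecord, cand: GygCandidate) -> str:
    """Translate the reported DNA slice in the reported frame (invariant check)."""
    dna = genome.sequence[cand.dna_start : cand.dna_end]
    if cand.frame < 0:
        dna = reverse_complement(dna)
    return _translate(dna)
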