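"""Antigen protein sequences, point substitutions, and k-mer peptide windows.

Coordinates are 1-based inclusive throughout the package: residue 1 is the
first residue of the protein, and a window with ``start=s`` and length ``k``
covers residues ``s .. s+k-1``.  Every writer that emits positions documents
this convention in its header.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import (
    EmptyInputError,
    FastaFormatError,
    HgvsParseError,
    ReferenceMismatchError,
    ValidationError,
)

#: The 20 standard one-letter amino-acid codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues tolerated beyond the standard alphabet.  'X' (unknown) is accepted
#: but flagged on windows so the binding layer can skip it.
AA_AMBIGUOUS = frozenset("X")

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_HGVS_P_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


@dataclass(frozen=True)
class ProteinSequence:
    """An antigen protein sequence.

    Parameters
    ----------
    id
        Text identifier (FASTA header word or allele name).
    residues
        One-letter amino-acid string, uppercase.  The 20 standard residues
        plus 'X' are accepted; gaps are rejected because antigen references
        are ungapped.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r}: length must be >= 1")
        allowed = AA_ALPHABET | AA_AMBIGUOUS
        bad = sorted({c for c in self.residues if c not in allowed})
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains non-amino-acid characters: {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} outside sequence {self.id!r} (1..{self.length})"
            )
        return self.residues[position - 1]

    def slice(self, start: int, k: int) -> str:
        """Residues ``start .. start+k-1`` (1-based inclusive)."""
        if start < 1 or start + k - 1 > self.length:
            raise ValidationError(
                f"window {start}..{start + k - 1} outside sequence "
                f"{self.id!r} (1..{self.length})"
            )
        return self.residues[start - 1 : start - 1 + k]


@dataclass(frozen=True)
class ProteinVariant:
    """A single amino-acid substitution in HGVS p. terms (e.g. p.Val270Gly)."""

    ref_residue: str
    position: int
    alt_residue: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.position}")
        if self.ref_residue == self.alt_residue:
            raise ValidationError(
                f"variant {self.label or self!r}: reference and alternate residues are equal"
            )
        for r in (self.ref_residue, self.alt_residue):
            if r not in AA_ALPHABET:
                raise ValidationError(f"unknown residue code {r!r}")

    def inverse(self) -> "ProteinVariant":
        """The substitution that undoes this one."""
        return ProteinVariant(
            ref_residue=self.alt_residue,
            position=self.position,
            alt_residue=self.ref_residue,
            label=f"p.{ONE_TO_THREE[self.alt_residue]}{self.position}"
            f"{ONE_TO_THREE[self.ref_residue]}",
        )


@dataclass(frozen=True)
class PeptideWindow:
    """A k-mer peptide core at a 1-based start position of its antigen."""

    antigen_id: str
    start: int
    sequence: str
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"window start must be >= 1, got {self.start}")
        if not self.sequence:
            raise ValidationError("window sequence must be non-empty")

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """Last covered residue, 1-based inclusive."""
        return self.start + self.k - 1


def parse_hgvs_p(label: str) -> ProteinVariant:
    """Parse a protein-level HGVS substitution label.

    Only the simple substitution form ``p.<Aaa><N><Bbb>`` with three-letter
    codes is supported (e.g. ``p.Val270Gly`` -> V270G).  Indels, frameshifts
    and nucleotide-level labels are out of scope.
    """
    m = _HGVS_P_RE.match(label.strip())
    if not m:
        raise HgvsParseError(f"not a p.<Aaa><N><Bbb> substitution label: {label!r}")
    ref3, pos, alt3 = m.groups()
    for code in (ref3, alt3):
        if code not in THREE_TO_ONE:
            raise HgvsParseError(f"unknown amino-acid code {code!r} in {label!r}")
    position = int(pos)
    if position < 1:
        raise HgvsParseError(f"non-positive position in {label!r}")
    ref1, alt1 = THREE_TO_ONE[ref3], THREE_TO_ONE[alt3]
    if ref1 == alt1:
        raise HgvsParseError(f"reference equals alternate in {label!r}")
    return ProteinVariant(ref_residue=ref1, position=position, alt_residue=alt1, label=label)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record protein FASTA file.

    Sequences are uppercased; record order is preserved.  An empty file
    raises :class:`EmptyInputError`; non-FASTA content (no ``>`` headers, or
    residues outside the amino-acid alphabet such as digits or gaps) raises
    :class:`FastaFormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: content does not start with a FASTA '>' header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def apply_variants(
    seq: ProteinSequence, variants: list[ProteinVariant], new_id: str | None = None
) -> ProteinSequence:
    """Apply point substitutions to a sequence, returning a new sequence.

    Each variant's stated reference residue must match the sequence at its
    position; a disagreement raises :class:`ReferenceMismatchError` naming
    the position and both residues.  The input sequence is not modified.
    """
    residues = list(seq.residues)
    for v in variants:
        if v.position > seq.length:
            raise ValidationError(
                f"variant {v.label or v!r} position {v.position} beyond "
                f"sequence length {seq.length}"
            )
        observed = residues[v.position - 1]
        if observed != v.ref_residue:
            raise ReferenceMismatchError(
                f"variant {v.label or v!r} at position {v.position}: expected "
                f"reference {v.ref_residue!r} but sequence {seq.id!r} has {observed!r}"
            )
        residues[v.position - 1] = v.alt_residue
    return ProteinSequence(id=new_id or seq.id, residues="".join(residues))


def enumerate_peptides(
    seq: ProteinSequence, k: int = 9, short_policy: str = "warn"
) -> list[PeptideWindow]:
    """Enumerate all k-mer windows of a sequence, in ascending start order.

    Returns exactly ``length - k + 1`` windows.  Windows containing 'X' are
    enumerated but flagged so downstream binding code can skip them.  A
    sequence shorter than ``k`` yields an empty list with a warning, or an
    error when ``short_policy='error'``.
    """
    if k < 1:
        raise ValidationError(f"window length k must be >= 1, got {k}")
    if seq.length < k:
        msg = f"sequence {seq.id!r} shorter than k={k}: no windows"
        if short_policy == "error":
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
        return []
    out = []
    for start in range(1, seq.length - k + 2):
        pep = seq.slice(start, k)
        out.append(
            PeptideWindow(
                antigen_id=seq.id,
                start=start,
                sequence=pep,
                flagged=any(c in AA_AMBIGUOUS for c in pep),
            )
        )
    return out


def write_windows_tsv(windows: list[PeptideWindow], path: str | Path) -> None:
    """Write windows as TSV: antigen_id, start, k, sequence (1-based inclusive starts)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# peptide windows; start is 1-based inclusive\n")
        fh.write("antigen_id\tstart\tk\tsequence\n")
        for w in windows:
            fh.write(f"{w.antigen_id}\t{w.start}\t{w.k}\t{w.sequence}\n")
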