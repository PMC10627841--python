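"""Nucleotide sequence model, IUPAC degeneracy semantics, and FASTA I/O.

The sequence alphabet is the 15 IUPAC nucleotide codes plus the gap character
``-``.  Input is uppercased on ingest and ``U`` is normalised to ``T``; any
other character is rejected immediately so that malformed input cannot reach
the consensus or design stages.  The gap dialect is ``-`` only (``.`` is
rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FastaFormatError

GAP = "-"

#: IUPAC degenerate code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Base-wise complement; degenerate codes map to the code of the
#: complemented set (R={A,G} -> Y={T,C}, etc.).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", GAP: GAP,
}

_ALPHABET = frozenset(IUPAC_SETS) | {GAP}


def _normalise(raw: str) -> str:
    out = raw.upper().replace("U", "T")
    bad = set(out) - _ALPHABET
    if bad:
        raise AlphabetError(
            f"character(s) {sorted(bad)!r} outside the IUPAC nucleotide "
            f"alphabet (gap is '-'; '.' is not accepted)"
        )
    return out


@dataclass
class NucSeq:
    """A (possibly gapped) nucleotide sequence with a free-text identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = _normalise(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def is_gapped(self) -> bool:
        return GAP in self.residues

    def degap(self) -> "NucSeq":
        return NucSeq(self.id, self.residues.replace(GAP, ""))


def iupac_matches(code: str, base: str) -> bool:
    """True iff concrete ``base`` is in the set denoted by IUPAC ``code``.

    ``code`` may be degenerate; ``base`` must be one of A/C/G/T.
    """
    code = code.upper()
    base = base.upper()
    if code not in IUPAC_SETS:
        raise AlphabetError(f"unknown IUPAC code {code!r}")
    if base not in "ACGT" or len(base) != 1:
        raise AlphabetError(f"base must be a concrete A/C/G/T, got {base!r}")
    return base in IUPAC_SETS[code]


def reverse_complement(seq: NucSeq | str) -> NucSeq:
    """Base-wise complement in reverse order; degenerate codes complement
    to the code of the complemented set.  Gapped input is rejected."""
    if isinstance(seq, str):
        seq = NucSeq("seq", seq)
    if seq.is_gapped:
        raise AlphabetError(f"sequence {seq.id!r} contains gaps; degap first")
    rc = "".join(COMPLEMENT[c] for c in reversed(seq.residues))
    return NucSeq(seq.id, rc)


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read all records of a FASTA file.

    Record ids are the first whitespace-delimited token of the header.
    Raises :class:`FastaFormatError` (with a line number) on an empty file or
    a file whose first non-blank line is not a ``>`` header.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if first is None:
        raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
    if not lines[first].startswith(">"):
        raise FastaFormatError(
            f"{path}: expected '>' header at line {first + 1}, "
            f"got {lines[first].strip()[:30]!r}"
        )
    records = list(SeqIO.parse(str(path), "fasta"))
    return [NucSeq(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class DegeneratePrimer:
    """An oligonucleotide given 5'->3', possibly with IUPAC degenerate codes.

    Whitespace inside the sequence string (the conventional triplet grouping
    of primer tables) is stripped on ingest.  A sanity floor of 10 bases
    guards against truncated table parses.
    """

    name: str
    sequence5to3: NucSeq
    orientation: str = "forward"  # {"forward", "reverse"}

    MIN_LENGTH = 10

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.sequence5to3.is_gapped:
            raise AlphabetError(f"primer {self.name!r} contains gap characters")
        if len(self.sequence5to3) < self.MIN_LENGTH:
            raise ValueError(
                f"primer {self.name!r} has {len(self.sequence5to3)} bases; "
                f"minimum is {self.MIN_LENGTH} (suspected parse error)"
            )

    @classmethod
    def from_string(cls, name: str, sequence: str, orientation: str = "forward") -> "DegeneratePrimer":
        cleaned = "".join(sequence.split())
        return cls(name, NucSeq(name, cleaned), orientation)

    def __len__(self) -> int:
        return len(self.sequence5to3)


# ---------------------------------------------------------------------------
# Primer tables

PRIMER_TABLE_COLUMNS = [
    "gene", "primer_name_f", "primer_seq_f", "primer_name_r", "primer_seq_r",
]


def read_primer_table(path: str | Path) -> dict[str, tuple[DegeneratePrimer, DegeneratePrimer]]:
    """Read a primer CSV (columns gene, primer_name_f, primer_seq_f,
    primer_name_r, primer_seq_r; extra columns are ignored) into a mapping
    gene -> (forward primer, reverse primer)."""
    df = pd.read_csv(path)
    missing = [c for c in PRIMER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"primer table {path} lacks column(s) {missing}")
    out: dict[str, tuple[DegeneratePrimer, DegeneratePrimer]] = {}
    for _, row in df.iterrows():
        fwd = DegeneratePrimer.from_string(row["primer_name_f"], row["primer_seq_f"], "forward")
        rev = DegeneratePrimer.from_string(row["primer_name_r"], row["primer_seq_r"], "reverse")
        out[str(row["gene"])] = (fwd, rev)
    return out


def bundled_primer_path() -> Path:
    """Path of the primer table shipped with the package (one row per
    commonly assayed phylogenetic/functional gene)."""
    return Path(__file__).parent / "data" / "primers.csv"


def bundled_primers() -> dict[str, tuple[DegeneratePrimer, DegeneratePrimer]]:
    return read_primer_table(bundled_primer_path())
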