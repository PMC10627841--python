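"""Locate degenerate primer pairs on a consensus, assemble the synthetic
fragment with flanking ends, and validate it against synthesis constraints.

A primer position matches a consensus base when the concrete base is a member
of the IUPAC set the primer code denotes; a hit is any window whose mismatch
count stays within the budget (default 2).  The fragment is the amplicon plus
flanking consensus bases on each side (default 20, within the recommended
9-30 range), and must fall inside the 125-3,000 bp synthesis window of
commercial double-stranded fragments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import ConsensusResult
from .errors import AmpstdError, DesignError
from .sequences import (
    DegeneratePrimer,
    IUPAC_SETS,
    NucSeq,
    reverse_complement,
    write_fasta,
)

#: Orderable synthesis length window (bp) for double-stranded gene fragments.
MIN_SYNTHESIS_LENGTH = 125
MAX_SYNTHESIS_LENGTH = 3000

#: Recommended per-side flanking-end range (bp) outside the primer sites.
FLANK_RANGE = (9, 30)


@dataclass
class PrimerHit:
    """One placement of a (degenerate) primer on the consensus plus strand.

    For ``strand == "minus"`` the reverse complement of the primer was
    scanned, so ``target_window`` is the plus-strand sequence the reverse
    primer's binding site occupies.
    """

    primer: DegeneratePrimer
    strand: str  # {"plus", "minus"}
    start: int  # 0-based half-open on the consensus plus strand
    end: int
    mismatches: int
    target_window: str


@dataclass
class AmpliconDesign:
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    amplicon_start: int
    amplicon_end: int

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    @property
    def total_mismatches(self) -> int:
        return self.forward_hit.mismatches + self.reverse_hit.mismatches


@dataclass
class FragmentDesign:
    amplicon: AmpliconDesign
    flank5: int  # applied (possibly truncated) flank lengths
    flank3: int
    sequence: NucSeq
    total_length: int
    valid: bool
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    gene: str = ""


def _consensus_residues(consensus: ConsensusResult | NucSeq | str) -> str:
    if isinstance(consensus, ConsensusResult):
        residues = consensus.sequence.residues
    elif isinstance(consensus, NucSeq):
        residues = consensus.residues
    else:
        residues = NucSeq("consensus", consensus).residues
    bad = set(residues) - set("ACGT")
    if bad:
        raise AmpstdError(
            f"consensus must be A/C/G/T only; found {sorted(bad)!r}"
        )
    return residues


def count_mismatches(pattern: str, window: str) -> int:
    """Positions where the concrete window base is outside the pattern
    code's IUPAC set."""
    return sum(
        1 for p, b in zip(pattern, window) if b not in IUPAC_SETS[p]
    )


def find_primer_hits(
    consensus: ConsensusResult | NucSeq | str,
    primer: DegeneratePrimer,
    max_mismatches: int = 2,
    strand: str = "plus",
) -> list[PrimerHit]:
    """Scan every window of primer length on the requested strand and return
    hits within the mismatch budget, sorted by (mismatches, start).

    Minus-strand scanning slides ``reverse_complement(primer)`` along the
    plus strand, which is how a reverse primer's binding site appears on the
    consensus.
    """
    residues = _consensus_residues(consensus)
    if strand not in ("plus", "minus"):
        raise ValueError(f"strand must be plus/minus, got {strand!r}")
    if len(primer) > len(residues):
        raise AmpstdError(
            f"primer {primer.name!r} ({len(primer)} nt) is longer than the "
            f"consensus ({len(residues)} nt)"
        )
    pattern = primer.sequence5to3.residues
    if strand == "minus":
        pattern = reverse_complement(primer.sequence5to3).residues
    L = len(pattern)
    hits = []
    for start in range(len(residues) - L + 1):
        window = residues[start:start + L]
        mm = count_mismatches(pattern, window)
        if mm <= max_mismatches:
            hits.append(
                PrimerHit(primer, strand, start, start + L, mm, window)
            )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def design_amplicon(
    consensus: ConsensusResult | NucSeq | str,
    forward: DegeneratePrimer,
    reverse: DegeneratePrimer,
    max_mismatches: int = 2,
    expected_size_range: tuple[int, int] | None = None,
) -> AmpliconDesign:
    """Pick the best (forward, reverse) primer placement pair.

    Both primers are given 5'->3' as printed in primer tables (the reverse
    primer is the reverse-strand oligo).  Among pairs with the forward hit
    upstream of the reverse hit, the pair with the fewest total mismatches
    wins; ties go to the amplicon length closest to the midpoint of
    ``expected_size_range`` (when given), then to the leftmost start.
    """
    fhits = find_primer_hits(consensus, forward, max_mismatches, "plus")
    if not fhits:
        raise DesignError(
            f"forward primer {forward.name!r} has no site within "
            f"{max_mismatches} mismatches"
        )
    rhits = find_primer_hits(consensus, reverse, max_mismatches, "minus")
    if not rhits:
        raise DesignError(
            f"reverse primer {reverse.name!r} has no site within "
            f"{max_mismatches} mismatches"
        )
    pairs = [
        (f, r) for f in fhits for r in rhits if f.end <= r.start
    ]
    if not pairs:
        raise DesignError(
            f"no forward/reverse arrangement with {forward.name!r} upstream "
            f"of {reverse.name!r}"
        )

    if expected_size_range is not None:
        mid = sum(expected_size_range) / 2
    else:
        mid = None

    def key(pair: tuple[PrimerHit, PrimerHit]):
        f, r = pair
        length = r.end - f.start
        size_pref = abs(length - mid) if mid is not None else 0.0
        return (f.mismatches + r.mismatches, size_pref, f.start, r.start)

    f, r = min(pairs, key=key)
    return AmpliconDesign(f, r, f.start, r.end)


def assemble_fragment(
    consensus: ConsensusResult | NucSeq | str,
    amplicon: AmpliconDesign,
    flank5: int = 20,
    flank3: int = 20,
    gene: str = "",
) -> FragmentDesign:
    """Extend the amplicon with flanking consensus bases and validate it.

    Flanks are truncated to the available consensus (recorded as a warning,
    not a violation).  Violations are raised for a total length outside the
    synthesis window [125, 3000] bp and for a *requested* flank outside the
    recommended [9, 30] range.
    """
    residues = _consensus_residues(consensus)
    if flank5 < 0 or flank3 < 0:
        raise AmpstdError("flank lengths must be >= 0")
    if not (0 <= amplicon.amplicon_start <= amplicon.amplicon_end <= len(residues)):
        raise AmpstdError("amplicon coordinates outside the consensus")

    warnings: list[str] = []
    applied5 = min(flank5, amplicon.amplicon_start)
    applied3 = min(flank3, len(residues) - amplicon.amplicon_end)
    if applied5 < flank5:
        warnings.append(
            f"5' flank truncated from {flank5} to {applied5} (consensus edge)"
        )
    if applied3 < flank3:
        warnings.append(
            f"3' flank truncated from {flank3} to {applied3} (consensus edge)"
        )
    start = amplicon.amplicon_start - applied5
    end = amplicon.amplicon_end + applied3
    seq = residues[start:end]
    total = len(seq)

    violations: list[str] = []
    if total < MIN_SYNTHESIS_LENGTH:
        violations.append(
            f"below minimum synthesis length {MIN_SYNTHESIS_LENGTH} bp "
            f"(got {total})"
        )
    if total > MAX_SYNTHESIS_LENGTH:
        violations.append(
            f"above maximum synthesis length {MAX_SYNTHESIS_LENGTH} bp "
            f"(got {total})"
        )
    lo, hi = FLANK_RANGE
    for label, requested in (("5'", flank5), ("3'", flank3)):
        if not lo <= requested <= hi:
            violations.append(
                f"requested {label} flank of {requested} bases outside the "
                f"recommended [{lo}, {hi}] range"
            )

    name = f"{gene}_standard" if gene else "standard"
    return FragmentDesign(
        amplicon=amplicon,
        flank5=applied5,
        flank3=applied3,
        sequence=NucSeq(name, seq),
        total_length=total,
        valid=not violations,
        violations=violations,
        warnings=warnings,
        gene=gene,
    )


def _hit_record(hit: PrimerHit) -> dict:
    # reports use 1-based inclusive coordinates
    return {
        "primer": hit.primer.name,
        "strand": hit.strand,
        "start": hit.start + 1,
        "end": hit.end,
        "mismatches": hit.mismatches,
        "site": hit.target_window,
    }


def design_report(designs: list[FragmentDesign]) -> dict:
    """Machine-readable report (deterministic field order) over one or more
    fragment designs, with the fragment sequences included."""
    if not designs:
        raise AmpstdError("design_report needs at least one design")
    genes = []
    for d in designs:
        genes.append({
            "gene": d.gene or d.sequence.id,
            "forward": _hit_record(d.amplicon.forward_hit),
            "reverse": _hit_record(d.amplicon.reverse_hit),
            "amplicon_length": d.amplicon.amplicon_length,
            "flank5": d.flank5,
            "flank3": d.flank3,
            "fragment_length": d.total_length,
            "valid": d.valid,
            "violations": list(d.violations),
            "warnings": list(d.warnings),
            "fragment_sequence": d.sequence.residues,
        })
    return {"designs": genes}


def write_design_outputs(
    designs: list[FragmentDesign],
    fasta_path: str | Path | None = None,
    json_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> dict:
    report = design_report(designs)
    if fasta_path:
        write_fasta([d.sequence for d in designs], fasta_path)
    if json_path:
        Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
    if tsv_path:
        lines = ["gene\tforward\treverse\tamplicon_bp\tfragment_bp\tvalid\tviolations"]
        for g in report["designs"]:
            lines.append(
                "\t".join([
                    g["gene"], g["forward"]["primer"], g["reverse"]["primer"],
                    str(g["amplicon_length"]), str(g["fragment_length"]),
                    str(g["valid"]).lower(), "; ".join(g["violations"]),
                ])
            )
        Path(tsv_path).write_text("\n".join(lines) + "\n")
    return report
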