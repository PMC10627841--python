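"""Global alignment with free end gaps, progressive multiple alignment, and
majority-rule consensus calling.

This module reconstructs the consensus-design stage of the synthetic-standard
workflow: 10-20 homologous gene sequences are globally aligned under affine
gap penalties with unpenalised terminal gaps (appropriate for homologs of
unequal extent), and a strict A/C/G/T consensus is called column by column.

The aligner is a Gotoh three-state dynamic program generalised to
sequence-vs-profile alignment so the same kernel serves both pairwise
alignment and center-star progressive alignment with iterative refinement.

Scoring model
-------------
* substitution: ``match_score`` on character identity, else ``mismatch_score``
  (defaults +5 / -4, a conventional nucleotide matrix tolerant of ~65%
  identity between diverged homologs);
* a gap run of length L costs ``gap_open + (L - 1) * gap_extend``
  (defaults 12 / 3);
* with ``free_end_gaps`` (default), terminal gap runs in either sequence
  cost nothing;
* a profile column is scored against a residue as the arithmetic mean of the
  per-row substitution scores, with gap rows contributing ``mismatch_score``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AmpstdError
from .sequences import GAP, IUPAC_SETS, NucSeq, reverse_complement

_CHARS = "ACGTRYSWKMBDHVN" + GAP
_IDX = {c: i for i, c in enumerate(_CHARS)}
_NEG = -1e30


@dataclass
class AlignParams:
    """Alignment scoring parameters (defaults mirror the published settings:
    gap open 12, gap extension 3, free end gaps, 2 refinement iterations)."""

    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 3.0
    free_end_gaps: bool = True
    refinement_iterations: int = 2

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.refinement_iterations < 0:
            raise ValueError("refinement_iterations must be >= 0")


@dataclass
class Alignment:
    """A multiple alignment: equal-length gapped rows."""

    rows: list[NucSeq]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AmpstdError("alignment has no rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise AmpstdError(f"ragged alignment: row lengths {sorted(widths)}")

    @property
    def names(self) -> list[str]:
        return [r.id for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)


@dataclass
class ConsensusResult:
    """Majority-rule A/C/G/T-only consensus of an alignment.

    ``column_counts`` holds, per retained consensus position, the (possibly
    fractional, see :func:`call_consensus`) A/C/G/T counts and the gap count;
    ``source_columns`` maps each consensus base back to its alignment column.
    """

    sequence: NucSeq
    column_counts: np.ndarray  # shape (L, 5): A, C, G, T, gap
    source_columns: np.ndarray  # shape (L,)
    n_sequences: int

    def __len__(self) -> int:
        return len(self.sequence)

    def counts_frame(self, dropped: "pd.DataFrame | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(self.column_counts, columns=["A", "C", "G", "T", "gap"])
        df.insert(0, "column", self.source_columns)
        df["called_base"] = list(self.sequence.residues)
        df["kept"] = True
        return df


# ---------------------------------------------------------------------------
# Profile machinery


def _freq_matrix(rows: list[str]) -> np.ndarray:
    """Character frequencies per column, shape (n_cols, len(_CHARS))."""
    k = len(rows)
    n = len(rows[0])
    F = np.zeros((n, len(_CHARS)))
    cols = np.arange(n)
    for row in rows:
        codes = np.fromiter((_IDX[c] for c in row), dtype=np.intp, count=n)
        np.add.at(F, (cols, codes), 1.0)
    return F / k


def _align_seq_to_profile(
    F: np.ndarray, seq: str, p: AlignParams
) -> tuple[float, list[str]]:
    """Optimal free-end-gap affine alignment of ``seq`` against a profile.

    Returns (score, ops) where ops is a list over alignment columns:
    'M' consume profile column + residue, 'D' consume profile column against
    a gap in the sequence, 'I' insert a gap column into the profile for a
    residue of the sequence.
    """
    n = F.shape[0]
    m = len(seq)
    codes = np.fromiter((_IDX[c] for c in seq), dtype=np.intp, count=m)
    # mean per-row score: identity fraction scores match, everything else
    # (other residues and gap rows) scores mismatch
    S = p.mismatch_score + (p.match_score - p.mismatch_score) * F[:, codes]

    go, ge = p.gap_open, p.gap_extend
    free = p.free_end_gaps
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in sequence (consume profile)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in profile (consume residue)
    M[0, 0] = 0.0
    i_idx = np.arange(1, n + 1, dtype=float)
    j_idx = np.arange(1, m + 1, dtype=float)
    X[1:, 0] = 0.0 if free else -(go + (i_idx - 1) * ge)
    Y[0, 1:] = 0.0 if free else -(go + (j_idx - 1) * ge)

    karr = np.arange(m + 1) * ge
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        base = np.maximum(M[i - 1], Y[i - 1])
        X[i, 1:] = np.maximum(base[1:] - go, X[i - 1, 1:] - ge)
        if free:
            X[i, 0] = 0.0
            X[i, m] = max(prev_best[m], X[i, m])
        MX = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(MX + karr)
        Y[i, 1:] = run[:-1] - go - (j_idx - 1) * ge
        if free and i == n:
            best_row = np.maximum.accumulate(np.maximum(MX, Y[i]))
            Y[i, 1:] = np.maximum(Y[i, 1:], best_row[:-1])

    finals = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    state = max(("M", "X", "Y"), key=lambda s: (finals[s], s == "M", s == "X"))
    score = finals[state]

    # traceback
    eps = 1e-6
    ops: list[str] = []
    i, j = n, m
    while (i, j) != (0, 0):
        if state == "M":
            ops.append("M")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) < eps:
                    state = s
                    break
            else:  # pragma: no cover - numerical safety
                raise AmpstdError("traceback failure in M state")
        elif state == "X":
            ops.append("D")
            cost0 = free and (j == 0 or j == m)
            cands = (
                ("M", M[i - 1, j], 0.0 if cost0 else go),
                ("X", X[i - 1, j], 0.0 if cost0 else ge),
                ("Y", Y[i - 1, j], 0.0 if cost0 else go),
            )
            cur = X[i, j]
            i -= 1
            for s, val, cost in cands:
                if abs(val - cost - cur) < eps:
                    state = s
                    break
            else:  # pragma: no cover
                raise AmpstdError("traceback failure in X state")
        else:  # Y
            ops.append("I")
            cost0 = free and (i == 0 or i == n)
            cands = (
                ("M", M[i, j - 1], 0.0 if cost0 else go),
                ("X", X[i, j - 1], 0.0 if cost0 else go),
                ("Y", Y[i, j - 1], 0.0 if cost0 else ge),
            )
            cur = Y[i, j]
            j -= 1
            for s, val, cost in cands:
                if abs(val - cost - cur) < eps:
                    state = s
                    break
            else:  # pragma: no cover
                raise AmpstdError("traceback failure in Y state")
    ops.reverse()
    return float(score), ops


def _apply_ops(rows: list[str], seq: str, ops: list[str]) -> list[str]:
    """Merge ``seq`` into the alignment ``rows`` according to traceback ops."""
    out_rows: list[list[str]] = [[] for _ in rows]
    new_row: list[str] = []
    i = j = 0
    for op in ops:
        if op == "M":
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            new_row.append(seq[j])
            i += 1
            j += 1
        elif op == "D":
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            new_row.append(GAP)
            i += 1
        else:  # I
            for r in out_rows:
                r.append(GAP)
            new_row.append(seq[j])
            j += 1
    assert i == len(rows[0]) and j == len(seq)
    return ["".join(r) for r in out_rows] + ["".join(new_row)]


def _drop_all_gap_columns(rows: list[str]) -> list[str]:
    keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
    return ["".join(r[j] for j in keep) for r in rows]


# ---------------------------------------------------------------------------
# Public operations


def pairwise_align(
    a: NucSeq, b: NucSeq, params: AlignParams | None = None
) -> tuple[Alignment, float]:
    """Optimal global alignment of two gap-free sequences.

    With ``params.free_end_gaps`` terminal overhangs are unpenalised
    (semi-global alignment); otherwise the alignment is fully global.
    """
    params = params or AlignParams()
    for s in (a, b):
        if len(s) == 0:
            raise AmpstdError(f"empty sequence {s.id!r}")
        if s.is_gapped:
            raise AmpstdError(f"sequence {s.id!r} is gapped; degap first")
    F = _freq_matrix([a.residues])
    score, ops = _align_seq_to_profile(F, b.residues, params)
    rows = _apply_ops([a.residues], b.residues, ops)
    aln = Alignment([NucSeq(a.id, rows[0]), NucSeq(b.id, rows[1])])
    return aln, score


def progressive_msa(
    seqs: list[NucSeq], params: AlignParams | None = None
) -> Alignment:
    """Center-star progressive multiple alignment with iterative refinement.

    The center is the sequence with the highest summed pairwise score against
    all others; remaining sequences join the profile in decreasing order of
    their score against the center.  ``params.refinement_iterations`` passes
    of leave-one-out row re-alignment follow.  Row order of the result matches
    the input order.
    """
    params = params or AlignParams()
    if len(seqs) < 2:
        raise AmpstdError("progressive_msa needs at least 2 sequences")
    for s in seqs:
        if len(s) == 0:
            raise AmpstdError(f"empty sequence {s.id!r}")
        if s.is_gapped:
            raise AmpstdError(f"sequence {s.id!r} is gapped; degap first")

    k = len(seqs)
    scores = np.zeros((k, k))
    for i in range(k):
        Fi = _freq_matrix([seqs[i].residues])
        for j in range(i + 1, k):
            sc, _ = _align_seq_to_profile(Fi, seqs[j].residues, params)
            scores[i, j] = scores[j, i] = sc
    center = int(np.argmax(scores.sum(axis=1)))
    order = sorted(
        (j for j in range(k) if j != center),
        key=lambda j: (-scores[center, j], j),
    )

    rows = [seqs[center].residues]
    row_ids = [center]
    for j in order:
        F = _freq_matrix(rows)
        _, ops = _align_seq_to_profile(F, seqs[j].residues, params)
        rows = _apply_ops(rows, seqs[j].residues, ops)
        row_ids.append(j)

    for _ in range(params.refinement_iterations):
        for r in range(len(rows)):
            held = rows[r].replace(GAP, "")
            rest = _drop_all_gap_columns(rows[:r] + rows[r + 1:])
            F = _freq_matrix(rest)
            _, ops = _align_seq_to_profile(F, held, params)
            merged = _apply_ops(rest, held, ops)
            rows = merged[:r] + [merged[-1]] + merged[r:-1]

    rows = _drop_all_gap_columns(rows)
    by_input = {rid: row for rid, row in zip(row_ids, rows)}
    return Alignment([NucSeq(seqs[i].id, by_input[i]) for i in range(k)])


def auto_orient(seqs: list[NucSeq], params: AlignParams | None = None) -> list[NucSeq]:
    """Reverse-complement any homolog whose alignment score against the first
    sequence improves when flipped (guards against mixed-strand input)."""
    params = params or AlignParams()
    if not seqs:
        return []
    ref = seqs[0]
    out = [ref]
    for s in seqs[1:]:
        _, fwd = pairwise_align(ref, s, params)
        _, rev = pairwise_align(ref, reverse_complement(s), params)
        out.append(reverse_complement(s) if rev > fwd else s)
    return out


_BASE_ORDER = "ACGT"


def call_consensus(
    aln: Alignment, gap_fraction_max: float = 0.5
) -> ConsensusResult:
    """Majority-rule A/C/G/T consensus of an alignment.

    Degenerate residues contribute fractionally: a code denoting k bases adds
    1/k to each member base's count.  Columns whose gap fraction exceeds
    ``gap_fraction_max`` are dropped (their alignment indices are simply
    absent from ``source_columns``); elsewhere gaps are ignored and the
    concrete base with the highest count is called, ties broken
    alphabetically A < C < G < T.
    """
    if len(aln.rows) == 0 or aln.width == 0:
        raise AmpstdError("cannot call a consensus on an empty alignment")
    if not 0.0 <= gap_fraction_max <= 1.0:
        raise ValueError("gap_fraction_max must be in [0, 1]")
    k = len(aln.rows)
    counts = []
    sources = []
    bases = []
    for j in range(aln.width):
        col = aln.column(j)
        n_gap = col.count(GAP)
        if n_gap / k > gap_fraction_max:
            continue
        acgt = np.zeros(4)
        for c in col:
            if c == GAP:
                continue
            members = IUPAC_SETS[c]
            w = 1.0 / len(members)
            for b in members:
                acgt[_BASE_ORDER.index(b)] += w
        best = int(np.argmax(acgt))  # argmax takes the first max: A<C<G<T
        bases.append(_BASE_ORDER[best])
        counts.append([*acgt, float(n_gap)])
        sources.append(j)
    if not bases:
        raise AmpstdError("every column exceeded the gap fraction threshold")
    return ConsensusResult(
        sequence=NucSeq("consensus", "".join(bases)),
        column_counts=np.asarray(counts),
        source_columns=np.asarray(sources, dtype=int),
        n_sequences=k,
    )
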