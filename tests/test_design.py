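"""Primer-site search, amplicon selection, and fragment assembly."""

import numpy as np
import pytest

from ampstd.design import (
    assemble_fragment,
    count_mismatches,
    design_amplicon,
    design_report,
    find_primer_hits,
)
from ampstd.errors import AmpstdError, DesignError
from ampstd.sequences import (
    DegeneratePrimer,
    IUPAC_SETS,
    NucSeq,
    bundled_primers,
    reverse_complement,
)

F_349 = DegeneratePrimer.from_string("349F", "AGG CAG CAG TDR GGA AT")
R_806 = DegeneratePrimer.from_string("806R", "GGA CTA CYV GGG TAT CTA AT", "reverse")


def brute_force_hits(consensus: str, pattern: str, budget: int):
    """Enumeration oracle: mismatch count of every window by direct
    set-membership test."""
    out = []
    for start in range(len(consensus) - len(pattern) + 1):
        window = consensus[start:start + len(pattern)]
        mm = sum(b not in IUPAC_SETS[p] for p, b in zip(pattern, window))
        if mm <= budget:
            out.append((mm, start))
    return sorted(out)


class TestFindPrimerHits:
    def test_degenerate_codes_match_member_bases(self):
        # the literal window realises D->T and R->A
        consensus = "T" * 10 + "AGGCAGCAGTTAGGAAT" + "T" * 10
        hits = find_primer_hits(consensus, F_349, max_mismatches=2)
        assert len(hits) == 1
        assert hits[0].mismatches == 0 and hits[0].start == 10

    def test_all_windows_over_budget(self):
        primer = DegeneratePrimer.from_string("pA", "AAAAAAAAAA")
        assert find_primer_hits("T" * 30, primer, max_mismatches=2) == []

    @pytest.mark.parametrize("n_mut,found", [(0, True), (2, True), (3, False)])
    def test_mutated_planted_site(self, n_mut, found):
        rng = np.random.default_rng(3)
        site = "AGGCAGCAGTTAGGAAT"
        mutated = list(site)
        # mutate positions where the primer code is concrete, to a base
        # outside the code's set
        concrete = [i for i, c in enumerate(F_349.sequence5to3.residues)
                    if len(IUPAC_SETS[c]) == 1]
        for i in rng.choice(concrete, size=n_mut, replace=False):
            bad = [b for b in "ACGT" if b not in IUPAC_SETS[F_349.sequence5to3.residues[i]]]
            mutated[i] = bad[0]
        consensus = "C" * 15 + "".join(mutated) + "C" * 15
        hits = find_primer_hits(consensus, F_349, max_mismatches=2)
        planted = [h for h in hits if h.start == 15]
        assert bool(planted) is found
        if planted:
            assert planted[0].mismatches == n_mut

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        primer = DegeneratePrimer.from_string("p", "ACGTRYSWKMAC")
        for _ in range(10):
            cons = "".join(rng.choice(list("ACGT"), size=60))
            hits = find_primer_hits(cons, primer, max_mismatches=4)
            expect = brute_force_hits(cons, primer.sequence5to3.residues, 4)
            assert [(h.mismatches, h.start) for h in hits] == expect
            assert all(h.mismatches <= 4 for h in hits)

    def test_minus_strand_scans_reverse_complement(self):
        rc = reverse_complement(R_806.sequence5to3).residues
        # make the planted site concrete
        concrete = "".join(sorted(IUPAC_SETS[c])[0] for c in rc)
        consensus = "G" * 12 + concrete + "G" * 12
        hits = find_primer_hits(consensus, R_806, max_mismatches=0, strand="minus")
        assert hits and hits[0].start == 12 and hits[0].strand == "minus"

    def test_primer_longer_than_consensus(self):
        with pytest.raises(AmpstdError):
            find_primer_hits("ACGTACGTAC", F_349)


def _toy_consensus(fwd: DegeneratePrimer, rev: DegeneratePrimer,
                   spacer: int = 150, flank: int = 20, seed: int = 0):
    rng = np.random.default_rng(seed)
    concretize = lambda s: "".join(
        c if c in "ACGT" else rng.choice(sorted(IUPAC_SETS[c])) for c in s
    )
    f_site = concretize(fwd.sequence5to3.residues)
    r_site = concretize(reverse_complement(rev.sequence5to3).residues)
    middle = "".join(rng.choice(list("ACGT"), size=spacer))
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + f_site + middle + r_site + right


class TestDesignAmplicon:
    def test_constructed_consensus_arithmetic(self):
        cons = _toy_consensus(F_349, R_806, spacer=150, flank=20)
        amp = design_amplicon(cons, F_349, R_806)
        assert amp.forward_hit.mismatches == 0
        assert amp.reverse_hit.mismatches == 0
        assert amp.amplicon_length == len(F_349) + 150 + len(R_806)
        assert amp.amplicon_start == 20

    def test_fewest_mismatches_beats_size_preference(self):
        # two reverse sites: near one at 1 mismatch, far one at 0 -> far wins
        rng = np.random.default_rng(1)
        fwd = DegeneratePrimer.from_string("f", "ACGTACGTACGT")
        rev = DegeneratePrimer.from_string("r", "TTTTGGGGCCCC", "reverse")
        r_site = reverse_complement(rev.sequence5to3).residues  # GGGGCCCCAAAA
        near = r_site[:-1] + ("C" if r_site[-1] != "C" else "G")  # 1 mismatch
        spacer1 = "".join(rng.choice(list("ACGT"), size=80))
        spacer2 = "".join(rng.choice(list("ACGT"), size=120))
        cons = "ACGTACGTACGT" + spacer1 + near + spacer2 + r_site
        amp = design_amplicon(cons, fwd, rev, expected_size_range=(80, 120))
        assert amp.reverse_hit.mismatches == 0
        assert amp.amplicon_end == len(cons)

    def test_missing_forward_site_names_primer(self):
        cons = _toy_consensus(F_349, R_806)
        absent = DegeneratePrimer.from_string("ghost", "AAAAAAAAAAAAAAAA")
        with pytest.raises(DesignError, match="ghost"):
            design_amplicon(cons, absent, R_806)


class TestAssembleFragment:
    def test_16s_row_length(self):
        # amplicon 460 bp with 19/19 flanks gives the printed 498 bp standard
        cons = _toy_consensus(F_349, R_806, spacer=460 - len(F_349) - len(R_806),
                              flank=25)
        amp = design_amplicon(cons, F_349, R_806)
        assert amp.amplicon_length == 460
        frag = assemble_fragment(cons, amp, flank5=19, flank3=19)
        assert frag.total_length == 498 and frag.valid

    def test_nosz_row_length(self):
        fwd, rev = bundled_primers()["nosZ"]
        cons = _toy_consensus(fwd, rev, spacer=249 - len(fwd) - len(rev), flank=35)
        amp = design_amplicon(cons, fwd, rev)
        assert amp.amplicon_length == 249
        frag = assemble_fragment(cons, amp, flank5=30, flank3=30)
        assert frag.total_length == 309 and frag.valid

    def test_below_minimum_synthesis_length(self):
        fwd = DegeneratePrimer.from_string("f", "ACGTACGTACGTACG")
        rev = DegeneratePrimer.from_string("r", "GGGCCCTTTAAAGGG", "reverse")
        cons = _toy_consensus(fwd, rev, spacer=100 - 2 * 15, flank=15)
        amp = design_amplicon(cons, fwd, rev)
        assert amp.amplicon_length == 100
        frag = assemble_fragment(cons, amp, flank5=9, flank3=9)
        assert frag.total_length == 118
        assert not frag.valid
        assert any("below minimum synthesis length 125" in v for v in frag.violations)

    def test_flank_truncation_is_warning_not_violation(self):
        cons = _toy_consensus(F_349, R_806, spacer=200, flank=10)
        amp = design_amplicon(cons, F_349, R_806)
        frag = assemble_fragment(cons, amp, flank5=20, flank3=20)
        assert frag.flank5 == 10 and frag.flank3 == 10
        assert frag.warnings and frag.valid

    def test_flank_outside_recommended_range_is_violation(self):
        cons = _toy_consensus(F_349, R_806, spacer=200, flank=40)
        amp = design_amplicon(cons, F_349, R_806)
        frag = assemble_fragment(cons, amp, flank5=35, flank3=20)
        assert not frag.valid
        assert any("recommended [9, 30]" in v for v in frag.violations)

    def test_length_conservation_and_containment(self):
        cons = _toy_consensus(F_349, R_806, spacer=300, flank=30)
        amp = design_amplicon(cons, F_349, R_806)
        frag = assemble_fragment(cons, amp, flank5=25, flank3=12)
        assert frag.total_length == amp.amplicon_length + frag.flank5 + frag.flank3
        amplicon_seq = cons[amp.amplicon_start:amp.amplicon_end]
        assert amplicon_seq in frag.sequence.residues
        # the fragment's amplicon window matches the forward primer in budget
        start = frag.flank5
        window = frag.sequence.residues[start:start + len(F_349)]
        assert sum(
            b not in IUPAC_SETS[p]
            for p, b in zip(F_349.sequence5to3.residues, window)
        ) <= 2


class TestDesignReport:
    def test_report_fields(self):
        cons = _toy_consensus(F_349, R_806, spacer=400, flank=25)
        amp = design_amplicon(cons, F_349, R_806)
        good = assemble_fragment(cons, amp, 20, 20, gene="16S")
        rep = design_report([good])
        (d,) = rep["designs"]
        assert d["valid"] is True and d["violations"] == []
        assert d["fragment_sequence"] == good.sequence.residues
        assert d["forward"]["start"] == amp.forward_hit.start + 1  # 1-based

    def test_violation_string_present(self):
        cons = _toy_consensus(F_349, R_806, spacer=400, flank=25)
        amp = design_amplicon(cons, F_349, R_806)
        bad = assemble_fragment(cons, amp, 0, 0, gene="16S")
        (d,) = design_report([bad])["designs"]
        assert d["valid"] is False
        assert any("recommended" in v for v in d["violations"])

    def test_count_mismatches_helper(self):
        assert count_mismatches("TDR", "TTA") == 0
        assert count_mismatches("TDR", "TCA") == 1
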