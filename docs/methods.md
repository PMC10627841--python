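# Methods

## Scope and model

`ampstd` covers the dry-lab half of establishing qPCR assays with synthetic
double-stranded DNA standards: consensus design from homologous gene
sequences, degenerate-primer placement and fragment assembly, copy-number
and standard-curve arithmetic, and the statistics used to compare
quantifications obtained with synthetic versus plasmid standards. Wet-lab
steps (cloning, thermocycling, melting-curve QC) and raw-fluorescence
processing are out of scope; Cq values are taken as instrument output.

## Alignment and consensus

Pairwise and progressive alignment share one Gotoh three-state dynamic
program over a sequence and a profile.

* **Scoring.** Substitutions score `match_score` (+5) on character identity
  and `mismatch_score` (−4) otherwise; this +5/−4 scheme is the
  conventional nucleotide matrix for aligning homologs near 65 % identity
  and is fully configurable. A gap run of length L costs
  `gap_open + (L−1)·gap_extend` (defaults 12 / 3). With `free_end_gaps`
  (default) terminal gap runs in either sequence cost nothing, which is the
  right model for homologs of unequal extent.
* **Profile columns** are scored against a residue as the arithmetic mean
  of per-row substitution scores, with gap rows contributing
  `mismatch_score`. Degenerate residues in input rows are compared by
  character identity during alignment (set-aware matching only applies to
  primer placement, where it is the point of the operation).
* **Progressive strategy.** Center-star: the center is the sequence with
  the highest summed pairwise score; the others join the growing profile in
  decreasing order of score against the center (index order breaks ties —
  the procedure is fully deterministic). At 10–20 sequences a guide tree
  buys nothing over center-star. Two leave-one-out refinement passes follow
  (each row removed, all-gap columns collapsed, the row re-aligned to the
  remaining profile); the pass count is configurable.
* **Consensus.** Per retained column the concrete base with the highest
  count is called, ties broken alphabetically A < C < G < T (a rule is
  needed for determinism; no biological claim). Degenerate residues add
  1/k to each of their k member bases. Columns with more than
  `gap_fraction_max` (default 50 %) gaps are dropped, so the consensus is
  strictly A/C/G/T; the per-column counts and source-column indices are
  retained for audit.

The aligner is verified against two independent oracles: exhaustive
enumeration of all alignments of short strings, and Biopython's
`PairwiseAligner` configured with identical parameters on longer random
pairs.

## Primer placement and fragment assembly

A primer position matches a consensus base when the base is a member of the
IUPAC set of the primer code; no positional weighting is applied (3′-end
criticality is deliberately not modelled). Every window on the requested
strand is scored and windows within the budget (default 2 mismatches per
primer) are returned. Among compatible forward/reverse placements the pair
with the fewest total mismatches wins; ties prefer the amplicon length
closest to the expected size midpoint, then the leftmost placement.
Coordinates are 0-based half-open internally and printed 1-based inclusive
in reports.

Fragments are the amplicon plus per-side flanks (default 20 bases, the
representative value inside the recommended 9–30 range). Truncation against
the consensus edge is a warning; a requested flank outside [9, 30] or a
total length outside the orderable 125–3,000 bp window is a violation and
marks the design invalid.

## Copy numbers, curves, quantification

* `copies/µL = C·10⁻⁹·N_A / (L·660)` with `N_A = 6.022×10²³` (the value as
  conventionally rounded in this formula, kept exact so results reproduce
  the published arithmetic) and 660 g/mol per base pair. For plasmids
  `L = 3015 + amplicon` (pGEM-T Easy backbone).
* The dilution planner emits strictly geometric series (defaults: ten-fold,
  10⁸ → 10¹ copies/µL, triplicate) plus a pipetting plan for a stated
  working volume; the lowest level defines the detection limit.
* Standard curves are OLS of Cq on log₁₀(copies) over **all replicate
  points**, not level means — the replicate-aware choice; it changes r²
  only, not slope/intercept expectations. Efficiency is
  `10^(−1/slope) − 1`; values outside [0.70, 1.10] are flagged (assays are
  reported down to E ≈ 0.70 in practice). Per-level CV is
  `100·sd/mean` of raw Cq with the sample (n−1) standard deviation.
  Non-amplified replicates (missing Cq) are dropped from the fit but
  counted per level and flagged.
* Quantification inverts the curve at the mean replicate Cq. The
  copies-per-gram-dry-soil conversion,
  `copies/µL × dilution factor × elution volume / soil mass`, is an
  explicit modelling assumption — extraction bookkeeping varies between
  labs, so all context fields must be supplied and the conversion is only
  reported when they are.

## Comparison statistics

The t-test is two-sided Welch (unequal variances) — the default of the
common convenience wrappers — switchable to pooled variance. Bonferroni
adjustment is `min(1, m·p)` with m defaulting to the number of samples per
gene (the panel adjusted over). The agreement statistic
`delta = mean_p/(mean_p − mean_s)` is reported signed, with equal means
rendered as infinite; percent difference uses the plasmid mean as
denominator. Cross-standard agreement is the r² of the log₁₀–log₁₀
regression of synthetic on plasmid sample means (≥ 3 samples; non-positive
means excluded with a warning), and per-gene profiles normalized to the
highest-copy soil are provided for variation comparisons.

## Simulators

`simulate_family` draws a uniform-ACGT ancestor, splices in concrete
realisations of the primer sites, and applies i.i.d. substitutions and
geometric-length indels (truncated at `indel_max_len`) per descendant,
skipping protected primer sites. `simulate_cq` draws
`Cq = b + m·log₁₀(copies) + N(0, sd)`; Cq beyond the cycle budget (default
40 cycles) becomes a missing value — a hard cutoff is the simplest
mechanism that exercises the dropout path. Inhibition is modelled as an
additive Cq bias at the least-diluted levels; note that raising Cq at the
highest-copy (lowest-Cq) end makes the fitted line *shallower* and inflates
apparent efficiency. All generators are pure functions of their seed.

What the simulations do **not** emulate: sequence-dependent amplification
bias, per-cycle PCR chemistry, primer-dimer and off-target products,
plate/position effects, and real phylogenetic correlation structure among
homologs (descendants are i.i.d. around one ancestor). Passing tests
demonstrate the correctness of the arithmetic and the designer's behaviour
under controlled divergence — not performance on any particular real gene
family.

### Demo study conditions

The demo bundle fixes one realistic configuration: the *nosZ* primer pair,
a 249 bp amplicon with 30-base flanks (309 bp fragment), 15 homologs at 3 %
substitution and 0.5 % indel rate; synthetic-standard truth efficiency
0.95 / intercept 38 Cq, plasmid truth 0.92 / 37.5 (curve differences of the
size observed between real standard types), Cq noise sd 0.15 cycles,
triplicates, five soils spanning ~3.5 decades. The same soil reactions are
quantified against both curves, so the resulting percent differences
(tens of percent, within one log) reflect the curve offset, as they do in
practice.

## Numerical choices and degenerate inputs

* Alignment traceback prefers substitution over deletion over insertion on
  exact score ties, making outputs deterministic.
* Curve fitting requires ≥ 3 distinct levels with data; a non-negative
  slope is flagged "non-quantitative" and refuses quantification.
* Bonferroni validates p ∈ [0, 1]; constant identical arms short-circuit
  the t-test to t = 0, p = 1 rather than dividing by zero variance.
* Seeds: every stochastic routine takes an explicit seed and two calls with
  the same seed produce byte-identical outputs.

## Known limitations

* The +5/−4 matrix is a stand-in for the proprietary "65 % similarity"
  preset of commercial alignment software; scores (not alignments of
  well-conserved families) may differ from that tool.
* Whether gap-majority columns should be dropped or bridged when emitting
  an ACGT-only consensus is not standardised; the 50 % threshold is
  configurable.
* The mismatch budget is applied per primer, not summed over the pair.
* Flank lengths are symmetric by default; published fragment lengths
  suggest real designs sometimes used asymmetric or out-of-range flanks, so
  per-side overrides are provided.
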