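# ampstd

Design of **synthetic double-stranded DNA qPCR standards** from consensus
sequences of aligned gene families, plus the downstream qPCR analytics:
copy-number computation, dilution-series standard curves, amplification
efficiency, and synthetic-vs-plasmid comparison statistics.

## Who this is for

Microbial ecologists quantifying phylogenetic markers (16S rRNA, ITS) and
functional genes of the C/N/P cycles (*mcrA*, *pmoA*, *nifH*, *nosZ*,
*amoA*, *nirS*/*nirK*, *nxrB*, *norB*, *phoD*, ...) by SYBR-green qPCR.
Instead of cloning each target into a plasmid to obtain a calibration
standard, a standard can be ordered as a synthetic double-stranded fragment
designed from the consensus of 10–20 homologous sequences. This package
automates that design and the calibration arithmetic around it.

## The method

1. **Consensus.** Homologs are aligned by global alignment with free end
   gaps (affine penalties: gap open 12, extension 3; match +5 / mismatch −4
   by default) using a center-star progressive strategy with two iterative
   refinement passes. The consensus is the most frequent concrete
   nucleotide per column — A/C/G/T only, gap-majority columns dropped.
2. **Design.** The gene's degenerate primers (IUPAC codes, e.g. `TDR`) are
   located on the consensus with a budget of ≤ 2 mismatches per primer
   (membership test of the consensus base in each code's set; the reverse
   primer is scanned as its reverse complement). The fragment is the
   amplicon plus 9–30 flanking bases per side (default 20) and must fall in
   the orderable 125–3,000 bp synthesis window.
3. **Quantification.** Copies of a standard follow from its mass
   concentration *C* (ng/µL) and length *L* (bp):

   `copies/µL = C · 10⁻⁹ · 6.022×10²³ / (L · 660)`

   where *L* is the fragment length (synthetic) or 3,015 bp vector + insert
   (plasmid, pGEM-T Easy). A ten-fold dilution series (10⁸ → 10¹ copies/µL,
   triplicate) is fitted by OLS of Cq on log₁₀(copies); efficiency is
   `E = 10^(−1/slope) − 1` (slope ≈ −3.32 ⇔ E = 1, perfect doubling); the
   detection limit is the lowest standard level (10 copies/µL).
4. **Comparison.** Per sample, a two-sided Welch t-test on replicate copy
   numbers with Bonferroni adjustment, the agreement statistic
   `delta = mean_plasmid / (mean_plasmid − mean_synthetic)` (large |delta|
   ⇒ close agreement), the percent difference relative to the plasmid mean,
   and per gene the log-log cross-standard correlation (r²).

A simulation module (`ampstd.simdata`) generates gene families with planted
primer sites and Cq tables following `Cq = b + m·log₁₀(copies) + ε`, so the
whole workflow runs and is tested without any external data.

## Worked example

```sh
ampstd simulate bundle --seed 42 --out bundle
ampstd align    --in bundle/family.fasta --out aln.fasta --consensus cons.fasta
ampstd design   --consensus cons.fasta --primers bundle/primers.csv \
                --gene nosZ --flank5 30 --flank3 30 --out-fasta frag.fasta
ampstd curve    --in bundle/plate_synthetic.csv --gene nosZ --out curve_s.csv
ampstd quantify --curve bundle/plate_synthetic.csv --in bundle/plate_synthetic.csv \
                --gene nosZ --context bundle/context.yaml --out quant_s.csv
```

prints

```
aligned 15 sequences over 335 columns; consensus 309 bp
nosZ: amplicon 249 bp (0+0 mismatches), fragment 309 bp, valid=True
nosZ: slope -3.4359, intercept 37.98, r2 0.9999, E 95.5%
quantified 5 samples for nosZ
```

Reading: the 15 simulated *nosZ* homologs align into 335 columns and yield a
309 bp consensus; the nosZ-1F/nosZ_1R primer pair is found with zero
mismatches enclosing a 249 bp amplicon, and with 30-base flanks the 309 bp
fragment is a valid synthesis order. The simulated synthetic-standard
dilution series fits with r² = 0.9999 and 95.5 % efficiency (slope −3.44
cycles per decade), and the five simulated soils are quantified against
that curve. Running the plasmid plate the same way and then
`ampstd compare --synthetic quant_s.csv --plasmid quant_p.csv --out cmp.csv`
reports the per-sample t/delta statistics and a cross-standard log-log
r² > 0.999.

The primer table for all 13 bundled genes ships with the package
(`ampstd.sequences.bundled_primers()`).

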