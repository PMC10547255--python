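# kzfptools

Statistics and bookkeeping for the KRAB zinc finger protein (KZFP)
family — the largest group of human transcription factors, whose members
pair an N-terminal KRAB repressor domain with a C-terminal array of C2H2
zinc fingers and whose genomic targets are dominated by transposable
elements (TEs).  The package is aimed at regulatory-genomics analysts
who need to go from raw annotations (domain-hit tables, protein FASTA,
population variant tables, ChIP peak BEDs, RepeatMasker repeats, TE
alignments) to family-level statistics without bespoke one-off scripts.

It provides five pipeline stages plus a synthetic-data generator:

- **census** — pair KRAB- and ZF-array domain hits into KZFP gene calls
  (nearest same-strand hit within a gap limit, KRAB upstream) and call
  gene clusters: maximal single-linkage chains of ≥ 3 genes whose
  centers lie ≤ 250 kb from another member, named `Chr <n>.<k>` from the
  short arm.
- **fingerprint** — detect C2H2 fingers with a regex surrogate for the
  Pfam zf-C2H2 profile (`C-x(2,4)-C-x(12)-H-x(3,5)-H`), read the zinc
  fingerprint (recognition-helix residues −1/+3/+6, i.e. offsets
  −7/−4/−1 from the first zinc-coordinating histidine), and cluster
  paralogs by single linkage at ≥ 60% fingerprint identity.
- **constraint** — per-domain population coding-constraint Z scores:
  after a quality cascade (PASS filter, missense/LoF extraction,
  last-5% LoF removal, 20× coverage filters, singleton removal), variant
  counts *x* per region class are normalized (CDS length; domain length;
  finger count for the Cys/His class) and standardized,
  `z = (rate − mean(rate)) / sd(rate)`, across the gene set.  Low z =
  strong purifying selection.
- **te_enrichment** — TE subfamily/family enrichment of peak sets with a
  mappable-genome-corrected binomial null
  `p_u = (L_u + m_u(w̄−1)) / G`, upper-tail binomial p-values,
  Benjamini–Hochberg FDR (< 0.05 significant), primary-target calls
  (scaled −log10 FDR > 0.9 of the experiment maximum), a permutation
  oracle validating the closed form, recurrent-peak blacklisting, and
  the targets-per-cluster dispersion summary.
- **msa_profile** — project per-base ChIP signal onto TE multiple
  sequence alignments (strand-aware, gap-masked), drop columns with
  > 85% gaps, min-max scale rows, average into meta-profiles; plus
  unaligned consensus-motif-centered windows for VNTR-bearing elements
  (SVA).
- **synthetic_data** — genomes with planted repeat subfamilies, KZFP
  gene models with planted fingerprints, variant tables with planted
  constraint multipliers, peak sets with a planted target fraction, and
  zero-coverage masks, so every stage is testable against ground truth.

## Worked example

`examples/04_te_enrichment.py` plants 60% of 500 peaks on one of three
repeat subfamilies in a 1-Mb genome and prints:

```
mappable genome: 843,715 bp
    unit  observed  expected           fdr  scaled_score  significant  primary
L1PA_toy       270 15.017967 7.246649e-270      1.000000         True     True
AluY_toy        15 17.101047  9.769404e-01      0.000038        False    False
 LTR_toy         5 10.293775  9.769404e-01      0.000038        False    False
```

The planted subfamily shows 270 observed peak overlaps against ~15
expected under uniform placement on the mappable genome — FDR ≈ 0,
scaled enrichment 1.0, a primary target — while the background
subfamilies sit at their expectation.  The permutation oracle printed
below it agrees with the binomial p-values within Monte-Carlo error.
The other examples walk through the census (`01`), fingerprints — the
Zif268 finger-1 triplet reads `R,E,R` (`02`), constraint recovery of
planted multipliers at Spearman ρ ≈ 0.92 (`03`), and MSA profiles
localizing a planted signal bump (`05`).

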