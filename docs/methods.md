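# Methods

This note documents the models, conventions and numerical choices
behind each stage of `kzfptools`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinates and conventions

All internal genomic coordinates are 0-based half-open (BED
convention); variant positions are 1-based CDS coordinates, the
convention of population variant tables.  Interval sets are stored as
per-chromosome sorted disjoint arrays; overlap means ≥ 1 shared base
throughout.  Every generator takes one master seed and spawns a named
substream per artifact (`numpy.random.SeedSequence`), so a fixed seed
yields byte-identical outputs and any one artifact can be regenerated
independently.

## Census

KZFP genes are defined by juxtaposed KRAB- and C2H2-array-coding
domains on the same strand.  Pairing is greedy on the gap between the
KRAB end and the ZF-array start in transcription orientation (KRAB
upstream, the family's domain order), smallest gap first, ties to the
leftmost hit, each hit used once.  The gap limit defaults to 50 kb and
is configurable; the orientation requirement can be relaxed.  The
manual-curation step a human annotator would apply on real genomes is
out of scope; callers can pre-filter the hit tables instead.

Clusters are maximal single-linkage chains over per-chromosome sorted
gene centers with an inclusive ≤ 250 kb center-to-center threshold and
a minimum size of 3, non-coding members included.  Single linkage on
sorted centers is exactly the transitive closure of the pairwise
relation; the test suite verifies this equivalence against an
exhaustive union-find oracle over 1,000 random layouts.  Cluster names
number from the lowest coordinate (`Chr 19.1`, `Chr 19.2`, ...), which
treats the assembly's coordinate origin as the short arm.

## Fingerprints and paralogs

Fingers are found with the regular expression
`C-x(2,4)-C-x(12)-H-x(3,5)-H`, a deliberate surrogate for the Pfam
zf-C2H2 profile: fingers with non-canonical linker spacing are missed
by design, a documented limitation rather than a bug.  The first
zinc-coordinating histidine is taken as recognition-helix position +7,
so the DNA-contacting fingerprint residues −1/+3/+6 sit at offsets
−7/−4/−1 from that histidine.  The fourth, minor DNA-contacting residue
is excluded from the fingerprint.

Fingerprint identity is the best ungapped sliding alignment of the two
triplet arrays over all integer offsets: matching residues divided by
3 × (shorter array length).  Overhangs of the longer array are free;
unmatched fingers of the shorter array are penalized through the
denominator.  Identity is symmetric, bounded in [0,1], and 1 on
identical arrays.  Paralog sets are single-linkage components at an
inclusive ≥ 0.60 cutoff; raising the threshold can only refine sets
(tested).  Per-residue granularity and ungapped sliding were chosen
because the classic cutoff is quoted as a residue-identity percentage;
a per-triplet or gapped variant would need its own calibration.

## Constraint Z scores

The cascade order matters and is: PASS filter → consequence extraction
(missense + frameshift/stop-gain/splice) → removal of low-confidence
LoF and of LoF at CDS positions ≥ ceil(0.95 L) (truncations in the last
5% of a transcript often escape nonsense-mediated decay and read as
false LoF) → exclusion of genes with length-weighted mean coverage
< 20× → removal of exons with mean coverage < 20×, their variants, and
their length from the effective CDS length → singleton removal (allele
count 1; sequencing-artifact guard).  The cascade is idempotent.

Region classes per gene: FULL (any surviving variant in the CDS), LOF
(LoF anywhere — a truncation ablates the whole protein, so it is not
attributed to a residue class), KRAB, ZF_ALL (all survivors at labeled
positions), and missense-only C2H2 (the structural Cys/His codons),
FINGERPRINT (−1/+3/+6 codons) and ZF_OTHER.  Normalizers: effective CDS
length for FULL and LOF; domain length in bp for KRAB, ZF_ALL, ZF_OTHER
and FINGERPRINT (the domain-length normalizer is extended to the two
sub-finger classes by analogy, their natural length being proportional
to it); the number of fingers for C2H2.  Z scores standardize the
rates within each class using the sample (n−1) standard deviation; no
theoretically expected mutation count is applied, because the unstable
ZF-array-coding regions make such expectations unreliable — scores are
therefore relative to the analysed gene set, and mean 0 / sd 1 per
class is an invariant (checked to 1e−9).  A class with zero spread is
an error, not a silent NaN.  Spearman correlations between scores and
external covariates use complete pairs and Bonferroni correction over
the unique off-diagonal cells.

## TE enrichment

The null places each peak uniformly on the mappable genome G: the
reference minus zero-coverage regions common to all experiments
(merged when separated by < 100 bp, kept when > 40 kb) minus excluded
chromosomes (chrY by default, absent from the HEK293T background the
assays use).  The 40-kb floor drops a myriad of small regions whose
individual effect on G is negligible.  For unit u with mappable
fragments of total length L_u in m_u pieces and mean peak width w̄,

    p_u = min(1, (L_u + m_u (w̄ − 1)) / G),

the (w̄−1) term counting the extra start positions from which a peak
still reaches a fragment.  Observed counts (a peak counts once per
unit, however many fragments it touches; one peak may count toward
several units) get upper-tail binomial p-values, BH-corrected
separately at subfamily and family level, significance at FDR < 0.05.
Primary targets: −log10(FDR) scaled by the experiment maximum > 0.9,
with exact-zero FDRs floored to a tenth of the smallest positive FDR so
the scale stays finite and rank-preserving.  Only enrichment (upper
tail) is tested, not depletion.

The closed form is approximate — it ignores chromosome-edge clipping
and the merging of overlap windows of fragments closer than w̄ — so a
permutation oracle (uniform re-placement of all peaks, width preserved,
empirical p = (1 + #{k* ≥ k_obs})/(n_iter + 1)) is the arbiter: the
acceptance checks require agreement within 3 Monte-Carlo SE on 1-Mb
genomes, and type-I error ≤ 10% over 200 null runs (measured ≈ 1–2%,
i.e. the approximation errs conservative at these fragment densities).

## MSA signal profiles

Alignment computation is upstream (MAFFT); inputs are aligned FASTA
rows with genomic provenance.  Projection maps the j-th non-gap
character of a copy to its genomic base, strand-aware, and masks gaps;
optional unaligned flanks (200 bp typical, up to 500) are appended
around the element.  Columns with strictly more than 85% gaps are
removed; each row is min-max scaled to [0,1] over its non-gap cells
(constant rows become 0 — an arbitrary but harmless choice for
signal-free copies); the meta-profile is the per-column mean over
non-gap cells, NaN where a column is all gaps.  The profile averages
the *scaled* rows, so every copy contributes equally regardless of its
absolute signal level.  For elements whose internal tandem repeats
defeat alignment (SVA VNTRs), copies are centered on the
minimum-Hamming-distance placement of a consensus motif (ties
leftmost; copies worse than ceil(len/4) mismatches dropped and
reported) and profiled in plain genomic windows of ± flank around the
match midpoint.

## Synthetic data: what it emulates and what it does not

The generator plants: repeat fragments placed uniformly without overlap
(rejection sampling; subfamily → family → class hierarchy); gene models
whose proteins are KRAB (45 aa) + tandem 21-aa canonical fingers with
randomized fingerprint residues drawn from a Cys/His-free alphabet so
the planted fingers are the only regex matches; variant tables with
per-gene Poisson rates (base rate × multiplier × CDS length), uniform
positions, configurable LoF/singleton/non-PASS fractions, and a
geometric allele-count tail; peak sets with floor(f·n) peaks centered
in random target fragments and the rest uniform on the mappable set.

Defaults used by the acceptance checks are the standing study
conditions: 1-Mb single-chromosome genomes with three subfamilies
(~1–2% genome coverage each), 500 peaks of 100–350 bp, 100-gene
constraint panels with ~1.5-kb CDS, base rate 0.02 variants/bp and
log-uniform multipliers in [0.2, 5], 10,000 permutation iterations, and
200/50-seed replications.  These sizes keep every check within seconds
to a couple of minutes on one CPU while leaving the statistics
well-powered.

What passing does not show: real repeat annotations are nested and
fragmented (the generator's fragments are disjoint), real coverage and
mappability are correlated with repeat content rather than independent,
real variant rates vary with sequence context, and real alignments
contain misalignments the projection faithfully propagates.  The tests
demonstrate correctness of the computations under their stated models,
not robustness to those real-data pathologies.

## Degenerate inputs and tie-breaks

Pairing ties break by smaller gap, then leftmost coordinates.  Cluster
calling is invariant to input order (canonical sort first).  Empty
fingerprints make identity undefined (raised, not NaN).  Enrichment
with an empty mappable genome, zero peaks on it, or n_iter < 100 in the
oracle raises.  classify_targets with all FDR = 1 yields all-zero
scaled scores and no calls.  Fingers with fewer than 7 residues before
the anchor are skipped with a record; variants outside the CDS are
dropped with a count.
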