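# Methods

## Scope and model of the data

`plastdiv` analyses per-locus multiple alignments of chloroplast (plastome)
sequence sampled across a taxonomy of genera, species and individuals.  The
plastome is modelled as a circular quadripartite molecule — Large Single Copy
(LSC), Small Single Copy (SSC) and two Inverted Repeat copies (IRa/IRb) that
are exact reverse complements and evolve in concert — with loci of three
feature classes (exon, intron, intergenic spacer).  Diversity is measured as
SNP counts standardised per kilobase of *effective* alignment length and as
variable number tandem repeats (VNTRs), and a downstream population workflow
turns chloroplast SNPs into chlorotypes (haplotypes), frequency tests and a
minimum spanning network.

Alignments are inputs: the package never aligns divergent real sequences.
In synthetic mode the generator knows the full mutation history, so the
emitted alignments are true alignments by construction.

## SNP calling and the per-kb statistic

A SNP is an alignment column carrying at least two distinct unambiguous
bases (A/C/G/T) among the samples considered.  Columns containing a gap in
*any* considered sample are part of the length-variable fraction and are
excluded from SNP calling entirely; IUPAC ambiguity codes and N are missing
observations, never alleles; multi-allelic columns count once.  The
standardised statistic is

    SNP/kb = snp_count / effective_length x 1000

where the effective length is the alignment length minus the union of
gap-containing columns and detected VNTR spans (columns meeting both
conditions are subtracted once).  Within a grouping (region, feature class)
counts and effective lengths are pooled before dividing — a length-weighted
ratio, not a mean of per-locus ratios — and the report's `Mean` row pools
across all loci.  Means of ratios are used only where a mean of discrete
comparisons is the quantity of interest (within-genus species pairs,
between-genus comparisons), in which case the unweighted arithmetic mean of
the per-comparison pooled ratios is taken.

A locus whose effective length is zero has an undefined SNP/kb; it is
reported as missing and dropped from means with a warning.

## Tandem repeat detection

Detection operates on ungapped sequences and reports every maximal perfect
tandem array with a primitive motif of 1–30 bp that clears the class floor:

| motif length | floor |
|---|---|
| 1 bp (homopolymer) | run of >= 7 bp |
| 2–3 bp | >= 3 full repeats |
| >= 4 bp | >= 2 full repeats |

The 7 bp homopolymer floor follows the convention used when counting
plastome homopolymers; the 2-repeat floor for longer motifs deliberately
includes incipient, 2-unit direct repeats.  A partial terminal unit extends
the span and yields a fractional repeat count (floored for reporting).
Overlapping candidate arrays are resolved deterministically: largest
repeated span first, ties to the longer motif, then the leftmost start.
Motifs are canonicalised to their lexicographically smallest rotation so the
same array matches across samples regardless of phase; only perfect
(mismatch- and gap-free) arrays are modelled.

Per-sample arrays are projected onto alignment coordinates and merged into
one record when spans overlap and canonical motifs agree; a sample without a
detected array at a merged span gets its repeat count read directly from its
own sequence over the span (possibly 1, or 0 when absent).  Tabulation
follows the conventions of plastome screens: motif-length classes
(mononucleotide, dinucleotide, motif > 3 bp; trinucleotides are tallied as
their own auxiliary class rather than silently merged), and a polynucleotide
listing restricted to motifs >= 2 bp with repeat number above 2 and
repeat-count variation within at least one genus.

## Inverted repeat detection and region assignment

The detector seeds exact 20-mers between the doubled genome and its reverse
complement (N never matches), extends each seed without gaps, and keeps the
longest pair of disjoint segments, each at least `min_ir_length` bp
(default 1000 — real plastome IRs run 10–30 kb; synthetic ones are smaller),
where one is the reverse complement of the other.  The two arcs between the
copies become LSC (longer) and SSC (shorter).  Absence of a qualifying pair
is a result (`quadripartite=False`), not an error; all loci are then
labelled LSC.  Coordinates are 0-based half-open throughout, reported modulo
the genome length on the circle, so region lengths are rotation-invariant.
A locus is assigned to the region holding the majority of its length
(midpoint breaks exact ties); both IR copies map to the single label `IR`.

## Statistics

*Kruskal–Wallis.* Mid-ranks over the pooled values with the tie correction
`1 - sum(t^3 - t)/(N^3 - N)`; the null distribution is chi-squared with
k−1 degrees of freedom, with the upper tail evaluated as the regularised
incomplete gamma Q(df/2, x/2).  For total N <= 10 an exact permutation
p-value is also computed (full enumeration of distinct group assignments
when that count is <= 100,000, otherwise seeded sampling).  When every value
is identical the tie factor vanishes and H is defined as 0 with p = 1.  The
sampling unit is the locus: tests compare per-locus SNP/kb values between
regions or feature classes, the only unit of replication the data support.

*Chi-squared frequency test.* Species x chlorotype contingency table
(optionally restricted to a pair; all-zero rows/columns dropped), Pearson
statistic without continuity correction.  When any expected count falls
below 5 a seeded Monte-Carlo p-value is added: 10,000 permutations of
species labels conditioned on both margins, with `(count+1)/(B+1)`
protection.  Full-table and pooled/pairwise comparisons are both exposed,
since either granularity can be of interest.

*Bootstrap CI.* Percentile interval of the mean over seeded resamples with
replacement (default B = 10,000, level 0.95).  The percentile method is
stated explicitly in outputs because interval methods differ; a single value
yields a degenerate interval with a warning.

## Chlorotypes and the minimum spanning network

Genotypes are the bases at a panel of SNP sites; gaps and ambiguity codes
are missing, and individuals with any missing site are excluded from
chlorotype counting (reported separately) rather than imputed.  Chlorotypes
are the distinct complete allele vectors, numbered by descending total
frequency with ties broken by first occurrence.  Diagnostic-locus selection
retains a locus iff at least one of its sites carries an allele observed in
exactly one of the two target taxa and absent from the other — the
operational form of "polymorphism specific to one taxon".

The MSN is the union of *all* minimum spanning trees of the complete graph
on chlorotypes weighted by Hamming distance (differing sites only, no
transition/transversion weighting).  It is built by processing edges in
ascending weight classes; within a class, every edge joining two components
as they stood *before* the class was processed is kept, then the class is
merged.  This reproduces exactly the union-of-all-MSTs edge set (verified
against exhaustive spanning-tree enumeration) and shows every
equally-parsimonious link, with edge labels carrying the discriminating
sites.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
a calibrated molecular-evolution model:

- **Template.** Regions are assembled as LSC + IRb + SSC + IRa with IRa the
  reverse complement of IRb.  Loci are laid out inside their regions with
  3 bp spacers; locus sequence is re-randomised until free of tandem arrays
  (using thresholds one notch stricter than detection) so planted arrays sit
  in genuinely non-repetitive flanks, and array flanks are pinned so the
  planted span is exactly the maximal array.  Junction bases are pinned so
  the true inverted repeat is exactly the configured IR unit.
- **Substitutions.** Jukes–Cantor-like: per branch of the
  genus > species > individual tree, each eligible site mutates with the
  region's per-bp probability and a uniformly chosen different base.
  Relative counts are all the analysis needs, so no calibrated model is
  fitted.  Optional per-level multipliers (`level_rates`) scale all rates on
  genus/species/individual branches, allowing population samples with much
  lower intraspecific than interspecific diversity — the regime in which
  chloroplast population genetics is typically done.
- **IR concert.** Loci live once (in IRb); every individual's IRa is
  reconstructed as the reverse complement of its IRb, so both copies mutate
  identically by construction.
- **VNTRs.** Planted arrays evolve by symmetric +/-1-repeat steps with a
  per-branch probability, floored at one repeat — the simplest model
  producing polymorphic repeat-count ranges.  Substitutions and indels never
  land inside planted spans, so repeat counts stay well defined and the
  event log fully determines the true alignment.
- **Indels.** 1–5 bp insertions or deletions (equiprobable), only in
  non-exon loci so exon frames stay alignable.
- **Determinism.** One seeded generator; branches are visited in a fixed
  depth-first order (genera and species sorted, individuals numbered), so an
  identical configuration reproduces byte-identical output.

What the generator does *not* emulate: recombination (cpDNA effectively
lacks it), heteroplasmy, codon structure and selection, imperfect or
compound repeats, small inversions, and alignment error — in real data the
alignment step itself can create or destroy apparent variation, so passing
tests here validate the scanners and statistics, not an aligner.

## Problem sizes and numerical choices

The bundled scenarios are desk-scale by design: the region screen uses 20
loci of 300 bp per region over two species with two individuals each; the
repeat-rich screen plants 21 arrays (13 with motifs > 3 bp) across 12 loci
and 3 genera; the population scenario samples 160 individuals (66/39/55
across three congeneric species) at 5 loci.  These sizes keep every
simulation-based check fast while leaving all counting statistics far from
degenerate.  Tolerances: exact rank statistics are checked to 1e-12;
Monte-Carlo agreement checks use the binomial error of the replicate count;
rate-recovery checks are framed as success frequencies over seeded runs
(e.g. IR:LSC SNP/kb ratio < 0.5) rather than point equalities.

## Known limitations

- Detection of repeats is exact-match only; diverged or interrupted arrays
  appear as separate records.
- `project_to_alignment` merges arrays by span overlap and canonical motif;
  two distinct same-motif arrays separated by a deletion in one sample can
  merge.
- The IR detector reports the single longest repeat pair; plastomes with
  additional large repeats would need manual region tables (supported via
  the region TSV input).
- The diagnostic-locus rule is presence/absence of a private allele; it does
  not weight allele frequencies or require fixation.
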