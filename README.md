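# plastdiv

Locus-by-locus diversity screening for chloroplast genomes: SNP and tandem
repeat (VNTR) detection in per-locus multiple alignments, per-kilobase
standardisation across the quadripartite plastome (LSC / SSC / IR), rank
tests between regions and feature classes, and a chloroplast population
genetics workflow — diagnostic-SNP selection, chlorotype calling,
chi-squared frequency comparison and minimum spanning networks.

The package is aimed at researchers developing or applying chloroplast
sequence markers in plants: screening many loci for variability, deciding
which regions and feature classes are worth sequencing, and using the
resulting SNPs for population-level questions in species complexes.  A
synthetic plastome-evolution generator with complete truth tables stands in
for field samples, so every stage is testable end to end without downloads.

## The statistics at the core

For a locus alignment, SNPs are columns with at least two unambiguous bases;
columns containing any gap, and detected VNTR spans, are length-variable and
are removed from the denominator:

    SNP/kb = n_SNP / (L_alignment − L_gap columns ∪ VNTR spans) × 1000

Group values pool counts over summed effective lengths (length-weighted).
Regions and feature classes are compared with tie-corrected Kruskal–Wallis
tests on per-locus SNP/kb values.  Tandem arrays (motifs 1–30 bp) are
detected per sequence, matched across samples by canonical motif rotation at
homologous spans, and classified by motif length.  A chlorotype is the
combination of chloroplast SNP alleles an individual carries; chlorotype
frequencies are compared between species with a chi-squared test and related
in a minimum spanning network (MSN) — the union of all minimum spanning
trees of the Hamming-distance graph, so every equally-parsimonious link is
drawn.

## Worked example

`examples/` contains one short script per capability.  Running
`python examples/03_snp_diversity_table.py` simulates 20 loci per region
with the inverted repeat mutating at one fifth of the single-copy rate,
scans them and prints:

```
group  snp_count  effective_length  vntr_count  snp_per_kb
  LSC        178              6000           0   29.666667
   IR         39              6000           0    6.500000
  SSC        170              6000           0   28.333333
 Mean        387             18000           0   21.500000

LSC vs IR Kruskal-Wallis: H = 28.644, p = 8.70e-08
```

LSC and SSC show similar SNP/kb while the IR row is strongly depressed — the
regime the simulation planted — and the rank test over per-locus values
rejects LSC = IR.  The `Mean` row pools counts and lengths over all loci
(length-weighted), which is why it is not the arithmetic mean of the rows
above it.

`python examples/05_chlorotype_network.py` runs the population workflow on a
simulated crop–wild complex (160 individuals, three species) and prints the
diagnostic loci, the chlorotype-by-species table, the chi-squared result and
the MSN edges with their discriminating SNP sites.

## Command line

A thin CLI wraps the library for shell use:

```bash
plastdiv simulate --preset demo --out demo_data --seed 1
plastdiv regions --fasta demo_data/genome.fasta --min-ir 200
plastdiv scan-snps --loci demo_data/loci --annot demo_data/loci.tsv \
    --samples demo_data/samples.tsv --group-by region
plastdiv scan-vntr --loci demo_data/loci --annot demo_data/loci.tsv \
    --samples demo_data/samples.tsv
plastdiv chlorotype --loci demo_data/loci --annot demo_data/loci.tsv \
    --samples demo_data/samples.tsv --out demo_out
plastdiv run --config pipeline.yaml
```

All tables are TSV with headers; machine outputs use 0-based half-open
coordinates; the MSN is written as DOT and as an edge list.

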