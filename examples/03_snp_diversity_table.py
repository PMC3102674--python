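"""Scan per-locus alignments for SNPs and build the per-kb diversity table.

SNP counts are standardised to 1 kb of *effective* length: gap-containing
columns and tandem-repeat spans are length-variable and are subtracted from
the denominator before the per-kb ratio is formed.  Groups pool counts over
summed lengths (length-weighted), and a Kruskal-Wallis rank test compares
per-locus SNP/kb values between regions.
"""

from plastdiv import (
    build_template_genome,
    emit_locus_alignments,
    kruskal_wallis,
    locus_summary,
    simulate_divergence,
    summarize,
)
from plastdiv.presets import region_rate_config

config = region_rate_config(seed=5)
template = build_template_genome(config)
individuals, truth = simulate_divergence(template, config)
alignments = emit_locus_alignments(individuals, template, truth)

annotations = {
    l.name: {"region": l.region, "feature_class": l.feature_class}
    for l in template.loci
}
summaries = [locus_summary(a) for a in alignments.values()]
table = summarize(summaries, annotations, group_by="region")
print(table.to_string(index=False))

per_locus = {}
for aln in alignments.values():
    s = locus_summary(aln)
    per_locus.setdefault(aln.region, []).append(s.snp_per_kb)
kw = kruskal_wallis([per_locus["LSC"], per_locus["IR"]])
print(f"\nLSC vs IR Kruskal-Wallis: H = {kw.statistic:.3f}, p = {kw.pvalue:.2e}")
print("The IR row sits far below LSC/SSC: the simulated inverted repeat "
      "mutates five times more slowly, and the rank test sees it.")
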