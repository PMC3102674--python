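"""Screen alignments for tandem repeats and tabulate polymorphic VNTRs.

Detection runs per degapped sequence (homopolymers >= 7 bp, 2-3 bp motifs
with >= 3 repeats, longer motifs with >= 2 repeats), then arrays from
different samples are matched at homologous alignment spans via canonical
motif rotation.  The listing keeps polynucleotide arrays with repeat number
above 2 that vary within at least one genus.
"""

from plastdiv import (
    build_template_genome,
    emit_locus_alignments,
    find_tandem_repeats,
    project_to_alignment,
    simulate_divergence,
    tabulate_vntr,
)
from plastdiv.presets import palm_like_config

print("standalone detection:", find_tandem_repeats("GGGATAGATAGATATT"))

config = palm_like_config(seed=2)
template = build_template_genome(config)
individuals, truth = simulate_divergence(template, config)
alignments = emit_locus_alignments(individuals, template, truth)

records = [r for a in alignments.values() for r in project_to_alignment(a)]
genus_of = {
    s.sample_id: s.genus for a in alignments.values() for s in a.samples
}
feature_of = {l.name: l.feature_class for l in template.loci}
tables = tabulate_vntr(records, genus_of, feature_of)

print("\npolymorphic VNTRs per motif class and genus:")
print(tables["by_class"].to_string())
print("\npolynucleotide listing (repeat number > 2, polymorphic in a genus):")
print(tables["listing"].to_string(index=False))
print("\nfeature context of polymorphic VNTRs:")
print(tables["feature_shares"].to_string(index=False))
print("\nRepeats concentrate in IGS and introns: the simulator never plants "
      "arrays in exons and indels are excluded from them.")
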