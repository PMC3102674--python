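"""Ready-made simulation configurations for the study conditions.

Three scenarios recur throughout the tests, examples and the acceptance
script:

``region_rate_config``
    20 loci per region with per-branch substitution rates
    LSC = SSC = 5e-3 /bp and IR = 1e-3 /bp — the depressed-IR regime whose
    recovery the pipeline is validated against.

``palm_like_config``
    A three-genus sampling (two individuals per genus pair member) rich in
    tandem repeats: mono-, di- and >3 bp motifs planted with stepwise
    mutation, the desk-scale analogue of a palm family screen where 13
    polynucleotide (motif >3 bp) VNTRs segregate.

``population_config``
    One genus, three species with population-scale sampling (66/39/55
    individuals by default) and intraspecific substitution strongly reduced
    relative to the species branches, so diversity is structured into a few
    species-sorted haplotypes — the regime in which diagnostic-SNP panels
    and chlorotype networks are informative.
"""

from __future__ import annotations

from .simulate import LocusSpec, SimulationConfig, VNTRSpec

FEATURES = ("IGS", "intron", "exon")


def _layout(n_per_region: int, length: int) -> list[LocusSpec]:
    loci = []
    for region in ("LSC", "SSC", "IR"):
        for i in range(n_per_region):
            loci.append(
                LocusSpec(
                    name=f"{region.lower()}_{i + 1:02d}",
                    feature_class=FEATURES[i % 3],
                    region=region,
                    length=length,
                )
            )
    return loci


def region_rate_config(
    seed: int,
    n_loci_per_region: int = 20,
    locus_length: int = 300,
    lsc_rate: float = 5e-3,
    ssc_rate: float = 5e-3,
    ir_rate: float = 1e-3,
) -> SimulationConfig:
    """Depressed-IR regime: equal LSC/SSC rates, IR at one fifth."""
    margin = 3 * (n_loci_per_region + 1) + 20
    region_len = n_loci_per_region * locus_length + margin
    return SimulationConfig(
        seed=seed,
        genome_lengths={"LSC": region_len + 50, "SSC": region_len, "IR": region_len},
        locus_layout=_layout(n_loci_per_region, locus_length),
        taxonomy={"Genus1": {"speciesA": 2, "speciesB": 2}},
        snp_rate={"LSC": lsc_rate, "SSC": ssc_rate, "IR": ir_rate},
    )


# Motifs modelled on repeat classes seen in palm plastomes: tetra- to 20-mer
# units, several at 2-3 initial copies so +/-1 steps cross the "repeat
# number > 2" reporting threshold.
_POLY_MOTIFS = [
    ("GATA", 3),
    ("AAATA", 3),
    ("AATATT", 2),
    ("TTACTTAT", 2),
    ("ACTACTATACTA", 3),
    ("CTCGTTTACAAATATCCAAA", 2),
    ("TCTAG", 3),
    ("ATTCGT", 2),
    ("GTTAACAT", 2),
    ("TACGATT", 3),
    ("CATTAGCAT", 2),
    ("ATCG", 4),
    ("TTGCA", 3),
]
_DI_MOTIFS = [("AT", 6), ("AT", 5)]
_MONO_RUNS = [("A", 9), ("T", 10), ("A", 8), ("T", 9), ("A", 11), ("T", 8)]


def palm_like_config(
    seed: int, step_rate: float = 0.35, snp_rate: float = 1.5e-3
) -> SimulationConfig:
    """Tandem-repeat-rich three-genus sampling (13 planted >3 bp motifs)."""
    n_loci = 12
    layout = []
    for i in range(n_loci):
        region = ("LSC", "LSC", "SSC", "IR")[i % 4]
        layout.append(
            LocusSpec(
                name=f"palm_{i + 1:02d}",
                feature_class=("IGS", "intron")[i % 2],  # VNTRs avoid exons
                region=region,
                length=420,
            )
        )
    vntrs = []
    hosts = [layout[i % n_loci].name for i in range(len(_POLY_MOTIFS))]
    for (motif, reps), host in zip(_POLY_MOTIFS, hosts):
        vntrs.append(VNTRSpec(motif, reps, step_rate, host))
    for i, (motif, reps) in enumerate(_DI_MOTIFS):
        vntrs.append(VNTRSpec(motif, reps, step_rate, layout[(i + 5) % n_loci].name))
    for i, (motif, reps) in enumerate(_MONO_RUNS):
        vntrs.append(VNTRSpec(motif, reps, step_rate, layout[(i + 2) % n_loci].name))
    lsc_n = sum(1 for l in layout if l.region == "LSC")
    ssc_n = sum(1 for l in layout if l.region == "SSC")
    ir_n = sum(1 for l in layout if l.region == "IR")
    return SimulationConfig(
        seed=seed,
        genome_lengths={
            "LSC": lsc_n * 420 + 3 * (lsc_n + 1) + 60,
            "SSC": ssc_n * 420 + 3 * (ssc_n + 1) + 30,
            "IR": ir_n * 420 + 3 * (ir_n + 1) + 30,
        },
        locus_layout=layout,
        taxonomy={
            "PalmA": {"sp1": 1, "sp2": 1},
            "PalmB": {"sp1": 1, "sp2": 1},
            "PalmC": {"sp1": 2},
        },
        snp_rate={"LSC": snp_rate, "SSC": snp_rate, "IR": snp_rate / 5},
        vntr_specs=vntrs,
    )


def population_config(
    seed: int,
    n_by_species: dict[str, int] | None = None,
    n_loci: int = 5,
    locus_length: int = 400,
) -> SimulationConfig:
    """Crop-wild complex: three congeneric species, population sampling.

    Species branches carry most substitutions; individual branches are an
    order of magnitude quieter, so haplotypes sort largely by species with
    occasional private variants — a few chlorotypes, not one per individual.
    """
    if n_by_species is None:
        n_by_species = {"wildA": 66, "wildB": 39, "cultivated": 55}
    layout = [
        LocusSpec(
            name=f"pop_{i + 1:02d}",
            feature_class=("exon", "IGS", "exon", "exon", "IGS")[i % 5],
            region=("SSC", "SSC", "IR", "LSC", "SSC")[i % 5],
            length=locus_length,
        )
        for i in range(n_loci)
    ]
    per_region = {r: sum(1 for l in layout if l.region == r) for r in ("LSC", "SSC", "IR")}
    lengths = {
        r: max(1, per_region[r]) * locus_length + 3 * (per_region[r] + 1) + 40
        for r in per_region
    }
    lengths["LSC"] = max(lengths["LSC"], lengths["SSC"] + 10)
    return SimulationConfig(
        seed=seed,
        genome_lengths=lengths,
        locus_layout=layout,
        taxonomy={"Yam": dict(n_by_species)},
        snp_rate={"LSC": 1.5e-3, "SSC": 1.5e-3, "IR": 8e-4},
        level_rates={"genus": 1.0, "species": 1.0, "individual": 0.005},
    )


def demo_config(seed: int) -> SimulationConfig:
    """Small all-features configuration used by the bundled pipeline demo."""
    cfg = palm_like_config(seed)
    cfg.indel_rate = 2e-4
    return cfg
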