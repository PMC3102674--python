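"""Synthetic plastome generator: determinism, structure, truth bookkeeping."""

import numpy as np
import pytest

from plastdiv.align import GAP
from plastdiv.presets import palm_like_config, region_rate_config
from plastdiv.regions import reverse_complement
from plastdiv.simulate import (
    LocusSpec,
    SimulationConfig,
    VNTRSpec,
    build_template_genome,
    emit_locus_alignments,
    expected_snp_columns,
    individual_genome,
    simulate_divergence,
)
from plastdiv.snps import scan_snps


def small_config(seed=1, **overrides):
    base = dict(
        seed=seed,
        genome_lengths={"LSC": 1200, "SSC": 500, "IR": 400},
        locus_layout=[
            LocusSpec("lsc_a", "IGS", "LSC", 300),
            LocusSpec("lsc_b", "exon", "LSC", 250),
            LocusSpec("ssc_a", "intron", "SSC", 300),
            LocusSpec("ir_a", "exon", "IR", 200),
        ],
        taxonomy={"GenA": {"sp1": 2, "sp2": 1}, "GenB": {"sp1": 2}},
        snp_rate={"LSC": 4e-3, "SSC": 4e-3, "IR": 1e-3},
    )
    base.update(overrides)
    return SimulationConfig(**base)


def run(cfg):
    tpl = build_template_genome(cfg)
    inds, truth = simulate_divergence(tpl, cfg)
    alns = emit_locus_alignments(inds, tpl, truth)
    return tpl, inds, truth, alns


class TestTemplate:
    def test_genome_length_is_sum_of_regions(self):
        tpl = build_template_genome(small_config())
        assert len(tpl.sequence) == 1200 + 500 + 2 * 400

    def test_ira_is_reverse_complement_of_irb(self):
        tpl = build_template_genome(small_config())
        seq = tpl.sequence
        irb = seq[slice(*tpl.region_map.irb)]
        ira = seq[slice(*tpl.region_map.ira)]
        assert ira == reverse_complement(irb)

    def test_same_seed_identical_genome(self):
        assert (
            build_template_genome(small_config(seed=9)).sequence
            == build_template_genome(small_config(seed=9)).sequence
        )

    def test_locus_overflow_rejected(self):
        with pytest.raises(ValueError, match="overflow"):
            small_config(
                genome_lengths={"LSC": 400, "SSC": 300, "IR": 400}
            ).validate()

    def test_loci_stay_inside_their_regions(self):
        tpl = build_template_genome(small_config())
        for loc in tpl.loci:
            start, end = tpl.locus_interval(loc.name)
            label_iv = {
                "LSC": tpl.region_map.lsc,
                "SSC": tpl.region_map.ssc,
                "IR": tpl.region_map.irb,
            }[loc.region]
            assert label_iv[0] <= start < end <= label_iv[1]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(base_composition=(0.5, 0.5, 0.1, 0.1)).validate()
        with pytest.raises(ValueError, match="motif length"):
            small_config(
                vntr_specs=[VNTRSpec("A" * 31, 2, 0.1, "lsc_a")]
            ).validate()
        with pytest.raises(ValueError, match="host locus"):
            small_config(vntr_specs=[VNTRSpec("GATA", 3, 0.1, "nope")]).validate()


class TestDivergence:
    def test_zero_rates_produce_identical_individuals(self):
        cfg = small_config(snp_rate={"LSC": 0, "SSC": 0, "IR": 0})
        tpl, inds, truth, alns = run(cfg)
        assert truth.snps == [] and truth.indels == []
        for aln in alns.values():
            assert len(set(aln.rows)) == 1
            assert GAP not in aln.rows[0]

    def test_zero_ir_rate_means_no_ir_truth_entries(self):
        cfg = small_config(snp_rate={"LSC": 5e-3, "SSC": 5e-3, "IR": 0.0})
        tpl, inds, truth, alns = run(cfg)
        ir_loci = {l.name for l in tpl.loci if l.region == "IR"}
        assert all(ev["locus"] not in ir_loci for ev in truth.snps)

    def test_determinism_bytewise(self):
        cfg = small_config(seed=42, indel_rate=5e-4)
        _, _, truth1, alns1 = run(cfg)
        _, _, truth2, alns2 = run(cfg)
        assert truth1.snps == truth2.snps
        assert truth1.indels == truth2.indels
        for name in alns1:
            assert alns1[name].rows == alns2[name].rows

    def test_event_counts_match_independent_rng_replay(self):
        """Replaying the documented draw order reproduces the event log."""
        cfg = small_config(seed=77)
        tpl, inds, truth, _ = run(cfg)

        rng = np.random.default_rng([cfg.seed, 1])
        replayed = []
        branches = []
        for genus in sorted(cfg.taxonomy):
            branches.append(("genus", genus))
            for sp in sorted(cfg.taxonomy[genus]):
                branches.append(("species", f"{genus}/{sp}"))
                for i in range(cfg.taxonomy[genus][sp]):
                    branches.append(("individual", f"{genus}_{sp}_{i + 1:02d}"))
        for level, label in branches:
            for loc in tpl.loci:
                rate = cfg.snp_rate[loc.region]
                if rate <= 0:
                    continue
                k = int(rng.binomial(loc.length, rate))
                if k:
                    pos = np.sort(
                        rng.choice(np.arange(loc.length), size=k, replace=False)
                    )
                    for p in pos:
                        rng.integers(3)  # alt-base draw
                        replayed.append((f"{level}:{label}", loc.name, int(p)))
        observed = [(ev["branch"], ev["locus"], ev["template_pos"]) for ev in truth.snps]
        assert observed == replayed

    def test_vntr_counts_floor_at_one(self):
        cfg = small_config(
            snp_rate={"LSC": 0, "SSC": 0, "IR": 0},
            vntr_specs=[VNTRSpec("GATA", 2, 0.9, "lsc_a")],
        )
        _, inds, truth, _ = run(cfg)
        assert all(row["count"] >= 1 for row in truth.vntr_counts)


class TestAlignments:
    def test_no_events_no_gap_columns(self):
        cfg = small_config(snp_rate={"LSC": 0, "SSC": 0, "IR": 0})
        _, _, _, alns = run(cfg)
        assert all(GAP not in r for a in alns.values() for r in a.rows)

    def test_gap_columns_match_event_log(self):
        """Gap columns = unique deleted columns + inserted length + repeat range."""
        cfg = small_config(seed=5, indel_rate=1e-3,
                          vntr_specs=[VNTRSpec("AATG", 3, 0.5, "ssc_a")])
        tpl, inds, truth, alns = run(cfg)
        for loc in tpl.loci:
            aln = alns[loc.name]
            mat = np.array([list(r) for r in aln.rows])
            gap_cols = int((mat == GAP).any(axis=0).sum())

            deleted = set()
            for ind in inds:
                st = ind.loci[loc.name]
                deleted |= set(np.nonzero(~st.present)[0])
            ins_len = sum(
                len(info["seq"])
                for eid, info in truth.insertion_registry.items()
                if info["locus"] == loc.name
                and not all(eid in i.loci[loc.name].insertions for i in inds)
            )
            vntr_gaps = 0
            for vi, v in enumerate(loc.vntrs):
                counts = [i.loci[loc.name].vntr_counts[vi] for i in inds]
                vntr_gaps += len(v.motif) * (max(counts) - min(counts))
            assert gap_cols == len(deleted) + ins_len + vntr_gaps

    def test_scan_recovers_exactly_the_observable_truth(self):
        cfg = small_config(seed=13)
        tpl, inds, truth, alns = run(cfg)
        total_truth = 0
        for loc in tpl.loci:
            expected = expected_snp_columns(inds, tpl, truth, loc.name)
            found = {r.column for r in scan_snps(alns[loc.name])}
            assert found == expected
            total_truth += len(expected)
        assert total_truth > 0  # the comparison is not vacuous

    def test_sample_ids_encode_taxonomy(self):
        _, _, _, alns = run(small_config())
        aln = next(iter(alns.values()))
        for s in aln.samples:
            genus, species, idx = s.sample_id.split("_")
            assert s.genus == genus and s.species == species


class TestIRConcertedEvolution:
    def test_ira_mirrors_irb_in_every_individual(self):
        cfg = small_config(seed=3, indel_rate=5e-4)
        tpl, inds, truth, _ = run(cfg)
        for ind in inds:
            from plastdiv.simulate import _ungapped_locus_sequence

            # genome layout is LSC | IRb | SSC | IRa; the emitted IRa tail
            # must be the reverse complement of this individual's IRb
            genome = individual_genome(tpl, ind, truth)
            irb = ""
            tmpl = tpl.region_seqs["IR"]
            pos = 0
            for loc in sorted(
                (l for l in tpl.loci if l.region == "IR"),
                key=lambda l: l.region_offset,
            ):
                irb += tmpl[pos : loc.region_offset]
                irb += _ungapped_locus_sequence(
                    loc, ind.loci[loc.name], truth.insertion_registry
                )
                pos = loc.region_offset + loc.length
            irb += tmpl[pos:]
            assert genome.endswith(reverse_complement(irb))


class TestRateRecovery:
    def test_depressed_ir_recovered_in_most_runs(self):
        """IR:LSC SNP/kb ratio < 0.5 in >= 95% of seeded runs (20 loci/region)."""
        from plastdiv.snps import locus_summary

        ok = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = region_rate_config(seed, n_loci_per_region=20)
            tpl, inds, truth, alns = run(cfg)
            per_region = {"LSC": [0, 0], "IR": [0, 0]}
            for aln in alns.values():
                if aln.region in per_region:
                    s = locus_summary(aln)
                    per_region[aln.region][0] += s.snp_count
                    per_region[aln.region][1] += s.effective_length
            lsc = per_region["LSC"][0] / per_region["LSC"][1]
            ir = per_region["IR"][0] / per_region["IR"][1]
            ok += (ir / lsc) < 0.5
        assert ok >= 0.95 * n_runs
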