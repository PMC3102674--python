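"""Genotype calling, diagnostic loci, chlorotypes, chi-squared, MSN."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plastdiv.align import LocusAlignment, Sample
from plastdiv.chlorotype import (
    ChlorotypeSet,
    Chlorotype,
    GenotypeMatrix,
    SNPSite,
    build_msn,
    call_genotypes,
    compare_frequencies,
    define_chlorotypes,
    hamming,
    select_diagnostic_loci,
)


def gm_from_rows(rows, species, sites=None):
    """GenotypeMatrix from a dict sample -> allele string ('.' = missing)."""
    ids = list(rows)
    n_sites = len(next(iter(rows.values())))
    sites = sites or [SNPSite(f"L{i + 1}", 0) for i in range(n_sites)]
    calls = pd.DataFrame(
        {
            s.label: [rows[i][k] if rows[i][k] != "." else None for i in ids]
            for k, s in enumerate(sites)
        },
        index=ids,
    )
    return GenotypeMatrix(calls, pd.Series(species), sites)


def aln(rows_by_sample, species_by_sample, locus="loc1"):
    samples = [
        Sample(sid, "G", species_by_sample[sid]) for sid in rows_by_sample
    ]
    return LocusAlignment(locus, "IGS", "LSC", samples, list(rows_by_sample.values()))


class TestCallGenotypes:
    SPECIES = {"a1": "A", "a2": "A", "b1": "B"}

    def test_clean_calls(self):
        a = aln({"a1": "ACGT", "a2": "ACCT", "b1": "TCGT"}, self.SPECIES)
        gm = call_genotypes({"loc1": a}, [SNPSite("loc1", 0), SNPSite("loc1", 2)])
        assert gm.calls.shape == (3, 2)
        assert gm.calls.loc["b1", "loc1:0"] == "T"
        assert gm.incomplete_individuals == []

    def test_gap_and_ambiguity_become_missing(self):
        a = aln({"a1": "A-GT", "a2": "ACNT", "b1": "TCGT"}, self.SPECIES)
        gm = call_genotypes(
            {"loc1": a}, [SNPSite("loc1", 1), SNPSite("loc1", 2)]
        )
        assert gm.calls.loc["a1", "loc1:1"] is None
        assert set(gm.incomplete_individuals) == {"a1", "a2"}

    def test_absent_column_is_an_error(self):
        a = aln({"a1": "ACGT", "a2": "ACGT", "b1": "ACGT"}, self.SPECIES)
        with pytest.raises(IndexError, match="outside alignment"):
            call_genotypes({"loc1": a}, [SNPSite("loc1", 99)])


class TestDiagnosticLoci:
    def test_private_allele_retains_locus(self):
        gm = gm_from_rows(
            {"a1": "G", "a2": "G", "b1": "T", "b2": "T"},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        kept, table = select_diagnostic_loci(gm, ("A", "B"))
        assert kept == ["L1"]
        assert table["diagnostic"].all()

    def test_shared_polymorphism_drops_locus(self):
        gm = gm_from_rows(
            {"a1": "G", "a2": "T", "b1": "G", "b2": "T"},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        kept, _ = select_diagnostic_loci(gm, ("A", "B"))
        assert kept == []

    def test_example_screen_fixture(self):
        """19 loci / 21 SNPs, 5 loci with taxon-private alleles: exactly 5 kept."""
        rng = np.random.default_rng(4)
        n_a, n_b = 5, 5  # one reference + four extra individuals per taxon
        species = {f"a{i}": "A" for i in range(n_a)}
        species.update({f"b{i}": "B" for i in range(n_b)})
        ids = list(species)

        sites, rows = [], {i: [] for i in ids}
        private_loci = {"L03", "L07", "L11", "L15", "L19"}
        # loci L01..L19; L05 and L10 carry two SNPs each -> 21 sites
        per_locus = {f"L{i:02d}": 1 for i in range(1, 20)}
        per_locus["L05"] = per_locus["L10"] = 2
        for locus, k in per_locus.items():
            for col in range(k):
                sites.append(SNPSite(locus, col))
                if locus in private_loci and col == 0:
                    for i in ids:
                        rows[i].append("G" if species[i] == "A" else "T")
                else:
                    # shared polymorphism: both alleles occur in both taxa
                    for j, i in enumerate(ids):
                        rows[i].append("C" if (j + col) % 2 else "A")
        gm = gm_from_rows(
            {i: "".join(rows[i]) for i in ids}, species, sites=sites
        )
        assert len(sites) == 21
        kept, _ = select_diagnostic_loci(gm, ("A", "B"))
        assert kept == sorted(private_loci)


class TestDefineChlorotypes:
    def test_all_identical_one_chlorotype(self):
        gm = gm_from_rows(
            {"x1": "AC", "x2": "AC", "x3": "AC"},
            {"x1": "A", "x2": "A", "x3": "B"},
        )
        cset = define_chlorotypes(gm)
        assert len(cset.chlorotypes) == 1
        assert cset.chlorotypes[0].counts == {"A": 2, "B": 1}

    def test_counts_and_ranking(self):
        gm = gm_from_rows(
            {"x1": "AAA", "x2": "AAA", "x3": "AAC", "x4": "ACC"},
            {k: "A" for k in ("x1", "x2", "x3", "x4")},
        )
        cset = define_chlorotypes(gm)
        assert [c.total for c in cset.chlorotypes] == [2, 1, 1]
        assert cset.chlorotypes[0].alleles == ("A", "A", "A")

    def test_missing_data_excluded_and_counted(self):
        gm = gm_from_rows(
            {"x1": "AA", "x2": "A.", "x3": "CC"},
            {"x1": "A", "x2": "A", "x3": "B"},
        )
        cset = define_chlorotypes(gm)
        assert cset.n_excluded == 1
        assert sum(c.total for c in cset.chlorotypes) == 2

    def test_invariant_to_individual_order(self, rng):
        ids = [f"x{i}" for i in range(12)]
        vecs = ["".join(rng.choice(list("AG"), size=3)) for _ in ids]
        species = {i: "S" for i in ids}
        base = define_chlorotypes(gm_from_rows(dict(zip(ids, vecs)), species))
        perm = rng.permutation(len(ids))
        shuffled = define_chlorotypes(
            gm_from_rows(
                {ids[i]: vecs[i] for i in perm}, species
            )
        )
        assert {c.alleles: c.total for c in base.chlorotypes} == {
            c.alleles: c.total for c in shuffled.chlorotypes
        }

    def test_matches_bruteforce_row_set(self, rng):
        for _ in range(20):
            ids = [f"x{i}" for i in range(rng.integers(2, 15))]
            vecs = ["".join(rng.choice(list("ACGT"), size=4)) for _ in ids]
            cset = define_chlorotypes(
                gm_from_rows(dict(zip(ids, vecs)), {i: "S" for i in ids})
            )
            assert len(cset.chlorotypes) == len(set(vecs))

    def test_no_complete_individuals_is_an_error(self):
        gm = gm_from_rows({"x1": ".A", "x2": "A."}, {"x1": "A", "x2": "A"})
        with pytest.raises(ValueError, match="complete"):
            define_chlorotypes(gm)


def cset_from_vectors(vectors, counts=None, species="S"):
    counts = counts or [1] * len(vectors)
    cts = [
        Chlorotype(i + 1, tuple(v), {species: c})
        for i, (v, c) in enumerate(zip(vectors, counts))
    ]
    sites = [SNPSite(f"L{i + 1}", 0) for i in range(len(vectors[0]))]
    return ChlorotypeSet(cts, sites, {}, 0)


class TestCompareFrequencies:
    def _cset(self, table):
        """ChlorotypeSet with given species x chlorotype counts."""
        species = [f"sp{i}" for i in range(len(table))]
        cts = []
        for j in range(len(table[0])):
            counts = {species[i]: table[i][j] for i in range(len(table)) if table[i][j]}
            cts.append(Chlorotype(j + 1, tuple("A" * (j + 1)), counts))
        sites = [SNPSite("L1", 0)]
        return ChlorotypeSet(cts, sites, {}, 0), species

    def test_perfect_separation_closed_form(self):
        cset, sp = self._cset([[10, 0], [0, 10]])
        res = compare_frequencies(cset, (sp[0], sp[1]))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_identical_rows_give_zero(self):
        cset, sp = self._cset([[5, 5], [5, 5]])
        res = compare_frequencies(cset, (sp[0], sp[1]))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        table = rng.integers(1, 30, size=(3, 5))
        cset, sp = self._cset(table.tolist())
        res = compare_frequencies(cset)
        expected = table.sum(1, keepdims=True) * table.sum(0) / table.sum()
        stat = (((table - expected) ** 2) / expected).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 8

    def test_monte_carlo_close_to_asymptotic_on_large_tables(self):
        cset, sp = self._cset([[40, 30, 4], [30, 40, 4]])
        res = compare_frequencies(cset, n_permutations=20_000, seed=11)
        assert res.pvalue_monte_carlo is not None  # an expected count < 5
        # the conditional MC null and the chi-squared approximation differ
        # slightly when one column is sparse; they must still agree closely
        assert res.pvalue_monte_carlo == pytest.approx(res.pvalue, abs=0.03)

    def test_degenerate_table_rejected(self):
        cset, sp = self._cset([[10], [5]])
        with pytest.raises(ValueError, match="degenerate"):
            compare_frequencies(cset)


def all_minimum_spanning_trees_union(vectors):
    """Oracle: enumerate every spanning tree of the complete Hamming graph."""
    n = len(vectors)
    nodes = list(range(n))
    edges = [
        (i, j, hamming(vectors[i], vectors[j]))
        for i, j in itertools.combinations(nodes, 2)
    ]
    best_weight = None
    union = set()
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(combo)
        if not nx.is_connected(g):
            continue
        w = sum(e[2] for e in combo)
        if best_weight is None or w < best_weight:
            best_weight = w
            union = {(e[0], e[1]) for e in combo}
        elif w == best_weight:
            union |= {(e[0], e[1]) for e in combo}
    return union, best_weight


class TestMSN:
    def test_single_chlorotype(self):
        g = build_msn(cset_from_vectors(["AAA"]))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_chain_topology(self):
        g = build_msn(cset_from_vectors(["AAA", "AAC", "ACC"]))
        edges = {tuple(sorted(e)) for e in g.edges}
        assert edges == {(1, 2), (2, 3)}

    def test_equidistant_vectors_give_complete_graph(self):
        # all pairwise Hamming distances equal 2
        g = build_msn(cset_from_vectors(["AAAA", "AACC", "ACAC", "ACCA"]))
        assert g.number_of_edges() == 6

    def test_edge_labels_carry_discriminating_sites(self):
        g = build_msn(cset_from_vectors(["AAA", "AAC"]))
        assert g.edges[1, 2]["sites"] == ["L3:0"]

    def test_union_of_all_msts_oracle(self, rng):
        """MSN edge set equals the brute-force union over random small sets."""
        for _ in range(60):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 7))
            vectors = list(
                {tuple(rng.choice(list("AG"), size=k)) for _ in range(n)}
            )
            if len(vectors) < 2:
                continue
            cset = cset_from_vectors(["".join(v) for v in vectors])
            g = build_msn(cset)
            oracle, best = all_minimum_spanning_trees_union(
                ["".join(v) for v in vectors]
            )
            got = {(u - 1, v - 1) for u, v in g.edges}
            assert got == {tuple(sorted(e)) for e in oracle}

    def test_contains_a_minimum_spanning_tree(self, rng):
        vectors = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(6)]
        vectors = list(dict.fromkeys(vectors))
        cset = cset_from_vectors(vectors)
        g = build_msn(cset)
        full = nx.Graph()
        for i, j in itertools.combinations(range(len(vectors)), 2):
            full.add_edge(i + 1, j + 1, weight=hamming(vectors[i], vectors[j]))
        mst_w = sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(full).edges(data=True))
        sub = nx.minimum_spanning_tree(g)
        assert nx.is_connected(g)
        assert sum(d["weight"] for _, _, d in sub.edges(data=True)) == mst_w
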