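"""Chlorotype workflow: diagnostic loci, haplotype calling, tests, MSN.

A chlorotype is a haplotype defined by the combination of chloroplast SNP
alleles an individual carries.  Because cpDNA is haploid, uniparentally
inherited and effectively non-recombining, the allele vector over a panel of
SNP sites characterises a maternal lineage; frequencies of chlorotypes can be
compared between species with a chi-squared test and their relationships
drawn as a minimum spanning network (MSN) — the union of *all* minimum
spanning trees of the complete Hamming-distance graph, so that every
equally-parsimonious link is shown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .align import BASES, LocusAlignment


@dataclass(frozen=True)
class SNPSite:
    """A SNP address: locus name plus 0-based alignment column."""

    locus: str
    column: int

    @property
    def label(self) -> str:
        return f"{self.locus}:{self.column}"


@dataclass
class GenotypeMatrix:
    """Individuals x SNP sites; entries are bases or None for missing."""

    calls: pd.DataFrame  # index: sample_id, columns: site labels
    species: pd.Series  # sample_id -> species
    sites: list[SNPSite]

    def complete_mask(self) -> pd.Series:
        return self.calls.notna().all(axis=1)

    @property
    def incomplete_individuals(self) -> list[str]:
        return list(self.calls.index[~self.complete_mask()])


@dataclass
class Chlorotype:
    id: int  # 1-based, numbered by descending total frequency
    alleles: tuple[str, ...]
    counts: dict[str, int]  # species -> individuals

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ChlorotypeSet:
    chlorotypes: list[Chlorotype]
    sites: list[SNPSite]
    assignments: dict[str, int]  # sample_id -> chlorotype id (complete data only)
    n_excluded: int = 0

    def frequency_table(self) -> pd.DataFrame:
        """Species x chlorotype contingency table."""
        species = sorted({sp for c in self.chlorotypes for sp in c.counts})
        data = {
            f"chlorotype_{c.id}": [c.counts.get(sp, 0) for sp in species]
            for c in self.chlorotypes
        }
        return pd.DataFrame(data, index=species)


def call_genotypes(
    alignments: dict[str, LocusAlignment], sites: Sequence[SNPSite]
) -> GenotypeMatrix:
    """Read each individual's base at each SNP site.

    Gaps, Ns and ambiguity codes become missing values; individuals with any
    missing site are excluded from chlorotype counting downstream (they stay
    in the matrix, flagged via :meth:`GenotypeMatrix.complete_mask`).
    """
    if not sites:
        raise ValueError("no SNP sites given")
    first = alignments[sites[0].locus]
    sample_ids = first.sample_ids
    species = pd.Series(
        {s.sample_id: s.species for aln in alignments.values() for s in aln.samples}
    )
    data: dict[str, list[Optional[str]]] = {}
    for site in sites:
        if site.locus not in alignments:
            raise KeyError(f"no alignment for locus {site.locus!r}")
        aln = alignments[site.locus]
        if not 0 <= site.column < aln.n_columns:
            raise IndexError(
                f"column {site.column} outside alignment {site.locus!r} "
                f"({aln.n_columns} columns)"
            )
        col: list[Optional[str]] = []
        for sid in sample_ids:
            base = aln.row_for(sid)[site.column]
            col.append(base if base in BASES else None)
        data[site.label] = col
    calls = pd.DataFrame(data, index=sample_ids)
    return GenotypeMatrix(calls, species.loc[sample_ids], list(sites))


def select_diagnostic_loci(
    gm: GenotypeMatrix, taxa: tuple[str, str]
) -> tuple[list[str], pd.DataFrame]:
    """Retain loci carrying an allele private to one of two target taxa.

    A locus is kept iff at least one of its sites shows an allele observed in
    exactly one of the two taxa and absent from the other, the site being
    polymorphic across the pooled pair.  Returns the retained locus names and
    a per-site justification table.
    """
    a, b = taxa
    in_a = gm.species == a
    in_b = gm.species == b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"both taxa {taxa} need at least one individual")

    rows = []
    for site in gm.sites:
        col = gm.calls[site.label]
        alleles_a = set(col[in_a.values].dropna())
        alleles_b = set(col[in_b.values].dropna())
        pooled = alleles_a | alleles_b
        private = sorted((alleles_a ^ alleles_b)) if len(pooled) >= 2 else []
        rows.append(
            {
                "locus": site.locus,
                "column": site.column,
                "alleles_" + a: "/".join(sorted(alleles_a)),
                "alleles_" + b: "/".join(sorted(alleles_b)),
                "private_alleles": "/".join(private),
                "diagnostic": bool(private),
            }
        )
    table = pd.DataFrame(rows)
    kept = sorted(table.loc[table["diagnostic"], "locus"].unique())
    return kept, table


def define_chlorotypes(gm: GenotypeMatrix) -> ChlorotypeSet:
    """Collapse complete-data individuals into unique allele combinations."""
    complete = gm.complete_mask()
    if not complete.any():
        raise ValueError("no individual has complete data at all sites")
    sub = gm.calls[complete]
    order: list[tuple[str, ...]] = []
    members: dict[tuple[str, ...], list[str]] = {}
    for sid, row in sub.iterrows():
        vec = tuple(row)
        if vec not in members:
            members[vec] = []
            order.append(vec)
        members[vec].append(sid)

    ranked = sorted(order, key=lambda v: (-len(members[v]), order.index(v)))
    chlorotypes = []
    assignments: dict[str, int] = {}
    for cid, vec in enumerate(ranked, start=1):
        counts: dict[str, int] = {}
        for sid in members[vec]:
            sp = gm.species[sid]
            counts[sp] = counts.get(sp, 0) + 1
            assignments[sid] = cid
        chlorotypes.append(Chlorotype(cid, vec, counts))
    return ChlorotypeSet(
        chlorotypes,
        list(gm.sites),
        assignments,
        n_excluded=int((~complete).sum()),
    )


@dataclass
class FrequencyTestResult:
    table: pd.DataFrame
    statistic: float
    df: int
    pvalue: float
    pvalue_monte_carlo: Optional[float] = None
    min_expected: float = float("nan")


def compare_frequencies(
    cset: ChlorotypeSet,
    species_pair: Optional[tuple[str, str]] = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> FrequencyTestResult:
    """Chi-squared test of chlorotype frequencies between species.

    Uses the full species x chlorotype table (restricted to a pair when
    given), dropping all-zero columns.  When any expected count is below 5 a
    seeded Monte-Carlo p-value (permutation of species labels) is added.
    """
    table = cset.frequency_table()
    if species_pair is not None:
        table = table.loc[list(species_pair)]
    table = table.loc[:, (table.sum(axis=0) > 0)]
    table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {table.shape}: nothing to compare"
        )
    obs = table.to_numpy()
    res = chi2_contingency(obs, correction=False)
    stat, p, dof, expected = res.statistic, res.pvalue, res.dof, res.expected_freq

    p_mc = None
    if (expected < 5).any():
        p_mc = _monte_carlo_pvalue(obs, stat, n_permutations, seed)
    return FrequencyTestResult(
        table, float(stat), int(dof), float(p), p_mc, float(expected.min())
    )


def _chi2_stat(obs: np.ndarray) -> float:
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows * cols / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _monte_carlo_pvalue(
    obs: np.ndarray, stat: float, n_permutations: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(obs.shape[0]), obs.sum(axis=1))
    col_labels = np.repeat(np.arange(obs.shape[1]), obs.sum(axis=0))
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(col_labels)
        perm = np.zeros_like(obs)
        np.add.at(perm, (row_labels, col_labels), 1)
        if _chi2_stat(perm) >= stat - 1e-9:
            count += 1
    return (count + 1) / (n_permutations + 1)


def hamming(a: Sequence[str], b: Sequence[str]) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_msn(cset: ChlorotypeSet) -> nx.Graph:
    """Minimum spanning network over chlorotypes.

    Builds the complete graph weighted by Hamming distance over the SNP
    sites, then keeps exactly the union of all its minimum spanning trees:
    edges are processed in ascending weight classes and, within a class,
    every edge joining two components *as they stood before the class was
    processed* is retained.  Edge attributes carry the weight and the
    discriminating site labels.
    """
    g = nx.Graph()
    for c in cset.chlorotypes:
        g.add_node(c.id, frequency=c.total, alleles=c.alleles, counts=c.counts)
    n = len(cset.chlorotypes)
    if n == 1:
        return g

    by_id = {c.id: c for c in cset.chlorotypes}
    edges: dict[int, list[tuple[int, int]]] = {}
    for i, ci in by_id.items():
        for j, cj in by_id.items():
            if i < j:
                edges.setdefault(hamming(ci.alleles, cj.alleles), []).append((i, j))

    parent = {c.id: c.id for c in cset.chlorotypes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    labels = [s.label for s in cset.sites]
    for w in sorted(edges):
        snapshot = {nid: find(nid) for nid in parent}
        keep = [(i, j) for i, j in edges[w] if snapshot[i] != snapshot[j]]
        for i, j in keep:
            diff = [
                labels[k]
                for k, (x, y) in enumerate(zip(by_id[i].alleles, by_id[j].alleles))
                if x != y
            ]
            g.add_edge(i, j, weight=w, sites=diff)
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return g
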