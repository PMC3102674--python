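"""Synthetic plastome evolution with a fully known event history.

The generator emulates the statistical structure the diversity analysis
assumes: a circular quadripartite genome (LSC + IRb + SSC + IRa, with IRa the
exact reverse complement of IRb), loci of three feature classes laid out
inside the regions, a genus > species > individual lineage tree, per-region
substitution rates (the IR is typically given a depressed rate), stepwise
(+/-1 unit) mutation of planted tandem repeats, and small 1-5 bp indels
restricted to non-exon features.

Every mutation event is logged in a :class:`TruthTable`, and because the full
event history is known the emitted per-locus alignments are *true*
alignments: indel and repeat-count differences appear as gap columns placed
exactly where the events dictate, with no realignment step.  Identical
configurations (including the seed) produce byte-identical output.

Substitutions and indels never land inside planted repeat arrays and both IR
copies mutate identically (concerted evolution), so repeat counts and the IR
mirror remain well defined throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import LocusAlignment, Sample
from .regions import RegionMap, reverse_complement
from .vntr import find_tandem_repeats

REGION_ORDER = ("LSC", "IR", "SSC")
SPACER = 3  # bp of non-locus sequence between placed loci
_ALT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass(frozen=True)
class LocusSpec:
    name: str
    feature_class: str  # exon | intron | IGS
    region: str  # LSC | SSC | IR
    length: int


@dataclass(frozen=True)
class VNTRSpec:
    """A tandem array planted in the template that mutates by +/-1 repeat steps."""

    motif: str
    initial_repeats: int
    step_rate: float  # probability of one +/-1 step per lineage split
    locus: str


@dataclass
class SimulationConfig:
    seed: int
    genome_lengths: dict[str, int]  # LSC, SSC and one IR unit, in bp
    locus_layout: list[LocusSpec]
    taxonomy: dict[str, dict[str, int]]  # genus -> species -> n individuals
    snp_rate: dict[str, float]  # region -> substitutions / bp / lineage split
    vntr_specs: list[VNTRSpec] = field(default_factory=list)
    indel_rate: float = 0.0  # events / bp / lineage split, non-exon loci only
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    #: per-level multipliers applied to every rate on branches of that level;
    #: lets population samples be much less diverged than species or genera
    level_rates: dict[str, float] = field(
        default_factory=lambda: {"genus": 1.0, "species": 1.0, "individual": 1.0}
    )

    def validate(self) -> None:
        for region in ("LSC", "SSC", "IR"):
            if region not in self.genome_lengths:
                raise ValueError(f"genome_lengths missing {region}")
        if self.genome_lengths["LSC"] < self.genome_lengths["SSC"]:
            raise ValueError("LSC must be at least as long as SSC")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.indel_rate < 0 or any(r < 0 for r in self.snp_rate.values()):
            raise ValueError("rates must be non-negative")
        names = [l.name for l in self.locus_layout]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for region in REGION_ORDER:
            loci = [l for l in self.locus_layout if l.region == region]
            need = sum(l.length for l in loci) + SPACER * (len(loci) + 1)
            if need > self.genome_lengths[region]:
                raise ValueError(
                    f"loci overflow region {region}: need {need} bp, "
                    f"have {self.genome_lengths[region]}"
                )
        by_name = {l.name: l for l in self.locus_layout}
        for v in self.vntr_specs:
            if not 1 <= len(v.motif) <= 30:
                raise ValueError(f"motif length {len(v.motif)} outside [1, 30]")
            if v.initial_repeats < 1 or v.step_rate < 0:
                raise ValueError("initial_repeats >= 1 and step_rate >= 0 required")
            if v.locus not in by_name:
                raise ValueError(f"VNTR host locus {v.locus!r} not in layout")
            if by_name[v.locus].length < len(v.motif) * v.initial_repeats + 4:
                raise ValueError(f"locus {v.locus!r} too short for its VNTR")
        if not self.taxonomy or not any(
            n >= 1 for sp in self.taxonomy.values() for n in sp.values()
        ):
            raise ValueError("taxonomy must contain at least one individual")
        if any(v < 0 for v in self.level_rates.values()):
            raise ValueError("level_rates must be non-negative")


@dataclass(frozen=True)
class PlantedVNTR:
    offset: int  # within locus template
    motif: str
    initial_repeats: int
    step_rate: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.offset, self.offset + len(self.motif) * self.initial_repeats)


@dataclass
class PlacedLocus:
    name: str
    feature_class: str
    region: str
    region_offset: int  # start within its region
    template: str
    vntrs: list[PlantedVNTR] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.template)


@dataclass
class AnnotatedGenome:
    region_seqs: dict[str, str]  # LSC, IR (= IRb unit), SSC templates
    loci: list[PlacedLocus]
    region_map: RegionMap

    @property
    def sequence(self) -> str:
        lsc, ir, ssc = (self.region_seqs[r] for r in REGION_ORDER)
        return lsc + ir + ssc + reverse_complement(ir)

    def locus_interval(self, name: str) -> tuple[int, int]:
        """Absolute 0-based half-open genome coordinates of a locus."""
        offsets = {
            "LSC": 0,
            "IR": len(self.region_seqs["LSC"]),
            "SSC": len(self.region_seqs["LSC"]) + len(self.region_seqs["IR"]),
        }
        for loc in self.loci:
            if loc.name == name:
                start = offsets[loc.region] + loc.region_offset
                return (start, start + loc.length)
        raise KeyError(name)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

_CLEAN_THRESHOLDS = dict(min_homopolymer=6, min_repeats_short=2, min_repeats_long=2)


def _random_bases(rng: np.random.Generator, n: int, comp) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n, p=list(comp)))


def _clean_sequence(
    rng: np.random.Generator,
    seq: list[str],
    comp,
    protected: Sequence[tuple[int, int]] = (),
    max_rounds: int = 200,
) -> None:
    """Re-randomise spans that form tandem arrays, leaving protected spans alone.

    Cleaning uses thresholds slightly stricter than detection so that planted
    arrays sit in genuinely non-repetitive flanking sequence.
    """
    for _ in range(max_rounds):
        arrays = find_tandem_repeats("".join(seq), **_CLEAN_THRESHOLDS)
        offenders = [
            a
            for a in arrays
            if not any(a.offset >= s and a.end <= e for s, e in protected)
        ]
        if not offenders:
            return
        for a in offenders:
            for i in range(a.offset, a.end):
                if not any(s <= i < e for s, e in protected):
                    seq[i] = str(rng.choice(list("ACGT"), p=list(comp)))
    raise RuntimeError("could not generate non-repetitive sequence")


def _plant_array(
    rng: np.random.Generator, seq: list[str], offset: int, motif: str, repeats: int
) -> None:
    """Overwrite seq[offset:] with a tandem array and break both flanks."""
    m = len(motif)
    end = offset + m * repeats
    seq[offset:end] = list(motif * repeats)
    # left flank must not extend the period; same for the right flank
    left_ban = {motif[-1], seq[offset - 2] if offset >= 2 else ""}
    seq[offset - 1] = next(b for b in "ACGT" if b not in left_ban)
    right_ban = {motif[0], seq[end + 1] if end + 1 < len(seq) else ""}
    seq[end] = next(b for b in "ACGT" if b not in right_ban)


def build_template_genome(config: SimulationConfig) -> AnnotatedGenome:
    """Construct the ancestral circular genome with loci and planted arrays."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    comp = config.base_composition
    vntrs_by_locus: dict[str, list[VNTRSpec]] = {}
    for v in config.vntr_specs:
        vntrs_by_locus.setdefault(v.locus, []).append(v)

    region_seqs: dict[str, str] = {}
    placed: list[PlacedLocus] = []
    for region in REGION_ORDER:
        loci = [l for l in config.locus_layout if l.region == region]
        chunks: list[str] = []
        cursor = 0
        for spec in loci:
            chunks.append("".join(_random_bases(rng, SPACER, comp)))
            cursor += SPACER
            seq = _random_bases(rng, spec.length, comp)
            _clean_sequence(rng, seq, comp)
            planted: list[PlantedVNTR] = []
            for v in vntrs_by_locus.get(spec.name, ()):
                m = len(v.motif)
                span_len = m * v.initial_repeats
                lo, hi = 2, spec.length - span_len - 2
                # keep arrays in one locus well separated
                for _ in range(100):
                    off = int(rng.integers(lo, hi + 1))
                    if all(
                        off + span_len + 2 <= p.offset or off >= p.span[1] + 2
                        for p in planted
                    ):
                        break
                else:
                    raise RuntimeError(f"cannot place VNTRs in locus {spec.name}")
                _plant_array(rng, seq, off, v.motif, v.initial_repeats)
                planted.append(
                    PlantedVNTR(off, v.motif, v.initial_repeats, v.step_rate)
                )
            _clean_sequence(rng, seq, comp, protected=[p.span for p in planted])
            placed.append(
                PlacedLocus(
                    spec.name, spec.feature_class, region, cursor, "".join(seq),
                    sorted(planted, key=lambda p: p.offset),
                )
            )
            chunks.append(placed[-1].template)
            cursor += spec.length
        tail = config.genome_lengths[region] - cursor
        chunks.append("".join(_random_bases(rng, tail, comp)))
        region_seqs[region] = "".join(chunks)

    # pin the single-copy flanks so the true inverted repeat is exactly the
    # configured IR unit: chance complementarity at the junctions would
    # otherwise extend the maximal repeat by a base or two
    comp_of = dict(zip("ACGT", "TGCA"))
    lsc = list(region_seqs["LSC"])
    if lsc[-1] == comp_of[lsc[0]]:
        lsc[-1] = next(b for b in "ACGT" if b != comp_of[lsc[0]] and b != lsc[-2])
    region_seqs["LSC"] = "".join(lsc)
    ssc = list(region_seqs["SSC"])
    if ssc[0] == comp_of[ssc[-1]]:
        ssc[0] = next(b for b in "ACGT" if b != comp_of[ssc[-1]] and b != ssc[1])
    region_seqs["SSC"] = "".join(ssc)

    l_lsc = len(region_seqs["LSC"])
    l_ir = len(region_seqs["IR"])
    l_ssc = len(region_seqs["SSC"])
    n = l_lsc + 2 * l_ir + l_ssc
    region_map = RegionMap(
        lsc=(0, l_lsc),
        irb=(l_lsc, l_lsc + l_ir),
        ssc=(l_lsc + l_ir, l_lsc + l_ir + l_ssc),
        ira=(l_lsc + l_ir + l_ssc, n),
        genome_length=n,
    )
    return AnnotatedGenome(region_seqs, placed, region_map)


# ---------------------------------------------------------------------------
# divergence simulation
# ---------------------------------------------------------------------------


@dataclass
class _LocusState:
    bases: list[str]
    present: np.ndarray  # bool per template column (False = deleted)
    insertions: set[int]  # active insertion event ids
    vntr_counts: list[int]


@dataclass
class IndividualData:
    sample: Sample
    loci: dict[str, _LocusState]


@dataclass
class TruthTable:
    """Complete mutation history of one simulation run."""

    snps: list[dict]  # locus, template_pos, aln_col, branch, ref, alt
    indels: list[dict]  # locus, kind, position/anchor, length, branch, event_id
    vntr_counts: list[dict]  # locus, vntr_index, offset, motif, sample_id, count
    insertion_registry: dict[int, dict]  # event_id -> locus, anchor, seq
    region_truth: RegionMap
    column_maps: dict[str, np.ndarray] = field(default_factory=dict)
    vntr_alignment_spans: dict[tuple[str, int], tuple[int, int]] = field(
        default_factory=dict
    )


def _taxonomy_walk(taxonomy: dict[str, dict[str, int]]):
    """Deterministic depth-first traversal yielding (kind, labels)."""
    for genus in sorted(taxonomy):
        yield ("genus", genus, None, None)
        for species in sorted(taxonomy[genus]):
            yield ("species", genus, species, None)
            for i in range(taxonomy[genus][species]):
                yield ("individual", genus, species, i)


def sample_id_for(genus: str, species: str, index: int) -> str:
    return f"{genus}_{species}_{index + 1:02d}"


def simulate_divergence(
    template: AnnotatedGenome, config: SimulationConfig
) -> tuple[list[IndividualData], TruthTable]:
    """Evolve individuals down the taxonomy tree, logging every event.

    One branch per lineage split (root->genus, genus->species,
    species->individual).  Substitutions hit non-repeat, non-deleted columns
    at the region's rate; indels (1-5 bp, equiprobable insertion/deletion)
    hit non-exon loci; planted arrays step by +/-1 repeat with their
    configured probability, floored at 1 repeat.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthTable([], [], [], {}, template.region_map)
    next_event_id = [0]

    def fresh_states() -> dict[str, _LocusState]:
        return {
            loc.name: _LocusState(
                bases=list(loc.template),
                present=np.ones(loc.length, dtype=bool),
                insertions=set(),
                vntr_counts=[v.initial_repeats for v in loc.vntrs],
            )
            for loc in template.loci
        }

    def vntr_mask(loc: PlacedLocus) -> np.ndarray:
        mask = np.zeros(loc.length, dtype=bool)
        for v in loc.vntrs:
            mask[v.span[0] : v.span[1]] = True
        return mask

    masks = {loc.name: vntr_mask(loc) for loc in template.loci}

    def apply_branch(states: dict[str, _LocusState], branch: str) -> None:
        scale = config.level_rates.get(branch.split(":", 1)[0], 1.0)
        indel_rate = config.indel_rate * scale
        for loc in template.loci:
            st = states[loc.name]
            cand = np.nonzero(st.present & ~masks[loc.name])[0]
            rate = config.snp_rate.get(loc.region, 0.0) * scale
            if rate > 0 and cand.size:
                k = int(rng.binomial(cand.size, rate))
                if k:
                    positions = np.sort(rng.choice(cand, size=k, replace=False))
                    for p in positions:
                        ref = st.bases[p]
                        alt = _ALT[ref][int(rng.integers(3))]
                        st.bases[p] = alt
                        truth.snps.append(
                            dict(
                                locus=loc.name,
                                template_pos=int(p),
                                aln_col=-1,
                                branch=branch,
                                ref=ref,
                                alt=alt,
                            )
                        )
            if indel_rate > 0 and loc.feature_class != "exon" and cand.size:
                k = int(rng.binomial(cand.size, indel_rate))
                for _ in range(k):
                    length = int(rng.integers(1, 6))
                    if rng.random() < 0.5:  # deletion of consecutive columns
                        start = int(rng.choice(cand))
                        end = start
                        removed = 0
                        while (
                            end < loc.length
                            and removed < length
                            and st.present[end]
                            and not masks[loc.name][end]
                        ):
                            st.present[end] = False
                            end += 1
                            removed += 1
                        if removed:
                            truth.indels.append(
                                dict(
                                    locus=loc.name,
                                    kind="deletion",
                                    position=start,
                                    length=removed,
                                    branch=branch,
                                    event_id=-1,
                                )
                            )
                        cand = np.nonzero(st.present & ~masks[loc.name])[0]
                    else:  # insertion anchored between template columns
                        anchors = [
                            a
                            for a in range(loc.length + 1)
                            if not any(s < a < e for s, e in (v.span for v in loc.vntrs))
                        ]
                        anchor = int(rng.choice(anchors))
                        seq = "".join(
                            rng.choice(
                                list("ACGT"),
                                size=length,
                                p=list(config.base_composition),
                            )
                        )
                        eid = next_event_id[0]
                        next_event_id[0] += 1
                        truth.insertion_registry[eid] = dict(
                            locus=loc.name, anchor=anchor, seq=seq
                        )
                        truth.indels.append(
                            dict(
                                locus=loc.name,
                                kind="insertion",
                                position=anchor,
                                length=length,
                                branch=branch,
                                event_id=eid,
                            )
                        )
                        st.insertions.add(eid)
            for vi, v in enumerate(loc.vntrs):
                if v.step_rate > 0 and rng.random() < v.step_rate * scale:
                    delta = 1 if rng.random() < 0.5 else -1
                    new = max(1, st.vntr_counts[vi] + delta)
                    st.vntr_counts[vi] = new

    individuals: list[IndividualData] = []
    genus_state: dict[str, _LocusState] = {}
    species_state: dict[str, _LocusState] = {}
    for kind, genus, species, idx in _taxonomy_walk(config.taxonomy):
        if kind == "genus":
            genus_state = fresh_states()
            apply_branch(genus_state, f"genus:{genus}")
        elif kind == "species":
            species_state = copy.deepcopy(genus_state)
            apply_branch(species_state, f"species:{genus}/{species}")
        else:
            sid = sample_id_for(genus, species, idx)
            ind_state = copy.deepcopy(species_state)
            apply_branch(ind_state, f"individual:{sid}")
            individuals.append(
                IndividualData(Sample(sid, genus, species), ind_state)
            )

    for ind in individuals:
        for loc in template.loci:
            st = ind.loci[loc.name]
            for vi, v in enumerate(loc.vntrs):
                truth.vntr_counts.append(
                    dict(
                        locus=loc.name,
                        vntr_index=vi,
                        offset=v.offset,
                        motif=v.motif,
                        sample_id=ind.sample.sample_id,
                        count=st.vntr_counts[vi],
                    )
                )
    return individuals, truth


# ---------------------------------------------------------------------------
# alignment emission
# ---------------------------------------------------------------------------


def emit_locus_alignments(
    individuals: Sequence[IndividualData],
    template: AnnotatedGenome,
    truth: TruthTable,
) -> dict[str, LocusAlignment]:
    """Assemble the true per-locus alignments implied by the event history.

    Also back-fills alignment column indices on the SNP truth entries, the
    template-column -> alignment-column maps and the alignment spans of every
    planted array.
    """
    alignments: dict[str, LocusAlignment] = {}
    for loc in template.loci:
        ins_by_anchor: dict[int, list[tuple[int, str]]] = {}
        for eid, info in truth.insertion_registry.items():
            if info["locus"] == loc.name:
                ins_by_anchor.setdefault(info["anchor"], []).append(
                    (eid, info["seq"])
                )
        for lst in ins_by_anchor.values():
            lst.sort()
        vntr_at = {v.offset: (vi, v) for vi, v in enumerate(loc.vntrs)}
        max_counts = {
            vi: max(ind.loci[loc.name].vntr_counts[vi] for ind in individuals)
            for vi in range(len(loc.vntrs))
        }

        pieces: list[list[str]] = [[] for _ in individuals]
        t2a = np.full(loc.length, -1, dtype=int)
        aln_pos = 0
        c = 0
        while c <= loc.length:
            for eid, seq in ins_by_anchor.get(c, ()):  # insertions before col c
                for row, ind in zip(pieces, individuals):
                    has = eid in ind.loci[loc.name].insertions
                    row.append(seq if has else "-" * len(seq))
                aln_pos += len(seq)
            if c == loc.length:
                break
            if c in vntr_at:
                vi, v = vntr_at[c]
                m = len(v.motif)
                width = m * max_counts[vi]
                for row, ind in zip(pieces, individuals):
                    count = ind.loci[loc.name].vntr_counts[vi]
                    row.append(v.motif * count + "-" * (m * (max_counts[vi] - count)))
                truth.vntr_alignment_spans[(loc.name, vi)] = (
                    aln_pos,
                    aln_pos + width,
                )
                aln_pos += width
                c += m * v.initial_repeats
            else:
                t2a[c] = aln_pos
                for row, ind in zip(pieces, individuals):
                    st = ind.loci[loc.name]
                    row.append(st.bases[c] if st.present[c] else "-")
                aln_pos += 1
                c += 1
        truth.column_maps[loc.name] = t2a
        alignments[loc.name] = LocusAlignment(
            locus_name=loc.name,
            feature_class=loc.feature_class,
            region=loc.region,
            samples=[ind.sample for ind in individuals],
            rows=["".join(row) for row in pieces],
        )
    for ev in truth.snps:
        ev["aln_col"] = int(truth.column_maps[ev["locus"]][ev["template_pos"]])
    return alignments


def expected_snp_columns(
    individuals: Sequence[IndividualData],
    template: AnnotatedGenome,
    truth: TruthTable,
    locus: str,
) -> set[int]:
    """Alignment columns where the event history implies an observable SNP.

    A mutated template column is observable when no individual has it deleted
    and at least two distinct bases survive among the individuals (multiple
    hits can revert a site).
    """
    positions = {
        ev["template_pos"] for ev in truth.snps if ev["locus"] == locus
    }
    out = set()
    t2a = truth.column_maps[locus]
    for p in positions:
        if not all(ind.loci[locus].present[p] for ind in individuals):
            continue
        bases = {ind.loci[locus].bases[p] for ind in individuals}
        if len(bases) >= 2:
            out.add(int(t2a[p]))
    return out


def individual_genome(
    template: AnnotatedGenome, ind: IndividualData, truth: Optional[TruthTable] = None
) -> str:
    """Reconstruct one individual's full circular genome (IRa mirrors IRb)."""
    registry = truth.insertion_registry if truth is not None else {}
    by_region: dict[str, list[PlacedLocus]] = {r: [] for r in REGION_ORDER}
    for loc in template.loci:
        by_region[loc.region].append(loc)
    region_out: dict[str, str] = {}
    for region in REGION_ORDER:
        tmpl = template.region_seqs[region]
        out = []
        pos = 0
        for loc in sorted(by_region[region], key=lambda l: l.region_offset):
            out.append(tmpl[pos : loc.region_offset])
            out.append(_ungapped_locus_sequence(loc, ind.loci[loc.name], registry))
            pos = loc.region_offset + loc.length
        out.append(tmpl[pos:])
        region_out[region] = "".join(out)
    return (
        region_out["LSC"]
        + region_out["IR"]
        + region_out["SSC"]
        + reverse_complement(region_out["IR"])
    )


def _ungapped_locus_sequence(
    loc: PlacedLocus, st: _LocusState, registry: dict[int, dict]
) -> str:
    ins_by_anchor: dict[int, list[tuple[int, str]]] = {}
    for eid in sorted(st.insertions):  # global id order preserves event order
        info = registry.get(eid)
        if info is not None and info["locus"] == loc.name:
            ins_by_anchor.setdefault(info["anchor"], []).append((eid, info["seq"]))
    vntr_at = {v.offset: (vi, v) for vi, v in enumerate(loc.vntrs)}
    pieces: list[str] = []
    c = 0
    while c <= loc.length:
        for _, seq in ins_by_anchor.get(c, ()):
            pieces.append(seq)
        if c == loc.length:
            break
        if c in vntr_at:
            vi, v = vntr_at[c]
            pieces.append(v.motif * st.vntr_counts[vi])
            c += len(v.motif) * v.initial_repeats
        else:
            if st.present[c]:
                pieces.append(st.bases[c])
            c += 1
    return "".join(pieces)
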