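"""Tandem-repeat (VNTR) detection, cross-sample matching and tabulation.

Detects perfect tandem arrays with motifs of 1-30 bp on ungapped sequences:
homopolymer runs of at least 7 bp, 2-3 bp motifs with at least 3 repeats, and
motifs of 4 bp or longer with at least 2 repeats (arrays with a partial
terminal unit keep a real-valued repeat count).  Overlapping candidates are
resolved deterministically: largest repeated span first, ties broken by longer
motif, then by leftmost position.  Motifs are reported in their
lexicographically smallest rotation so the same array matches across samples
regardless of phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import GAP, LocusAlignment

MAX_MOTIF = 30


@dataclass(frozen=True)
class TandemArray:
    """A maximal perfect tandem array on one ungapped sequence."""

    offset: int  # 0-based start on the sequence
    end: int  # half-open end (includes any partial terminal unit)
    motif: str  # as-found phase (primitive)

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def repeats(self) -> float:
        return (self.end - self.offset) / len(self.motif)

    @property
    def canonical_motif(self) -> str:
        return canonical_rotation(self.motif)


@dataclass
class VNTRRecord:
    """A tandem-repeat site matched across the samples of one alignment."""

    locus_name: str
    span: tuple[int, int]  # alignment columns, 0-based half-open
    motif: str  # canonical rotation
    motif_length: int
    counts: dict[str, float]  # sample id -> repeat count (0 = absent)
    polymorphic: bool

    def count_floor(self, sample_id: str) -> int:
        return math.floor(self.counts[sample_id])

    @property
    def max_count(self) -> float:
        return max(self.counts.values())


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def smallest_period(s: str) -> int:
    for p in range(1, len(s)):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


def meets_thresholds(
    motif_length: int,
    span_length: int,
    min_homopolymer: int = 7,
    min_repeats_short: int = 3,
    min_repeats_long: int = 2,
) -> bool:
    """Detection floor per motif-length class."""
    if motif_length == 1:
        return span_length >= min_homopolymer
    full = span_length // motif_length
    if motif_length <= 3:
        return full >= min_repeats_short
    return full >= min_repeats_long


def find_tandem_repeats(
    sequence: str,
    max_motif: int = MAX_MOTIF,
    min_homopolymer: int = 7,
    min_repeats_short: int = 3,
    min_repeats_long: int = 2,
) -> list[TandemArray]:
    """All maximal, non-overlapping tandem arrays meeting the thresholds.

    The sequence must be ungapped (degap alignment rows first).  Candidate
    arrays are every maximal run of period p for each primitive motif length
    p <= ``max_motif``; overlaps are resolved by largest span, then longer
    motif, then leftmost start.
    """
    sequence = sequence.upper()
    if GAP in sequence:
        raise ValueError("gap characters present; degap before repeat search")
    n = len(sequence)
    if n < 2:
        return []
    candidates: list[TandemArray] = []
    for m in range(1, min(max_motif, n // 2) + 1):
        i = 0
        limit = n - m
        while i < limit:
            if sequence[i] != sequence[i + m]:
                i += 1
                continue
            # maximal run of period m starting at i
            j = i
            while j < limit and sequence[j] == sequence[j + m]:
                j += 1
            span_start, span_end = i, j + m  # includes partial terminal unit
            i = j + 1
            motif = sequence[span_start : span_start + m]
            if smallest_period(motif) != m:
                continue  # counted at its primitive period
            if "N" in motif:
                continue
            if meets_thresholds(
                m, span_end - span_start, min_homopolymer, min_repeats_short, min_repeats_long
            ):
                candidates.append(TandemArray(span_start, span_end, motif))
    return resolve_overlaps(candidates)


def resolve_overlaps(candidates: Sequence[TandemArray]) -> list[TandemArray]:
    """Greedy non-overlapping selection: span desc, motif length desc, leftmost."""
    ordered = sorted(
        candidates,
        key=lambda a: (-(a.end - a.offset), -a.motif_length, a.offset),
    )
    chosen: list[TandemArray] = []
    for cand in ordered:
        if all(cand.end <= c.offset or cand.offset >= c.end for c in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda a: a.offset)


def _tandem_count(segment: str, canonical: str, m: int) -> float:
    """Repeat count of a motif (any rotation) within a short segment; 0 if absent."""
    best = 0.0
    n = len(segment)
    for i in range(n - m + 1):
        if canonical_rotation(segment[i : i + m]) != canonical:
            continue
        j = i + m
        while j < n and segment[j] == segment[j - m]:
            j += 1
        best = max(best, (j - i) / m)
    return best


def project_to_alignment(
    aln: LocusAlignment,
    per_row: Optional[dict[str, list[TandemArray]]] = None,
    **thresholds,
) -> list[VNTRRecord]:
    """Match per-sample tandem arrays at homologous alignment positions.

    Arrays found on different rows are merged into one record when their
    alignment spans overlap and their canonical motifs agree.  Samples without
    a detected array at a merged span get the repeat count read directly from
    their own sequence over that span (possibly 1, or 0 when the motif is
    absent).
    """
    if per_row is None:
        per_row = {
            sid: find_tandem_repeats(aln.degapped_row(sid), **thresholds)
            for sid in aln.sample_ids
        }

    # lift each array onto alignment coordinates
    lifted: list[tuple[str, int, int, str, float]] = []
    for sid, arrays in per_row.items():
        cmap = aln.column_map(sid)
        for arr in arrays:
            a_start = int(cmap[arr.offset])
            a_end = int(cmap[arr.end - 1]) + 1
            lifted.append((sid, a_start, a_end, arr.canonical_motif, arr.repeats))

    # cluster by canonical motif + overlapping alignment spans
    clusters: list[dict] = []
    for sid, a_start, a_end, motif, reps in sorted(lifted, key=lambda t: t[1]):
        placed = False
        for cl in clusters:
            if cl["motif"] == motif and a_start < cl["end"] and a_end > cl["start"]:
                cl["start"] = min(cl["start"], a_start)
                cl["end"] = max(cl["end"], a_end)
                cl["counts"][sid] = reps
                placed = True
                break
        if not placed:
            clusters.append(
                {"motif": motif, "start": a_start, "end": a_end, "counts": {sid: reps}}
            )

    records = []
    for cl in clusters:
        m = len(cl["motif"])
        counts = dict(cl["counts"])
        for sid in aln.sample_ids:
            if sid in counts:
                continue
            segment = "".join(
                c for c in aln.row_for(sid)[cl["start"] : cl["end"]] if c != GAP
            )
            counts[sid] = _tandem_count(segment, cl["motif"], m) if len(segment) >= m else 0.0
        floors = {math.floor(c) for c in counts.values()}
        records.append(
            VNTRRecord(
                locus_name=aln.locus_name,
                span=(cl["start"], cl["end"]),
                motif=cl["motif"],
                motif_length=m,
                counts=counts,
                polymorphic=len(floors) > 1,
            )
        )
    return sorted(records, key=lambda r: r.span)


MOTIF_CLASSES = ("mononucleotide", "dinucleotide", "trinucleotide", "motif>3bp")


def classify_motif(record: VNTRRecord) -> str:
    """Motif-length class; trinucleotides are reported as their own class."""
    if record.motif_length == 1:
        return "mononucleotide"
    if record.motif_length == 2:
        return "dinucleotide"
    if record.motif_length == 3:
        return "trinucleotide"
    return "motif>3bp"


def _polymorphic_within(record: VNTRRecord, sample_ids: Sequence[str]) -> bool:
    floors = {record.count_floor(s) for s in sample_ids if s in record.counts}
    return len(floors) > 1


def tabulate_vntr(
    records: Sequence[VNTRRecord],
    genus_of: dict[str, str],
    feature_of: Optional[dict[str, str]] = None,
    min_listing_count: float = 2,
) -> dict[str, pd.DataFrame]:
    """Motif-class counts, the polynucleotide listing and feature-context shares.

    Returns three frames: ``by_class`` counts records polymorphic within each
    genus per motif-length class; ``listing`` is the polynucleotide table
    (motif length >= 2 bp, maximum repeat count > ``min_listing_count``,
    repeat-count variation within at least one genus) with per-genus count
    ranges; ``feature_shares`` gives the fraction of polymorphic records per
    feature class when locus feature classes are supplied.
    """
    genera = sorted(set(genus_of.values()))
    members = {g: [s for s, gg in genus_of.items() if gg == g] for g in genera}

    by_class = pd.DataFrame(0, index=list(MOTIF_CLASSES), columns=genera)
    for rec in records:
        cls = classify_motif(rec)
        for g in genera:
            if _polymorphic_within(rec, members[g]):
                by_class.loc[cls, g] += 1

    listing_rows = []
    for rec in records:
        if rec.motif_length < 2 or rec.max_count <= min_listing_count:
            continue
        if not any(_polymorphic_within(rec, members[g]) for g in genera):
            continue
        row = {
            "locus": rec.locus_name,
            "motif_length": rec.motif_length,
            "motif": rec.motif,
        }
        for g in genera:
            counts = sorted(
                {rec.count_floor(s) for s in members[g] if s in rec.counts}
            )
            if not counts:
                row[g] = ""
            elif counts[0] == counts[-1]:
                row[g] = str(counts[0])
            else:
                row[g] = f"{counts[0]}-{counts[-1]}"
        listing_rows.append(row)
    listing = pd.DataFrame(
        listing_rows, columns=["locus", "motif_length", "motif", *genera]
    )

    shares = pd.DataFrame()
    if feature_of is not None:
        poly = [r for r in records if r.polymorphic]
        tally: dict[str, int] = {}
        for r in poly:
            feat = feature_of.get(r.locus_name, "unknown")
            tally[feat] = tally.get(feat, 0) + 1
        total = sum(tally.values())
        shares = pd.DataFrame(
            [
                {"feature_class": f, "count": c, "share": c / total if total else 0.0}
                for f, c in sorted(tally.items())
            ]
        )
    return {"by_class": by_class, "listing": listing, "feature_shares": shares}
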