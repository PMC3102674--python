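"""Quadripartite plastome structure: inverted-repeat detection and region assignment.

Plastomes are circular molecules tiled by four regions: a Large Single Copy
(LSC), a Small Single Copy (SSC) and two Inverted Repeat copies (IRa/IRb) that
are exact reverse complements of each other and separate the single-copy
regions.  Loci are assigned to one of three labels (LSC, SSC, IR); both IR
copies collapse onto the single "IR" label because they evolve in concert.

Coordinates are 0-based half-open on the forward strand.  Intervals on the
circle are stored as ``(start, end)`` with ``start < end <= start + n``; an
``end`` past the genome length denotes wrap-around and positions are reported
modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGION_LABELS = ("LSC", "SSC", "IR")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


Interval = Tuple[int, int]


@dataclass(frozen=True)
class RegionMap:
    """Coordinates of LSC, SSC, IRa and IRb on a circular genome.

    When no inverted repeat of the requested size exists, ``quadripartite``
    is False, ``lsc`` covers the whole genome and the other intervals are
    ``None`` — every locus is then labelled LSC.
    """

    lsc: Interval
    ssc: Optional[Interval]
    ira: Optional[Interval]
    irb: Optional[Interval]
    genome_length: int
    circular: bool = True
    quadripartite: bool = True

    def __post_init__(self) -> None:
        if self.quadripartite:
            if None in (self.ssc, self.ira, self.irb):
                raise ValueError("quadripartite map requires all four intervals")
            if _length(self.ira) != _length(self.irb):
                raise ValueError("IR copies must have equal length")
            if _length(self.lsc) < _length(self.ssc):
                raise ValueError("LSC must be at least as long as SSC")
            total = sum(
                _length(iv) for iv in (self.lsc, self.ssc, self.ira, self.irb)
            )
            if total != self.genome_length:
                raise ValueError(
                    f"regions tile {total} bp but genome is {self.genome_length} bp"
                )

    @classmethod
    def no_structure(cls, genome_length: int) -> "RegionMap":
        return cls(
            lsc=(0, genome_length),
            ssc=None,
            ira=None,
            irb=None,
            genome_length=genome_length,
            quadripartite=False,
        )

    def label_intervals(self) -> list[tuple[str, Interval]]:
        if not self.quadripartite:
            return [("LSC", self.lsc)]
        return [
            ("LSC", self.lsc),
            ("SSC", self.ssc),
            ("IR", self.ira),
            ("IR", self.irb),
        ]

    def region_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, iv in self.label_intervals():
            out[label] = out.get(label, 0) + _length(iv)
        return out


def _length(iv: Interval) -> int:
    return iv[1] - iv[0]


def _circular_overlap(a: Interval, b: Interval, n: int) -> int:
    """Overlap in bp of two intervals on a circle of size n."""
    best = 0
    for shift in (-n, 0, n):
        lo = max(a[0], b[0] + shift)
        hi = min(a[1], b[1] + shift)
        best += max(0, hi - lo)
    return best


def detect_inverted_repeat(
    genome: str, min_ir_length: int = 1000, k: int = 20
) -> RegionMap:
    """Locate the longest inverted-repeat pair on a circular genome.

    Seeds exact k-mer matches (k=20 by default) between the doubled genome and
    its reverse complement, extends each seed without gaps, and keeps the
    longest pair of disjoint segments, each at least ``min_ir_length`` bp,
    where one is the reverse complement of the other.  ``N`` never matches.

    Returns a :class:`RegionMap`; if no qualifying repeat exists the map has
    ``quadripartite=False`` (this is a result, not an error).
    """
    genome = genome.upper()
    n = len(genome)
    if n < 4 * min_ir_length:
        raise ValueError(
            f"genome of {n} bp is shorter than 4 x min_ir_length ({min_ir_length})"
        )
    if min_ir_length < k:
        raise ValueError("min_ir_length must be at least the seed size k")

    dbl = genome + genome
    rc = reverse_complement(dbl)
    m = len(dbl)

    # index k-mers of the reverse complement (skip anything containing N)
    index: dict[str, list[int]] = {}
    for p in range(m - k + 1):
        kmer = rc[p : p + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(p)

    best: tuple[int, Interval, Interval] | None = None
    # per-diagonal rightmost extent already covered, to skip redundant seeds
    covered: dict[int, int] = {}
    for a in range(n):
        kmer = dbl[a : a + k]
        if len(kmer) < k or "N" in kmer:
            continue
        for p in index.get(kmer, ()):
            diag = a - p
            if covered.get(diag, -1) >= a + k:
                continue
            # extend left
            i, j = a - 1, p - 1
            while i >= 0 and j >= 0 and dbl[i] == rc[j] and dbl[i] != "N":
                i -= 1
                j -= 1
            a0, p0 = i + 1, j + 1
            # extend right
            i, j = a + k, p + k
            while i < m and j < m and dbl[i] == rc[j] and dbl[i] != "N":
                i += 1
                j += 1
            covered[diag] = i
            length = i - a0
            length = min(length, n)
            if length < min_ir_length:
                continue
            b0 = 2 * n - (p0 + length)  # partner segment start on the circle
            seg_a = (a0 % n, a0 % n + length)
            seg_b = (b0 % n, b0 % n + length)
            if _circular_overlap(seg_a, seg_b, n) > 0:
                continue  # self-pairing / overlapping palindrome
            if best is None or length > best[0]:
                best = (length, seg_a, seg_b)

    if best is None:
        return RegionMap.no_structure(n)

    length, seg_a, seg_b = best
    return _build_region_map(n, seg_a, seg_b)


def _build_region_map(n: int, seg_a: Interval, seg_b: Interval) -> RegionMap:
    """Assemble a RegionMap from two disjoint IR copies on the circle."""
    # order copies by start position modulo n
    first, second = sorted([seg_a, seg_b], key=lambda iv: iv[0] % n)
    # arcs between the copies (single-copy regions)
    arc1 = (first[1], second[0] if second[0] >= first[1] else second[0] + n)
    arc2 = (second[1], first[0] + n)
    arcs = [arc1, arc2]
    arcs_sorted = sorted(arcs, key=_length, reverse=True)
    lsc, ssc = arcs_sorted[0], arcs_sorted[1]
    # IRb is the copy immediately following the LSC on the circle: arc1 runs
    # from the end of `first` to the start of `second`, arc2 wraps back.
    if lsc == arc1:
        irb, ira = second, first
    else:
        irb, ira = first, second
    # normalise every interval start into [0, n)
    def norm(iv: Interval) -> Interval:
        s, e = iv
        s_mod = s % n
        return (s_mod, s_mod + (e - s))

    return RegionMap(
        lsc=norm(lsc),
        ssc=norm(ssc),
        ira=norm(ira),
        irb=norm(irb),
        genome_length=n,
    )


def assign_region(locus: Interval, region_map: RegionMap) -> str:
    """Label a locus interval as LSC, SSC or IR.

    A locus straddling a region boundary is assigned to the region containing
    the majority of its length; exact ties go to the region containing the
    locus midpoint.
    """
    start, end = locus
    if end <= start:
        raise ValueError(f"empty locus interval {locus!r}")
    n = region_map.genome_length
    if end - start > n:
        raise ValueError("locus longer than genome")
    locus_n = (start % n, start % n + (end - start))

    overlaps: dict[str, int] = {}
    for label, iv in region_map.label_intervals():
        overlaps[label] = overlaps.get(label, 0) + _circular_overlap(
            locus_n, iv, n
        )
    total = sum(overlaps.values())
    if total < _length(locus_n):
        raise ValueError(f"locus {locus!r} outside genome bounds")
    best = max(overlaps.values())
    winners = [lab for lab, ov in overlaps.items() if ov == best]
    if len(winners) == 1:
        return winners[0]
    mid = (locus_n[0] + _length(locus_n) // 2) % n
    for label, iv in region_map.label_intervals():
        s, e = iv
        if s <= mid < e or s <= mid + n < e:
            return label
    return winners[0]
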