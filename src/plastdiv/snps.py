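"""SNP detection and per-kilobase diversity standardisation.

A SNP is an alignment column where at least two distinct unambiguous bases
(A/C/G/T) occur among the samples considered.  Columns containing a gap in any
considered sample belong to the length-variable fraction of the alignment and
are excluded from SNP calling entirely; together with tandem-repeat spans they
are subtracted from the alignment length to give the *effective length*, the
denominator of the SNP/kb statistic.  Ambiguity codes and N are treated as
missing observations, never as alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .align import BASES, GAP, LocusAlignment


@dataclass
class SNPRecord:
    """One variable alignment column."""

    locus_name: str
    column: int  # 0-based alignment column
    allele_counts: dict[str, int]
    carriers: dict[str, list[str]]  # base -> sample ids

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(sorted(self.allele_counts))


@dataclass
class DiversitySummary:
    """SNP/VNTR tallies for one grouping key, standardised per kb.

    For pooled summaries ``snp_per_kb == snp_count / effective_length * 1000``;
    summaries produced by the mean-of-comparisons aggregations carry the mean
    ratio instead and are flagged by ``aggregated="mean"``.
    """

    key: str
    snp_count: int
    effective_length: int
    snp_per_kb: Optional[float]
    vntr_count: int = 0
    aggregated: str = "pooled"


def scan_snps(
    aln: LocusAlignment, sample_ids: Optional[Iterable[str]] = None
) -> list[SNPRecord]:
    """Return one :class:`SNPRecord` per variable column of the alignment.

    Columns with any gap in the considered samples are skipped; N and
    ambiguity codes are ignored when tallying alleles.
    """
    idx = aln.subset_indices(sample_ids)
    if len(idx) < 2:
        raise ValueError("SNP scan requires at least 2 samples")
    mat = aln.matrix()[idx]
    ids = [aln.sample_ids[i] for i in idx]

    gap_any = (mat == ord(GAP)).any(axis=0)
    presence = np.stack([(mat == ord(b)).sum(axis=0) for b in BASES])
    distinct = (presence > 0).sum(axis=0)
    snp_cols = np.nonzero((~gap_any) & (distinct >= 2))[0]

    records = []
    for col in snp_cols:
        counts: dict[str, int] = {}
        carriers: dict[str, list[str]] = {}
        column = mat[:, col]
        for bi, b in enumerate(BASES):
            n = int(presence[bi, col])
            if n:
                counts[b] = n
                carriers[b] = [ids[r] for r in np.nonzero(column == ord(b))[0]]
        records.append(SNPRecord(aln.locus_name, int(col), counts, carriers))
    return records


def excluded_columns(
    aln: LocusAlignment,
    sample_ids: Optional[Iterable[str]] = None,
    vntr_spans: Sequence[tuple[int, int]] = (),
) -> np.ndarray:
    """Boolean mask of length-variable columns (gap-containing or in a VNTR span)."""
    idx = aln.subset_indices(sample_ids)
    mat = aln.matrix()[idx]
    mask = (mat == ord(GAP)).any(axis=0)
    for start, end in vntr_spans:
        mask[max(0, start) : min(aln.n_columns, end)] = True
    return mask


def effective_length(
    aln: LocusAlignment,
    sample_ids: Optional[Iterable[str]] = None,
    vntr_spans: Sequence[tuple[int, int]] = (),
) -> int:
    """Alignment length minus gap-containing and VNTR columns (no double count)."""
    return int(aln.n_columns - excluded_columns(aln, sample_ids, vntr_spans).sum())


def snp_per_kb(snp_count: int, eff_length: int) -> Optional[float]:
    """SNP count standardised to 1 kb of effective length; None if length is 0."""
    if eff_length < 0:
        raise ValueError("effective length cannot be negative")
    if eff_length == 0:
        warnings.warn(
            "effective length 0: SNP/kb undefined, locus dropped from means",
            stacklevel=2,
        )
        return None
    return snp_count / eff_length * 1000.0


def locus_summary(
    aln: LocusAlignment,
    sample_ids: Optional[Iterable[str]] = None,
    vntr_spans: Sequence[tuple[int, int]] = (),
    vntr_count: int = 0,
) -> DiversitySummary:
    """Scan one locus and standardise: the per-locus diversity-table row."""
    snps = scan_snps(aln, sample_ids)
    eff = effective_length(aln, sample_ids, vntr_spans)
    return DiversitySummary(
        key=aln.locus_name,
        snp_count=len(snps),
        effective_length=eff,
        snp_per_kb=snp_per_kb(len(snps), eff),
        vntr_count=vntr_count,
    )


def aggregate_intrageneric(
    summaries: Sequence[DiversitySummary], mode: str = "mean_of_pairs"
) -> DiversitySummary:
    """Aggregate within-genus comparisons.

    ``mean_of_pairs`` takes the unweighted arithmetic mean of the per-pair
    SNP/kb ratios (each ratio already pooled over that pair's loci);
    ``within_species`` and ``between_close_species`` pass a single comparison
    through unchanged.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    if mode not in ("within_species", "between_close_species", "mean_of_pairs"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if mode != "mean_of_pairs":
        if len(summaries) != 1:
            raise ValueError(f"mode {mode!r} expects a single comparison")
        return summaries[0]
    return _mean_of_comparisons(summaries, key="intrageneric mean")


def aggregate_intergeneric(
    summaries: Sequence[DiversitySummary],
) -> DiversitySummary:
    """Unweighted mean over genus-pair comparisons."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    if len(summaries) == 1:
        return summaries[0]
    return _mean_of_comparisons(summaries, key="intergeneric mean")


def _mean_of_comparisons(
    summaries: Sequence[DiversitySummary], key: str
) -> DiversitySummary:
    ratios = [s.snp_per_kb for s in summaries if s.snp_per_kb is not None]
    if not ratios:
        raise ValueError("all comparisons have undefined SNP/kb")
    return DiversitySummary(
        key=key,
        snp_count=sum(s.snp_count for s in summaries),
        effective_length=sum(s.effective_length for s in summaries),
        snp_per_kb=float(np.mean(ratios)),
        vntr_count=sum(s.vntr_count for s in summaries),
        aggregated="mean",
    )


def summarize(
    summaries: Sequence[DiversitySummary],
    annotations: dict[str, dict[str, str]],
    group_by: str = "region",
) -> pd.DataFrame:
    """Pool per-locus summaries into a region/feature-class report.

    ``annotations`` maps locus name to ``{"region": ..., "feature_class": ...}``.
    Within each group SNP counts and effective lengths are pooled and SNP/kb is
    recomputed on the pooled values (length-weighted, not a mean of ratios).
    A final ``Mean`` row pools across all loci.
    """
    if group_by not in ("region", "feature_class", "locus"):
        raise ValueError(f"cannot group by {group_by!r}")

    rows = []
    for s in summaries:
        if group_by == "locus":
            group = s.key
        else:
            try:
                group = annotations[s.key][group_by]
            except KeyError as exc:
                raise KeyError(f"locus {s.key!r} missing {group_by} annotation") from exc
        rows.append(
            {
                "group": group,
                "snp_count": s.snp_count,
                "effective_length": s.effective_length,
                "vntr_count": s.vntr_count,
            }
        )
    df = pd.DataFrame(rows)
    pooled = df.groupby("group", sort=False).sum(numeric_only=True)
    if group_by != "locus":
        total = df.drop(columns="group").sum()
        pooled.loc["Mean"] = total
    pooled["snp_per_kb"] = [
        snp_per_kb(int(c), int(l)) if l > 0 else np.nan
        for c, l in zip(pooled["snp_count"], pooled["effective_length"])
    ]
    return pooled.reset_index()
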