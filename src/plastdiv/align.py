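"""Per-locus multiple-alignment container shared by the scanning modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

GAP = "-"
#: Unambiguous nucleotides that can constitute an allele.
BASES = "ACGT"
#: Characters tolerated in alignments: bases, N, gap and IUPAC ambiguity codes.
IUPAC = set("ACGTNRYSWKMBDHV-")

FEATURE_CLASSES = ("exon", "intron", "IGS", "exon+intron", "IGS+gene")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    genus: str
    species: str


@dataclass
class LocusAlignment:
    """A named multiple alignment of one locus across samples.

    Rows are uppercase strings over the IUPAC alphabet with ``-`` for gaps;
    all rows have equal length and sample identifiers are unique.
    """

    locus_name: str
    feature_class: str
    region: str
    samples: list[Sample]
    rows: list[str]
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.rows):
            raise ValueError("one row per sample required")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment for locus {self.locus_name}: row lengths {sorted(lengths)}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in locus {self.locus_name}")
        self.rows = [r.upper() for r in self.rows]
        bad = set("".join(self.rows)) - IUPAC
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in locus {self.locus_name}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def matrix(self) -> np.ndarray:
        """Byte matrix (n_samples x n_columns) of the alignment."""
        if self._matrix is None or self._matrix.shape[0] != len(self.rows):
            object.__setattr__(
                self,
                "_matrix",
                np.frombuffer(
                    "".join(self.rows).encode("ascii"), dtype=np.uint8
                ).reshape(len(self.rows), -1),
            )
        return self._matrix

    def row_for(self, sample_id: str) -> str:
        return self.rows[self.sample_ids.index(sample_id)]

    def subset_indices(self, sample_ids: Optional[Iterable[str]]) -> np.ndarray:
        if sample_ids is None:
            return np.arange(len(self.rows))
        wanted = list(sample_ids)
        have = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in have]
        if missing:
            raise KeyError(f"samples {missing} absent from locus {self.locus_name}")
        return np.array([have[s] for s in wanted], dtype=int)

    def degapped_row(self, sample_id: str) -> str:
        return self.row_for(sample_id).replace(GAP, "")

    def column_map(self, sample_id: str) -> np.ndarray:
        """Alignment column index of each ungapped position of one sample."""
        row = np.frombuffer(self.row_for(sample_id).encode(), dtype=np.uint8)
        return np.nonzero(row != ord(GAP))[0]


def alignment_from_records(
    locus_name: str,
    records: Sequence[tuple[str, str]],
    sample_table: dict[str, Sample],
    feature_class: str = "IGS",
    region: str = "LSC",
) -> LocusAlignment:
    """Build a LocusAlignment from (id, sequence) pairs plus sample metadata."""
    samples, rows = [], []
    for sid, seq in records:
        if sid not in sample_table:
            raise KeyError(f"sample {sid!r} missing from metadata table")
        samples.append(sample_table[sid])
        rows.append(seq)
    return LocusAlignment(locus_name, feature_class, region, samples, rows)
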