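"""Readers and writers: FASTA, TSV tables, region maps, DOT graphs.

All machine-readable tables are TSV with a mandatory header row (tab
separation avoids collisions with motif strings and count ranges); genomic
coordinates in files are 0-based half-open.  FASTA parsing is delegated to
Biopython with strict validation layered on top: duplicate identifiers,
ragged rows where an alignment is expected and non-IUPAC characters are
explicit errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .align import IUPAC, LocusAlignment, Sample
from .regions import RegionMap

PathLike = Union[str, Path]


def read_fasta(path: PathLike, alignment: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs, in file order.

    With ``alignment=True`` all sequences must have equal length.  CRLF line
    endings and lowercase input are tolerated; duplicate ids and characters
    outside the IUPAC alphabet (plus gap) are rejected.
    """
    records = []
    seen = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        seq = str(rec.seq).upper().strip()
        bad = set(seq) - IUPAC
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if alignment:
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError(
                f"{path}: ragged alignment, row lengths {sorted(lengths)}"
            )
    return records


def write_fasta(
    path: PathLike, records: Sequence[tuple[str, str]], width: int = 80
) -> None:
    """Write records wrapped at ``width`` columns, uppercase, ``-`` for gaps."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            seq = seq.upper()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(path: PathLike, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_samples(path: PathLike, samples: Sequence[Sample]) -> None:
    write_tsv(
        path,
        pd.DataFrame(
            [
                {"sample_id": s.sample_id, "genus": s.genus, "species": s.species}
                for s in samples
            ]
        ),
    )


def read_samples(path: PathLike) -> dict[str, Sample]:
    df = read_tsv(path)
    required = {"sample_id", "genus", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    return {
        r.sample_id: Sample(r.sample_id, r.genus, r.species)
        for r in df.itertuples(index=False)
    }


def write_locus_annotations(path: PathLike, rows: Sequence[dict]) -> None:
    """Locus table: locus, feature_class, region (plus optional coordinates)."""
    write_tsv(path, pd.DataFrame(rows))


def read_locus_annotations(path: PathLike) -> dict[str, dict[str, str]]:
    df = read_tsv(path)
    required = {"locus", "feature_class", "region"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: locus table needs columns {sorted(required)}")
    return {
        row["locus"]: {k: row[k] for k in df.columns if k != "locus"}
        for _, row in df.iterrows()
    }


def read_locus_alignment(
    fasta_path: PathLike,
    samples: dict[str, Sample],
    locus_name: Optional[str] = None,
    feature_class: str = "IGS",
    region: str = "LSC",
) -> LocusAlignment:
    name = locus_name or Path(fasta_path).stem
    records = read_fasta(fasta_path, alignment=True)
    missing = [sid for sid, _ in records if sid not in samples]
    if missing:
        raise ValueError(f"{fasta_path}: samples {missing} absent from metadata")
    return LocusAlignment(
        locus_name=name,
        feature_class=feature_class,
        region=region,
        samples=[samples[sid] for sid, _ in records],
        rows=[seq for _, seq in records],
    )


def region_map_to_frame(rm: RegionMap) -> pd.DataFrame:
    rows = []
    for label, iv in zip(("LSC", "SSC", "IRa", "IRb"), (rm.lsc, rm.ssc, rm.ira, rm.irb)):
        if iv is None:
            continue
        rows.append(
            {
                "region": label,
                "start": iv[0] % rm.genome_length,
                "end": iv[1] if iv[1] <= rm.genome_length else iv[1] % rm.genome_length,
                "length": iv[1] - iv[0],
            }
        )
    return pd.DataFrame(rows)


def write_region_map(path: PathLike, rm: RegionMap) -> None:
    write_tsv(path, region_map_to_frame(rm))


def write_region_map_json(path: PathLike, rm: RegionMap) -> None:
    payload = {
        "genome_length": rm.genome_length,
        "circular": rm.circular,
        "quadripartite": rm.quadripartite,
        "regions": region_map_to_frame(rm).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_region_map(path: PathLike, genome_length: int) -> RegionMap:
    """Load a user-supplied region table, bypassing IR detection."""
    df = read_tsv(path)
    iv = {
        row["region"]: (int(row["start"]), int(row["start"]) + int(row["length"]))
        for _, row in df.iterrows()
    }
    if "IRa" not in iv:
        return RegionMap.no_structure(genome_length)
    return RegionMap(
        lsc=iv["LSC"],
        ssc=iv["SSC"],
        ira=iv["IRa"],
        irb=iv["IRb"],
        genome_length=genome_length,
    )


def write_dot(path: PathLike, graph: nx.Graph) -> None:
    """Minimal DOT serialisation of an MSN (node sizes scale with frequency)."""
    lines = ["graph MSN {", "  node [shape=circle];"]
    for node, data in graph.nodes(data=True):
        freq = data.get("frequency", 1)
        lines.append(f'  n{node} [label="{node} (n={freq})"];')
    for u, v, data in graph.edges(data=True):
        sites = ",".join(data.get("sites", []))
        lines.append(f'  n{u} -- n{v} [label="{sites}", weight={data["weight"]}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_msn_edges(path: PathLike, graph: nx.Graph) -> None:
    rows = [
        {
            "chlorotype_a": u,
            "chlorotype_b": v,
            "hamming": d["weight"],
            "sites": ";".join(d.get("sites", [])),
        }
        for u, v, d in graph.edges(data=True)
    ]
    write_tsv(path, pd.DataFrame(rows, columns=["chlorotype_a", "chlorotype_b", "hamming", "sites"]))
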