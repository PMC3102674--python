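"""End-to-end driver: simulate (optional) -> regions -> scans -> stats -> network.

The pipeline is deterministic given its configuration: the manifest written
alongside the outputs records the package version, seed and every parameter,
and re-running with the same configuration reproduces every file byte for
byte.  A stage failure aborts the run with a stage-labelled error and removes
whatever partial outputs were written.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, io, presets
from .align import LocusAlignment
from .chlorotype import (
    SNPSite,
    build_msn,
    call_genotypes,
    compare_frequencies,
    define_chlorotypes,
)
from .regions import detect_inverted_repeat
from .simulate import (
    SimulationConfig,
    build_template_genome,
    emit_locus_alignments,
    simulate_divergence,
)
from .snps import locus_summary, summarize
from .stats import kruskal_wallis
from .vntr import project_to_alignment, tabulate_vntr


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: Optional[SimulationConfig] = None  # None => real-data mode
    loci_dir: Optional[str] = None  # real-data inputs
    annotations: Optional[str] = None
    samples: Optional[str] = None
    min_ir_length: int = 200
    min_homopolymer: int = 7
    group_by: str = "region"
    chlorotype_pair: Optional[tuple[str, str]] = None

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        sim = raw.pop("simulation", None)
        if isinstance(sim, str):  # named preset, e.g. "demo"
            seed = raw.get("seed", 0)
            sim_cfg = getattr(presets, f"{sim}_config")(seed)
        elif isinstance(sim, dict):
            from .simulate import LocusSpec, VNTRSpec

            sim = dict(sim)
            sim["locus_layout"] = [LocusSpec(**l) for l in sim["locus_layout"]]
            sim["vntr_specs"] = [VNTRSpec(**v) for v in sim.get("vntr_specs", [])]
            sim_cfg = SimulationConfig(**sim)
        else:
            sim_cfg = None
        pair = raw.pop("chlorotype_pair", None)
        cfg = cls(simulation=sim_cfg, **raw)
        if pair is not None:
            cfg.chlorotype_pair = tuple(pair)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns a summary dict."""
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        io.write_tsv(path, df, index=index)
        written.append(path)

    report: dict = {"seed": config.seed}
    try:
        alignments, annotations, genome = _stage_inputs(config, out, written)

        # --- region detection --------------------------------------------
        if genome is not None:
            try:
                rm = detect_inverted_repeat(genome, config.min_ir_length)
            except Exception as exc:  # noqa: BLE001
                raise StageError("regions", exc) from exc
            io.write_region_map(out / "regions.tsv", rm)
            io.write_region_map_json(out / "regions.json", rm)
            written += [out / "regions.tsv", out / "regions.json"]
            report["quadripartite"] = rm.quadripartite

        # --- VNTR scan ----------------------------------------------------
        try:
            vntr_records = {
                name: project_to_alignment(
                    aln, min_homopolymer=config.min_homopolymer
                )
                for name, aln in alignments.items()
            }
            genus_of = {
                s.sample_id: s.genus
                for aln in alignments.values()
                for s in aln.samples
            }
            feature_of = {n: a["feature_class"] for n, a in annotations.items()}
            all_records = [r for recs in vntr_records.values() for r in recs]
            vntr_tables = tabulate_vntr(all_records, genus_of, feature_of)
        except Exception as exc:  # noqa: BLE001
            raise StageError("scan-vntr", exc) from exc
        save_tsv("vntr_by_class.tsv", vntr_tables["by_class"], index=True)
        save_tsv("vntr_listing.tsv", vntr_tables["listing"])
        if len(vntr_tables["feature_shares"]):
            save_tsv("vntr_feature_shares.tsv", vntr_tables["feature_shares"])
        report["n_vntr_records"] = len(all_records)

        # --- SNP scan + grouped diversity summary -------------------------
        try:
            summaries = []
            snp_rows = []
            for name, aln in alignments.items():
                spans = [r.span for r in vntr_records[name]]
                s = locus_summary(aln, vntr_spans=spans,
                                  vntr_count=sum(r.polymorphic for r in vntr_records[name]))
                summaries.append(s)
                from .snps import scan_snps

                for rec in scan_snps(aln):
                    snp_rows.append(
                        {
                            "locus": name,
                            "column": rec.column,
                            "alleles": "/".join(rec.alleles),
                        }
                    )
            table = summarize(summaries, annotations, group_by=config.group_by)
        except Exception as exc:  # noqa: BLE001
            raise StageError("scan-snps", exc) from exc
        save_tsv("snps.tsv", pd.DataFrame(snp_rows, columns=["locus", "column", "alleles"]))
        save_tsv("diversity_summary.tsv", table)
        report["diversity"] = table.to_dict(orient="records")

        # --- Kruskal-Wallis across groups ---------------------------------
        try:
            groups: dict[str, list[float]] = {}
            for s in summaries:
                g = annotations[s.key][config.group_by]
                if s.snp_per_kb is not None:
                    groups.setdefault(g, []).append(s.snp_per_kb)
            if len(groups) >= 2 and sum(map(len, groups.values())) >= 3:
                kw = kruskal_wallis(groups, seed=config.seed)
                report["kruskal_wallis"] = {
                    "H": kw.statistic,
                    "df": kw.df,
                    "p": kw.pvalue,
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("stats", exc) from exc

        # --- chlorotypes + MSN --------------------------------------------
        try:
            from .snps import scan_snps

            sites = [
                SNPSite(name, rec.column)
                for name, aln in alignments.items()
                for rec in scan_snps(aln)
            ]
            if sites:
                gm = call_genotypes(alignments, sites)
                cset = define_chlorotypes(gm)
                assign = pd.DataFrame(
                    sorted(cset.assignments.items()),
                    columns=["sample_id", "chlorotype"],
                )
                save_tsv("chlorotypes.tsv", assign)
                report["n_chlorotypes"] = len(cset.chlorotypes)
                freq = cset.frequency_table()
                save_tsv("chlorotype_frequencies.tsv", freq, index=True)
                if freq.shape[0] >= 2 and freq.shape[1] >= 2:
                    test = compare_frequencies(
                        cset, config.chlorotype_pair, seed=config.seed
                    )
                    payload = {
                        "statistic": test.statistic,
                        "df": test.df,
                        "p": test.pvalue,
                        "p_monte_carlo": test.pvalue_monte_carlo,
                        "min_expected": test.min_expected,
                    }
                    (out / "chi2.json").write_text(json.dumps(payload, indent=2))
                    written.append(out / "chi2.json")
                    report["chi_squared"] = payload
                msn = build_msn(cset)
                io.write_dot(out / "msn.dot", msn)
                io.write_msn_edges(out / "msn_edges.tsv", msn)
                written += [out / "msn.dot", out / "msn_edges.tsv"]
                report["msn_edges"] = msn.number_of_edges()
        except Exception as exc:  # noqa: BLE001
            raise StageError("chlorotype", exc) from exc

        manifest = {
            "plastdiv_version": __version__,
            "seed": config.seed,
            "parameters": _jsonable(asdict(config)),
            "outputs": sorted(p.name for p in written),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return report
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _stage_inputs(config: PipelineConfig, out: Path, written: list[Path]):
    """Simulate or load the per-locus alignments; returns (alignments, annotations, genome)."""
    if config.simulation is not None:
        try:
            sim = config.simulation
            template = build_template_genome(sim)
            individuals, truth = simulate_divergence(template, sim)
            alignments = emit_locus_alignments(individuals, template, truth)
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", exc) from exc
        annotations = {
            loc.name: {"feature_class": loc.feature_class, "region": loc.region}
            for loc in template.loci
        }
        loci_dir = out / "loci"
        loci_dir.mkdir(exist_ok=True)
        for name, aln in alignments.items():
            path = loci_dir / f"{name}.fasta"
            io.write_fasta(path, list(zip(aln.sample_ids, aln.rows)))
            written.append(path)
        io.write_samples(out / "samples.tsv", next(iter(alignments.values())).samples)
        io.write_locus_annotations(
            out / "loci.tsv",
            [{"locus": n, **a} for n, a in annotations.items()],
        )
        written += [out / "samples.tsv", out / "loci.tsv"]
        return alignments, annotations, template.sequence

    if not (config.loci_dir and config.annotations and config.samples):
        raise StageError(
            "inputs",
            ValueError("real-data mode needs loci_dir, annotations and samples"),
        )
    try:
        samples = io.read_samples(config.samples)
        annotations = io.read_locus_annotations(config.annotations)
        alignments: dict[str, LocusAlignment] = {}
        for path in sorted(Path(config.loci_dir).glob("*.fasta")):
            name = path.stem
            ann = annotations.get(name, {})
            alignments[name] = io.read_locus_alignment(
                path,
                samples,
                locus_name=name,
                feature_class=ann.get("feature_class", "IGS"),
                region=ann.get("region", "LSC"),
            )
        if not alignments:
            raise ValueError(f"no .fasta files under {config.loci_dir}")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc
    return alignments, annotations, None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
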