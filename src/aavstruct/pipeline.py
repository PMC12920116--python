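"""End-to-end orchestration: simulate -> align -> filter -> classify -> junctions.

``run_pipeline`` executes the stages against a run directory, writing every
stage table as TSV (header line starting ``#``), a manifest recording
inputs, seed and thresholds, and a versioned JSON summary.  A stage failure
raises :class:`~aavstruct.errors.PipelineError` naming the stage; partial
outputs are retained next to a ``FAILED`` marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import anchor_dataset, blocks_to_dataframe, parse_alignments, dataframe_to_blocks
from .errors import PipelineError
from .junctions import (
    annotate_junctions, extract_junctions, genes_from_panel,
    hotspot_assessment, junction_position_profile, junctions_to_dataframe,
    self_link_arcs,
)
from .panel import ReferencePanel, build_panel
from .qc import filter_reads, verdicts_to_dataframe
from .simulate import SimConfig, simulate_dataset
from .structure import (
    calls_to_dataframe, chain_blocks, classify_structure, summarize_categories,
)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline thresholds and paths, single source of truth."""

    out_dir: str
    seed: int = 0
    # simulate
    simulate: bool = True
    sim: SimConfig | None = None
    reads_fastq: str | None = None  # used when simulate=False
    # align
    alignments: str | None = None   # pre-computed SAM/PAF; else built-in anchorer
    alignment_format: str = "auto"
    k: int = 15
    min_anchor_chain: int = 100
    # filter
    min_length: int = 1000
    min_fraction: float = 0.8
    min_run: int = 100
    coverage_mode: str = "union"
    # classify
    merge_tol: int = 50
    max_read_gap: int = 100
    overlap_frac: float = 0.5
    packaging_limit: int = 5000
    # junctions
    hotspot_bin: int = 100
    hotspot_fdr: float = 0.05
    arc_round: int = 10
    # panel
    vector_len: int = 6000
    host_len: int = 50000


def write_tsv(df: pd.DataFrame, path) -> None:
    """TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header, keep_default_na=False)


def _read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def run_pipeline(config: RunConfig, panel: ReferencePanel | None = None) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "setup"
    try:
        if panel is None:
            panel = build_panel(config.seed, config.vector_len, config.host_len)
        panel.write_fasta(out / "panel.fasta")
        panel.write_bed(out / "panel_features.bed")

        stage = "simulate"
        if config.simulate:
            sim = config.sim or SimConfig(seed=config.seed)
            sim.to_json(out / "sim_config.json")
            fastq = out / "reads.fastq"
            simulate_dataset(sim, panel, fastq, out / "truth.tsv")
        else:
            if not config.reads_fastq or not Path(config.reads_fastq).exists():
                raise PipelineError("simulate", f"input reads not found: {config.reads_fastq}")
            fastq = Path(config.reads_fastq)
        reads = _read_fastq(fastq)
        read_lengths = {rid: len(seq) for rid, seq in reads}

        stage = "align"
        if config.alignments:
            if not Path(config.alignments).exists():
                raise PipelineError("align", f"alignments not found: {config.alignments}")
            blocks_list = parse_alignments(config.alignments, config.alignment_format)
            blocks = {}
            for b in blocks_list:
                blocks.setdefault(b.read_id, []).append(b)
        else:
            blocks = anchor_dataset(
                reads, panel, k=config.k, min_anchor_chain=config.min_anchor_chain
            )
        write_tsv(blocks_to_dataframe(blocks), out / "blocks.tsv")

        stage = "filter"
        verdicts = filter_reads(
            read_lengths, blocks,
            min_length=config.min_length, min_fraction=config.min_fraction,
            min_run=config.min_run, coverage_mode=config.coverage_mode,
        )
        write_tsv(verdicts_to_dataframe(verdicts), out / "filter_verdicts.tsv")
        passed = {v.read_id for v in verdicts if v.passed}

        stage = "classify"
        calls, chains = [], {}
        for rid in sorted(passed):
            chain = chain_blocks(
                blocks.get(rid, []), merge_tol=config.merge_tol,
                max_read_gap=config.max_read_gap, read_id=rid, panel=panel,
            )
            chains[rid] = chain
            calls.append(classify_structure(
                chain, panel, overlap_frac=config.overlap_frac,
                packaging_limit=config.packaging_limit,
            ))
        if not calls:
            raise PipelineError("classify", "no reads passed the retention filter")
        write_tsv(calls_to_dataframe(calls), out / "structure_calls.tsv")
        summary_df = summarize_categories(calls)
        write_tsv(summary_df, out / "category_summary.tsv")

        stage = "junctions"
        genes = genes_from_panel(panel)
        all_junctions = []
        for rid in sorted(passed):
            all_junctions.extend(extract_junctions(chains[rid], panel))
        if len(genes):
            all_junctions = annotate_junctions(all_junctions, genes)
        write_tsv(junctions_to_dataframe(all_junctions), out / "junctions.tsv")

        vec_name, v0, v1 = panel.vector_region()
        vec_len = len(panel.sequences[vec_name])
        profile = junction_position_profile(all_junctions, vec_name, vec_len)
        write_tsv(
            pd.DataFrame({"position": range(vec_len), "count": profile}),
            out / "junction_profile.tsv",
        )
        arcs = self_link_arcs(all_junctions, vector_length=vec_len, arc_round=config.arc_round)
        write_tsv(arcs, out / "self_link_arcs.tsv")
        if profile.sum() > 0:
            hotspots = hotspot_assessment(
                profile, bin_size=config.hotspot_bin, fdr=config.hotspot_fdr
            )
            write_tsv(hotspots, out / "hotspots.tsv")
            n_hot = int(hotspots["hotspot"].sum())
        else:
            n_hot = 0

        stage = "report"
        jtype_counts = junctions_to_dataframe(all_junctions)
        jc = (
            jtype_counts["jtype"].value_counts().to_dict()
            if len(jtype_counts) else {}
        )
        summary = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "n_reads": len(reads),
            "n_passed_filter": len(passed),
            "category_counts": {
                row.category: int(row.count)
                for row in summary_df.itertuples(index=False)
            },
            "junction_counts_by_type": {k: int(v) for k, v in sorted(jc.items())},
            "n_hotspots": n_hot,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "stages": ["simulate", "align", "filter", "classify", "junctions", "report"],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except PipelineError:
        failed_marker.write_text(stage + "\n")
        raise
    except Exception as exc:
        failed_marker.write_text(stage + "\n")
        raise PipelineError(stage, str(exc)) from exc
    return out
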