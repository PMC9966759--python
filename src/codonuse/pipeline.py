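"""End-to-end orchestration: filter -> composition -> metrics -> inference.

``run_pipeline`` is a pure function of its configuration and input files:
rerunning with the same inputs produces byte-identical tables.  Every
stage writes its TSV outputs into the configured directory and the run
ends with a JSON manifest recording the configuration, a hash of it,
per-stage record counts and the SHA-256 of every emitted file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias_inference import (
    build_rscu_matrix,
    correlation_screen,
    detect_preferred_codons,
    pca_rscu,
    subset_bias_comparison,
)
from .codon_metrics import count_codons, expected_enc_curve, gene_metrics, pooled_rscu
from .composition import all_junction_ratios, composition_table, pooled_composition
from .sequence_io import (
    attach_expression,
    attach_subset_labels,
    filter_cds,
    read_cds_fasta,
    write_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the analysis; defaults are the standard thresholds."""

    fasta: str
    outdir: str
    expression: str | None = None
    subsets: str | None = None
    min_len: int = 200
    max_n_frac: float = 0.10
    max_internal_stops: int = 1
    preferred_rscu: float = 1.5  # display threshold for preferred codons
    avoided_rscu: float = 0.5  # display threshold for avoided codons
    r_threshold: float = 0.05
    p_threshold: float = 0.001
    correlation_method: str = "pearson"
    n_components: int = 2
    make_plots: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}
    stage_trace: list[str] = []

    def _stage(name: str):
        stage_trace.append(name)
        logger.info("stage %s", name)
        return _StageTimer(name, timings)

    try:
        with _stage("filter"):
            records = read_cds_fasta(config.fasta)
            counts["input"] = len(records)
            if config.expression:
                records = attach_expression(records, config.expression)
            if config.subsets:
                records = attach_subset_labels(records, config.subsets)
            kept, report = filter_cds(
                records,
                min_len=config.min_len,
                max_n_frac=config.max_n_frac,
                max_internal_stops=config.max_internal_stops,
            )
            counts["pass_filter"] = len(kept)
            report.write_tsv(outdir / "filter_report.tsv")
            write_fasta(kept, outdir / "filtered.fasta")
        with _stage("composition"):
            _write(
                composition_table(kept), outdir / "gene_composition.tsv", index=True
            )
            _write(all_junction_ratios(kept), outdir / "dinucleotide_ratios.tsv")
            pooled = pooled_composition(kept)
            pooled_frame = pd.DataFrame(
                {
                    "statistic": ["frac_A", "frac_C", "frac_G", "frac_T",
                                  "gc1", "gc2", "gc3", "gc12", "gc_overall"],
                    "value": [*pooled.overall, pooled.gc1, pooled.gc2,
                              pooled.gc3, pooled.gc12, pooled.gc_overall],
                }
            )
            _write(pooled_frame, outdir / "pooled_composition.tsv")
        with _stage("metrics"):
            metrics, rscu_matrix, aa_profiles = gene_metrics(kept)
            _write(metrics, outdir / "gene_metrics.tsv", index=True)
            tables = [count_codons(r) for r in kept]
            pooled_table = pooled_rscu(tables)
            pooled_table["preferred"] = pooled_table["rscu"] > config.preferred_rscu
            pooled_table["avoided"] = pooled_table["rscu"] < config.avoided_rscu
            _write(pooled_table, outdir / "pooled_rscu.tsv")
            _write(expected_enc_curve(), outdir / "expected_enc_curve.tsv")
            counts["enc_defined"] = int(metrics["enc"].notna().sum())
        with _stage("inference"):
            matrix = build_rscu_matrix(rscu_matrix)
            scores, var_frac, loadings = pca_rscu(
                matrix, gc3=metrics["gc3"], n_components=config.n_components
            )
            _write(scores, outdir / "pca_scores.tsv", index=True)
            _write(
                pd.DataFrame(
                    {
                        "component": [f"PC{i + 1}" for i in range(len(var_frac))],
                        "variance_fraction": var_frac,
                    }
                ),
                outdir / "pca_variance.tsv",
            )
            _write(loadings, outdir / "pca_loadings.tsv", index=True)
            screen = correlation_screen(
                metrics, scores, aa_profiles, method=config.correlation_method
            )
            _write(screen, outdir / "correlations.tsv")
            preferred = None
            if metrics["fpkm"].notna().sum() >= 10:
                preferred = detect_preferred_codons(
                    tables,
                    metrics["fpkm"],
                    r_threshold=config.r_threshold,
                    p_threshold=config.p_threshold,
                    method=config.correlation_method,
                )
                _write(preferred, outdir / "preferred_codons.tsv")
                counts["preferred_codon_calls"] = int(
                    preferred["preferred_codon"].notna().sum()
                )
            else:
                logger.info("no/insufficient expression data; preferred-codon "
                            "screen skipped")
            if metrics["subset_label"].notna().any():
                _write(subset_bias_comparison(metrics), outdir / "subset_comparison.tsv")
        if config.make_plots:
            with _stage("plots"):
                from . import plots

                plots.enc_gc3_plot(
                    metrics,
                    outdir / "enc_gc3.png",
                    colour_by_subset=metrics["subset_label"].notna().any(),
                )
                plots.deviation_ratio_histogram(metrics, outdir / "deviation_ratio.png")
                plots.dinucleotide_ratio_plot(
                    pd.read_csv(outdir / "dinucleotide_ratios.tsv", sep="\t"),
                    outdir / "dinucleotide_ratios.png",
                )
                plots.pca_scatter(
                    scores, metrics["gc3"], var_frac, outdir / "pca_scores.png"
                )
    except Exception as exc:  # annotate the failing stage for the caller
        stage = stage_trace[-1] if stage_trace else "startup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "record_counts": counts,
        "filter_report": {
            "n_input": report.n_input,
            "n_too_short": report.n_too_short,
            "n_too_many_n": report.n_too_many_n,
            "n_internal_stops": report.n_internal_stops,
            "n_pass": report.n_pass,
        },
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix == ".tsv" or p.name == "filtered.fasta"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


class _StageTimer:
    def __init__(self, name: str, sink: dict[str, float]):
        self.name = name
        self.sink = sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.sink[self.name] = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s failed: %s", self.name, exc)
        else:
            logger.info("stage %s done in %.2fs", self.name, self.sink[self.name])
        return False
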