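"""End-to-end orchestration of the analysis stages.

A run is configured by a YAML file (see :func:`load_config`) and executes
simulate (optional) -> parse/screen -> GC matrix (plus GC4 matrix when
annotations are present, plus an IQR-filtered rebuild) -> correlation
subsets -> Jaccard -> enrichment, writing every intermediate as TSV so
each stage is independently re-runnable, plus a machine-readable
``report.json`` with the counts at every filter stage, the parameters
and the seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .codon_sites import extract_sites, gc4_matrix, sites_to_frame
from .community_similarity import genus_sets, jaccard_matrix, write_genus_sets
from .cross_phylum_correlation import run_subsets, write_correlation_tables
from .gc_metrics import build_gc_matrix, iqr_filter_reads, relative_abundance
from .gut_enrichment import enrichment_frame, enrichment_table
from .sequence_io import parse_reads, read_annotations, read_labels, read_samples, screen_reads
from .synthetic_community import (
    ConfigurationError,
    EnvironmentProfile,
    PhylumProfile,
    SyntheticConfig,
    default_phylum_profiles,
    generate_collection,
)

__all__ = ["StageFailure", "load_config", "build_synthetic_config", "run_pipeline"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path}: expected a mapping")
    return cfg


def build_synthetic_config(section: Mapping[str, Any], seed: int) -> SyntheticConfig:
    """Turn the ``simulate:`` section of a run config into a SyntheticConfig."""
    phyla_spec = section.get("phyla", "default")
    if phyla_spec == "default":
        phyla = default_phylum_profiles(
            coding_fraction=float(section.get("coding_fraction", 0.0))
        )
    else:
        phyla = [PhylumProfile(**p) for p in phyla_spec]
    environments = [EnvironmentProfile(**e) for e in section["environments"]]
    return SyntheticConfig(
        phyla=phyla,
        environments=environments,
        reads_per_sample=int(section["reads_per_sample"]),
        read_length=int(section.get("read_length", 300)),
        offset_sd=float(section.get("offset_sd", 0.0)),
        confidence_noise=float(section.get("confidence_noise", 0.05)),
        seed=seed,
    )


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the run report.

    Any stage failure raises :class:`StageFailure` after writing a FAILED
    marker; partial outputs are retained. An empty post-screening read
    set is not a failure: the report records it and downstream stages are
    skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if k != "simulate"},
        "stages": {},
    }
    stage = "configure"
    try:
        # --- acquire inputs -------------------------------------------------
        if "simulate" in config:
            stage = "simulate"
            syn = build_synthetic_config(config["simulate"], seed)
            collection = generate_collection(syn)
            collection.write(outdir / "data")
            reads = collection.reads
            labels = collection.labels
            annotations = collection.annotations
            samples = collection.samples
            report["stages"]["simulate"] = {
                "n_reads": len(reads),
                "n_samples": len(samples),
                "n_annotations": len(annotations),
            }
        else:
            stage = "parse"
            inputs = config["inputs"]
            labels = read_labels(inputs["labels"])
            reads = parse_reads(inputs["reads"], labels)
            annotations = (
                read_annotations(inputs["annotations"])
                if inputs.get("annotations")
                else pd.DataFrame(
                    columns=["read_id", "start", "end", "strand", "frame_offset"]
                )
            )
            samples = read_samples(inputs["samples"])
            report["stages"]["parse"] = {
                "n_reads": len(reads),
                "n_samples": len(samples),
                "n_annotations": len(annotations),
            }

        # --- screen ---------------------------------------------------------
        stage = "screen"
        screen_cfg = config.get("screen", {})
        min_len = int(screen_cfg.get("min_len", 100))
        min_conf = float(screen_cfg.get("min_conf", 0.80))
        screened, removals = screen_reads(reads, min_len=min_len, min_conf=min_conf)
        report["stages"]["screen"] = {
            "input": len(reads),
            "kept": len(screened),
            "removed": removals,
        }
        if not screened:
            report["status"] = "empty-after-screening"
            _write_report(report, outdir)
            return report

        # --- GC matrices ----------------------------------------------------
        stage = "gc"
        min_reads = int(config.get("gc", {}).get("min_reads", 10))
        gc = build_gc_matrix(screened, min_reads=min_reads)
        gc.to_tsv(outdir / "gc")
        abundance = relative_abundance(screened)
        abundance.to_csv(outdir / "abundance.tsv", sep="\t", float_format="%.6f")
        report["stages"]["gc"] = {
            "n_samples": len(gc.samples),
            "n_phyla": len(gc.phyla),
            "min_reads": min_reads,
        }

        stage = "iqr"
        iqr_mode = config.get("iqr_mode", "literal")
        iqr_reads, iqr_removed = iqr_filter_reads(screened, mode=iqr_mode)
        gc_iqr = build_gc_matrix(iqr_reads, min_reads=min_reads)
        gc_iqr.to_tsv(outdir / "gc_iqr")
        report["stages"]["iqr"] = {
            "mode": iqr_mode,
            "input": len(screened),
            "kept": len(iqr_reads),
            "removed_per_phylum": iqr_removed,
        }

        gc_variants = {"raw": gc, "iqr": gc_iqr}
        stage = "gc4"
        if len(annotations):
            sites = extract_sites(screened, annotations)
            sites_to_frame(sites).to_csv(
                outdir / "fourfold_sites.tsv", sep="\t", index=False
            )
            gc4 = gc4_matrix(sites, screened, min_sites=min_reads)
            gc4.to_tsv(outdir / "gc4")
            gc_variants["gc4"] = gc4
            report["stages"]["gc4"] = {
                "n_annotated_reads": len(sites),
                "n_fourfold_sites": int(sum(s.n_fourfold for s in sites)),
            }

        # --- correlations ---------------------------------------------------
        stage = "correlate"
        alpha = float(config.get("alpha", 0.05))
        focal_env = config.get("focal_environment")
        method = config.get("p_value_method", "auto")
        corr_report = {}
        for variant, matrix in gc_variants.items():
            res = run_subsets(
                matrix, samples, focal_environment=focal_env, method=method, alpha=alpha
            )
            write_correlation_tables(res, outdir / f"correlations_{variant}", alpha)
            corr_report[variant] = {
                key: {
                    "n_samples": r["n_samples"],
                    "mean_significant_fraction": r["summary"].attrs["mean_fraction"],
                }
                for key, r in res.items()
            }
        report["stages"]["correlate"] = corr_report

        # --- Jaccard --------------------------------------------------------
        stage = "jaccard"
        sets = genus_sets(reads, samples)  # permissive: no confidence filter
        jm = jaccard_matrix(sets)
        jm.to_csv(outdir / "jaccard.tsv", sep="\t", na_rep="NA", float_format="%.4f")
        write_genus_sets(sets, outdir / "genus_sets")
        report["stages"]["jaccard"] = {
            "environments": {env: len(s) for env, s in sets.items()}
        }

        # --- enrichment -----------------------------------------------------
        stage = "enrich"
        focal_phylum = config.get("focal_phylum", "Actinobacteria")
        rule = config.get("enrichment_rule", "threshold")
        env_of = {s.sample_id: s.environment for s in samples}
        if focal_env is not None:
            ids = [s for s in gc.samples if env_of.get(s) == focal_env]
        else:
            ids = gc.samples
        sub_gc = gc.subset(ids)
        sub_ab = abundance.loc[[s for s in ids if s in abundance.index]]
        if focal_phylum in sub_ab.columns and len(ids) >= 4:
            results = enrichment_table(sub_gc, sub_ab, focal_phylum, rule=rule)
            enrichment_frame(results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report["stages"]["enrich"] = {
                "focal_phylum": focal_phylum,
                "rule": rule,
                "n_samples": len(ids),
                "n_phyla_tested": len(results),
            }
        else:
            report["stages"]["enrich"] = {"skipped": "focal phylum absent or too few samples"}

        report["status"] = "ok"
        _write_report(report, outdir)
        return report
    except Exception as exc:  # annotate with the failing stage
        report["status"] = "FAILED"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _write_report(report, outdir)
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageFailure(stage, exc) from exc


def _write_report(report: Mapping[str, Any], outdir: Path) -> None:
    (Path(outdir) / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
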