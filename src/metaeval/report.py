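"""End-to-end evaluation runs: gold + submissions in, metric tables + ranking out.

`run_evaluation` takes a plain configuration mapping (mirroring the CLI
flags), dispatches to the category's metric module for every tool and sample,
and writes tab-separated per-sample tables, an aggregated per-tool table, the
placement-score table and a JSON summary. Deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import assembly as assembly_eval
from . import genome_binning, profiling, taxonomic_binning
from .cami_io import (
    read_assembly_report,
    read_binning,
    read_gold_standard,
    read_profile,
)
from .errors import FormatError
from .ranking import average_over_samples, default_registry, rank_tools
from .taxonomy import load_taxonomy

logger = logging.getLogger(__name__)

CATEGORIES = ("assembly", "genome-binning", "taxonomic-binning", "profiling")


def _load_gold(paths) -> dict[str, object]:
    gold = {}
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"gold standard file not found: {p}")
        gs = read_gold_standard(p)
        sample = gs.sample_id or p.stem
        gold[sample] = gs
    return gold


def _rows_for_sample(tool: str, sample: str, metrics: dict | list, rank_key: str = "rank"):
    rows = []
    if isinstance(metrics, dict):
        for metric, value in metrics.items():
            rows.append({"tool": tool, "sample": sample, "metric": metric, "rank": "", "value": value})
    else:
        for rec in metrics:
            rank = rec.get(rank_key, "")
            for metric, value in rec.items():
                if metric in (rank_key, "n_bins", "n_gs_taxa"):
                    continue
                rows.append(
                    {"tool": tool, "sample": sample, "metric": metric, "rank": rank, "value": value}
                )
    return rows


def run_evaluation(config: dict) -> dict:
    """Run one category evaluation as described by ``config``.

    Required keys: ``category``; ``predictions`` (map tool label -> list of
    file paths); ``out_dir``. Category-dependent keys: ``gold`` (list of
    gold-standard mapping files), ``gold_profile`` (profile file),
    ``taxonomy_dir``, ``gold_genomes``/``genome_partition`` and
    ``thresholds_preset`` (assembly), ``filter_fraction``, ``strict``.

    Returns a bundle with the per-sample table, the per-tool averages and the
    ranking (``None`` with fewer than two tools), after writing all tables
    under ``out_dir``.
    """
    category = config["category"]
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    predictions: dict[str, list] = {
        tool: [paths] if isinstance(paths, (str, Path)) else list(paths)
        for tool, paths in config["predictions"].items()
    }

    db = None
    if category in ("taxonomic-binning", "profiling"):
        tax_dir = Path(config["taxonomy_dir"])
        db = load_taxonomy(
            tax_dir / "nodes.dmp",
            tax_dir / "names.dmp",
            tax_dir / "merged.dmp" if (tax_dir / "merged.dmp").exists() else None,
        )

    rows = []
    if category == "assembly":
        gold_genomes = set(config.get("gold_genomes") or ())
        if not gold_genomes and config.get("gold"):
            for gs in _load_gold(config["gold"]).values():
                gold_genomes |= set(gs.genome_sizes())
        for tool, paths in predictions.items():
            for p in paths:
                report = read_assembly_report(p)
                metrics = assembly_eval.evaluate(
                    report,
                    gold_genomes,
                    thresholds=config.get("thresholds_preset", "marine"),
                    genome_partition=config.get("genome_partition"),
                )
                rows += _rows_for_sample(tool, Path(p).stem, metrics)
    elif category in ("genome-binning", "taxonomic-binning"):
        gold = _load_gold(config["gold"])
        for tool, paths in predictions.items():
            for p in paths:
                pred = read_binning(p)
                sample = pred.sample_id or Path(p).stem
                if sample not in gold:
                    raise FormatError(f"{p}: sample {sample!r} has no gold standard")
                if category == "genome-binning":
                    metrics = genome_binning.evaluate(gold[sample], pred)
                    rows += _rows_for_sample(tool, sample, metrics)
                else:
                    recs = taxonomic_binning.evaluate(
                        gold[sample],
                        pred,
                        db,
                        filter_fraction=float(config.get("filter_fraction", 0.01)),
                        strict=bool(config.get("strict", False)),
                    )
                    rows += _rows_for_sample(tool, sample, recs)
    else:  # profiling
        gold_profiles = {p.sample_id: p for p in read_profile(config["gold_profile"])}
        for tool, paths in predictions.items():
            for path in paths:
                for pred in read_profile(path):
                    sample = pred.sample_id
                    if sample not in gold_profiles:
                        raise FormatError(f"{path}: sample {sample!r} has no gold profile")
                    recs, unifrac = profiling.evaluate(gold_profiles[sample], pred, db)
                    rows += _rows_for_sample(tool, sample, recs)
                    rows.append(
                        {
                            "tool": tool,
                            "sample": sample,
                            "metric": "weighted_unifrac",
                            "rank": "",
                            "value": unifrac,
                        }
                    )

    per_sample = pd.DataFrame(rows)
    per_sample.to_csv(out_dir / "per_sample_metrics.tsv", sep="\t", index=False)
    averaged = average_over_samples(per_sample)
    averaged.to_csv(out_dir / "per_tool_metrics.tsv", sep="\t", index=False)

    ranking = None
    if per_sample["tool"].nunique() >= 2:
        ranking = rank_tools(averaged, default_registry(), weights=config.get("weights"))
        ranking.rows.to_csv(out_dir / "ranking_scores.tsv", sep="\t", index=False)
    summary = {
        "category": category,
        "tools": sorted(predictions),
        "n_samples": int(per_sample["sample"].nunique()),
        "totals": ranking.totals if ranking else None,
        "ordered_tools": ranking.ordered_tools() if ranking else None,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"per_sample": per_sample, "per_tool": averaged, "ranking": ranking, "summary": summary}
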