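"""Strain-resolved assembly scoring from per-genome report tables.

Strain recall is the fraction of all ground-truth genomes assembled to high
quality — genome fraction strictly above a threshold and mismatch rate
strictly below one. Strain precision is, among the high-genome-fraction
assemblies, the share that is also low-mismatch. Cross-genome summaries
average each report column, substituting NGA50 = 0 for genomes below 50 %
genome fraction before averaging.

Two named threshold presets ship: ``"marine"`` (genome fraction > 90 %,
mismatches < 0.5 % of aligned bases) and ``"strain-madness"`` (> 75 %,
< 0.5 %). A mismatch threshold given as a percentage is converted to a rate
per 100 kb (0.5 % = 500 mismatches per 100 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cami_io import AssemblyReport
from .errors import UndefinedMetricError

NGA50_GENOME_FRACTION_MIN = 50.0  # percent; below it NGA50 averages as 0


@dataclass(frozen=True)
class StrainThresholds:
    genome_fraction_min: float  # percent, strict >
    mismatch_max: float  # per 100 kb, strict <

    def __post_init__(self):
        if not (0 < self.genome_fraction_min <= 100):
            raise ValueError("genome_fraction_min must lie in (0, 100]")
        if self.mismatch_max <= 0:
            raise ValueError("mismatch_max must be positive")

    @classmethod
    def from_percent_mismatch(cls, genome_fraction_min: float, mismatch_percent: float):
        """Build thresholds with the mismatch cap given as % of aligned bases."""
        return cls(genome_fraction_min, mismatch_percent * 1000.0)


PRESETS: dict[str, StrainThresholds] = {
    "marine": StrainThresholds.from_percent_mismatch(90.0, 0.5),
    "strain-madness": StrainThresholds.from_percent_mismatch(75.0, 0.5),
}


def _is_high_fraction(row: dict | None, th: StrainThresholds) -> bool:
    if row is None or row.get("genome_fraction") is None:
        return False
    return row["genome_fraction"] > th.genome_fraction_min


def _is_low_mismatch(row: dict, th: StrainThresholds) -> bool:
    mm = row.get("mismatches_per_100kbp")
    return mm is not None and mm < th.mismatch_max


def strain_recall(report: AssemblyReport, gold_genomes, th: StrainThresholds) -> float:
    """High-quality assemblies over all ground-truth genomes.

    Genomes absent from the report count as not recovered.
    """
    gold_genomes = set(gold_genomes)
    if not gold_genomes:
        raise UndefinedMetricError("empty set of ground-truth genomes")
    recovered = 0
    for g in gold_genomes:
        row = report.rows.get(g)
        if row is not None and _is_high_fraction(row, th) and _is_low_mismatch(row, th):
            recovered += 1
    return recovered / len(gold_genomes)


def strain_precision(report: AssemblyReport, th: StrainThresholds) -> float:
    """Low-mismatch share among the high-genome-fraction assemblies.

    Undefined (raised) when no assembly clears the genome-fraction threshold.
    """
    high = [row for row in report.rows.values() if _is_high_fraction(row, th)]
    if not high:
        raise UndefinedMetricError("no assembly above the genome-fraction threshold")
    return sum(1 for row in high if _is_low_mismatch(row, th)) / len(high)


def summarize_assembly(report: AssemblyReport) -> dict:
    """Cross-genome means of the report columns.

    NGA50 is set to 0 (not excluded) for genomes under 50 % genome fraction or
    with an undefined NGA50, then averaged over all genomes. Other columns are
    averaged over the genomes where they are defined.
    """
    if not report.rows:
        raise UndefinedMetricError("empty assembly report")

    def mean_defined(key: str):
        vals = [r[key] for r in report.rows.values() if r.get(key) is not None]
        return sum(vals) / len(vals) if vals else None

    nga_values = []
    for row in report.rows.values():
        gf = row.get("genome_fraction")
        nga = row.get("nga50")
        if gf is None or gf < NGA50_GENOME_FRACTION_MIN or nga is None:
            nga_values.append(0.0)
        else:
            nga_values.append(float(nga))
    return {
        "genome_fraction_mean": mean_defined("genome_fraction"),
        "mismatches_mean": mean_defined("mismatches_per_100kbp"),
        "nga50_mean": sum(nga_values) / len(nga_values),
        "misassemblies_mean": mean_defined("misassemblies"),
        "duplication_mean": mean_defined("duplication_ratio"),
    }


def evaluate(
    report: AssemblyReport,
    gold_genomes,
    thresholds: StrainThresholds | str = "marine",
    genome_partition: dict[str, str] | None = None,
) -> dict:
    """Summary record incl. strain recall/precision; optional per-partition columns.

    ``genome_partition`` maps genome ID to a partition label (e.g. "unique" /
    "common"); per-partition recall/precision columns are appended when given.
    """
    th = PRESETS[thresholds] if isinstance(thresholds, str) else thresholds
    out = summarize_assembly(report)
    out["strain_recall"] = strain_recall(report, gold_genomes, th)
    try:
        out["strain_precision"] = strain_precision(report, th)
    except UndefinedMetricError:
        out["strain_precision"] = float("nan")
    if genome_partition:
        parts = sorted(set(genome_partition.values()))
        for part in parts:
            genomes = {g for g in gold_genomes if genome_partition.get(g) == part}
            if not genomes:
                continue
            sub = AssemblyReport(rows={g: r for g, r in report.rows.items() if g in genomes})
            out[f"strain_recall_{part}"] = strain_recall(sub, genomes, th)
            try:
                out[f"strain_precision_{part}"] = strain_precision(sub, th)
            except UndefinedMetricError:
                out[f"strain_precision_{part}"] = float("nan")
    return out
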