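"""Rank aggregation of per-sample metric tables into an overall summary statistic.

Per metric (and per taxonomic rank for rank-resolved metrics) every tool gets
a placement score: 0 for first place, 1 for second, and so on, with ties
sharing the better (minimum) score. Metric values are first averaged over the
samples of a dataset, then ranked. The overall summary statistic per tool is
the (optionally weighted) sum of its placement scores — lower is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricSpec:
    name: str
    higher_is_better: bool
    category: str
    per_rank: bool = False


@dataclass
class MetricRegistry:
    """Orientation and category for every metric that enters a ranking."""

    metrics: dict[str, MetricSpec] = field(default_factory=dict)

    def add(self, name, higher_is_better, category, per_rank=False):
        self.metrics[name] = MetricSpec(name, higher_is_better, category, per_rank)
        return self

    def __contains__(self, name):
        return name in self.metrics

    def __getitem__(self, name) -> MetricSpec:
        return self.metrics[name]


def default_registry() -> MetricRegistry:
    """Registry covering the four benchmark categories."""
    r = MetricRegistry()
    # assembly
    for name in ("genome_fraction_mean", "nga50_mean", "strain_recall", "strain_precision"):
        r.add(name, True, "assembly")
    for name in ("mismatches_mean", "misassemblies_mean", "duplication_mean"):
        r.add(name, False, "assembly")
    # genome binning
    for name in (
        "average_purity",
        "average_completeness",
        "f1",
        "ari",
        "binned_fraction",
        "n_moderate",
        "n_high",
    ):
        r.add(name, True, "genome-binning")
    # taxonomic binning and profiling share the detection-metric names; the
    # orientation is the same so one entry each suffices
    for name in ("purity", "completeness", "accuracy", "purity_f", "completeness_f", "accuracy_f"):
        r.add(name, True, "taxonomic-binning", per_rank=True)
    for name in ("l1", "bray_curtis", "shannon_error"):
        r.add(name, False, "profiling", per_rank=True)
    r.add("weighted_unifrac", False, "profiling")
    return r


@dataclass
class RankingTable:
    """Placement scores per (tool, metric[, rank]) and per-tool totals."""

    rows: pd.DataFrame  # columns: tool, metric, rank, score
    totals: dict[str, float]

    def ordered_tools(self) -> list[str]:
        return sorted(self.totals, key=lambda t: (self.totals[t], t))


def average_over_samples(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean metric value per (tool, metric[, rank]) across samples.

    Expects a long table with columns ``tool``, ``sample``, ``metric``,
    ``value`` and optionally ``rank``. Undefined (NaN) sample values are
    excluded from the mean with a logged count; a tool whose values are all
    undefined for a metric is simply absent from the output for it.
    """
    df = metrics.copy()
    if "rank" not in df.columns:
        df["rank"] = ""
    df["rank"] = df["rank"].fillna("")
    n_nan = int(df["value"].isna().sum())
    if n_nan:
        logger.warning("excluding %d undefined sample values from the averages", n_nan)
    df = df.dropna(subset=["value"])
    out = (
        df.groupby(["tool", "metric", "rank"], as_index=False)["value"]
        .mean()
        .sort_values(["metric", "rank", "tool"], ignore_index=True)
    )
    return out


def rank_tools(
    values: pd.DataFrame,
    registry: MetricRegistry,
    weights: dict[str, float] | None = None,
) -> RankingTable:
    """Score tools 0..n-1 per metric (and rank) and sum into the overall statistic.

    A tool missing a metric receives the worst score (n-1, logged). Per-rank
    metrics contribute the sum of their per-level scores. ``weights`` scales
    each metric's contribution (default 1).
    """
    df = values.copy()
    if "rank" not in df.columns:
        df["rank"] = ""
    df["rank"] = df["rank"].fillna("")
    tools = sorted(df["tool"].unique())
    if len(tools) < 2:
        raise UndefinedMetricError("ranking needs at least two tools")
    n = len(tools)
    weights = weights or {}

    rows = []
    totals = {t: 0.0 for t in tools}
    for (metric, rank), group in df.groupby(["metric", "rank"], sort=True):
        if metric not in registry:
            logger.warning("metric %r not in the registry; skipped", metric)
            continue
        spec = registry[metric]
        series = group.dropna(subset=["value"]).set_index("tool")["value"]
        oriented = -series if spec.higher_is_better else series
        # competition ranking, 0-based, ties share the minimum score
        scores = oriented.rank(method="min").astype(int) - 1
        w = weights.get(metric, 1.0)
        for tool in tools:
            if tool in scores.index:
                score = int(scores[tool])
            else:
                score = n - 1
                logger.warning("tool %r missing metric %r: assigned worst score", tool, metric)
            rows.append({"tool": tool, "metric": metric, "rank": rank, "score": score})
            totals[tool] += w * score
    return RankingTable(rows=pd.DataFrame(rows), totals=totals)
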