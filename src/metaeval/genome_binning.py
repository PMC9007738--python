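"""Genome-binning metrics on a base-pair-weighted genome x bin contingency table.

Every assigned sequence contributes its gold-standard length to one
(genome, bin) cell. For a bin b, TP_b is the size of its largest genome cell
(the bin's majority genome), FP_b the rest of the bin, and completeness is
TP_b over the majority genome's total gold size. Average completeness divides
by |B| + |X| where X is the set of gold genomes that are the majority genome
of no bin. The adjusted Rand index is computed on the binned portion only and
is therefore read together with the binned base-pair fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cami_io import BinningResult, GoldStandard
from .errors import EmptyEvaluationError, UndefinedMetricError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    genome_totals: dict[str, int] = field(default_factory=dict)
    bin_totals: dict[str, int] = field(default_factory=dict)
    binned_bp: int = 0
    total_bp: int = 0

    def bins(self) -> list[str]:
        return sorted(self.bin_totals)

    def bin_cells(self, bin_id: str) -> dict[str, int]:
        return {g: c for (g, b), c in self.counts.items() if b == bin_id}

    def majority_genome(self, bin_id: str) -> str:
        """Most abundant genome in the bin; ties broken by lexicographic genome ID."""
        cells = self.bin_cells(bin_id)
        if not cells:
            raise UndefinedMetricError(f"bin {bin_id!r} is empty")
        return max(sorted(cells), key=lambda g: cells[g])


def build_contingency(gold: GoldStandard, pred: BinningResult) -> ContingencyTable:
    """Cross-tabulate gold genomes against predicted bins, weighted by bp.

    Predicted sequences missing from the gold standard are dropped with a
    warning; zero overlap raises :class:`EmptyEvaluationError`.
    """
    t = ContingencyTable()
    t.genome_totals = gold.genome_sizes()
    t.total_bp = gold.total_bp
    dropped = 0
    for seq, bin_id in pred.assignments.items():
        rec = gold.records.get(seq)
        if rec is None:
            dropped += 1
            continue
        genome, _, length = rec
        key = (genome, bin_id)
        t.counts[key] = t.counts.get(key, 0) + length
        t.bin_totals[bin_id] = t.bin_totals.get(bin_id, 0) + length
        t.binned_bp += length
    if dropped:
        logger.warning("dropped %d predicted sequences absent from the gold standard", dropped)
    if not t.counts:
        raise EmptyEvaluationError("no overlap between prediction and gold standard")
    return t


def bin_purity(t: ContingencyTable, bin_id: str) -> float:
    """TP_b / (TP_b + FP_b): share of the bin held by its majority genome."""
    cells = t.bin_cells(bin_id)
    if not cells:
        raise UndefinedMetricError(f"bin {bin_id!r} is empty")
    return max(cells.values()) / sum(cells.values())


def bin_completeness(t: ContingencyTable, bin_id: str) -> float:
    """TP_b over the gold size of the bin's majority genome."""
    g = t.majority_genome(bin_id)
    return t.counts[(g, bin_id)] / t.genome_totals[g]


def average_purity(t: ContingencyTable) -> float:
    bins = t.bins()
    if not bins:
        raise UndefinedMetricError("no predicted bins")
    return sum(bin_purity(t, b) for b in bins) / len(bins)


def average_completeness(t: ContingencyTable) -> float:
    """Mean per-bin completeness, with unrepresented gold genomes in the denominator."""
    bins = t.bins()
    if not bins:
        raise UndefinedMetricError("no predicted bins")
    majority = {b: t.majority_genome(b) for b in bins}
    represented = set(majority.values())
    n_unrepresented = sum(1 for g in t.genome_totals if g not in represented)
    total = sum(t.counts[(majority[b], b)] / t.genome_totals[majority[b]] for b in bins)
    return total / (len(bins) + n_unrepresented)


def f1_score(t: ContingencyTable) -> float:
    """Harmonic mean of average purity and average completeness."""
    p, c = average_purity(t), average_completeness(t)
    if p + c == 0:
        return 0.0
    return 2 * p * c / (p + c)


def binned_fraction(t: ContingencyTable) -> float:
    if t.total_bp == 0:
        raise UndefinedMetricError("gold standard holds zero base pairs")
    return t.binned_bp / t.total_bp


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Pair-counting ARI over the bp-weighted contingency, binned portion only.

    Uses the standard closed form on cell counts; 1 for a perfect match of the
    two partitions of the binned base pairs, ~0 for a chance-level match
    (slightly negative values are reported as computed).
    """
    n = t.binned_bp
    if n < 2:
        raise UndefinedMetricError("ARI needs at least 2 binned base pairs")

    def comb2(x: int) -> int:
        return x * (x - 1) // 2

    sum_cells = sum(comb2(c) for c in t.counts.values())
    row_tot: dict[str, int] = {}
    for (g, _), c in t.counts.items():
        row_tot[g] = row_tot.get(g, 0) + c
    sum_rows = sum(comb2(a) for a in row_tot.values())
    sum_cols = sum(comb2(b) for b in t.bin_totals.values())
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        # both partitions are single clusters (or equivalent degenerate case)
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def count_quality_bins(
    t: ContingencyTable, completeness_min: float, contamination_max: float
) -> int:
    """Bins with completeness strictly above and contamination strictly below threshold.

    The conventional tiers are (0.5, 0.10) for "moderate or higher" and
    (0.9, 0.05) for high quality.
    """
    n = 0
    for b in t.bins():
        if (
            bin_completeness(t, b) > completeness_min
            and (1.0 - bin_purity(t, b)) < contamination_max
        ):
            n += 1
    return n


def evaluate(gold: GoldStandard, pred: BinningResult) -> dict:
    """All genome-binning metrics for one sample as a flat dict."""
    t = build_contingency(gold, pred)
    return {
        "average_purity": average_purity(t),
        "average_completeness": average_completeness(t),
        "f1": f1_score(t),
        "ari": adjusted_rand_index(t) if t.binned_bp >= 2 else float("nan"),
        "binned_fraction": binned_fraction(t),
        "n_moderate": count_quality_bins(t, 0.5, 0.10),
        "n_high": count_quality_bins(t, 0.9, 0.05),
    }
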