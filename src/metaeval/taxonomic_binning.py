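"""Per-rank taxon-binning metrics and the 1 % smallest-bins filter.

Gold and predicted taxon labels are both projected onto the requested major
rank. Sequences whose gold lineage lacks a node at that rank are excluded
from the gold set GS and from the accuracy denominator n; predictions that do
not project contribute no bin. Filtering removes the smallest predicted bins
whose cumulative size is <= the given fraction of all binned bp, while GS and
n stay fixed, so filtered completeness and accuracy can only decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cami_io import BinningResult, GoldStandard
from .errors import UndefinedMetricError, UnknownTaxonError
from .taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)


@dataclass
class RankConfusion:
    """Per-taxon (TP, FP, FN) base-pair counts at a single rank."""

    rank: str
    per_taxon: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    gold_taxa: set[int] = field(default_factory=set)
    total_gold_bp: int = 0


def rank_confusion(
    gold: GoldStandard,
    pred: BinningResult,
    db: TaxonomyDB,
    rank: str,
    strict: bool = False,
) -> RankConfusion:
    """Confusion counts between projected gold and predicted taxon assignments.

    Unknown predicted taxon IDs are dropped with a warning (or raised with
    ``strict=True``).
    """
    gold_at_rank: dict[str, int | None] = {}
    gold_taxon_bp: dict[int, int] = {}
    for seq, (_, taxid, length) in gold.records.items():
        proj = db.project_to_rank(taxid, rank)
        gold_at_rank[seq] = proj
        if proj is not None:
            gold_taxon_bp[proj] = gold_taxon_bp.get(proj, 0) + length

    tp: dict[int, int] = {}
    fp: dict[int, int] = {}
    rejected = 0
    for seq, label in pred.assignments.items():
        rec = gold.records.get(seq)
        if rec is None:
            rejected += 1
            continue
        try:
            pred_proj = db.project_to_rank(int(label), rank)
        except (ValueError, UnknownTaxonError) as e:
            if strict:
                raise
            rejected += 1
            continue
        if pred_proj is None:
            continue
        length = rec[2]
        if gold_at_rank.get(seq) == pred_proj:
            tp[pred_proj] = tp.get(pred_proj, 0) + length
        else:
            fp[pred_proj] = fp.get(pred_proj, 0) + length
    if rejected:
        logger.warning("rank %s: rejected %d predictions (unknown sequence or taxon)", rank, rejected)

    c = RankConfusion(rank=rank)
    c.gold_taxa = set(gold_taxon_bp)
    c.total_gold_bp = sum(gold_taxon_bp.values())
    for taxon in set(tp) | set(fp):
        t = tp.get(taxon, 0)
        f = fp.get(taxon, 0)
        fn = gold_taxon_bp.get(taxon, 0) - t
        c.per_taxon[taxon] = (t, f, fn)
    return c


def _bin_purity(counts: tuple[int, int, int]) -> float:
    t, f, _ = counts
    return t / (t + f) if (t + f) > 0 else 0.0


def _bin_completeness(counts: tuple[int, int, int]) -> float:
    t, _, fn = counts
    return t / (t + fn) if (t + fn) > 0 else 0.0


def rank_metrics(c: RankConfusion) -> tuple[float, float, float]:
    """(average purity, average completeness, accuracy) at one rank.

    Average purity is the unweighted mean over predicted bins; average
    completeness divides the summed per-bin completeness by |GS|; accuracy is
    total TP over the gold bp at the rank.
    """
    if not c.gold_taxa:
        raise UndefinedMetricError(f"gold standard holds no taxa at rank {c.rank!r}")
    if c.per_taxon:
        purity = sum(_bin_purity(v) for v in c.per_taxon.values()) / len(c.per_taxon)
    else:
        purity = float("nan")
    completeness = sum(_bin_completeness(v) for v in c.per_taxon.values()) / len(c.gold_taxa)
    accuracy = sum(v[0] for v in c.per_taxon.values()) / c.total_gold_bp
    return purity, completeness, accuracy


def filter_small_bins(c: RankConfusion, fraction: float = 0.01) -> RankConfusion:
    """Drop the smallest predicted bins whose cumulative size is <= ``fraction`` of the total.

    Bin size is the predicted bp in the bin (TP + FP). The bins are sorted by
    increasing size and removed while the running sum stays within the
    threshold. GS and n are left untouched.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    sizes = {taxon: v[0] + v[1] for taxon, v in c.per_taxon.items()}
    total = sum(sizes.values())
    threshold = fraction * total
    kept = dict(c.per_taxon)
    cumulative = 0
    for taxon in sorted(sizes, key=lambda t: (sizes[t], t)):
        cumulative += sizes[taxon]
        if cumulative <= threshold:
            del kept[taxon]
        else:
            break
    out = RankConfusion(rank=c.rank, gold_taxa=set(c.gold_taxa), total_gold_bp=c.total_gold_bp)
    out.per_taxon = kept
    return out


def evaluate(
    gold: GoldStandard,
    pred: BinningResult,
    db: TaxonomyDB,
    ranks=None,
    filter_fraction: float = 0.01,
    strict: bool = False,
) -> list[dict]:
    """Per-rank metric rows (unfiltered and filtered) for one sample."""
    rows = []
    for rank in ranks if ranks is not None else db.major_ranks:
        c = rank_confusion(gold, pred, db, rank, strict=strict)
        if not c.gold_taxa:
            continue
        purity, completeness, accuracy = rank_metrics(c)
        cf = filter_small_bins(c, filter_fraction)
        purity_f, completeness_f, accuracy_f = rank_metrics(cf)
        rows.append(
            {
                "rank": rank,
                "purity": purity,
                "completeness": completeness,
                "accuracy": accuracy,
                "purity_f": purity_f,
                "completeness_f": completeness_f,
                "accuracy_f": accuracy_f,
                "n_bins": len(c.per_taxon),
                "n_gs_taxa": len(c.gold_taxa),
            }
        )
    return rows
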