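"""Taxonomic profiling metrics: taxon detection, abundance error and diversity.

Presence/absence quality is scored by purity, completeness and F1 over the
taxon-ID sets at a rank. Abundance error uses the L1 norm (range 0-2 per rank)
and the Bray-Curtis distance (range 0-1). The rank-independent weighted
UniFrac error is the earth-mover's distance between the two profiles' mass
placed on the taxonomic tree with unit branch lengths: with eight major ranks
below a virtual root the worst case (all mass in one species under one
superkingdom versus another) is 16. Alpha diversity is compared through the
Shannon equitability index (entropy over ln of the taxon count, 0-1).
"""

from __future__ import annotations

import logging
import math

from .cami_io import TaxonProfile
from .errors import UndefinedMetricError
from .taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)


def presence_metrics(
    gold: TaxonProfile, pred: TaxonProfile, rank: str
) -> tuple[float, float, float]:
    """(purity, completeness, F1) of detected-taxon sets at one rank."""
    gold_taxa = {t for t, a in gold.at_rank(rank).items() if a > 0}
    pred_taxa = {t for t, a in pred.at_rank(rank).items() if a > 0}
    if not gold_taxa:
        raise UndefinedMetricError(f"gold profile is empty at rank {rank!r}")
    tp = len(gold_taxa & pred_taxa)
    purity = tp / len(pred_taxa) if pred_taxa else float("nan")
    completeness = tp / len(gold_taxa)
    if not pred_taxa or (purity + completeness) == 0:
        f1 = 0.0
    else:
        f1 = 2 * purity * completeness / (purity + completeness)
    return purity, completeness, f1


def l1_norm(gold: TaxonProfile, pred: TaxonProfile, rank: str) -> float:
    """Total absolute abundance error over the union of taxa at a rank (0..2)."""
    x = gold.at_rank(rank)
    y = pred.at_rank(rank)
    return sum(abs(x.get(t, 0.0) - y.get(t, 0.0)) for t in set(x) | set(y))


def bray_curtis(gold: TaxonProfile, pred: TaxonProfile, rank: str) -> float:
    """L1 error over the summed abundances: equals L1/2 for two complete profiles."""
    x = gold.at_rank(rank)
    y = pred.at_rank(rank)
    denom = sum(x.values()) + sum(y.values())
    if denom == 0:
        raise UndefinedMetricError(f"both profiles are empty at rank {rank!r}")
    return l1_norm(gold, pred, rank) / denom


def shannon_equitability(profile: TaxonProfile, rank: str) -> float:
    """Normalised Shannon entropy of the abundance vector at a rank.

    (-sum x ln x) / ln m over the m taxa with positive abundance; defined as 0
    for a single taxon. Abundances are renormalised to sum to 1 so the index
    depends only on evenness.
    """
    x = [a for a in profile.at_rank(rank).values() if a > 0]
    if not x:
        raise UndefinedMetricError(f"profile is empty at rank {rank!r}")
    if len(x) == 1:
        return 0.0
    total = sum(x)
    entropy = -sum((a / total) * math.log(a / total) for a in x)
    return entropy / math.log(len(x))


def diversity_error(gold: TaxonProfile, pred: TaxonProfile, rank: str) -> float:
    """Absolute difference of the two profiles' Shannon equitability indices."""
    return abs(shannon_equitability(pred, rank) - shannon_equitability(gold, rank))


# ---------------------------------------------------------------------------
# weighted UniFrac


def _leaf_masses(profile: TaxonProfile, db: TaxonomyDB, renormalize: bool) -> dict[int, float]:
    """Place each profile's mass at its most specific annotated taxa.

    A profile typically repeats the same mass at every rank along a lineage
    (60% Proteobacteria at phylum, 60% E. coli at species, ...). For the
    transport problem each unit of mass must sit at exactly one node, so for
    every entry the mass already explained by more specific profile entries
    beneath it is subtracted; what remains sits at that node. Taxa that do not
    resolve in the taxonomy are dropped with a warning and the remaining mass
    is renormalised (unless ``renormalize=False``).
    """
    entries: dict[int, float] = {}
    dropped = 0.0
    for e in profile.entries:
        if e.abundance <= 0:
            continue
        try:
            taxid = db.resolve(e.taxid)
        except Exception:
            dropped += e.abundance
            continue
        entries[taxid] = entries.get(taxid, 0.0) + e.abundance
    if dropped:
        logger.warning("dropped %.3g unresolvable abundance from profile %s", dropped, profile.sample_id)
    # subtract, from each node, the mass of profile nodes strictly below it
    # whose nearest profile ancestor is that node
    masses = dict(entries)
    for taxid in entries:
        lineage = db.lineage(taxid)[:-1]  # ancestors, root first
        for anc in reversed(lineage):
            if anc in masses:
                masses[anc] -= entries[taxid]
                break
    masses = {t: m for t, m in masses.items() if m > 1e-12}
    total = sum(masses.values())
    if total <= 0:
        raise UndefinedMetricError("profile carries zero resolvable mass")
    if renormalize:
        masses = {t: m / total for t, m in masses.items()}
    return masses


def weighted_unifrac(
    gold: TaxonProfile,
    pred: TaxonProfile,
    db: TaxonomyDB,
    renormalize: bool = True,
) -> float:
    """Earth-mover's distance between two profiles on the taxonomic tree.

    Unit branch lengths; each taxon's edge to its parent (or to a virtual root
    joining the superkingdoms) costs 1. The EMD on a tree is the sum over
    edges of the absolute net mass imbalance of the subtree below the edge, so
    a single tree traversal suffices.
    """
    gold_mass = _leaf_masses(gold, db, renormalize)
    pred_mass = _leaf_masses(pred, db, renormalize)

    # signed mass difference placed on each node
    imbalance: dict[int, float] = {}
    for t, m in gold_mass.items():
        imbalance[t] = imbalance.get(t, 0.0) + m
    for t, m in pred_mass.items():
        imbalance[t] = imbalance.get(t, 0.0) - m

    # every node that can carry pushed-up mass: the massed nodes plus all
    # their ancestors up to the root
    nodes: set[int] = set()
    for t in imbalance:
        nodes.update(db.lineage(t))

    depths = db.depth_map()
    distance = 0.0
    for taxid in sorted(nodes, key=lambda t: (-depths[t], t)):
        net = imbalance.pop(taxid, 0.0)
        node = db.nodes[taxid]
        if node.parent == taxid:  # root: no edge above, nothing to transport
            continue
        distance += abs(net)  # unit branch length for the edge above taxid
        imbalance[node.parent] = imbalance.get(node.parent, 0.0) + net
    return distance


def evaluate(
    gold: TaxonProfile,
    pred: TaxonProfile,
    db: TaxonomyDB,
    ranks=None,
) -> tuple[list[dict], float]:
    """Per-rank metric rows plus the rank-independent weighted UniFrac error."""
    rows = []
    for rank in ranks if ranks is not None else db.major_ranks:
        gold_vec = {t: a for t, a in gold.at_rank(rank).items() if a > 0}
        if not gold_vec:
            continue
        purity, completeness, f1 = presence_metrics(gold, pred, rank)
        pred_vec = {t: a for t, a in pred.at_rank(rank).items() if a > 0}
        rows.append(
            {
                "rank": rank,
                "purity": purity,
                "completeness": completeness,
                "f1": f1,
                "l1": l1_norm(gold, pred, rank),
                "bray_curtis": bray_curtis(gold, pred, rank),
                "shannon_error": diversity_error(gold, pred, rank) if pred_vec else float("nan"),
            }
        )
    try:
        unifrac = weighted_unifrac(gold, pred, db)
    except UndefinedMetricError:
        unifrac = float("nan")  # e.g. an empty prediction; ranked as missing
    return rows, unifrac
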