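"""Toy benchmark generator: taxonomies, gold standards and controlled-error predictions.

The generator emulates, at desk scale, the structure of a multi-sample
metagenome benchmark: a community of genomes with full eight-rank lineages
(optionally with pairs of closely related genomes sharing a species node,
mirroring "common" strains), per-sample log-normal abundances, per-genome
contig sets with log-normally distributed lengths (min 500 bp, so bp
weighting genuinely differs from sequence counting), and internally
consistent gold-standard profiles whose per-rank abundances are the
bp-weighted genome shares.

Corruption operators then produce predictions with known error levels:
mis-binning/unassignment for binners, Dirichlet abundance noise plus taxon
drop/relabel for profilers, and a configurable quality generator for
assembly reports. Every operator draws from its own named stream derived
from one integer seed, so outputs are stable for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cami_io import (
    BinningResult,
    GoldStandard,
    ProfileEntry,
    TaxonProfile,
    AssemblyReport,
    write_assembly_report,
    write_binning,
    write_gold_standard,
    write_profile,
)
from .taxonomy import MAJOR_RANKS, TaxNode, TaxonomyDB

# per-operator offsets for named substreams of the master seed
_STREAMS = {"gold": 0, "binning": 1, "profile": 2, "assembly": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class CommunitySpec:
    """Parameters of the simulated community and its sequencing gold standard.

    Abundances follow the log-normal model conventional for microbial
    communities (sigma = 2 gives the long-tailed profiles typical of
    simulated benchmark data). ``n_common_pairs`` genome pairs share a
    species node, the bookkeeping analogue of strains at >= 95 % ANI.
    """

    n_genomes: int = 10
    n_samples: int = 2
    n_common_pairs: int = 2
    abundance_mu: float = 1.0
    abundance_sigma: float = 2.0
    contigs_per_genome: int = 20
    contig_length_mu: float = 8.5  # ln scale; e^8.5 ~ 4.9 kb
    contig_length_sigma: float = 1.0
    min_contig_length: int = 500
    seed: int = 42

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if 2 * self.n_common_pairs > self.n_genomes:
            raise ValueError("more paired genomes than genomes")


@dataclass
class Community:
    """Generated fixture bundle for one community."""

    spec: CommunitySpec
    taxonomy: TaxonomyDB
    gold: dict[str, GoldStandard]  # sample -> per-sample truth
    profiles: dict[str, TaxonProfile]  # sample -> gold profile
    genome_taxids: dict[str, int]  # genome -> most specific taxon (strain node)

    @property
    def samples(self) -> list[str]:
        return list(self.gold)


def _build_taxonomy(spec: CommunitySpec, rng: np.random.Generator) -> tuple[TaxonomyDB, dict[str, int]]:
    """Random rooted taxonomy with full lineages over the 8 major ranks.

    Genomes hang as strain nodes below species; common pairs share a species.
    Grouping proceeds bottom-up with random parent fan-outs, forced to at
    least two superkingdoms when the community is large enough.
    """
    db = TaxonomyDB()
    next_id = [1]

    def new_node(parent: int, rank: str, name: str) -> int:
        taxid = next_id[0]
        next_id[0] += 1
        db.nodes[taxid] = TaxNode(taxid=taxid, parent=parent, rank=rank, name=name)
        return taxid

    root = new_node(1, "no rank", "root")  # parent == self

    n_species = spec.n_genomes - spec.n_common_pairs
    ranks_up = list(MAJOR_RANKS[:-1][::-1])  # genus ... superkingdom

    # build species placeholders, then group upwards rank by rank
    level = [("species", f"sp_{i}") for i in range(n_species)]
    assigned: dict[str, list] = {"species": [None] * n_species}
    # track children lists per created node
    tree: list[tuple[str, str, list]] = [(r, n, []) for r, n in level]  # (rank, name, children)
    current = tree
    for rank in ranks_up:
        n_parents = max(1, int(np.ceil(len(current) / max(1, rng.integers(2, 4)))))
        if len(current) >= 2:
            # keep at least two lineages alive at every rank so each level of
            # the tree genuinely discriminates (full collapse happens only at
            # the root)
            n_parents = max(2, min(n_parents, len(current)))
        groups = np.array_split(rng.permutation(len(current)), n_parents)
        parents = []
        for gi, idx in enumerate(groups):
            if len(idx) == 0:
                continue
            parents.append((rank, f"{rank[:3]}_{gi}", [current[i] for i in idx]))
        current = parents

    # materialise nodes top-down
    species_ids: dict[str, int] = {}

    def materialise(node, parent_id):
        rank, name, children = node
        taxid = new_node(parent_id, rank, name)
        if rank == "species":
            species_ids[name] = taxid
        for ch in children:
            materialise(ch, taxid)

    for top in current:
        materialise(top, root)

    # attach genomes as strain nodes; the first 2*n_common_pairs genomes share
    # species pairwise, the rest get one species each
    genome_taxids: dict[str, int] = {}
    species_names = sorted(species_ids)
    genome_idx = 0
    for p in range(spec.n_common_pairs):
        sp = species_ids[species_names[p]]
        for _ in range(2):
            g = f"genome_{genome_idx}"
            genome_taxids[g] = new_node(sp, "strain", f"{g}_strain")
            genome_idx += 1
    for sp_name in species_names[spec.n_common_pairs :]:
        g = f"genome_{genome_idx}"
        genome_taxids[g] = new_node(species_ids[sp_name], "strain", f"{g}_strain")
        genome_idx += 1

    db.validate()
    return db, genome_taxids


def _profile_from_shares(
    shares: dict[str, float],
    genome_taxids: dict[str, int],
    db: TaxonomyDB,
    sample_id: str,
) -> TaxonProfile:
    """Project genome shares onto every major rank to form the gold profile."""
    prof = TaxonProfile(sample_id=sample_id)
    for rank in db.major_ranks:
        agg: dict[int, float] = {}
        for genome, share in shares.items():
            if share <= 0:
                continue
            node = db.project_to_rank(genome_taxids[genome], rank)
            if node is not None:
                agg[node] = agg.get(node, 0.0) + share
        for taxid in sorted(agg):
            lineage = db.lineage(taxid)[1:]  # drop the root
            prof.entries.append(
                ProfileEntry(
                    taxid=taxid,
                    rank=rank,
                    taxpath="|".join(str(t) for t in lineage),
                    taxpath_sn="|".join(db.nodes[t].name for t in lineage),
                    abundance=agg[taxid],
                )
            )
    return prof


def generate_gold(spec: CommunitySpec) -> Community:
    """Generate the taxonomy, per-sample gold standards and gold profiles.

    Deterministic for a given ``spec.seed``. Profile abundances per rank are
    the bp-weighted genome shares (abundance x genome size, normalised) and
    sum to 1 at every rank.
    """
    rng = _rng(spec.seed, "gold")
    db, genome_taxids = _build_taxonomy(spec, rng)
    genomes = sorted(genome_taxids)

    # one contig set per genome, shared across samples
    contigs: dict[str, list[int]] = {}
    for g in genomes:
        raw = rng.lognormal(spec.contig_length_mu, spec.contig_length_sigma, spec.contigs_per_genome)
        contigs[g] = [max(spec.min_contig_length, int(round(x))) for x in raw]
    genome_bp = {g: sum(contigs[g]) for g in genomes}

    gold: dict[str, GoldStandard] = {}
    profiles: dict[str, TaxonProfile] = {}
    for s in range(spec.n_samples):
        sample = f"sample_{s}"
        weights = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, len(genomes))
        bp_shares = {g: w * genome_bp[g] for g, w in zip(genomes, weights)}
        total = sum(bp_shares.values())
        shares = {g: v / total for g, v in bp_shares.items()}

        records: dict[str, tuple[str, int, int]] = {}
        for g in genomes:
            for k, length in enumerate(contigs[g]):
                records[f"{sample}|{g}|c{k}"] = (g, genome_taxids[g], length)
        gold[sample] = GoldStandard(sample_id=sample, records=records)
        profiles[sample] = _profile_from_shares(shares, genome_taxids, db, sample)
    return Community(spec=spec, taxonomy=db, gold=gold, profiles=profiles, genome_taxids=genome_taxids)


def perfect_binning(gold: GoldStandard, kind: str = "genome") -> BinningResult:
    """Prediction identical to the gold standard (genome or taxon labels)."""
    assignments = {
        seq: (genome if kind == "genome" else str(taxid))
        for seq, (genome, taxid, _) in gold.records.items()
    }
    return BinningResult(sample_id=gold.sample_id, kind=kind if kind == "genome" else "taxonomic", assignments=assignments)


def corrupt_binning(
    gold: GoldStandard,
    misbin_rate: float,
    unassigned_rate: float,
    seed: int,
    kind: str = "genome",
) -> BinningResult:
    """Prediction with controlled error: drop or mis-assign each sequence independently.

    Each sequence is left unassigned with probability ``unassigned_rate``;
    otherwise it is moved to a uniformly chosen wrong bin with probability
    ``misbin_rate``. Rates of 0 reproduce the gold standard exactly.
    """
    if not (0 <= misbin_rate <= 1 and 0 <= unassigned_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = _rng(seed, "binning")
    labels = sorted({(g if kind == "genome" else str(t)) for g, t, _ in gold.records.values()})
    assignments: dict[str, str] = {}
    for seq, (genome, taxid, _) in sorted(gold.records.items()):
        if rng.random() < unassigned_rate:
            continue
        true_label = genome if kind == "genome" else str(taxid)
        if len(labels) > 1 and rng.random() < misbin_rate:
            wrong = [l for l in labels if l != true_label]
            assignments[seq] = wrong[rng.integers(len(wrong))]
        else:
            assignments[seq] = true_label
    return BinningResult(
        sample_id=gold.sample_id,
        kind="genome" if kind == "genome" else "taxonomic",
        assignments=assignments,
    )


def corrupt_profile(
    gold_profile: TaxonProfile,
    db: TaxonomyDB,
    dirichlet_concentration: float = 1000.0,
    drop_rate: float = 0.0,
    relabel_rate: float = 0.0,
    seed: int = 0,
) -> TaxonProfile:
    """Noisy profile: Dirichlet abundance noise plus taxon dropout and relabeling.

    Works on the species-level vector, then re-projects the corrupted masses
    onto every major rank. ``dirichlet_concentration -> inf`` with zero rates
    recovers the gold profile. A taxon is dropped (false negative) with
    probability ``drop_rate * (1 - x_t)`` — detection failures hit rare taxa,
    not the dominant community members — and relabeled with probability
    ``relabel_rate * (1 - x_t)`` for the same reason (per-taxon evidence grows
    with abundance). A relabeled taxon moves its mass to a sibling species
    under the same genus where one exists (strain/species confusion; false
    positive + false negative), otherwise to a random other species.
    """
    if dirichlet_concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = _rng(seed, "profile")
    species_rank = db.major_ranks[-1]
    vec = {t: a for t, a in gold_profile.at_rank(species_rank).items() if a > 0}
    if not vec:
        raise ValueError("gold profile has no species-level entries")
    taxa = sorted(vec)

    all_species = sorted(
        t for t, n in db.nodes.items() if n.rank == species_rank
    )
    masses: dict[int, float] = {}
    probs = np.array([vec[t] for t in taxa])
    if np.isinf(dirichlet_concentration) or len(taxa) == 1:
        noisy = probs / probs.sum()  # no abundance noise in the limit
    else:
        noisy = rng.dirichlet(dirichlet_concentration * probs)
    genus_rank = db.major_ranks[-2]
    for taxid, mass in zip(taxa, noisy):
        if rng.random() < drop_rate * (1.0 - vec[taxid]):
            continue
        target = taxid
        if rng.random() < relabel_rate * (1.0 - vec[taxid]):
            genus = db.project_to_rank(taxid, genus_rank)
            siblings = [
                t
                for t in all_species
                if t != taxid and db.project_to_rank(t, genus_rank) == genus
            ]
            pool = siblings or [t for t in all_species if t != taxid]
            if pool:
                target = pool[rng.integers(len(pool))]
        masses[target] = masses.get(target, 0.0) + float(mass)
    if not masses:
        return TaxonProfile(sample_id=gold_profile.sample_id, entries=[])
    total = sum(masses.values())
    shares = {f"sp{t}": m / total for t, m in masses.items()}
    taxid_map = {f"sp{t}": t for t in masses}
    return _profile_from_shares(shares, taxid_map, db, gold_profile.sample_id)


def generate_assembly_report(
    community: Community,
    quality=None,
    include_fraction: float = 1.0,
    seed: int = 0,
) -> AssemblyReport:
    """Per-genome report rows with a configurable quality generator.

    ``quality`` is a callable ``(rng, genome)`` returning either
    ``(genome_fraction, mismatches per 100 kb)`` or a dict of report fields to
    override; the default draws genome fraction uniformly in [70, 100] and
    mismatch rates log-uniformly in [10, 1000]. A random subset of
    ``include_fraction`` of the genomes is reported; omitted genomes count as
    unrecovered for strain recall.
    """
    rng = _rng(seed, "assembly")
    if quality is None:

        def quality(r, genome):
            return float(r.uniform(70, 100)), float(10 ** r.uniform(1, 3))

    genome_bp: dict[str, int] = {}
    for gs in community.gold.values():
        for g, size in gs.genome_sizes().items():
            genome_bp[g] = size
        break  # contig sets are shared across samples

    rows: dict[str, dict] = {}
    for g in sorted(genome_bp):
        if rng.random() >= include_fraction:
            continue
        q = quality(rng, g)
        override = q if isinstance(q, dict) else {"genome_fraction": q[0], "mismatches_per_100kbp": q[1]}
        gf = override["genome_fraction"]
        covered = genome_bp[g] * gf / 100.0
        nga50 = int(covered / max(1, community.spec.contigs_per_genome // 2)) if gf >= 50 else None
        row = {
            "genome_fraction": gf,
            "mismatches_per_100kbp": None,
            "duplication_ratio": float(1.0 + rng.uniform(0, 0.2)),
            "nga50": nga50,
            "misassemblies": int(rng.poisson(2)),
            "coverage": float(rng.uniform(3, 50)),
        }
        row.update(override)
        rows[g] = row
    return AssemblyReport(rows=rows)


def assembly_quality_level(level: int):
    """Per-genome quality generator degrading coherently with ``level``.

    Level 0 is a near-perfect assembly (full genome fraction, well under one
    mismatch per 100 kb); every further level loses genome fraction and gains
    mismatches, misassemblies and duplication, so all summary metrics order
    the levels consistently.
    """

    def quality(r, genome):
        gf = float(np.clip(r.uniform(98 - 16 * level, 100 - 13 * level), 1.0, 100.0))
        mm = float(10 ** r.uniform(level - 1.5, level - 0.5))
        return {
            "genome_fraction": gf,
            "mismatches_per_100kbp": mm,
            "misassemblies": int(r.poisson(0.5 + 3 * level)),
            "duplication_ratio": float(1.0 + 0.08 * level + r.uniform(0, 0.03)),
        }

    return quality


def two_lineage_taxonomy() -> tuple[TaxonomyDB, int, int]:
    """Minimal taxonomy with two superkingdoms, each a full 8-rank lineage to one species.

    Returns ``(db, species_a, species_b)``. With unit branch lengths each
    species sits 8 edges below the root, so two single-species profiles in
    different superkingdoms attain the worst-case weighted UniFrac of 16.
    """
    db = TaxonomyDB()
    db.nodes[1] = TaxNode(1, 1, "no rank", "root")
    next_id = 2
    leaves = []
    for side in ("A", "B"):
        parent = 1
        for rank in MAJOR_RANKS:
            db.nodes[next_id] = TaxNode(next_id, parent, rank, f"{side}_{rank}")
            parent = next_id
            next_id += 1
        leaves.append(parent)
    db.validate()
    return db, leaves[0], leaves[1]


# ---------------------------------------------------------------------------
# on-disk fixture bundles


def write_taxonomy_dump(db: TaxonomyDB, outdir) -> None:
    """Write nodes.dmp / names.dmp (and an empty merged.dmp) in NCBI dump format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "nodes.dmp", "w") as fh:
        for taxid in sorted(db.nodes):
            n = db.nodes[taxid]
            fh.write(f"{taxid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
    with open(outdir / "names.dmp", "w") as fh:
        for taxid in sorted(db.nodes):
            n = db.nodes[taxid]
            fh.write(f"{taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")
    with open(outdir / "merged.dmp", "w") as fh:
        for old in sorted(db.merged):
            fh.write(f"{old}\t|\t{db.merged[old]}\t|\n")


def write_fixture_bundle(
    spec: CommunitySpec,
    outdir,
    n_submissions: int = 3,
    misbin_step: float = 0.15,
    unassigned_step: float = 0.1,
    drop_step: float = 0.1,
) -> Community:
    """Emit a complete toy benchmark directory.

    Layout: ``taxonomy/`` (dump files), ``gold/`` (per-sample mappings and the
    profile file) and ``submissions/`` with ``n_submissions`` corrupted
    predictions per category at linearly increasing corruption levels
    (submission 0 is perfect).
    """
    outdir = Path(outdir)
    community = generate_gold(spec)
    write_taxonomy_dump(community.taxonomy, outdir / "taxonomy")
    gold_dir = outdir / "gold"
    gold_dir.mkdir(parents=True, exist_ok=True)
    for sample, gs in community.gold.items():
        write_gold_standard(gs, gold_dir / f"{sample}.tsv")
    write_profile(list(community.profiles.values()), gold_dir / "profile.tsv")

    for i in range(n_submissions):
        sub = outdir / "submissions" / f"tool_{i}"
        sub.mkdir(parents=True, exist_ok=True)
        for sample, gs in community.gold.items():
            gb = corrupt_binning(gs, i * misbin_step, i * unassigned_step, spec.seed + i, "genome")
            write_binning(gb, sub / f"{sample}.genome_binning.tsv")
            tb = corrupt_binning(gs, i * misbin_step, i * unassigned_step, spec.seed + i, "taxonomic")
            write_binning(tb, sub / f"{sample}.tax_binning.tsv")
        rep = generate_assembly_report(
            community, quality=assembly_quality_level(i), seed=spec.seed + i
        )
        write_assembly_report(rep, sub / "assembly_report.tsv")
        profs = [
            corrupt_profile(
                community.profiles[sample],
                community.taxonomy,
                dirichlet_concentration=float("inf") if i == 0 else 1e6 / (10.0 ** i),
                drop_rate=i * drop_step,
                seed=spec.seed + i,
            )
            for sample in community.samples
        ]
        write_profile(profs, sub / "profile.tsv")
    return community
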