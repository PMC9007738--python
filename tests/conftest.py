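import pytest

from metaeval.cami_io import GoldStandard, ProfileEntry, TaxonProfile
from metaeval.genome_binning import ContingencyTable
from metaeval.synthetic import CommunitySpec, generate_gold, two_lineage_taxonomy


@pytest.fixture(scope="session")
def two_lineages():
    """Toy taxonomy: two superkingdoms, each one full 8-rank lineage to a species."""
    return two_lineage_taxonomy()


@pytest.fixture(scope="session")
def community():
    """Small deterministic community: 8 genomes (2 common pairs), 2 samples."""
    return generate_gold(CommunitySpec(n_genomes=8, n_samples=2, n_common_pairs=2, seed=11))


@pytest.fixture
def worked_table():
    """Gold {A:100, B:100, C:50}; bin1 = {A:80, B:20}, bin2 = {B:60}."""
    return ContingencyTable(
        counts={("A", "bin1"): 80, ("B", "bin1"): 20, ("B", "bin2"): 60},
        genome_totals={"A": 100, "B": 100, "C": 50},
        bin_totals={"bin1": 100, "bin2": 60},
        binned_bp=160,
        total_bp=250,
    )


@pytest.fixture
def worked_gold():
    records = {}
    for g, total in (("A", 100), ("B", 100), ("C", 50)):
        records[f"{g}_seq"] = (g, 1, total)
    return GoldStandard(sample_id="s", records=records)


def make_profile(masses, rank="species", sample="s"):
    """Quick profile from {taxid: fraction} at one rank."""
    return TaxonProfile(
        sample_id=sample,
        entries=[ProfileEntry(taxid=t, rank=rank, taxpath="", abundance=a) for t, a in masses.items()],
    )
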