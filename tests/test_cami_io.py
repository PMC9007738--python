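import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaeval.cami_io import (
    AssemblyReport,
    BinningResult,
    GoldStandard,
    ProfileEntry,
    TaxonProfile,
    read_assembly_report,
    read_binning,
    read_gold_standard,
    read_profile,
    write_assembly_report,
    write_binning,
    write_gold_standard,
    write_profile,
)
from metaeval.errors import FormatError


class TestBinningFormat:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            "@Version:0.9.0\n@SampleID:s1\n@@SEQUENCEID\tBINID\n"
            "s1\tbinA\ns2\tbinA\ns3\tbinB\n"
        )
        res = read_binning(p)
        assert res.kind == "genome"
        assert res.sample_id == "s1"
        assert len(res.assignments) == 3
        assert len(set(res.assignments.values())) == 2

    def test_duplicate_keeps_first(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("@@SEQUENCEID\tBINID\ns1\tbinA\ns1\tbinB\n")
        res = read_binning(p)
        assert res.assignments == {"s1": "binA"}

    def test_missing_header_is_format_error(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("s1\tbinA\n")
        with pytest.raises(FormatError):
            read_binning(p)

    def test_taxid_only_is_taxonomic(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("@@SEQUENCEID\tTAXID\ns1\t1234\n")
        assert read_binning(p).kind == "taxonomic"

    def test_round_trip(self, tmp_path):
        res = BinningResult("s1", "genome", {"s1": "binA", "s2": "binA", "s3": "binB"})
        write_binning(res, tmp_path / "out.tsv")
        back = read_binning(tmp_path / "out.tsv")
        assert back.assignments == res.assignments
        assert back.kind == "genome"
        assert back.sample_id == "s1"

    def test_empty_round_trip(self, tmp_path):
        write_binning(BinningResult("s1", "genome", {}), tmp_path / "e.tsv")
        assert read_binning(tmp_path / "e.tsv").assignments == {}


class TestProfileFormat:
    def test_percentage_to_fraction(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "@SampleID:s1\n@Version:0.9.1\n@Ranks:phylum\n"
            "@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n"
            "10\tphylum\t2|10\tBac|P1\t60\n11\tphylum\t2|11\tBac|P2\t40\n"
        )
        profs = read_profile(p)
        assert len(profs) == 1
        assert profs[0].at_rank("phylum") == {10: pytest.approx(0.6), 11: pytest.approx(0.4)}

    def test_multiple_sample_blocks(self, tmp_path):
        block = (
            "@SampleID:{sid}\n@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n"
            "10\tphylum\t10\tP\t100\n"
        )
        p = tmp_path / "p.tsv"
        p.write_text(block.format(sid="a") + block.format(sid="b"))
        assert [x.sample_id for x in read_profile(p)] == ["a", "b"]

    def test_negative_percentage_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text(
            "@SampleID:s\n@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n10\tphylum\t10\tP\t-5\n"
        )
        with pytest.raises(ValueError):
            read_profile(p)

    def test_round_trip(self, tmp_path):
        prof = TaxonProfile(
            "s1",
            [
                ProfileEntry(10, "phylum", "2|10", 0.6, "B|P1"),
                ProfileEntry(11, "phylum", "2|11", 0.4, "B|P2"),
            ],
        )
        write_profile(prof, tmp_path / "out.tsv")
        back = read_profile(tmp_path / "out.tsv")[0]
        assert back.at_rank("phylum")[10] == pytest.approx(0.6)
        assert back.entries[0].taxpath == "2|10"


class TestGoldStandard:
    def test_round_trip(self, tmp_path):
        gs = GoldStandard("s1", {"c1": ("gA", 5, 100), "c2": ("gB", 6, 250)})
        write_gold_standard(gs, tmp_path / "gs.tsv")
        back = read_gold_standard(tmp_path / "gs.tsv")
        assert back.records == gs.records
        assert back.sample_id == "s1"
        assert back.total_bp == 350
        assert back.genome_sizes() == {"gA": 100, "gB": 250}

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            GoldStandard("s", {"c1": ("g", 1, 0)})


class TestAssemblyReport:
    def test_undefined_nga50_distinct_from_zero(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "Genome\tGenome_fraction\tMismatches_per_100kbp\tNGA50\n"
            "g1\t95.0\t50\t10000\ng2\t30.0\t10\t-\n"
        )
        rep = read_assembly_report(p)
        assert rep.rows["g1"]["nga50"] == 10000
        assert rep.rows["g2"]["nga50"] is None

    def test_out_of_range_fraction(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("Genome\tGenome_fraction\tMismatches_per_100kbp\ng1\t101\t5\n")
        with pytest.raises(ValueError):
            read_assembly_report(p)

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("Genome\tNGA50\ng1\t5\n")
        with pytest.raises(FormatError):
            read_assembly_report(p)

    def test_round_trip(self, tmp_path):
        rep = AssemblyReport(
            rows={
                "g1": {
                    "genome_fraction": 95.0,
                    "mismatches_per_100kbp": 50.0,
                    "duplication_ratio": 1.01,
                    "nga50": 10000,
                    "misassemblies": 3,
                    "coverage": None,
                }
            }
        )
        write_assembly_report(rep, tmp_path / "r.tsv")
        back = read_assembly_report(tmp_path / "r.tsv")
        assert back.rows == rep.rows


_ids = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters="_.-"),
    min_size=1,
    max_size=12,
)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(assignments=st.dictionaries(_ids, _ids, max_size=20), kind=st.sampled_from(["genome", "taxonomic"]))
def test_binning_round_trip_fuzzed(tmp_path_factory, assignments, kind):
    """read(write(x)) reproduces any valid binning result."""
    if kind == "taxonomic":
        assignments = {s: str(abs(hash(b)) % 10**6 + 1) for s, b in assignments.items()}
    path = tmp_path_factory.mktemp("rt") / "b.tsv"
    res = BinningResult("s", kind, dict(assignments))
    write_binning(res, path)
    back = read_binning(path)
    assert back.assignments == res.assignments
    if assignments:
        assert back.kind == kind


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    fracs=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10)
)
def test_profile_round_trip_fuzzed(tmp_path_factory, fracs):
    """Percent scaling survives a write/read cycle for arbitrary abundance vectors."""
    total = sum(fracs)
    prof = TaxonProfile(
        "s",
        [
            ProfileEntry(i + 1, "species", str(i + 1), f / total)
            for i, f in enumerate(fracs)
        ],
    )
    path = tmp_path_factory.mktemp("rt") / "p.tsv"
    write_profile(prof, path)
    back = read_profile(path)[0]
    got = back.at_rank("species")
    for i, f in enumerate(fracs):
        assert got[i + 1] == pytest.approx(f / total, rel=1e-9)


def test_synthetic_round_trips(tmp_path, community):
    """All readers are total on their writers' output for generated fixtures."""
    sample = community.samples[0]
    gs = community.gold[sample]
    write_gold_standard(gs, tmp_path / "gs.tsv")
    assert read_gold_standard(tmp_path / "gs.tsv").records == gs.records

    prof = community.profiles[sample]
    write_profile(prof, tmp_path / "p.tsv")
    back = read_profile(tmp_path / "p.tsv")[0]
    for rank in community.taxonomy.major_ranks:
        want = prof.at_rank(rank)
        got = back.at_rank(rank)
        assert set(want) == set(got)
        for t in want:
            assert got[t] == pytest.approx(want[t], abs=1e-9)
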