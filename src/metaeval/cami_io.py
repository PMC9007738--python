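"""Readers and writers for the CAMI (bioboxes) exchange formats.

Covers the binning format (``@@SEQUENCEID  BINID [TAXID]`` body), the profiling
format (``@@TAXID RANK TAXPATH TAXPATHSN PERCENTAGE``, possibly with several
``@SampleID`` blocks per file), a 4-column tab-separated gold-standard mapping
(SEQUENCEID, BINID, TAXID, LENGTH) and per-genome assembly report tables.

Abundances live as fractions in [0, 1] inside the package; the file-level 0-100
percentage scale exists only at these I/O boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

ABUNDANCE_TOL = 1e-6


@dataclass
class GoldStandard:
    """Per-sample ground truth: sequence ID -> (genome ID, taxon ID, length in bp)."""

    sample_id: str
    records: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for seq, (_, _, length) in self.records.items():
            if length <= 0:
                raise ValueError(f"sequence {seq!r} has non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return sum(length for _, _, length in self.records.values())

    def genome_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for genome, _, length in self.records.values():
            sizes[genome] = sizes.get(genome, 0) + length
        return sizes


@dataclass
class BinningResult:
    """Predicted grouping of sequences: genome bins or taxon bins.

    ``kind`` is ``"genome"`` when bin labels are free-form bin IDs and
    ``"taxonomic"`` when they are taxon IDs. Unassigned sequences are simply
    absent from ``assignments``.
    """

    sample_id: str
    kind: str  # "genome" | "taxonomic"
    assignments: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass
class ProfileEntry:
    taxid: int
    rank: str
    taxpath: str
    abundance: float  # fraction in [0, 1]
    taxpath_sn: str = ""


@dataclass
class TaxonProfile:
    """Per-sample relative abundances, one entry per (taxon, rank)."""

    sample_id: str
    entries: list[ProfileEntry] = field(default_factory=list)

    def at_rank(self, rank: str) -> dict[int, float]:
        """Abundance vector {taxid: fraction} restricted to one rank."""
        return {e.taxid: e.abundance for e in self.entries if e.rank == rank}

    def ranks(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.rank not in seen:
                seen.append(e.rank)
        return seen

    def validate(self) -> None:
        sums: dict[str, float] = {}
        for e in self.entries:
            if e.abundance < 0:
                raise ValueError(f"negative abundance for taxon {e.taxid}")
            sums[e.rank] = sums.get(e.rank, 0.0) + e.abundance
        for rank, s in sums.items():
            if s > 1 + ABUNDANCE_TOL:
                raise ValueError(f"abundances at rank {rank!r} sum to {s} > 1")


@dataclass
class AssemblyReport:
    """Per-genome alignment-derived assembly statistics.

    ``rows`` maps genome ID to a dict with keys ``genome_fraction`` (percent),
    ``mismatches_per_100kbp``, ``duplication_ratio``, ``nga50``,
    ``misassemblies`` and ``coverage``; undefined cells (``-`` in the table)
    become ``None``, distinct from 0.
    """

    rows: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# binning format


def read_binning(path) -> BinningResult:
    """Parse a CAMI bioboxes binning file.

    The kind is inferred from the body columns: a BINID column means genome
    binning; TAXID-only means taxonomic binning. Duplicate sequence rows keep
    the first occurrence (logged).
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    header_cols: list[str] | None = None
    assignments: dict[str, str] = {}
    bin_col = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@@"):
                header_cols = [c.strip().upper() for c in line[2:].split("\t")]
                if "SEQUENCEID" not in header_cols:
                    raise FormatError(f"{path}: @@ header lacks SEQUENCEID column")
                if "BINID" in header_cols:
                    bin_col = header_cols.index("BINID")
                elif "TAXID" in header_cols:
                    bin_col = header_cols.index("TAXID")
                else:
                    raise FormatError(f"{path}: @@ header needs a BINID or TAXID column")
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                metadata[key.strip()] = value.strip()
                continue
            if header_cols is None:
                raise FormatError(f"{path}: data row before the @@ header row")
            fields = line.split("\t")
            if len(fields) != len(header_cols):
                raise ParseError(
                    f"expected {len(header_cols)} columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            seq = fields[header_cols.index("SEQUENCEID")]
            if seq in assignments:
                logger.warning("%s:%d: duplicate assignment for %s kept first", path, lineno, seq)
                continue
            assignments[seq] = fields[bin_col]
    if header_cols is None:
        raise FormatError(f"{path}: missing @@ header row")
    kind = "genome" if "BINID" in header_cols else "taxonomic"
    return BinningResult(
        sample_id=metadata.get("SampleID", ""),
        kind=kind,
        assignments=assignments,
        metadata=metadata,
    )


def write_binning(result: BinningResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"@Version:{result.metadata.get('Version', '0.9.0')}\n")
        fh.write(f"@SampleID:{result.sample_id}\n")
        col = "BINID" if result.kind == "genome" else "TAXID"
        fh.write(f"@@SEQUENCEID\t{col}\n")
        for seq, label in result.assignments.items():
            fh.write(f"{seq}\t{label}\n")


# ---------------------------------------------------------------------------
# profiling format


def read_profile(path) -> list[TaxonProfile]:
    """Parse a CAMI profiling file into one :class:`TaxonProfile` per @SampleID block.

    PERCENTAGE values (0-100 scale) are converted to fractions.
    """
    path = Path(path)
    profiles: list[TaxonProfile] = []
    current: TaxonProfile | None = None
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@@"):
                header_cols = [c.strip().upper() for c in line[2:].split("\t")]
                required = {"TAXID", "RANK", "TAXPATH", "TAXPATHSN", "PERCENTAGE"}
                missing = required - set(header_cols)
                if missing:
                    raise FormatError(f"{path}: profile header lacks columns {sorted(missing)}")
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                if key.strip() == "SampleID":
                    current = TaxonProfile(sample_id=value.strip())
                    profiles.append(current)
                continue
            if header_cols is None or current is None:
                raise FormatError(f"{path}: data row before @SampleID/@@ header")
            fields = line.split("\t")
            if len(fields) != len(header_cols):
                raise ParseError(
                    f"expected {len(header_cols)} columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            row = dict(zip(header_cols, fields))
            pct = float(row["PERCENTAGE"])
            if pct < 0:
                raise ValueError(f"{path}:{lineno}: negative percentage {pct}")
            current.entries.append(
                ProfileEntry(
                    taxid=int(row["TAXID"]),
                    rank=row["RANK"],
                    taxpath=row["TAXPATH"],
                    taxpath_sn=row.get("TAXPATHSN", ""),
                    abundance=pct / 100.0,
                )
            )
    for p in profiles:
        p.validate()
    return profiles


def write_profile(profiles: list[TaxonProfile] | TaxonProfile, path, ranks=None) -> None:
    if isinstance(profiles, TaxonProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        for prof in profiles:
            fh.write(f"@SampleID:{prof.sample_id}\n")
            fh.write("@Version:0.9.1\n")
            rank_list = ranks if ranks is not None else prof.ranks()
            fh.write("@Ranks:" + "|".join(rank_list) + "\n")
            fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
            for e in prof.entries:
                fh.write(
                    f"{e.taxid}\t{e.rank}\t{e.taxpath}\t{e.taxpath_sn}\t"
                    f"{100.0 * e.abundance:.10g}\n"
                )


# ---------------------------------------------------------------------------
# gold standard


def read_gold_standard(path) -> GoldStandard:
    """Read the 4-column gold-standard mapping (SEQUENCEID, BINID, TAXID, LENGTH)."""
    path = Path(path)
    sample_id = ""
    header_cols: list[str] | None = None
    records: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@@"):
                header_cols = [c.strip().upper() for c in line[2:].split("\t")]
                missing = {"SEQUENCEID", "BINID", "TAXID", "LENGTH"} - set(header_cols)
                if missing:
                    raise FormatError(f"{path}: gold standard lacks columns {sorted(missing)}")
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                if key.strip() == "SampleID":
                    sample_id = value.strip()
                continue
            if header_cols is None:
                raise FormatError(f"{path}: data row before the @@ header row")
            fields = line.split("\t")
            if len(fields) != len(header_cols):
                raise ParseError(
                    f"expected {len(header_cols)} columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            row = dict(zip(header_cols, fields))
            seq = row["SEQUENCEID"]
            if seq in records:
                logger.warning("%s:%d: duplicate sequence %s kept first", path, lineno, seq)
                continue
            try:
                records[seq] = (row["BINID"], int(row["TAXID"]), int(row["LENGTH"]))
            except ValueError as e:
                raise ParseError(str(e), path=path, line=lineno)
    if header_cols is None:
        raise FormatError(f"{path}: missing @@ header row")
    return GoldStandard(sample_id=sample_id, records=records)


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{gold.sample_id}\n")
        fh.write("@@SEQUENCEID\tBINID\tTAXID\tLENGTH\n")
        for seq, (genome, taxid, length) in gold.records.items():
            fh.write(f"{seq}\t{genome}\t{taxid}\t{length}\n")


# ---------------------------------------------------------------------------
# assembly reports

_REPORT_ALIASES = {
    "genome": "genome",
    "assembly": "genome",
    "genome_fraction": "genome_fraction",
    "genome_fraction_(%)": "genome_fraction",
    "mismatches_per_100kbp": "mismatches_per_100kbp",
    "#_mismatches_per_100_kbp": "mismatches_per_100kbp",
    "duplication_ratio": "duplication_ratio",
    "nga50": "nga50",
    "misassemblies": "misassemblies",
    "#_misassemblies": "misassemblies",
    "coverage": "coverage",
    "avg_coverage_depth": "coverage",
}

_NUMERIC_FIELDS = ("genome_fraction", "mismatches_per_100kbp", "duplication_ratio", "coverage")
_INT_FIELDS = ("nga50", "misassemblies")


def _parse_cell(value: str, as_int: bool):
    value = value.strip()
    if value in ("", "-", "NA", "nan"):
        return None
    num = float(value)
    if math.isnan(num):
        return None
    return int(round(num)) if as_int else num


def read_assembly_report(path) -> AssemblyReport:
    """Read a tab-separated per-genome assembly statistics table.

    Column names are normalised (case/space-insensitive, a few common aliases);
    ``-`` or empty cells are undefined (``None``) — in particular an undefined
    NGA50 is distinct from an NGA50 of 0.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty assembly report")
    raw_cols = lines[0].split("\t")
    cols = []
    for c in raw_cols:
        key = c.strip().lower().replace(" ", "_")
        cols.append(_REPORT_ALIASES.get(key, key))
    if "genome" not in cols:
        raise FormatError(f"{path}: missing genome/assembly column")
    for required in ("genome_fraction", "mismatches_per_100kbp"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required}")
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise ParseError(
                f"expected {len(cols)} columns, got {len(fields)}", path=path, line=lineno
            )
        row = dict(zip(cols, fields))
        parsed: dict = {}
        for f in _NUMERIC_FIELDS:
            parsed[f] = _parse_cell(row.get(f, "-"), as_int=False)
        for f in _INT_FIELDS:
            parsed[f] = _parse_cell(row.get(f, "-"), as_int=True)
        gf = parsed["genome_fraction"]
        if gf is not None and not (0 <= gf <= 100):
            raise ValueError(f"{path}:{lineno}: genome fraction {gf} outside [0, 100]")
        if parsed["misassemblies"] is not None and parsed["misassemblies"] < 0:
            raise ValueError(f"{path}:{lineno}: negative misassembly count")
        rows[row["genome"]] = parsed
    return AssemblyReport(rows=rows)


def write_assembly_report(report: AssemblyReport, path) -> None:
    fields = list(_NUMERIC_FIELDS) + list(_INT_FIELDS)
    with open(path, "w") as fh:
        fh.write("Genome\t" + "\t".join(fields) + "\n")
        for genome, row in report.rows.items():
            cells = []
            for f in fields:
                v = row.get(f)
                cells.append("-" if v is None else f"{v:.10g}" if isinstance(v, float) else str(v))
            fh.write(genome + "\t" + "\t".join(cells) + "\n")
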