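"""Reading and writing the pipeline's external formats.

Formats handled here:

* protein FASTA (via Bio.SeqIO);
* per-protein evidence tables from external annotators — signal-peptide
  calls, transmembrane-region calls, domain hits, and 12-column tabular
  alignment hits;
* gene-by-cluster expression summaries (tab-separated matrix plus a
  two-column cluster annotation file).

All residue coordinates in this toolkit are 1-based and inclusive, matching
biological residue numbering; tabular writers state this in a header
comment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError, DuplicateIdError, ParseError, SchemaError, UsageError

#: The 20 standard residues plus X for an unknown residue.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

EVIDENCE_SOURCES = ("signal_caller", "tm_caller", "domain_scanner", "alignment_hits")

ALIGNMENT_COLUMNS = [
    "query", "subject", "pct_identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "e_value", "bitscore",
]


@dataclass
class Evidence:
    """Per-record annotation flags collated from external callers."""

    has_signal: Optional[bool] = None
    signal_end: Optional[int] = None
    n_tm_regions: int = 0
    tm_regions: list[tuple[int, int]] = field(default_factory=list)
    has_domain: bool = False


@dataclass
class PrecursorRecord:
    """One input protein: id, free-text description and residue string.

    ``residues`` is uppercase over the 20 standard amino acids plus X;
    positions are 1-based and inclusive throughout the toolkit.
    """

    id: str
    description: str
    residues: str
    evidence: Optional[Evidence] = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class EvidenceTable:
    """Normalized rows from one external annotator.

    ``source`` is one of ``signal_caller``, ``tm_caller``, ``domain_scanner``
    or ``alignment_hits``; ``table`` holds the normalized rows and ``ids``
    every protein id the file mentioned (a TM caller reports proteins with
    zero membrane segments through topology lines only, so ``ids`` can be a
    strict superset of ``table``'s ids).
    """

    source: str
    table: pd.DataFrame
    ids: set[str]

    def signal_call(self, record_id: str) -> tuple[Optional[bool], Optional[int]]:
        if self.source != "signal_caller":
            raise UsageError(f"signal_call on a {self.source} table")
        rows = self.table[self.table["id"] == record_id]
        if rows.empty:
            return None, None
        row = rows.iloc[0]
        end = row["signal_end"]
        return bool(row["has_signal"]), (None if pd.isna(end) else int(end))

    def tm_regions(self, record_id: str) -> Optional[list[tuple[int, int]]]:
        """Membrane-spanning segments for a protein, or None if unreported."""
        if self.source != "tm_caller":
            raise UsageError(f"tm_regions on a {self.source} table")
        if record_id not in self.ids:
            return None
        rows = self.table[self.table["id"] == record_id]
        return [(int(r.start), int(r.end)) for r in rows.itertuples()]

    def has_domain(self, record_id: str) -> Optional[bool]:
        if self.source != "domain_scanner":
            raise UsageError(f"has_domain on a {self.source} table")
        if record_id not in self.ids:
            return None
        return not self.table[self.table["id"] == record_id].empty

    def hits(self, query_id: str) -> pd.DataFrame:
        if self.source != "alignment_hits":
            raise UsageError(f"hits on a {self.source} table")
        return self.table[self.table["query"] == query_id]

    def orphans(self, known_ids: Iterable[str]) -> set[str]:
        """Ids mentioned by the annotator but absent from the loaded FASTA."""
        return self.ids - set(known_ids)


@dataclass
class ExpressionProfile:
    """Per-gene mean expression across cell clusters.

    ``neuronal_clusters`` is the subset of cluster names annotated as
    neuronal; values are non-negative cluster means.
    """

    gene_id: str
    cluster_means: dict[str, float]
    neuronal_clusters: set[str]

    @property
    def neuronal_max(self) -> float:
        return max((self.cluster_means[c] for c in self.neuronal_clusters), default=0.0)

    @property
    def overall_max(self) -> float:
        return max(self.cluster_means.values(), default=0.0)


def _validate_residues(record_id: str, residues: str) -> str:
    seq = residues.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALLOWED_RESIDUES:
            raise AlphabetError(record_id, pos, ch)
    return seq


def read_fasta(path) -> list[PrecursorRecord]:
    """Read a protein FASTA into PrecursorRecords.

    The record id is the first whitespace-delimited token of the header;
    wrapped sequence lines are concatenated and uppercased. Duplicate ids
    raise DuplicateIdError; residues outside the 20 standard amino acids
    plus X raise AlphabetError naming the record and position.
    """
    records: list[PrecursorRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _validate_residues(rec.id, str(rec.seq).strip())
        if not residues:
            raise ParseError(path, 0, f"record {rec.id!r} has an empty sequence")
        records.append(PrecursorRecord(id=rec.id, description=rec.description, residues=residues))
    return records


def write_fasta(records: Iterable[PrecursorRecord], path, width: int = 60) -> None:
    """Write records as FASTA with headers ``>id description`` and wrapped lines."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def _parse_signal_caller(path) -> EvidenceTable:
    rows, ids = [], set()
    for line_no, parts in _tsv_rows(path):
        if len(parts) < 2:
            raise ParseError(path, line_no, "expected at least 2 columns (id, prediction)")
        rec_id, pred = parts[0], parts[1]
        if pred not in ("SP", "OTHER"):
            raise ParseError(path, line_no, f"prediction must be SP or OTHER, got {pred!r}")
        signal_end = None
        if pred == "SP":
            if len(parts) < 3 or not parts[2].strip():
                raise ParseError(path, line_no, "SP row missing cleavage-site position")
            try:
                signal_end = int(parts[2])
            except ValueError:
                raise ParseError(path, line_no, f"bad cleavage-site position {parts[2]!r}") from None
        rows.append({"id": rec_id, "has_signal": pred == "SP", "signal_end": signal_end})
        ids.add(rec_id)
    table = pd.DataFrame(rows, columns=["id", "has_signal", "signal_end"])
    return EvidenceTable("signal_caller", table, ids)


#: Region-line types emitted by the TM-caller dialect; only the
#: membrane-spanning type counts toward n_tm_regions.
_TM_REGION_TYPES = {"TMhelix", "inside", "outside", "signal"}


def _parse_tm_caller(path) -> EvidenceTable:
    rows, ids = [], set()
    for line_no, parts in _tsv_rows(path):
        if len(parts) < 4:
            raise ParseError(path, line_no, "expected 4 columns (id, region_type, start, end)")
        rec_id, region, start, end = parts[0], parts[1], parts[2], parts[3]
        if region not in _TM_REGION_TYPES:
            raise ParseError(path, line_no, f"unknown region type {region!r}")
        ids.add(rec_id)
        if region == "TMhelix":
            try:
                rows.append({"id": rec_id, "start": int(start), "end": int(end)})
            except ValueError:
                raise ParseError(path, line_no, "non-integer region bounds") from None
    table = pd.DataFrame(rows, columns=["id", "start", "end"])
    return EvidenceTable("tm_caller", table, ids)


def _parse_domain_scanner(path) -> EvidenceTable:
    rows, ids = [], set()
    for line_no, parts in _tsv_rows(path):
        if len(parts) < 2:
            raise ParseError(path, line_no, "expected at least 2 columns (id, accession)")
        rows.append({"id": parts[0], "accession": parts[1]})
        ids.add(parts[0])
    table = pd.DataFrame(rows, columns=["id", "accession"])
    return EvidenceTable("domain_scanner", table, ids)


def _parse_alignment_hits(path) -> EvidenceTable:
    rows, ids = [], set()
    for line_no, parts in _tsv_rows(path):
        if len(parts) < 12:
            raise ParseError(path, line_no, f"expected 12 columns, got {len(parts)}")
        try:
            row = {
                "query": parts[0], "subject": parts[1],
                "pct_identity": float(parts[2]), "length": int(parts[3]),
                "mismatches": int(parts[4]), "gapopens": int(parts[5]),
                "qstart": int(parts[6]), "qend": int(parts[7]),
                "sstart": int(parts[8]), "send": int(parts[9]),
                "e_value": float(parts[10]), "bitscore": float(parts[11]),
            }
        except ValueError as exc:
            raise ParseError(path, line_no, f"bad numeric field: {exc}") from None
        row["description"] = parts[12] if len(parts) > 12 else ""
        rows.append(row)
        ids.add(parts[0])
    table = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["description"])
    return EvidenceTable("alignment_hits", table, ids)


def _tsv_rows(path):
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line_no, line.split("\t")


_PARSERS = {
    "signal_caller": _parse_signal_caller,
    "tm_caller": _parse_tm_caller,
    "domain_scanner": _parse_domain_scanner,
    "alignment_hits": _parse_alignment_hits,
}


def parse_evidence(path, source: str) -> EvidenceTable:
    """Parse one annotator's tab-separated output into an EvidenceTable.

    One documented dialect per source (see the module docstring); a
    malformed row raises ParseError with its line number, an unknown
    source raises UsageError. Rows whose id is absent from the loaded
    FASTA are reported later via :meth:`EvidenceTable.orphans` (warning,
    not error, since users commonly subset FASTAs).
    """
    if source not in _PARSERS:
        raise UsageError(
            f"unknown evidence source {source!r}; expected one of {EVIDENCE_SOURCES}"
        )
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return _PARSERS[source](path)


def warn_orphans(table: EvidenceTable, records: Iterable[PrecursorRecord]) -> set[str]:
    orphans = table.orphans(r.id for r in records)
    if orphans:
        shown = ", ".join(sorted(orphans)[:5])
        warnings.warn(
            f"{table.source} evidence mentions {len(orphans)} id(s) not in the "
            f"loaded FASTA (e.g. {shown}); these rows are ignored",
            stacklevel=2,
        )
    return orphans


def read_expression(matrix_path, clusters_path) -> list[ExpressionProfile]:
    """Read a genes-by-clusters mean-expression matrix and cluster annotation.

    The matrix is tab-separated with a header row of cluster names and gene
    ids in the first column. The annotation file maps each cluster name to
    ``neuronal`` or ``non_neuronal``; a matrix column missing from the
    annotation raises SchemaError, a negative expression value ValueError.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    annot: dict[str, str] = {}
    for line_no, parts in _tsv_rows(clusters_path):
        if len(parts) != 2:
            raise ParseError(clusters_path, line_no, "expected 2 columns (cluster, class)")
        name, cls = parts
        if cls not in ("neuronal", "non_neuronal"):
            raise ParseError(clusters_path, line_no, f"class must be neuronal or non_neuronal, got {cls!r}")
        annot[name] = cls

    missing = [c for c in matrix.columns if c not in annot]
    if missing:
        raise SchemaError(
            f"matrix clusters missing from annotation file: {', '.join(missing)}"
        )
    if (matrix.values < 0).any():
        bad = matrix[(matrix < 0).any(axis=1)].index[0]
        raise ValueError(f"negative expression value for gene {bad!r}")

    neuronal = {c for c in matrix.columns if annot[c] == "neuronal"}
    return [
        ExpressionProfile(
            gene_id=str(gene),
            cluster_means={str(c): float(v) for c, v in row.items()},
            neuronal_clusters=set(neuronal),
        )
        for gene, row in matrix.iterrows()
    ]


def write_table(df: pd.DataFrame, path, coordinate_note: bool = False, extra_header: Optional[list[str]] = None) -> None:
    """Write a tab-separated table with optional convention header lines."""
    with open(path, "w") as fh:
        if coordinate_note:
            fh.write("# coordinates: 1-based, inclusive\n")
        for line in extra_header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
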