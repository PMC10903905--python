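"""Readers and writers for every on-disk artifact.

Sequences travel as FASTA (wrapped or single-line); everything tabular —
count matrices, sample metadata, reference annotations, signature tables,
assignment tables — is tab-delimited UTF-8 with a header row.  The count
matrix is OTU x sample (rows = OTUs, first column ``otu_id``), the OTU-table
convention of amplicon pipelines.  Sequences are uppercased on load and U is
mapped to T, because signatures are defined over the DNA alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

HABITATS = ("CCFZ", "deep_sea", "shallow")

REFERENCE_CATEGORIES = ("described_clade", "ENFOR", "monothalamids_X", "undetermined")

PRIOR_STATUSES = (
    "assigned",
    "enfor",
    "monothalamids_X",
    "undetermined_monothalamid",
    "unassigned",
)


class SeqIOError(ValueError):
    """Malformed or cross-inconsistent input files."""


@dataclass
class OtuRecord:
    """One OTU: its representative sequence and per-sample read counts."""

    otu_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"OTU {self.otu_id!r}: empty sequence")


@dataclass(frozen=True)
class SampleMeta:
    """A sample's geographic area and habitat class.

    ``habitat`` is one of CCFZ (Clarion-Clipperton Fracture Zone),
    deep_sea (other deep-sea basins), or shallow (shallow-water sites).
    """

    sample_id: str
    area: str
    habitat: str

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise SeqIOError(
                f"sample {self.sample_id!r}: habitat {self.habitat!r} "
                f"not in {HABITATS}"
            )


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference-database sequence with its taxon and category label.

    ``category`` separates well-described clades from the environmental
    ENFOR groups, the poorly defined Monothalamids X, and undetermined refs.
    """

    ref_id: str
    sequence: str
    taxon: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in REFERENCE_CATEGORIES:
            raise SeqIOError(
                f"reference {self.ref_id!r}: category {self.category!r} "
                f"not in {REFERENCE_CATEGORIES}"
            )
        if not self.sequence:
            raise SeqIOError(f"reference {self.ref_id!r}: empty sequence")


@dataclass(frozen=True)
class PriorAssignment:
    """An OTU's label from an upstream similarity-based assigner."""

    otu_id: str
    label: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in PRIOR_STATUSES:
            raise SeqIOError(
                f"prior for {self.otu_id!r}: status {self.status!r} "
                f"not in {PRIOR_STATUSES}"
            )


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_DNA:
            raise SeqIOError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> cleaned-sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SeqIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = _clean_sequence(str(rec.seq), rec.id)
    return out


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def load_dataset(
    fasta_path: str | Path,
    counts_path: str | Path,
    meta_path: str | Path,
) -> tuple[list[OtuRecord], list[SampleMeta]]:
    """Load OTU sequences, the read-count matrix, and sample metadata.

    Every FASTA id must appear in the count matrix and every count-matrix
    sample column must appear in the metadata.  Cells absent from the matrix
    are read as 0 (sparse merges of multi-study tables); OTUs whose row sums
    to zero are retained.
    """
    seqs = read_fasta(fasta_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    counts = counts.fillna(0)

    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "area", "habitat"}
    if not required.issubset(meta_df.columns):
        raise SeqIOError(
            f"metadata must have columns {sorted(required)}, got {list(meta_df.columns)}"
        )
    if meta_df["sample_id"].duplicated().any():
        dups = sorted(meta_df.loc[meta_df["sample_id"].duplicated(), "sample_id"])
        raise SeqIOError(f"duplicate sample_ids in metadata: {dups}")
    meta = [
        SampleMeta(row.sample_id, row.area, row.habitat)
        for row in meta_df.itertuples()
    ]
    meta_ids = {m.sample_id for m in meta}

    missing_rows = sorted(set(seqs) - set(counts.index.astype(str)))
    if missing_rows:
        raise SeqIOError(f"FASTA ids absent from count matrix: {missing_rows}")
    missing_cols = sorted(set(counts.columns.astype(str)) - meta_ids)
    if missing_cols:
        raise SeqIOError(f"count-matrix samples absent from metadata: {missing_cols}")

    records = []
    for otu_id, seq in seqs.items():
        row = counts.loc[otu_id]
        cells = {str(s): int(row[s]) for s in counts.columns}
        # samples in metadata but not in the matrix count as 0
        for m in meta:
            cells.setdefault(m.sample_id, 0)
        if any(v < 0 for v in cells.values()):
            raise SeqIOError(f"negative read count for OTU {otu_id!r}")
        records.append(OtuRecord(otu_id=otu_id, sequence=seq, counts=cells))
    return records, meta


def write_dataset(
    records: Iterable[OtuRecord],
    meta: Iterable[SampleMeta],
    fasta_path: str | Path,
    counts_path: str | Path,
    meta_path: str | Path,
) -> None:
    records = list(records)
    meta = list(meta)
    write_fasta(((r.otu_id, r.sequence) for r in records), fasta_path)
    sample_ids = [m.sample_id for m in meta]
    table = pd.DataFrame(
        [[r.counts.get(s, 0) for s in sample_ids] for r in records],
        index=pd.Index([r.otu_id for r in records], name="otu_id"),
        columns=sample_ids,
    )
    table.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": sample_ids, "area": [m.area for m in meta],
         "habitat": [m.habitat for m in meta]}
    ).to_csv(meta_path, sep="\t", index=False)


def load_references(
    fasta_path: str | Path, annot_path: str | Path
) -> list[ReferenceRecord]:
    """Load the reference database: sequences plus category annotations.

    The annotation TSV has columns ref_id, taxon, category; every row must
    reference an existing FASTA entry and categories come from the closed
    enumeration.  An empty annotation table yields an empty list with a
    warning.
    """
    seqs = read_fasta(fasta_path)
    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    required = {"ref_id", "taxon", "category"}
    if not required.issubset(annot.columns):
        raise SeqIOError(
            f"reference annotations need columns {sorted(required)}, "
            f"got {list(annot.columns)}"
        )
    if annot.empty:
        warnings.warn(f"reference annotation file {annot_path} is empty")
        return []
    if annot["ref_id"].duplicated().any():
        dups = sorted(annot.loc[annot["ref_id"].duplicated(), "ref_id"])
        raise SeqIOError(f"duplicate ref_ids in annotations: {dups}")
    out = []
    for row in annot.itertuples():
        if row.ref_id not in seqs:
            raise SeqIOError(f"annotation id {row.ref_id!r} has no FASTA entry")
        out.append(
            ReferenceRecord(
                ref_id=row.ref_id,
                sequence=seqs[row.ref_id],
                taxon=row.taxon,
                category=row.category,
            )
        )
    return out


def write_references(
    references: Iterable[ReferenceRecord],
    fasta_path: str | Path,
    annot_path: str | Path,
) -> None:
    refs = list(references)
    write_fasta(((r.ref_id, r.sequence) for r in refs), fasta_path)
    pd.DataFrame(
        {"ref_id": [r.ref_id for r in refs],
         "taxon": [r.taxon for r in refs],
         "category": [r.category for r in refs]}
    ).to_csv(annot_path, sep="\t", index=False)


def load_prior(path: str | Path) -> list[PriorAssignment]:
    """Load an optional prior-taxonomy table (otu_id, label, status)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"otu_id", "label", "status"}
    if not required.issubset(df.columns):
        raise SeqIOError(
            f"prior table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["otu_id"].duplicated().any():
        dups = sorted(df.loc[df["otu_id"].duplicated(), "otu_id"])
        raise SeqIOError(f"duplicate otu_ids in prior table: {dups}")
    return [PriorAssignment(r.otu_id, r.label, r.status) for r in df.itertuples()]


# -- signature table -------------------------------------------------------

_SIG_COLUMNS = ["name", "pattern", "placement", "member_otus", "total_reads"]


def write_signatures(signatures, path: str | Path) -> None:
    """Persist a signature table: name, pattern, placement, members, reads."""
    rows = []
    for sig in signatures:
        rows.append(
            {
                "name": str(sig.name),
                "pattern": sig.pattern,
                "placement": sig.placement,
                "member_otus": ",".join(sorted(sig.member_otus)),
                "total_reads": sig.total_reads,
            }
        )
    pd.DataFrame(rows, columns=_SIG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_signatures(path: str | Path):
    """Read a signature table written by :func:`write_signatures`.

    Patterns must be uppercase A/C/G/T; anything else (including N) is
    rejected with the offending line number.
    """
    from foramsig.discovery import Signature, LineageName, PLACEMENTS

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _SIG_COLUMNS:
        raise SeqIOError(
            f"signature table columns {list(df.columns)} != {_SIG_COLUMNS}"
        )
    out = []
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        pattern = row.pattern
        if not pattern or set(pattern) - set("ACGT"):
            raise SeqIOError(f"{path} line {i}: pattern {pattern!r} is not A/C/G/T")
        if row.placement not in PLACEMENTS:
            raise SeqIOError(f"{path} line {i}: unknown placement {row.placement!r}")
        members = frozenset(m for m in (row.member_otus or "").split(",") if m)
        out.append(
            Signature(
                name=LineageName.parse(row.name),
                pattern=pattern,
                placement=row.placement,
                member_otus=members,
                total_reads=int(row.total_reads),
            )
        )
    return out


# -- assignment table ------------------------------------------------------

_ASSIGN_COLUMNS = ["otu_id", "label", "source", "matched_pattern", "conflict_note"]


def write_assignments(assignments, path: str | Path) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "otu_id": a.otu_id,
                "label": a.label,
                "source": a.source or "",
                "matched_pattern": a.matched_pattern or "",
                "conflict_note": a.conflict_note or "",
            }
        )
    pd.DataFrame(rows, columns=_ASSIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path):
    from foramsig.classify import AssignmentRecord

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns) != _ASSIGN_COLUMNS:
        raise SeqIOError(
            f"assignment table columns {list(df.columns)} != {_ASSIGN_COLUMNS}"
        )
    if df["otu_id"].duplicated().any():
        dups = sorted(df.loc[df["otu_id"].duplicated(), "otu_id"])
        raise SeqIOError(f"duplicate otu_ids in assignment table: {dups}")
    return [
        AssignmentRecord(
            otu_id=r.otu_id,
            label=r.label,
            source=r.source or None,
            matched_pattern=r.matched_pattern or None,
            conflict_note=r.conflict_note or None,
        )
        for r in df.itertuples()
    ]
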