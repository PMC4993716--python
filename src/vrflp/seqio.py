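"""Reading and writing of sequences, alignments, group maps and labeled matrices.

All downstream stages consume the types defined here.  Input is validated
eagerly so that later stages can assume well-formed data: unique ids, a
closed IUPAC alphabet, rectangular alignments, consistent group maps.

Coordinates are 0-based half-open internally; human-facing reports use
1-based inclusive positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

#: IUPAC nucleotide one-letter codes, gap included.  "." is normalized to "-".
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Concrete base sets for every IUPAC symbol (gap excluded).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad symbol, duplicate id, ...)."""


def _normalize_residues(raw: str, seq_id: str) -> str:
    residues = raw.upper().replace(".", "-")
    if not residues:
        raise SequenceError(f"sequence {seq_id!r} is empty")
    bad = set(residues) - IUPAC_CODES
    if bad:
        sym = sorted(bad)[0]
        raise SequenceError(
            f"sequence {seq_id!r} contains illegal symbol {sym!r}"
        )
    return residues


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence, optionally tagged with an
    accession and a group label."""

    id: str
    residues: str
    accession: str | None = None
    group: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be nonempty")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.id)
        )

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps stripped."""
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSet:
    """An alignment: equal-length sequence records in a fixed order."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise SequenceError("alignment is empty")
        _check_unique_ids(records)
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            shortest = min(records, key=len)
            longest = max(records, key=len)
            raise SequenceError(
                "ragged alignment: "
                f"{shortest.id!r} has {len(shortest)} columns while "
                f"{longest.id!r} has {len(longest)}"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, index: int) -> str:
        return "".join(r.residues[index] for r in self.records)


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping of sequence ids to group names.

    ``groups`` preserves first-appearance order from the source file.
    """

    mapping: dict[str, str]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.groups:
            seen: list[str] = []
            for g in self.mapping.values():
                if g not in seen:
                    seen.append(g)
            object.__setattr__(self, "groups", tuple(seen))
        for sid, g in self.mapping.items():
            if not g:
                raise SequenceError(f"blank group for id {sid!r}")

    def members(self, group: str) -> tuple[str, ...]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return tuple(s for s, g in self.mapping.items() if g == group)

    def validate_against(self, ids: Iterable[str]) -> None:
        """Ensure every mapped id exists in the sequence set."""
        known = set(ids)
        missing = sorted(set(self.mapping) - known)
        if missing:
            raise SequenceError(
                f"group map references unknown sequence id(s): {missing}"
            )


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The id is the first whitespace-delimited header token; the full header
    is retained as the description.  Residues are uppercased and "." is
    normalized to "-".
    """
    path = Path(path)
    records = [
        SequenceRecord(
            id=raw.id,
            residues=str(raw.seq),
            description=raw.description or None,
        )
        for raw in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    _check_unique_ids(records)
    return records


def read_aligned(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA file, enforcing equal sequence lengths."""
    return AlignedSet(tuple(read_fasta(path)))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_group_map(path: str | Path) -> GroupAssignment:
    """Read a two-column (id, group) delimited file.

    A header line whose first field is literally ``id`` is skipped.
    Duplicate rows must agree on the group.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) == 1:
                row = row[0].split()
            if len(row) < 2:
                raise SequenceError(
                    f"{path}:{lineno}: expected two columns (id, group)"
                )
            sid, group = row[0].strip(), row[1].strip()
            if lineno == 1 and sid.lower() == "id":
                continue
            if not group:
                raise SequenceError(f"{path}:{lineno}: blank group for {sid!r}")
            if sid in mapping and mapping[sid] != group:
                raise SequenceError(
                    f"{path}:{lineno}: conflicting groups for id {sid!r}: "
                    f"{mapping[sid]!r} vs {group!r}"
                )
            mapping[sid] = group
    if not mapping:
        raise SequenceError(f"no group assignments found in {path}")
    return GroupAssignment(mapping)


def write_group_map(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for sid, g in groups.mapping.items():
            fh.write(f"{sid}\t{g}\n")


def as_frame(
    values: Sequence[Sequence],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> pd.DataFrame:
    """Build a labeled DataFrame, rejecting non-rectangular input."""
    widths = {len(row) for row in values}
    if len(widths) > 1:
        raise ValueError(f"non-rectangular matrix: row widths {sorted(widths)}")
    if values and widths != {len(col_labels)}:
        raise ValueError(
            f"matrix has {widths.pop()} columns but {len(col_labels)} labels"
        )
    if len(values) != len(row_labels):
        raise ValueError(
            f"matrix has {len(values)} rows but {len(row_labels)} labels"
        )
    return pd.DataFrame(list(map(list, values)), index=list(row_labels),
                        columns=list(col_labels))


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as TSV (first row/column are labels)."""
    matrix.to_csv(path, sep="\t", index_label="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df
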