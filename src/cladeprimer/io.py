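"""Sequence records, FASTA I/O and group-label tables.

Templates are ungapped IUPAC nucleotide sequences; gapped FASTA is read only
through the alignment reader in :mod:`cladeprimer.phylo`. Group labels are a
two-column TSV (sequence_id, group) used to split a reference database into
the in-group clade and everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP_CHARS, IUPAC_SETS, normalize

__all__ = [
    "NucleotideSequence",
    "GroupLabeling",
    "ReferenceDatabase",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified nucleotide sequence over the IUPAC alphabet (U already mapped to T)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


def _validated(seq: str, *, allow_gaps: bool, where: str) -> str:
    allowed = set(IUPAC_SETS) | (set(GAP_CHARS) if allow_gaps else set())
    for ch in seq:
        if ch not in allowed:
            raise FastaParseError(f"invalid symbol {ch!r} {where}")
    return seq


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[NucleotideSequence]:
    """Read FASTA into :class:`NucleotideSequence` records.

    Sequences are uppercased and U is mapped to T; record order is preserved.
    Empty sequences and symbols outside the IUPAC alphabet raise
    :class:`FastaParseError` naming the offending line. Gap characters are
    rejected unless ``allow_gaps`` is set (used by the alignment reader).
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    with open(path) as fh:
        head = fh.read(1)
        if head not in (">", ""):
            raise FastaParseError(f"{path}: line 1: expected '>' header, got {head!r}")
        fh.seek(0)
        for title, raw_seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            seq_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if not seq_id:
                line = _locate(path, len(records), 0, header=True)
                raise FastaParseError(f"{path}: line {line}: empty FASTA header")
            seq = normalize(raw_seq)
            if not seq:
                line = _locate(path, len(records), 0, header=True)
                raise FastaParseError(
                    f"{path}: line {line}: record {seq_id!r} has an empty sequence"
                )
            try:
                _validated(seq, allow_gaps=allow_gaps, where="")
            except FastaParseError:
                bad = _first_bad(seq, allow_gaps)
                line = _locate(path, len(records), bad)
                raise FastaParseError(
                    f"{path}: line {line}: record {seq_id!r}: "
                    f"invalid symbol {seq[bad]!r}"
                ) from None
            records.append(NucleotideSequence(seq_id, seq, desc))
    return records


def _first_bad(seq: str, allow_gaps: bool) -> int:
    allowed = set(IUPAC_SETS) | (set(GAP_CHARS) if allow_gaps else set())
    for i, ch in enumerate(seq):
        if ch not in allowed:
            return i
    raise AssertionError("no invalid symbol found")


def _locate(path: Path, record_index: int, seq_offset: int, header: bool = False) -> int:
    """Line number of a record's header, or of the sequence line holding ``seq_offset``."""
    idx = -1
    consumed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                idx = idx + 1
                if idx == record_index and header:
                    return lineno
                consumed = 0
            elif idx == record_index:
                n = len(line.strip())
                if consumed + n > seq_offset:
                    return lineno
                consumed += n
    return lineno


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write records as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        seqio_write(seq_records, fh, "fasta")


@dataclass
class GroupLabeling:
    """Mapping sequence id -> group name, with a designated in-group name."""

    groups: dict[str, str]
    in_group: str | None = None

    def members(self, group: str) -> list[str]:
        return [sid for sid, g in self.groups.items() if g == group]

    def group_names(self) -> set[str]:
        return set(self.groups.values())

    def require_group(self, name: str) -> None:
        if name not in self.group_names():
            raise KeyError(
                f"unknown group {name!r}; known groups: {sorted(self.group_names())}"
            )


@dataclass
class ReferenceDatabase:
    """Labeled nucleotide sequences against which primers are evaluated."""

    records: list[NucleotideSequence]
    labels: GroupLabeling = field(default_factory=lambda: GroupLabeling({}))

    def __len__(self) -> int:
        return len(self.records)

    def in_group_records(self, in_group: str | None = None) -> list[NucleotideSequence]:
        name = in_group or self.labels.in_group
        if name is None:
            raise ValueError("no in-group name designated")
        self.labels.require_group(name)
        return [r for r in self.records if self.labels.groups.get(r.id) == name]

    def out_group_records(self, in_group: str | None = None) -> list[NucleotideSequence]:
        name = in_group or self.labels.in_group
        if name is None:
            raise ValueError("no in-group name designated")
        self.labels.require_group(name)
        return [r for r in self.records if self.labels.groups.get(r.id) != name]


def read_labels(path: str | Path, in_group: str | None = None) -> GroupLabeling:
    """Read a two-column (sequence_id, group) TSV; a literal header row is tolerated."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sequence_id", "group"],
        dtype=str, comment="#",
    )
    if len(df) and list(df.iloc[0]) == ["sequence_id", "group"]:
        df = df.iloc[1:]
    if df["sequence_id"].duplicated().any():
        dup = df.loc[df["sequence_id"].duplicated(), "sequence_id"].iloc[0]
        raise ValueError(f"duplicate sequence id in label table: {dup!r}")
    return GroupLabeling(dict(zip(df["sequence_id"], df["group"])), in_group=in_group)


def write_labels(labels: GroupLabeling, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, group in labels.groups.items():
            fh.write(f"{sid}\t{group}\n")
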