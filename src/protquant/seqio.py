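"""Sequence containers and FASTA I/O.

Sequences are stored as :class:`SequenceRecord` objects whose ``data`` is an
ordered list of elements.  Elements may be amino-acid symbols (single
characters), numbers produced by a property mapping, or reduced-alphabet class
labels — every downstream module consumes the same container, so conversions
and quantifications compose freely.  A :class:`SequenceSet` is an ordered,
named collection of records, optionally enforcing unique
``(identifier, feature_name)`` pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "FastaFormatError",
    "DuplicateIdentifierError",
    "read_fasta",
    "write_fasta",
    "merge",
    "columns",
    "subset",
    "compact",
    "write_table",
]


class FastaFormatError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


class DuplicateIdentifierError(ValueError):
    """Two records share (identifier, feature_name) in a unique-ids set."""


@dataclass
class SequenceRecord:
    """One identified sequence of elements.

    Parameters
    ----------
    identifier : str
        FASTA header token before the first whitespace.
    feature_name : str
        Name of the data carried: ``"fasta"`` for raw symbols, otherwise the
        name of the mapping/feature that produced it.
    data : list
        Ordered elements; single characters for symbolic records, numbers for
        quantitative ones.  A scalar feature result is a length-1 list.
    description : str
        Full FASTA header (after '>'), retained for round-tripping.
    """

    identifier: str
    feature_name: str
    data: list
    description: str = ""

    def __post_init__(self) -> None:
        if self.data is None:
            raise ValueError("record data must not be None")
        self.data = list(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def symbolic(self) -> bool:
        """True if every element is a single-character string."""
        return all(isinstance(x, str) and len(x) == 1 for x in self.data)

    @property
    def numeric(self) -> bool:
        return all(isinstance(x, (int, float)) and not isinstance(x, bool)
                   for x in self.data)

    def copy(self) -> "SequenceRecord":
        return SequenceRecord(self.identifier, self.feature_name,
                              list(self.data), self.description)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord`.

    With ``unique_ids=True``, adding a record whose
    ``(identifier, feature_name)`` pair is already present raises
    :class:`DuplicateIdentifierError`.  Insertion order is always preserved.
    """

    name: str = ""
    unique_ids: bool = False
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        records, self.records = list(self.records), []
        for rec in records:
            self.add(rec)

    def add(self, record: SequenceRecord) -> None:
        if self.unique_ids:
            key = (record.identifier, record.feature_name)
            if any((r.identifier, r.feature_name) == key for r in self.records):
                raise DuplicateIdentifierError(
                    f"duplicate record {key!r} in set {self.name!r}")
        self.records.append(record)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list:
        return [r.identifier for r in self.records]

    def copy(self, name: str | None = None) -> "SequenceSet":
        out = SequenceSet(name if name is not None else self.name,
                          self.unique_ids)
        for rec in self.records:
            out.add(rec.copy())
        return out


def read_fasta(path, feature_name: str = "fasta", uppercase: bool = True,
               name: str | None = None, unique_ids: bool = False) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The identifier is the header token before the first whitespace; the full
    header is kept as the record description.  Sequence lines are concatenated
    with internal whitespace removed.  Residue case is folded to upper unless
    ``uppercase=False``; non-standard symbols (B, Z, X, U, O, '*', '-') are
    preserved as read.

    An entry with a header but no sequence lines yields a record with empty
    data and a warning.  Non-blank content before the first '>' raises
    :class:`FastaFormatError`; an empty file yields an empty set.
    """
    with open(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError(
            f"{path}: sequence data before the first '>' header")
    sset = SequenceSet(name if name is not None else str(path),
                       unique_ids=unique_ids)
    if not stripped:
        return sset
    import io
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        identifier = title.split()[0] if title.split() else ""
        if uppercase:
            seq = seq.upper()
        if not seq:
            warnings.warn(f"FASTA entry {identifier!r} has an empty body",
                          stacklevel=2)
        sset.add(SequenceRecord(identifier, feature_name, list(seq),
                                description=title))
    return sset


def write_fasta(sset: SequenceSet, path, line_width: int = 60) -> None:
    """Write a symbolic :class:`SequenceSet` as multi-line FASTA.

    Sequence lines are wrapped at ``line_width`` characters.  A record whose
    elements are not single-character symbols raises ``TypeError`` naming the
    record.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as handle:
        for rec in sset:
            if not rec.symbolic:
                raise TypeError(
                    f"record {rec.identifier!r} ({rec.feature_name!r}) is not "
                    "symbolic; write_fasta requires single-character elements")
            header = rec.description if rec.description else rec.identifier
            handle.write(f">{header}\n")
            seq = "".join(rec.data)
            for i in range(0, len(seq), line_width):
                handle.write(seq[i:i + line_width] + "\n")


def merge(a: SequenceSet, b: SequenceSet, name: str = "",
          unique_ids: bool | None = None) -> SequenceSet:
    """Concatenate two sets: records of ``a`` then records of ``b``.

    ``unique_ids`` defaults to ``a.unique_ids or b.unique_ids``; a collision
    under that flag raises :class:`DuplicateIdentifierError`.
    """
    if unique_ids is None:
        unique_ids = a.unique_ids or b.unique_ids
    out = SequenceSet(name, unique_ids=unique_ids)
    for rec in list(a) + list(b):
        out.add(rec.copy())
    return out


def columns(sset: SequenceSet, indices: Sequence[int],
            transpose: bool = False) -> list:
    """Extract the given 0-based positions from every record as a matrix.

    Returns one row per record (one per index if ``transpose``).  Every index
    must be valid for every record.
    """
    for rec in sset:
        for i in indices:
            if not 0 <= i < len(rec):
                raise IndexError(
                    f"column {i} out of range for record {rec.identifier!r} "
                    f"(length {len(rec)})")
    matrix = [[rec.data[i] for i in indices] for rec in sset]
    if transpose:
        matrix = [list(row) for row in zip(*matrix)] if matrix else []
    return matrix


def subset(sset: SequenceSet, predicate: Callable[[SequenceRecord], bool],
           name: str | None = None) -> SequenceSet:
    """Records for which ``predicate`` holds, order preserved; input unchanged."""
    out = SequenceSet(name if name is not None else sset.name,
                      unique_ids=sset.unique_ids)
    for rec in sset:
        try:
            keep = predicate(rec)
        except Exception as exc:
            raise type(exc)(
                f"predicate failed on record {rec.identifier!r}: {exc}"
            ) from exc
        if keep:
            out.add(rec.copy())
    return out


def compact(sset: SequenceSet, name: str = "", sep: str = ":",
            strict: bool = False) -> SequenceSet:
    """Collapse single-value feature records into one vector per identifier.

    Every input record must carry exactly one value.  Output: one record per
    distinct identifier (encounter order), whose data concatenates that
    identifier's values in input order and whose feature_name joins the
    contributing feature names with ``sep``.

    With ``strict=True`` every identifier must have contributed the same
    ordered feature list (no ragged vectors).
    """
    for rec in sset:
        if len(rec) != 1:
            raise ValueError(
                f"compact requires single-value records; "
                f"{rec.identifier!r}/{rec.feature_name!r} has length {len(rec)}")
    grouped: dict = {}
    for rec in sset:
        grouped.setdefault(rec.identifier, []).append(rec)
    if strict:
        signatures = {tuple(r.feature_name for r in recs)
                      for recs in grouped.values()}
        if len(signatures) > 1:
            raise ValueError(
                "ragged compact: identifiers carry different feature lists: "
                f"{sorted(signatures)}")
    out = SequenceSet(name, unique_ids=sset.unique_ids)
    for identifier, recs in grouped.items():
        out.add(SequenceRecord(
            identifier,
            sep.join(r.feature_name for r in recs),
            [r.data[0] for r in recs],
            description=recs[0].description,
        ))
    return out


def write_table(sset: SequenceSet, path, sep: str = "\t",
                feature_sep: str = ":") -> None:
    """Export a (typically compacted) set as a tab-separated table.

    Columns: identifier followed by one column per value.  When every record
    shares the same feature_name, its ``feature_sep``-separated parts become
    the header; otherwise a generic ``value_i`` header is used.
    """
    names = {rec.feature_name for rec in sset}
    widths = {len(rec) for rec in sset}
    if len(names) == 1 and len(widths) == 1:
        header = ["identifier"] + next(iter(names)).split(feature_sep)
    else:
        width = max(widths, default=0)
        header = ["identifier"] + [f"value_{i}" for i in range(width)]
    with open(path, "w") as handle:
        handle.write(sep.join(header) + "\n")
        for rec in sset:
            cells = [rec.identifier] + [_fmt(v) for v in rec.data]
            handle.write(sep.join(cells) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)
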