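"""Residue-to-value tables: AAindex scales, custom mappings, reduced alphabets.

A :class:`PropertyMapping` converts symbolic sequences into quantitative ones
(charge, hydropathy, volume, any AAindex1 scale) or into reduced alphabets via
three discretization schemes: explicit thresholds, linear (equal-width)
thresholds, and 1-D k-means clustering of the property values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "RAISE",
    "AMINO_ACIDS",
    "AAINDEX_ROW1",
    "AAINDEX_ROW2",
    "PropertyMapping",
    "UnknownSymbolError",
    "AAIndexFormatError",
    "parse_aaindex1",
    "read_aaindex1_file",
    "load_predefined",
    "read_mapping",
    "write_mapping",
    "simplify_thresholds",
    "simplify_linear",
    "simplify_kmeans",
]

#: Sentinel for "raise on unknown symbol instead of substituting a default".
RAISE = "error"

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

# Canonical AAindex1 residue order: first and second value row of a record.
AAINDEX_ROW1 = tuple("ARNDCQEGHI")
AAINDEX_ROW2 = tuple("LKMFPSTWYV")


class UnknownSymbolError(KeyError):
    """A symbol without a table entry was met while default is RAISE."""


class AAIndexFormatError(ValueError):
    """Malformed or missing AAindex1 record."""


@dataclass
class PropertyMapping:
    """A named symbol→value table with a default for unlisted symbols.

    ``default=RAISE`` makes application to an unknown symbol an error rather
    than a silent substitution.  Values may be numbers (property scales) or
    arbitrary labels (reduced alphabets).  ``misc`` carries free-form metadata
    such as the AAindex accession and description.
    """

    name: str
    table: dict
    default: object = RAISE
    misc: dict = field(default_factory=dict)

    @property
    def source_alphabet(self) -> tuple:
        return tuple(self.table)

    @property
    def numeric(self) -> bool:
        return all(isinstance(v, (int, float)) and not isinstance(v, bool)
                   for v in self.table.values())

    def __getitem__(self, symbol):
        if symbol in self.table:
            return self.table[symbol]
        if self.default is RAISE:
            raise UnknownSymbolError(
                f"symbol {symbol!r} not in mapping {self.name!r}")
        return self.default

    def __call__(self, rec: SequenceRecord) -> SequenceRecord:
        return apply_mapping(self, rec)

    def values(self) -> list:
        return list(self.table.values())

    def normalized(self, lo: float | None = None, hi: float | None = None,
                   name: str | None = None) -> "PropertyMapping":
        """Affinely rescale a numeric mapping onto [0, 1].

        ``lo``/``hi`` default to the table's min/max; pass explicit limits to
        normalize onto a conventional range (e.g. Kyte–Doolittle hydropathy
        with lo=-4.5, hi=4.5 gives the (x+4.5)/9 scale used in
        charge–hydropathy plots).
        """
        if not self.numeric:
            raise TypeError(f"mapping {self.name!r} is not numeric")
        vals = self.values()
        lo = min(vals) if lo is None else lo
        hi = max(vals) if hi is None else hi
        if hi <= lo:
            raise ValueError("degenerate range: hi must exceed lo")
        span = hi - lo
        table = {s: (v - lo) / span for s, v in self.table.items()}
        default = self.default
        if default is not RAISE and isinstance(default, (int, float)):
            default = (default - lo) / span
        return PropertyMapping(name or f"{self.name}_norm", table, default,
                               dict(self.misc))


def apply_mapping(m: PropertyMapping, rec: SequenceRecord) -> SequenceRecord:
    """Convert a symbolic record element-wise through the mapping.

    Length is preserved; the output feature_name is the mapping's name.
    An unknown symbol under ``default=RAISE`` raises
    :class:`UnknownSymbolError` naming the position and symbol.
    """
    out = []
    for pos, symbol in enumerate(rec.data):
        if symbol in m.table:
            out.append(m.table[symbol])
        elif m.default is RAISE:
            raise UnknownSymbolError(
                f"unknown symbol {symbol!r} at position {pos} of record "
                f"{rec.identifier!r} (mapping {m.name!r})")
        else:
            out.append(m.default)
    return SequenceRecord(rec.identifier, m.name, out, rec.description)


# ---------------------------------------------------------------------------
# AAindex1 flat-file parsing

def parse_aaindex1(text: str, accession: str, default=RAISE,
                   name: str | None = None) -> PropertyMapping:
    """Extract one scale from AAindex1 flat-file content.

    An AAindex1 record starts with ``H <accession>``, carries a description
    on the ``D`` line, an ``I`` line naming the twenty residues in the
    canonical A/L R/K ... I/V column layout, followed by two rows of ten
    values, and ends with ``//``.  ``NA`` values are recorded as missing:
    the mapping's ``default`` is substituted for them on application.
    """
    for record in text.split("//"):
        lines = [ln for ln in record.splitlines() if ln.strip()]
        header = next((ln for ln in lines if ln.startswith("H ")), None)
        if header is None or header.split()[1] != accession:
            continue
        desc = next((ln[2:].strip() for ln in lines if ln.startswith("D ")), "")
        i_at = next((k for k, ln in enumerate(lines) if ln.startswith("I ")),
                    None)
        if i_at is None or len(lines) < i_at + 3:
            raise AAIndexFormatError(
                f"record {accession}: missing I line or value rows")
        values: list = []
        for row in lines[i_at + 1:i_at + 3]:
            values.extend(row.split())
        if len(values) != 20:
            raise AAIndexFormatError(
                f"record {accession}: expected 20 values, got {len(values)}")
        table = {}
        for residue, raw in zip(AAINDEX_ROW1 + AAINDEX_ROW2,
                                values[:10] + values[10:]):
            if raw.upper() == "NA":
                continue
            table[residue] = float(raw)
        return PropertyMapping(name or accession, table, default,
                               misc={"accession": accession,
                                     "description": desc})
    raise AAIndexFormatError(f"accession {accession!r} not found")


def read_aaindex1_file(path, accession: str, default=RAISE,
                       name: str | None = None) -> PropertyMapping:
    return parse_aaindex1(Path(path).read_text(), accession, default, name)


# ---------------------------------------------------------------------------
# Predefined scales and two-column mapping files

#: name -> (data file, default value for unlisted symbols)
_PREDEFINED = {
    "hydropathy": ("kyte_doolittle_hydropathy.tsv", RAISE),
    "charge": ("formal_charge.tsv", 0.0),
    "volume": ("residue_volume.tsv", RAISE),
}


def load_predefined(name: str) -> PropertyMapping:
    """Load a shipped property scale: 'hydropathy', 'charge' or 'volume'."""
    if name not in _PREDEFINED:
        raise KeyError(f"no predefined mapping {name!r}; "
                       f"choose from {sorted(_PREDEFINED)}")
    filename, default = _PREDEFINED[name]
    text = (resources.files("protquant") / "data" / filename).read_text()
    return _parse_two_column(text, name, default)


def read_mapping(path, name: str | None = None, default=RAISE) -> PropertyMapping:
    """Read a two-column (symbol, value) text mapping file."""
    return _parse_two_column(Path(path).read_text(),
                             name or Path(path).stem, default)


def _parse_two_column(text: str, name: str, default) -> PropertyMapping:
    table = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        symbol, raw = ln.split()[:2]
        try:
            value: object = float(raw)
        except ValueError:
            value = raw
        table[symbol] = value
    return PropertyMapping(name, table, default)


def write_mapping(m: PropertyMapping, path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# {m.name}\n")
        for symbol, value in m.table.items():
            handle.write(f"{symbol}\t{value}\n")


# ---------------------------------------------------------------------------
# Reduced alphabets

def simplify_thresholds(m: PropertyMapping, thresholds,
                        labels=None, name: str | None = None) -> PropertyMapping:
    """Discretize a numeric mapping at the given strictly increasing cuts.

    Half-open convention: a residue with value v gets class
    ``#{t : t <= v}`` — a value exactly on a threshold goes to the upper
    class.  ``labels`` (length ``len(thresholds)+1``) substitutes class
    labels for the integer classes.
    """
    if not m.numeric:
        raise TypeError(f"mapping {m.name!r} is not numeric")
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if labels is not None and len(labels) != len(thresholds) + 1:
        raise ValueError("labels must have length len(thresholds)+1")
    table = {}
    for symbol, value in m.table.items():
        cls = sum(1 for t in thresholds if t <= value)
        table[symbol] = labels[cls] if labels is not None else cls
    return PropertyMapping(name or f"{m.name}_classes", table,
                           RAISE if m.default is RAISE else
                           (labels[sum(1 for t in thresholds if t <= m.default)]
                            if labels is not None else
                            sum(1 for t in thresholds if t <= m.default)),
                           dict(m.misc))


def simplify_linear(m: PropertyMapping, k: int,
                    labels=None, name: str | None = None) -> PropertyMapping:
    """Discretize with k equal-width bins over the mapping's value range."""
    if not m.numeric:
        raise TypeError(f"mapping {m.name!r} is not numeric")
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = m.values()
    lo, hi = min(vals), max(vals)
    if k > 1 and hi == lo:
        raise ValueError(
            f"mapping {m.name!r} has a degenerate value range [{lo}, {hi}]")
    thresholds = [lo + i * (hi - lo) / k for i in range(1, k)]
    return simplify_thresholds(m, thresholds, labels, name)


def simplify_kmeans(m: PropertyMapping, k: int, seed: int = 0,
                    iterations: int = 100,
                    name: str | None = None) -> PropertyMapping:
    """Reduce the alphabet by 1-D k-means over the property values.

    Deterministic given ``seed``: the first center is drawn from the distinct
    values with the seeded generator, the remaining centers by farthest-point
    selection; Lloyd iterations run until assignments are stable or
    ``iterations`` is exhausted.  Clusters are relabeled 0..k-1 in increasing
    centroid order, so equal inputs always receive equal classes and the
    labeling is invariant to residue-name permutation of equal values.
    """
    if not m.numeric:
        raise TypeError(f"mapping {m.name!r} is not numeric")
    distinct = np.array(sorted(set(m.values())), dtype=float)
    if k < 1 or k > distinct.size:
        raise ValueError(
            f"k must be in [1, {distinct.size}] (number of distinct values)")
    rng = np.random.default_rng(seed)
    centers = [distinct[rng.integers(distinct.size)]]
    while len(centers) < k:
        gaps = np.min(np.abs(distinct[:, None] - np.array(centers)[None, :]),
                      axis=1)
        centers.append(distinct[int(np.argmax(gaps))])
    centers = np.array(centers)
    assign = np.zeros(distinct.size, dtype=int)
    for _ in range(iterations):
        new_assign = np.argmin(np.abs(distinct[:, None] - centers[None, :]),
                               axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for c in range(k):
            members = distinct[assign == c]
            if members.size:
                centers[c] = members.mean()
    order = np.argsort([centers[c] for c in range(k)])
    relabel = {int(old): int(new) for new, old in enumerate(order)}
    value_class = {v: relabel[int(a)] for v, a in zip(distinct, assign)}
    table = {symbol: value_class[float(v)] for symbol, v in m.table.items()}
    return PropertyMapping(name or f"{m.name}_kmeans{k}", table, RAISE,
                           dict(m.misc))
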