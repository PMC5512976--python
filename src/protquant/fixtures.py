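"""Deterministic synthetic sequence sets with controlled composition.

Every demo and test runs on generated data: sequences are drawn i.i.d. from a
weighted residue alphabet, with lengths uniform in a range, fully reproducible
from a seed.  Preset compositions emulate populations that differ in the
feature spaces the toolkit analyses — hydrophobic vs hydrophilic peptides
(large apolar vs small polar residues, the kind of contrast seen between
amyloid-forming and non-forming peptide collections) and disorder-prone vs
order-prone proteins (charge/proline/glycine-rich vs aliphatic-rich, the
contrast underlying the charge–hydropathy plot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import AMINO_ACIDS
from .seqio import SequenceRecord, SequenceSet

__all__ = [
    "FixtureSpec",
    "COMPOSITIONS",
    "generate_fixture",
    "generate_two_populations",
]


def _weights(high: dict, base: float = 1.0) -> dict:
    return {aa: high.get(aa, base) for aa in AMINO_ACIDS}


#: Preset residue-sampling weights (relative, unnormalized).
COMPOSITIONS = {
    "uniform": {aa: 1.0 for aa in AMINO_ACIDS},
    # large hydrophobic residues enriched 4x
    "hydrophobic": _weights({aa: 4.0 for aa in "ILVFWYM"}),
    # small/polar/charged residues enriched 4x
    "hydrophilic": _weights({aa: 4.0 for aa in "STNQGDEKR"}),
    # charged and structure-breaking residues dominate; hydrophobics rare
    "disorder": _weights({"D": 5.0, "E": 5.0, "K": 5.0, "R": 5.0,
                          "S": 3.0, "P": 3.0, "Q": 3.0, "G": 3.0}, base=0.5),
    # aliphatic/aromatic core-forming residues dominate; charged rare
    "order": _weights({"I": 5.0, "L": 5.0, "V": 5.0, "F": 5.0,
                       "A": 3.0, "M": 3.0, "W": 3.0, "Y": 3.0, "C": 3.0},
                      base=0.5),
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic population.

    ``alphabet`` maps symbols to non-negative sampling weights (a preset name
    from :data:`COMPOSITIONS` is also accepted); lengths are uniform over
    ``length_range`` (peptide-scale 10–50 by default); identifiers are
    ``{population_label}_{index}``.
    """

    n_sequences: int = 100
    length_range: tuple = (10, 50)
    alphabet: dict | str = "uniform"
    seed: int = 0
    population_label: str = "seq"

    def weights(self) -> tuple:
        table = COMPOSITIONS[self.alphabet] \
            if isinstance(self.alphabet, str) else dict(self.alphabet)
        if not table:
            raise ValueError("alphabet must not be empty")
        symbols = list(table)
        w = np.array([table[s] for s in symbols], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with a positive sum")
        return symbols, w / w.sum()

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 0:
            raise ValueError("length_range must satisfy 0 <= min <= max")


def generate_fixture(spec: FixtureSpec) -> SequenceSet:
    """Draw a reproducible :class:`SequenceSet` from the spec's recipe."""
    symbols, p = spec.weights()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    sset = SequenceSet(spec.population_label, unique_ids=True)
    for i in range(spec.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(symbols, size=length, p=p)
        sset.add(SequenceRecord(f"{spec.population_label}_{i}", "fasta",
                                list(residues)))
    return sset


def generate_two_populations(spec1: FixtureSpec,
                             spec2: FixtureSpec) -> tuple:
    """Two sets with distinct labels, for two-sample comparisons."""
    if spec1.population_label == spec2.population_label:
        raise ValueError("populations must carry distinct labels")
    return generate_fixture(spec1), generate_fixture(spec2)
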