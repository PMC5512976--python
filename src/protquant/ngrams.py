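"""Pattern matching, n-gram counting, and power-law (Zipf) fitting.

Gap-free patterns are matched exactly or within a similarity radius under the
same metrics the RQA module uses.  All n-grams of a sequence set are counted
in a single pass per sequence (overlapping occurrences included), and the
resulting count distribution can be fitted with a discrete power law
P(x) ∝ x^(-alpha), x >= xmin — the Zipf's-law description of n-gram
frequencies — by maximum likelihood with zeta-function normalization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from numbers import Number

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .seqio import SequenceRecord, SequenceSet

__all__ = [
    "Pattern",
    "NgramCountTable",
    "PowerLawFit",
    "match_positions",
    "count_ngrams",
    "ngram_profile",
    "rank_frequency",
    "fit_powerlaw",
    "powerlaw_loglikelihood",
    "sample_powerlaw",
    "write_counts",
]

#: Guard for declared-alphabet enumeration (|alphabet|^n table cells).
MAX_TABLE_CELLS = 10 ** 6


@dataclass(frozen=True)
class Pattern:
    """A gap-free pattern with an optional similarity radius.

    With the identity metric a window matches iff it equals the pattern
    element-wise (the radius is not used); numeric metrics aggregate
    element-wise differences (taxi: sum |d|, euclid: sqrt(sum d²),
    sup: max |d|) and match when the distance is <= radius.
    """

    elements: tuple
    metric: str = "identity"
    radius: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.metric not in ("identity", "taxi", "euclid", "sup"):
            raise ValueError("metric must be identity/taxi/euclid/sup")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    def __len__(self) -> int:
        return len(self.elements)


def match_positions(rec: SequenceRecord, p: Pattern) -> list:
    """0-based start positions of all (possibly overlapping) matches."""
    data = rec.data
    m = len(p)
    if m == 0 or m > len(data):
        return []
    if p.metric == "identity":
        target = p.elements
        return [i for i in range(len(data) - m + 1)
                if tuple(data[i:i + m]) == target]
    if not all(isinstance(x, Number) and not isinstance(x, bool)
               for x in data):
        raise TypeError(
            f"metric {p.metric!r} requires numeric data in record "
            f"{rec.identifier!r}")
    arr = np.asarray(data, dtype=float)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    diff = windows - np.asarray(p.elements, dtype=float)
    if p.metric == "taxi":
        dist = np.abs(diff).sum(axis=1)
    elif p.metric == "euclid":
        dist = np.sqrt((diff ** 2).sum(axis=1))
    else:
        dist = np.abs(diff).max(axis=1)
    return [int(i) for i in np.nonzero(dist <= p.radius)[0]]


@dataclass
class NgramCountTable:
    """Counts of all length-n windows over a sequence set.

    Keys are element tuples; ``total`` equals the number of windows,
    sum_i max(0, L_i - n + 1).  With a declared ``alphabet`` every possible
    n-gram appears, unobserved ones with count 0.
    """

    n: int
    counts: dict
    total: int
    alphabet: tuple | None = None

    def as_strings(self) -> dict:
        """Counts keyed by joined strings (symbolic n-grams only)."""
        return {"".join(map(str, k)): v for k, v in self.counts.items()}


def count_ngrams(sset: SequenceSet, n: int,
                 alphabet=None) -> NgramCountTable:
    """Tally every length-n window of every record in one pass each.

    Overlapping occurrences are counted.  When ``alphabet`` is declared, the
    full |alphabet|^n key space is materialized (0 for unseen n-grams),
    guarded by a cell cap to protect memory.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict = {}
    if alphabet is not None:
        alphabet = tuple(alphabet)
        if len(alphabet) ** n > MAX_TABLE_CELLS:
            raise ValueError(
                f"declared alphabet implies {len(alphabet)}^{n} cells, "
                f"above the {MAX_TABLE_CELLS} cap")
        for gram in itertools.product(alphabet, repeat=n):
            counts[gram] = 0
    total = 0
    for rec in sset:
        data = rec.data
        for i in range(len(data) - n + 1):
            gram = tuple(data[i:i + n])
            counts[gram] = counts.get(gram, 0) + 1
            total += 1
    return NgramCountTable(n, counts, total, alphabet)


def ngram_profile(sset: SequenceSet, n: int, alphabet) -> tuple:
    """Dense per-sequence n-gram count matrix.

    Returns (identifiers, ngrams, matrix) where matrix[i][j] counts n-gram j
    in sequence i; columns enumerate the declared alphabet's n-grams in
    product order.  Memory grows as |set| × |alphabet|^n (capped).
    """
    alphabet = tuple(alphabet)
    if len(alphabet) ** n * max(len(sset), 1) > MAX_TABLE_CELLS:
        raise ValueError("profile matrix exceeds the cell cap")
    grams = list(itertools.product(alphabet, repeat=n))
    index = {g: j for j, g in enumerate(grams)}
    matrix = np.zeros((len(sset), len(grams)), dtype=int)
    for i, rec in enumerate(sset):
        for k in range(len(rec.data) - n + 1):
            gram = tuple(rec.data[k:k + n])
            if gram in index:
                matrix[i, index[gram]] += 1
    return sset.ids(), grams, matrix


def rank_frequency(table: NgramCountTable) -> list:
    """(rank, count) pairs, counts descending, ties in lexicographic order."""
    if not table.counts:
        raise ValueError("empty n-gram table")
    ordered = sorted(table.counts.items(),
                     key=lambda kv: (-kv[1], tuple(map(str, kv[0]))))
    return [(rank, count) for rank, (_, count) in enumerate(ordered, start=1)]


def write_counts(table: NgramCountTable, path, sep: str = "\t") -> None:
    """Two-column (n-gram, count) export, most frequent first."""
    ordered = sorted(table.counts.items(),
                     key=lambda kv: (-kv[1], tuple(map(str, kv[0]))))
    with open(path, "w") as handle:
        handle.write(f"ngram{sep}count\n")
        for gram, count in ordered:
            handle.write(f"{''.join(map(str, gram))}{sep}{count}\n")


# ---------------------------------------------------------------------------
# Discrete power-law (Zipf) fitting

@dataclass
class PowerLawFit:
    """Discrete power-law MLE for P(x) ∝ x^(-alpha), x >= xmin.

    ``ks_distance`` is the Kolmogorov–Smirnov distance between the empirical
    and fitted tail distributions at the chosen xmin; ``n_tail`` the number
    of observations in the fitted tail.
    """

    alpha: float
    xmin: int
    n_tail: int
    ks_distance: float
    log_likelihood: float = field(default=math.nan)


def powerlaw_loglikelihood(counts, alpha: float, xmin: int) -> float:
    """Log-likelihood of the tail (x >= xmin) under the discrete power law.

    L(alpha) = -n log zeta(alpha, xmin) - alpha * sum log x.
    """
    tail = np.asarray([x for x in counts if x >= xmin], dtype=float)
    if tail.size == 0:
        raise ValueError("no observations at or above xmin")
    return float(-tail.size * math.log(zeta(alpha, xmin))
                 - alpha * np.log(tail).sum())


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.unique(tail)
    ecdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    model = 1.0 - zeta(alpha, xs + 1) / zeta(alpha, xmin)
    return float(np.max(np.abs(ecdf - model)))


def _fit_fixed_xmin(tail: np.ndarray, xmin: int) -> tuple:
    n = tail.size
    sum_log = float(np.log(tail).sum())

    def nll(alpha: float) -> float:
        return n * math.log(zeta(alpha, xmin)) + alpha * sum_log

    res = minimize_scalar(nll, bounds=(1.0 + 1e-6, 25.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x), -float(res.fun)


def fit_powerlaw(counts, xmin="auto") -> PowerLawFit:
    """Fit P(x) ∝ x^(-alpha), x >= xmin, to positive integer observations.

    With ``xmin='auto'`` every distinct observed value is tried as xmin and
    the one minimizing the KS distance between the empirical and fitted tail
    distributions is kept (the standard Clauset-style selection); a fixed
    integer ``xmin`` skips the search, which makes fits reproducible when the
    tail is known to start at 1.

    Raises on degenerate input: fewer than two tail observations, or a tail
    with a single distinct value (the exponent is then unidentifiable).
    """
    data = np.asarray(list(counts), dtype=float)
    if data.size and data.min() < 1:
        raise ValueError("counts must be positive integers >= 1")

    def one(xm: int):
        tail = data[data >= xm]
        if tail.size < 2:
            raise ValueError(
                f"fewer than 2 observations at or above xmin={xm}")
        if np.unique(tail).size < 2:
            raise ValueError(
                f"degenerate fit: all tail values identical at xmin={xm}")
        alpha, ll = _fit_fixed_xmin(tail, xm)
        return PowerLawFit(alpha, int(xm), int(tail.size),
                           _ks_distance(tail, alpha, xm), ll)

    if xmin != "auto":
        return one(int(xmin))
    best = None
    for xm in np.unique(data).astype(int):
        try:
            fit = one(xm)
        except ValueError:
            continue
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise ValueError("no xmin admits a non-degenerate power-law fit")
    return best


def sample_powerlaw(alpha: float, xmin: int, size: int, rng) -> np.ndarray:
    """Draw from the discrete power law by exact inverse-CDF sampling.

    The CDF is precomputed on [xmin, 10^6]; the rare draws beyond that range
    (survival ~zeta tail) are resolved individually by bisection on the
    zeta-function survival, so the sampler is exact over the whole support.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    x_cap = 10 ** 6
    xs = np.arange(xmin, x_cap + 1, dtype=float)
    pmf = xs ** (-alpha) / zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    out = xmin + np.searchsorted(cdf, u, side="left")
    beyond = u >= cdf[-1]
    for i in np.nonzero(beyond)[0]:
        out[i] = _inverse_survival(float(u[i]), alpha, xmin, lo=x_cap)
    return out.astype(int)


def _inverse_survival(u: float, alpha: float, xmin: int, lo: int) -> int:
    """Smallest x with CDF(x) >= u, searching above ``lo`` via zeta tails."""
    z0 = zeta(alpha, xmin)
    hi = lo
    while 1.0 - zeta(alpha, hi + 1) / z0 < u:
        hi *= 2
        if hi > 10 ** 15:
            return hi
    while lo < hi:
        mid = (lo + hi) // 2
        if 1.0 - zeta(alpha, mid + 1) / z0 >= u:
            hi = mid
        else:
            lo = mid + 1
    return lo
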