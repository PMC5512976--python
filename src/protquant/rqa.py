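"""Recurrence quantification analysis of sequences.

A recurrence plot of a length-L sequence embedded in dimension m is the
boolean N×N matrix (N = L - m + 1) whose cell (i, j) is set when the embedded
tuples v_i = (x_i, ..., x_{i+m-1}) and v_j are within ``radius`` of each other
under the chosen metric.  From the plot three statistics are computed:

* recurrence rate (RR) — the fraction of off-diagonal cells that are
  recurrent; the main diagonal (line of identity) is excluded because every
  tuple trivially recurs with itself;
* determinism (DET) — the fraction of off-diagonal recurrence points that lie
  on diagonal lines of at least a minimum length; diagonal lines mark repeated
  subsequences;
* palindromism (PAL) — the fraction of recurrence points that lie on
  *antidiagonal* lines of at least a minimum length; antidiagonal lines mark
  reversed (palindromic) repeats.  Antidiagonals cross the line of identity,
  so main-diagonal cells participate in PAL by default and the statistic is
  normalized by all recurrence points (configurable).

Lines are closed cyclically: runs are counted on the N cyclic diagonal
classes j - i ≡ o (mod N) and antidiagonal classes i + j ≡ s (mod N), each of
which partitions the plot into lines of length N.  This removes the corner
artifact of open-line counting — with open lines a perfectly recurrent
(constant) sequence could never reach DET = 1 because the two corner cells
sit on lines of length 1 — so an all-true plot attains DET = PAL = 1 exactly,
and every cell belongs to exactly one line of each family (no double
counting).  The cyclic diagonal class o = 0 is precisely the line of
identity, which keeps the LOI exclusion of RR and DET clean.

Building the plot costs O(N² m); when several parameter sets share a
(metric, radius, dim) triple, :func:`rqa_features` builds the plot once and
re-uses it for every measure and run-length setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Number

import numpy as np

from .features import Feature

__all__ = [
    "METRICS",
    "RQAConfig",
    "RecurrencePlot",
    "RQAResult",
    "EmbeddingError",
    "embed",
    "recurrence_plot",
    "recurrence_rate",
    "determinism",
    "palindromism",
    "rqa_measures",
    "rqa_features",
    "rqa_feature",
    "plot_to_text",
]

METRICS = ("identity", "taxi", "euclid", "sup")


class EmbeddingError(ValueError):
    """Embedding dimension exceeds the sequence length."""


@dataclass(frozen=True)
class RQAConfig:
    """Parameters of one RQA computation.

    metric : 'identity' (exact tuple equality, works on symbols), 'taxi'
        (L1), 'euclid' (L2) or 'sup' (L-infinity); the numeric metrics
        require numeric data.
    radius : similarity radius; with the identity metric only exact matches
        recur and the radius value is not used.
    dim : embedding dimension m >= 1.
    det_len / pal_len : minimum diagonal / antidiagonal run length (>= 2).
    """

    metric: str = "identity"
    radius: float = 0.0
    dim: int = 1
    det_len: int = 2
    pal_len: int = 2

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.det_len < 2 or self.pal_len < 2:
            raise ValueError("minimum run lengths must be >= 2")


@dataclass
class RecurrencePlot:
    """Boolean N×N recurrence structure; symmetric, main diagonal all true."""

    matrix: np.ndarray
    config: RQAConfig

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RQAResult:
    """RR/DET/PAL for one parameter set, all in [0, 1]."""

    recurrence: float
    determinism: float
    palindromism: float
    plot_size: int
    config: RQAConfig | None = None


def embed(data, m: int) -> list:
    """Overlapping m-tuples v_i = (x_i, ..., x_{i+m-1}), i = 0..L-m."""
    if m < 1:
        raise EmbeddingError("embedding dimension must be >= 1")
    if m > len(data):
        raise EmbeddingError(
            f"embedding dimension {m} exceeds sequence length {len(data)}")
    return [tuple(data[i:i + m]) for i in range(len(data) - m + 1)]


def recurrence_plot(data, cfg: RQAConfig) -> RecurrencePlot:
    """Build the recurrence plot of ``data`` under ``cfg``.

    Identity metric: cell (i, j) is set iff the embedded tuples are equal
    (symbols allowed).  Numeric metrics: iff the L1/L2/L-inf distance between
    tuples is <= radius.
    """
    tuples = embed(list(data), cfg.dim)
    n = len(tuples)
    if cfg.metric == "identity":
        codes: dict = {}
        ids = np.array([codes.setdefault(t, len(codes)) for t in tuples])
        cells = ids[:, None] == ids[None, :]
    else:
        if not all(isinstance(x, Number) and not isinstance(x, bool)
                   for t in tuples for x in t):
            raise TypeError(
                f"metric {cfg.metric!r} requires numeric data; "
                "convert symbols through a mapping first")
        emb = np.array(tuples, dtype=float)
        diff = emb[:, None, :] - emb[None, :, :]
        if cfg.metric == "taxi":
            dist = np.abs(diff).sum(axis=2)
        elif cfg.metric == "euclid":
            dist = np.sqrt((diff ** 2).sum(axis=2))
        else:  # sup
            dist = np.abs(diff).max(axis=2)
        cells = dist <= cfg.radius
    return RecurrencePlot(cells, cfg)


def _check_size(plot: RecurrencePlot) -> int:
    n = plot.size
    if n < 2:
        raise ValueError(
            f"RQA measures are undefined for plot size {n} (< 2)")
    return n


def recurrence_rate(plot: RecurrencePlot) -> float:
    """Fraction of off-diagonal cells that are recurrent: RR in [0, 1]."""
    n = _check_size(plot)
    off_true = int(plot.matrix.sum()) - n
    return off_true / (n * n - n)


def _run_mask(line: np.ndarray, min_len: int) -> np.ndarray:
    """Boolean mask of cells inside maximal True runs of length >= min_len."""
    mask = np.zeros(len(line), dtype=bool)
    run_start = None
    for i, v in enumerate(list(line) + [False]):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if i - run_start >= min_len:
                mask[run_start:i] = True
            run_start = None
    return mask


def _cyclic_run_mask(line: np.ndarray, min_len: int) -> np.ndarray:
    """Run mask on a cyclically closed line (wrap-around runs allowed)."""
    n = line.size
    if line.all():
        return np.ones(n, dtype=bool) if n >= min_len \
            else np.zeros(n, dtype=bool)
    start = int(np.argmin(line))  # a False cell; scan linearly from there
    return np.roll(_run_mask(np.roll(line, -start), min_len), start)


def determinism(plot: RecurrencePlot, min_len: int | None = None) -> float:
    """Fraction of off-diagonal recurrence points on diagonal lines.

    A diagonal line is a maximal run of consecutive recurrent cells along
    direction (+1, +1) within one cyclic diagonal class j - i ≡ o (mod N),
    o = 1..N-1 (o = 0 is the excluded line of identity).  Returns 0 when
    there are no off-diagonal recurrence points.
    """
    n = _check_size(plot)
    if min_len is None:
        min_len = plot.config.det_len
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    denom = int(plot.matrix.sum()) - n
    if denom == 0:
        return 0.0
    idx = np.arange(n)
    in_lines = 0
    for o in range(1, n):
        line = plot.matrix[idx, (idx + o) % n]
        in_lines += int(_cyclic_run_mask(line, min_len).sum())
    return in_lines / denom


def palindromism(plot: RecurrencePlot, min_len: int | None = None,
                 normalize: str = "all") -> float:
    """Fraction of recurrence points on antidiagonal lines.

    An antidiagonal line is a maximal run of consecutive recurrent cells
    along direction (+1, -1) within one cyclic antidiagonal class
    i + j ≡ s (mod N).  Antidiagonals cross the line of identity, so
    main-diagonal cells take part in runs.  With ``normalize='all'``
    (default) the count is divided by all recurrent cells including the main
    diagonal; ``normalize='off_diagonal'`` excludes main-diagonal cells from
    both numerator and denominator.
    """
    n = _check_size(plot)
    if min_len is None:
        min_len = plot.config.pal_len
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if normalize not in ("all", "off_diagonal"):
        raise ValueError("normalize must be 'all' or 'off_diagonal'")
    matrix = plot.matrix
    if normalize == "off_diagonal":
        denom = int(matrix.sum()) - n
    else:
        denom = int(matrix.sum())
    if denom == 0:
        return 0.0
    idx = np.arange(n)
    in_lines = 0
    for s in range(n):
        cols = (s - idx) % n
        mask = _cyclic_run_mask(matrix[idx, cols], min_len)
        if normalize == "off_diagonal":
            mask = mask & (idx != cols)
        in_lines += int(mask.sum())
    return in_lines / denom


def rqa_measures(data, cfg: RQAConfig) -> RQAResult:
    """RR, DET and PAL of one sequence under one configuration."""
    plot = recurrence_plot(data, cfg)
    return RQAResult(recurrence_rate(plot),
                     determinism(plot, cfg.det_len),
                     palindromism(plot, cfg.pal_len),
                     plot.size, cfg)


def rqa_features(data, cfgs) -> list:
    """Evaluate several configurations, sharing recurrence plots.

    Configurations are grouped by (metric, radius, dim); each group's plot is
    built once and re-used across det_len/pal_len settings.  Results equal
    independent evaluation, in input order.
    """
    plots: dict = {}
    results = []
    for cfg in cfgs:
        key = (cfg.metric, cfg.radius, cfg.dim)
        if key not in plots:
            plots[key] = recurrence_plot(data, cfg)
        plot = plots[key]
        results.append(RQAResult(recurrence_rate(plot),
                                 determinism(plot, cfg.det_len),
                                 palindromism(plot, cfg.pal_len),
                                 plot.size, cfg))
    return results


_MEASURES = {
    "recurrence": lambda data, cfg: rqa_measures(data, cfg).recurrence,
    "determinism": lambda data, cfg: rqa_measures(data, cfg).determinism,
    "palindromism": lambda data, cfg: rqa_measures(data, cfg).palindromism,
}


def rqa_feature(cfg: RQAConfig, measure: str, window: int = 0) -> Feature:
    """Wrap one RQA measure as a chainable :class:`~protquant.features.Feature`.

    With ``window=w > 0`` the measure is computed on every length-w stretch,
    producing an RQA profile.
    """
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {sorted(_MEASURES)}")
    fn = _MEASURES[measure]
    return Feature(lambda data: fn(data, cfg),
                   name=f"{measure}_{cfg.metric}_r{cfg.radius}_m{cfg.dim}",
                   window=window)


def plot_to_text(plot: RecurrencePlot) -> str:
    """Dense 0/1 text rendering of the recurrence plot, one row per line."""
    return "\n".join("".join("1" if v else "0" for v in row)
                     for row in plot.matrix)
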