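"""Chainable sequence features: single values and sliding-window profiles.

A :class:`Feature` wraps any function over a list of elements.  With
``window=0`` the function is applied once to the whole sequence; with
``window=w > 0`` it is applied to every contiguous stretch of length ``w``
(step 1, 0-based half-open), yielding a profile of length ``L - w + 1``.
Features chain with :meth:`Feature.then`, so a typical pipeline — map residues
to hydropathy, then average over a window — is a single object.  A
:class:`FeatureSet` applies an ordered list of features to every record of a
:class:`~protquant.seqio.SequenceSet`.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

import numpy as np

from .mapping import PropertyMapping, apply_mapping
from .seqio import SequenceRecord, SequenceSet

__all__ = [
    "Feature",
    "FeatureSet",
    "EmptyDataError",
    "sum_feature",
    "mean_feature",
    "net_abs_feature",
    "entropy_feature",
    "uversky_boundary",
    "UVERSKY_SLOPE",
    "UVERSKY_INTERCEPT",
]


class EmptyDataError(ValueError):
    """A quantification was asked of an empty sequence."""


class Feature:
    """A named, windowable, chainable transformation of sequence data.

    Parameters
    ----------
    function : callable or PropertyMapping
        Maps a list of elements to a value or a list.  A
        :class:`PropertyMapping` is applied element-wise.
    name : str, optional
        Defaults to the function's ``__name__`` or the mapping's name.
    window : int
        0 applies ``function`` to the full data; ``w > 0`` applies it to each
        of the ``L - w + 1`` full windows (each result must then be scalar).
    """

    def __init__(self, function, name: str | None = None, window: int = 0):
        if window < 0:
            raise ValueError("window must be >= 0")
        if isinstance(function, PropertyMapping):
            mapping = function
            function = lambda data: [mapping[x] for x in data]  # noqa: E731
            name = name or mapping.name
        self._stages = [(function, name or getattr(function, "__name__", "f"),
                         window)]

    @property
    def name(self) -> str:
        return ">".join(n for _, n, _ in self._stages)

    def then(self, other: "Feature") -> "Feature":
        """Compose: apply ``self`` first, then ``other`` to the result.

        Stages are flattened, so chaining is associative by construction.
        """
        out = object.__new__(Feature)
        out._stages = self._stages + other._stages
        return out

    def __call__(self, rec: SequenceRecord, strict: bool = True) -> SequenceRecord:
        """Evaluate on a record, returning a new record.

        A window longer than the data yields an empty profile with a warning
        in lenient mode (``strict=False``) and raises otherwise.  The output
        feature_name is the input's name extended with the feature's name.
        """
        data = list(rec.data)
        for function, _, window in self._stages:
            if window == 0:
                value = function(data)
                data = list(value) if isinstance(
                    value, (list, tuple, np.ndarray)) else [value]
            else:
                if window > len(data):
                    msg = (f"window {window} exceeds length {len(data)} of "
                           f"record {rec.identifier!r}")
                    if strict:
                        raise ValueError(msg)
                    warnings.warn(msg + "; empty profile", stacklevel=2)
                    data = []
                else:
                    data = [_as_scalar(function(data[i:i + window]))
                            for i in range(len(data) - window + 1)]
        return SequenceRecord(rec.identifier, f"{rec.feature_name}>{self.name}",
                              data, rec.description)


def _as_scalar(value):
    if isinstance(value, (list, tuple, np.ndarray)):
        if len(value) != 1:
            raise ValueError("windowed features must produce scalar values")
        return value[0]
    return value


class FeatureSet:
    """An ordered collection of features evaluated over a sequence set."""

    def __init__(self, name: str = "", *features: Feature):
        self.name = name
        self.features: list[Feature] = list(features)

    def add(self, feature, name: str | None = None,
            window: int = 0) -> "FeatureSet":
        """Register a feature (or wrap a bare callable/mapping); chainable."""
        if not isinstance(feature, Feature):
            feature = Feature(feature, name=name, window=window)
        self.features.append(feature)
        return self

    def __len__(self) -> int:
        return len(self.features)

    def __call__(self, sset: SequenceSet, strict: bool = True) -> SequenceSet:
        """Evaluate every feature on every record.

        The result holds ``len(features) * len(sset)`` records grouped by
        feature (registration order) then record (input order).  In lenient
        mode an inapplicable feature/record pair is skipped with a warning.
        """
        out = SequenceSet(self.name or sset.name)
        for feature in self.features:
            for rec in sset:
                try:
                    out.add(feature(rec, strict=strict))
                except Exception as exc:
                    if strict:
                        raise type(exc)(
                            f"feature {feature.name!r} failed on record "
                            f"{rec.identifier!r}: {exc}") from exc
                    warnings.warn(
                        f"skipping {feature.name!r} on {rec.identifier!r}: "
                        f"{exc}", stacklevel=2)
        return out

    def matrix(self, sset: SequenceSet, strict: bool = True) -> dict:
        """Per feature, the vector of scalar results across records."""
        result = self(sset, strict=strict)
        per_feature = len(sset)
        out: dict = {}
        for k, feature in enumerate(self.features):
            block = result.records[k * per_feature:(k + 1) * per_feature]
            vals = []
            for rec in block:
                if len(rec) != 1:
                    raise ValueError(
                        f"feature {feature.name!r} is not scalar on record "
                        f"{rec.identifier!r} (length {len(rec)})")
                vals.append(rec.data[0])
            out[feature.name] = vals
        return out


# ---------------------------------------------------------------------------
# Basic quantification metrics

def sum_feature(data) -> float:
    """Sum of the values."""
    _require_nonempty(data)
    return float(np.sum(np.asarray(data, dtype=float)))


def mean_feature(data) -> float:
    """Arithmetic mean of the values."""
    _require_nonempty(data)
    return float(np.mean(np.asarray(data, dtype=float)))


def net_abs_feature(data) -> float:
    """Net absolute value per position: |mean of signed values|.

    Applied to a formal-charge conversion this is the mean net absolute
    charge of the charge–hydropathy (Uversky) analysis: charges are summed
    with sign first, then averaged and the absolute value taken.
    """
    _require_nonempty(data)
    return float(abs(np.mean(np.asarray(data, dtype=float))))


def entropy_feature(data, base: float = 2.0) -> float:
    """Shannon entropy of the empirical element-frequency distribution.

    ``0 * log 0`` is taken as 0; equal frequencies of k distinct elements
    give ``log_base k``.
    """
    _require_nonempty(data)
    counts = np.array(list(Counter(data).values()), dtype=float)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)) / math.log(base))


def _require_nonempty(data) -> None:
    if len(data) == 0:
        raise EmptyDataError("quantification of an empty sequence")


# ---------------------------------------------------------------------------
# Charge–hydropathy boundary (used by the Uversky-plot demo)

#: Boundary line <H>_b = (<R> + intercept) / slope on the normalized
#: Kyte–Doolittle scale (x + 4.5) / 9; constants from the charge–hydropathy
#: literature on intrinsic disorder, configurable at call time.
UVERSKY_SLOPE = 2.785
UVERSKY_INTERCEPT = 1.151


def uversky_boundary(net_abs_charge: float, slope: float = UVERSKY_SLOPE,
                     intercept: float = UVERSKY_INTERCEPT) -> float:
    """Mean normalized hydropathy on the order/disorder boundary at ⟨R⟩.

    Sequences with mean normalized hydropathy above the returned value are
    expected on the ordered (folded) side, below it on the intrinsically
    disordered side.
    """
    return (net_abs_charge + intercept) / slope
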