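"""Core in-memory containers for connectome data.

All adjacency-like containers hold dense symmetric ``numpy`` arrays with a
zero diagonal, indexed consistently by a shared list of node labels.  The
structural side carries raw streamline counts plus surface-area-normalized
weights; the functional side carries nonnegative Pearson correlations
(negative correlations are zeroed at construction time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GROUPS = ("NC", "MCI", "AD")
SCORE_NAMES = ("CDR", "FAQ", "MMSE", "MoCA", "GDS")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def _as_square(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {a.shape}")
    return a


def check_symmetric_zero_diag(a: np.ndarray, name: str, atol: float = 1e-10) -> None:
    a = _as_square(a, name)
    bad = np.argwhere(~np.isclose(a, a.T, atol=atol))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(f"{name} is not symmetric (first offending pair: ({i}, {j}))")
    if not np.allclose(np.diagonal(a), 0, atol=atol):
        raise ValidationError(f"{name} must have a zero diagonal")


def default_labels(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"node_{i:0{width}d}" for i in range(n)]


@dataclass
class StreamlineCountMatrix:
    """Raw symmetric streamline (fiber) counts plus per-region surface areas.

    Parameters
    ----------
    counts
        N x N nonnegative integer matrix of streamline counts, symmetric,
        zero diagonal.
    surface_areas
        Length-N positive region surface areas in mm^2.
    labels
        Region labels; generated if omitted.
    """

    counts: np.ndarray
    surface_areas: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.surface_areas = np.asarray(self.surface_areas, dtype=float)
        check_symmetric_zero_diag(self.counts, "counts")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(f"negative streamline count at ({i}, {j})")
        n = self.counts.shape[0]
        if self.surface_areas.shape != (n,):
            raise ValidationError(
                f"surface_areas must have length {n}, got {self.surface_areas.shape}"
            )
        if np.any(self.surface_areas <= 0):
            raise ValidationError("all surface areas must be positive")
        if self.labels is None:
            self.labels = default_labels(n)
        elif len(self.labels) != n:
            raise ValidationError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class StructuralNetwork:
    """Weighted + binary structural adjacency.

    ``binary[i, j] == 1`` iff ``weights[i, j] > 0``; weights are streamline
    counts divided by the summed surface areas of the two regions.
    """

    weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        check_symmetric_zero_diag(self.weights, "weights")
        if np.any(self.weights < 0):
            raise ValidationError("structural weights must be nonnegative")
        if self.labels is None:
            self.labels = default_labels(self.weights.shape[0])
        elif len(self.labels) != self.weights.shape[0]:
            raise ValidationError("label count does not match matrix size")

    @property
    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.binary.sum()) // 2


@dataclass
class FunctionalNetwork:
    """Functional adjacency: Pearson correlations with negatives zeroed."""

    weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        check_symmetric_zero_diag(self.weights, "weights")
        if np.any(self.weights < 0):
            raise ValidationError("functional weights must be nonnegative")
        if np.any(self.weights > 1 + 1e-12):
            raise ValidationError("functional weights must be <= 1")
        if self.labels is None:
            self.labels = default_labels(self.weights.shape[0])
        elif len(self.labels) != self.weights.shape[0]:
            raise ValidationError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class RoiTimeSeries:
    """Regional BOLD time series: one row per region, T time points."""

    series: np.ndarray
    sampling_interval: float = 3.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValidationError("series must be a 2-D (regions x time) array")
        if self.series.shape[1] < 3:
            raise ValidationError("need at least 3 time points per region")
        if self.labels is None:
            self.labels = default_labels(self.series.shape[0])
        elif len(self.labels) != self.series.shape[0]:
            raise ValidationError("label count does not match series rows")

    def zero_variance_regions(self) -> list[str]:
        sd = self.series.std(axis=1)
        return [lab for lab, s in zip(self.labels, sd) if s == 0]


@dataclass
class SubjectRecord:
    """One subject: paired networks plus covariates and clinical scores."""

    subject_id: str
    group: str
    sc_counts: StreamlineCountMatrix | None
    sc: StructuralNetwork
    fc: FunctionalNetwork
    age: float
    sex: str
    education: float
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.sc.n_nodes != self.fc.n_nodes:
            raise ValidationError(
                f"subject {self.subject_id}: SC has {self.sc.n_nodes} nodes, "
                f"FC has {self.fc.n_nodes}"
            )

    @property
    def n_nodes(self) -> int:
        return self.sc.n_nodes


@dataclass
class CohortTable:
    """An ordered collection of subjects sharing one parcellation."""

    subjects: list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        sizes = {s.n_nodes for s in self.subjects}
        if len(sizes) > 1:
            raise ValidationError(f"subjects disagree on node count: {sorted(sizes)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def labels(self) -> Sequence[str]:
        return self.subjects[0].sc.labels

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]
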