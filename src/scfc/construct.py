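"""Network construction from streamline counts and regional time series.

A structural edge requires a minimum streamline count (default 3); its
weight is the count divided by the summed surface areas of the two regions.
Functional edges are Pearson correlations of regional BOLD series with
negative values set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    FunctionalNetwork,
    RoiTimeSeries,
    StreamlineCountMatrix,
    StructuralNetwork,
    ValidationError,
)

DEFAULT_MIN_STREAMLINES = 3


def sc_from_streamlines(
    m: StreamlineCountMatrix, min_count: int = DEFAULT_MIN_STREAMLINES
) -> StructuralNetwork:
    """Build a structural network from raw streamline counts.

    An edge is present iff ``counts[i, j] >= min_count``; its weight is
    ``counts[i, j] / (area_i + area_j)``.  The binary adjacency follows
    directly from positive weights.
    """
    counts = m.counts
    areas = m.surface_areas
    denom = areas[:, None] + areas[None, :]
    weights = np.where(counts >= min_count, counts / denom, 0.0)
    np.fill_diagonal(weights, 0.0)
    return StructuralNetwork(weights=weights, labels=list(m.labels))


def fc_from_timeseries(ts: RoiTimeSeries) -> FunctionalNetwork:
    """Pearson-correlation functional network with negatives zeroed."""
    flat = ts.zero_variance_regions()
    if flat:
        raise ValidationError(f"zero-variance time series for regions: {flat}")
    r = np.corrcoef(ts.series)
    np.fill_diagonal(r, 0.0)
    weights = np.clip(r, 0.0, 1.0)
    weights = (weights + weights.T) / 2  # guard against float asymmetry
    return FunctionalNetwork(weights=weights, labels=list(ts.labels))


@dataclass
class PairReport:
    """Machine-readable result of structural/functional pair validation."""

    passed: bool
    failures: list[dict] = field(default_factory=list)

    def add(self, code: str, message: str, **detail) -> None:
        self.passed = False
        self.failures.append({"code": code, "message": message, **detail})


def _weights_and_labels(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, np.ndarray):
        from .containers import default_labels

        return np.asarray(x, dtype=float), default_labels(x.shape[0])
    return np.asarray(x.weights, dtype=float), list(x.labels)


@dataclass
class _RawNet:
    weights: np.ndarray
    labels: list[str]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_pair(sc, fc) -> PairReport:
    """Check that a SC/FC pair is mutually consistent and each side valid.

    Accepts validated network containers or raw square arrays (so that
    files loaded from disk can be screened before strict construction).
    """
    sc = _RawNet(*_weights_and_labels(sc))
    fc = _RawNet(*_weights_and_labels(fc))
    report = PairReport(passed=True)
    if sc.n_nodes != fc.n_nodes:
        report.add(
            "shape_mismatch",
            f"SC has {sc.n_nodes} nodes but FC has {fc.n_nodes}",
            sc_nodes=sc.n_nodes,
            fc_nodes=fc.n_nodes,
        )
        return report
    if list(sc.labels) != list(fc.labels):
        if sorted(sc.labels) == sorted(fc.labels):
            perm = [fc.labels.index(lab) for lab in sc.labels]
            report.add(
                "label_permutation",
                "labels match as sets but not in order",
                permutation=perm,
            )
        else:
            report.add("label_mismatch", "SC and FC label sets differ")
    for name, w in (("SC", sc.weights), ("FC", fc.weights)):
        if not np.allclose(w, w.T):
            report.add("asymmetric", f"{name} matrix is not symmetric", matrix=name)
        if not np.allclose(np.diagonal(w), 0):
            report.add("nonzero_diagonal", f"{name} diagonal is not zero", matrix=name)
    if np.any(fc.weights < 0):
        report.add("negative_fc", "FC contains negative entries")
    if np.any(fc.weights > 1 + 1e-12):
        report.add("fc_above_one", "FC contains entries above 1")
    if np.any(sc.weights < 0):
        report.add("negative_sc", "SC contains negative weights")
    return report
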