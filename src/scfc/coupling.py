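"""Per-subject structure-function coupling.

For each subject, the weights of structurally connected region pairs are
rank-transformed to a Gaussian shape (Blom inverse-normal scores) and
Pearson-correlated with the corresponding functional weights, restricted to
pairs where both SC and FC are strictly positive.  The correlation can be
computed over all qualifying edges or restricted to one edge class
(rich-club / feeder / local), yielding one coupling value per subject per
scope — never a pooled correlation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortTable, FunctionalNetwork, StructuralNetwork
from .richclub import CLASSES, HubSet, edge_class_matrix

SCOPES = ("all",) + CLASSES
DEFAULT_MIN_EDGES = 10
_CLASS_CODE = {"rich_club": 1, "feeder": 2, "local": 3}


def gaussianize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps value ranks r (average ranks for ties) to standard-normal
    quantiles at (r - 3/8) / (n + 1/4).  Strictly monotone in the input;
    errors when all values are tied, since ranks carry no information then.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values to gaussianize")
    if np.all(values == values[0]):
        raise ValueError("all values identical; rank transform is degenerate")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 1.0 / 4.0))


@dataclass
class CouplingResult:
    """One subject's SC-FC coupling in one scope."""

    subject_id: str
    scope: str
    r: float
    n_edges: int
    status: str = "ok"  # "ok" | "too_few_edges" | "degenerate"
    transform: str = "blom_inverse_normal"


def _scope_mask(
    sc: StructuralNetwork, fc: FunctionalNetwork, scope: str, hubs: HubSet | None
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index arrays of pairs in the scope with SC>0 and FC>0."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    pos = (sc.weights > 0) & (fc.weights > 0)
    if scope != "all":
        if hubs is None:
            raise ValueError(f"scope {scope!r} requires a hub set")
        codes = edge_class_matrix(sc, hubs)
        pos &= codes == _CLASS_CODE[scope]
    iu, ju = np.triu_indices(sc.n_nodes, k=1)
    keep = pos[iu, ju]
    return iu[keep], ju[keep]


def sc_fc_coupling(
    sc: StructuralNetwork,
    fc: FunctionalNetwork,
    scope: str = "all",
    hubs: HubSet | None = None,
    min_edges: int = DEFAULT_MIN_EDGES,
    subject_id: str = "",
) -> CouplingResult:
    """Correlate Gaussianized SC weights with raw FC weights on one scope.

    Raises ``ValueError`` when the qualifying edge mask is smaller than
    ``min_edges`` (use :func:`cohort_coupling` for tolerant batch runs).
    """
    ii, jj = _scope_mask(sc, fc, scope, hubs)
    n = len(ii)
    if n < min_edges:
        raise ValueError(
            f"scope {scope!r}: only {n} edges with nonzero SC and FC "
            f"(minimum {min_edges})"
        )
    x = gaussianize(sc.weights[ii, jj])
    y = fc.weights[ii, jj]
    if np.std(y) == 0 or np.std(x) == 0:
        return CouplingResult(subject_id, scope, float("nan"), n, status="degenerate")
    r = float(stats.pearsonr(x, y).statistic)
    return CouplingResult(subject_id, scope, r, n)


def cohort_coupling(
    cohort: CohortTable,
    hubs: HubSet,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> pd.DataFrame:
    """Coupling for every subject in all four scopes, as a tidy table.

    Subjects whose mask in a scope is too small get a row with an explicit
    ``too_few_edges`` status and ``r = NaN`` rather than being dropped.
    """
    rows = []
    for s in cohort:
        for scope in SCOPES:
            try:
                res = sc_fc_coupling(
                    s.sc, s.fc, scope=scope, hubs=hubs,
                    min_edges=min_edges, subject_id=s.subject_id,
                )
            except ValueError:
                ii, jj = _scope_mask(s.sc, s.fc, scope, hubs)
                res = CouplingResult(
                    s.subject_id, scope, float("nan"), len(ii), status="too_few_edges"
                )
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "group": s.group,
                    "scope": res.scope,
                    "r": res.r,
                    "n_edges": res.n_edges,
                    "status": res.status,
                }
            )
    return pd.DataFrame(rows)
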