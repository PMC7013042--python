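"""Group statistics: ANCOVA, partial Pearson correlations, chi-square.

Group comparisons of network measures use ANCOVA — a linear model of the
outcome on group indicators plus age, sex, and education — with the group
factor tested by a Type-II F test and pairwise contrasts Bonferroni-adjusted
over the three group pairs.  Associations between continuous measures
(densities, coupling, clinical scores) use partial Pearson correlations:
the correlation of the two variables' residuals after regressing each on
the covariates.  Sex distributions are compared with a Pearson chi-square
test without continuity correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AncovaResult",
    "PartialCorrResult",
    "ancova",
    "partial_pearson",
    "chi_square_sex",
    "curve_groups_test",
    "encode_covariates",
]


def encode_covariates(covariates: pd.DataFrame | Mapping | None, n: int) -> pd.DataFrame:
    """Numeric covariate design block; 'sex' strings become a female indicator."""
    if covariates is None:
        return pd.DataFrame(index=range(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != n:
        raise ValueError(f"covariates have {len(cov)} rows, expected {n}")
    out = {}
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or str(s.dtype) == "category":
            levels = sorted(s.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {col!r} has >2 categorical levels")
            out[col] = (s == levels[-1]).astype(float)
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out)


@dataclass
class AncovaResult:
    outcome_name: str
    F: float
    p: float
    df: tuple[int, int]
    n: int
    adjusted_group_means: dict[str, float]
    pairwise: list[dict] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)


def _design(groups: Sequence[str], cov: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(set(groups))
    g = pd.Series(list(groups))
    cols = [np.ones(len(g))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((g == lev).to_numpy(float))
        names.append(f"group[{lev}]")
    for c in cov.columns:
        cols.append(cov[c].to_numpy(float))
        names.append(str(c))
    return np.column_stack(cols), names, levels


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit; returns (beta, residual sum of squares, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid), rank


def ancova(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: pd.DataFrame | Mapping | None = None,
    outcome_name: str = "outcome",
) -> AncovaResult:
    """Covariate-adjusted group comparison of a continuous outcome.

    Fits ``outcome ~ group + covariates`` and tests the group factor by
    comparing against the covariate-only model (Type-II sum of squares;
    with no interactions this equals the Type-III test).  Adjusted group
    means are model predictions at the covariate means, and pairwise group
    contrasts carry Bonferroni-adjusted p-values (m = number of pairs).
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    cov = encode_covariates(covariates, n)
    levels = sorted(set(group))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(list(group)).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 subjects: {small}")

    x_full, names, levels = _design(group, cov)
    p_full = x_full.shape[1]
    if np.linalg.matrix_rank(x_full) < p_full:
        raise ValueError(f"rank-deficient design; columns: {names}")
    beta, rss_full, _ = _ols(x_full, y)
    df_resid = n - p_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("zero residual variance; F test undefined")

    x_red = np.column_stack(
        [np.ones(n)] + [cov[c].to_numpy(float) for c in cov.columns]
    )
    _, rss_red, _ = _ols(x_red, y)
    df_group = len(levels) - 1
    f_stat = ((rss_red - rss_full) / df_group) / (rss_full / df_resid)
    p_val = float(sps.f.sf(f_stat, df_group, df_resid))

    # adjusted means: predict each group at the covariate means
    cov_means = cov.mean().to_numpy(float) if len(cov.columns) else np.array([])
    adj = {}
    for lev in levels:
        row = [1.0] + [1.0 if f"group[{l}]" == f"group[{lev}]" else 0.0 for l in levels[1:]]
        row += list(cov_means)
        adj[lev] = float(np.asarray(row) @ beta)

    # pairwise contrasts on the group coefficients
    sigma2 = rss_full / df_resid
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        c = np.zeros(p_full)
        for lev, sign in ((a, 1.0), (b, -1.0)):
            if lev != levels[0]:
                c[names.index(f"group[{lev}]")] = sign
        est = float(c @ beta)
        se = float(np.sqrt(sigma2 * c @ xtx_inv @ c))
        t = est / se
        p_raw = float(2 * sps.t.sf(abs(t), df_resid))
        pairwise.append(
            {
                "contrast": f"{a}-{b}",
                "estimate": est,
                "se": se,
                "t": float(t),
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m * p_raw),
                "m": m,
            }
        )

    return AncovaResult(
        outcome_name=outcome_name,
        F=float(f_stat),
        p=p_val,
        df=(df_group, df_resid),
        n=n,
        adjusted_group_means=adj,
        pairwise=pairwise,
        covariates=[str(c) for c in cov.columns],
    )


@dataclass
class PartialCorrResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int
    covariates: list[str]


def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | Mapping | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> PartialCorrResult:
    """Pearson correlation of x and y after removing linear covariate effects.

    Residualizes both variables on an intercept plus the covariates; p is
    from the t transform with n - k - 2 degrees of freedom (k covariates).
    With no covariates this equals the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = encode_covariates(covariates, n)
    k = len(cov.columns)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    z = np.column_stack([np.ones(n)] + [cov[c].to_numpy(float) for c in cov.columns])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if np.std(rx) < 1e-12 * max(1.0, np.abs(x).max()) or np.std(ry) < 1e-12 * max(
        1.0, np.abs(y).max()
    ):
        raise ValueError("a variable is constant after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(x_name, y_name, r, p, n, [str(c) for c in cov.columns])


def chi_square_sex(groups: Sequence[str], sexes: Sequence[str]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the group x sex table."""
    table = pd.crosstab(pd.Series(list(groups)), pd.Series(list(sexes)))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "contingency table has an empty row or column "
            "(need at least 2 groups and 2 sex levels with observations)"
        )
    res = sps.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), float(res.pvalue)


def curve_groups_test(
    curves: Mapping[str, "object"],
    groups: Mapping[str, str],
    covariates: pd.DataFrame | None = None,
    value: str = "phi",
) -> pd.DataFrame:
    """Per-k ANCOVA over subjects' rich-club curves, Bonferroni over k.

    ``curves`` maps subject id to a RichClubCurve; all curves must share a
    k grid up to differing lengths (grids are aligned on k).  At each k,
    subjects with an undefined (NaN) value are dropped and the per-k n is
    recorded; k values with any group below 2 subjects are skipped.  The
    Bonferroni factor is the number of k values actually tested.
    """
    ids = list(curves)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        if len(covariates) != len(ids):
            raise ValueError("covariates must have one row per subject, in order")
    per_k: dict[int, list[tuple[str, float]]] = {}
    for sid in ids:
        c = curves[sid]
        vals = getattr(c, value) if value != "phi" else c.phi
        if vals is None:
            raise ValueError(f"curve for {sid} lacks {value!r}")
        for k, v in zip(c.k_values, vals):
            per_k.setdefault(int(k), []).append((sid, float(v)))

    rows = []
    for k in sorted(per_k):
        entries = [(sid, v) for sid, v in per_k[k] if np.isfinite(v)]
        sids = [sid for sid, _ in entries]
        if len(sids) < len(ids) and not entries:
            continue
        g = [groups[sid] for sid in sids]
        cnt = pd.Series(g).value_counts()
        if len(cnt) < 2 or (cnt < 2).any():
            continue
        cov_k = None
        if covariates is not None:
            idx = [ids.index(sid) for sid in sids]
            cov_k = covariates.iloc[idx]
        try:
            res = ancova([v for _, v in entries], g, cov_k, outcome_name=f"{value}@k={k}")
        except ValueError:
            continue
        rows.append(
            {
                "k": k,
                "value": value,
                "F": res.F,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "n": res.n,
            }
        )
    if not rows:
        raise ValueError("no k with enough defined values in every group")
    out = pd.DataFrame(rows)
    m = len(out)
    out["m_tests"] = m
    out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    return out
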