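"""End-to-end analysis pipeline: cohort -> metrics -> rich club -> coupling -> stats.

Each stage writes a tidy delimited table into the output directory, and a
run manifest records the configuration, seed, and package versions so a
run can be reproduced exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SCORE_NAMES, CohortTable
from .coupling import SCOPES, cohort_coupling
from .io import read_cohort, write_cohort
from .metrics import EfficiencySummary, normalized_rich_club
from .richclub import (
    CLASSES,
    cohort_classification,
    consensus_mean_degree,
    select_hubs,
)
from .stats import ancova, chi_square_sex, curve_groups_test, partial_pearson
from .synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger("scfc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` (a manifest of an existing cohort) or
    ``generator`` (a synthetic-cohort configuration) must be set.
    """

    output_dir: str = "scfc_output"
    cohort_path: str | None = None
    generator: GeneratorConfig | None = None
    hub_rule: dict = field(
        default_factory=lambda: {"mode": "degree_threshold", "k_threshold": 10.0}
    )
    n_nulls: int = 100
    swaps_per_edge: int = 10
    coupling_min_edges: int = 10
    seed: int = 0
    compute_curves: bool = True

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ValueError("set exactly one of cohort_path or generator")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        gen = data.pop("generator", None)
        cfg = cls(
            generator=GeneratorConfig.from_dict(gen) if gen is not None else None,
            **data,
        )
        return cfg


def _load_or_simulate(config: RunConfig) -> CohortTable:
    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen.seed = config.seed
        log.info("simulating cohort: %s subjects", sum(gen.group_sizes.values()))
        return generate_cohort(gen)
    log.info("loading cohort from %s", config.cohort_path)
    cohort, errors = read_cohort(config.cohort_path, on_error="collect")
    for e in errors:
        log.warning("skipped subject %(subject_id)s: %(error)s", e)
    return cohort


def covariate_frame(cohort: CohortTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [s.age for s in cohort],
            "sex": [s.sex for s in cohort],
            "education": [s.education for s in cohort],
        }
    )


def metrics_stage(cohort: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, nodal_rows = [], []
    for s in cohort:
        summ = EfficiencySummary.from_network(s.sc)
        for metric, value in (
            ("global_efficiency", summ.global_eff),
            ("local_efficiency", summ.local_eff),
            ("mean_degree", summ.mean_degree),
        ):
            rows.append({"subject_id": s.subject_id, "group": s.group,
                         "metric": metric, "value": value})
        for lab, eff in zip(s.sc.labels, summ.nodal_eff):
            nodal_rows.append({"subject_id": s.subject_id, "node_label": lab,
                               "nodal_eff": float(eff)})
    return pd.DataFrame(rows), pd.DataFrame(nodal_rows)


def curves_stage(cohort: CohortTable, config: RunConfig) -> tuple[dict, pd.DataFrame]:
    curves = {}
    rows = []
    rng = np.random.default_rng(config.seed)
    for s in cohort:
        curve = normalized_rich_club(
            s.sc, n_nulls=config.n_nulls,
            swaps_per_edge=config.swaps_per_edge, seed=rng,
        )
        curves[s.subject_id] = curve
        rows.extend(curve.as_records(s.subject_id))
    return curves, pd.DataFrame(rows)


def stats_stage(
    cohort: CohortTable,
    density_table: pd.DataFrame,
    metric_table: pd.DataFrame,
    coupling_table: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    cov = covariate_frame(cohort)
    groups = cohort.groups
    order = [s.subject_id for s in cohort]

    ancova_rows, pairwise_rows = [], []

    def run_ancova(name: str, values: pd.Series) -> None:
        vals = values.reindex(order)
        keep = np.isfinite(vals.to_numpy(float))
        try:
            res = ancova(
                vals.to_numpy(float)[keep],
                [g for g, k in zip(groups, keep) if k],
                cov[keep].reset_index(drop=True),
                outcome_name=name,
            )
        except ValueError as exc:
            log.warning("ANCOVA on %s skipped: %s", name, exc)
            return
        ancova_rows.append(
            {"outcome": name, "F": res.F, "df1": res.df[0], "df2": res.df[1],
             "p": res.p, "n": res.n,
             **{f"adj_mean_{g}": m for g, m in res.adjusted_group_means.items()}}
        )
        for pw in res.pairwise:
            pairwise_rows.append({"outcome": name, **pw})

    for cls in CLASSES:
        sub = density_table[density_table["class"] == cls]
        run_ancova(f"density_{cls}", sub.set_index("subject_id")["density"])
    for metric in metric_table["metric"].unique():
        sub = metric_table[metric_table["metric"] == metric]
        run_ancova(metric, sub.set_index("subject_id")["value"])
    for scope in SCOPES:
        sub = coupling_table[coupling_table["scope"] == scope]
        run_ancova(f"coupling_{scope}", sub.set_index("subject_id")["r"])

    stat, p = chi_square_sex(groups, [s.sex for s in cohort])
    sex_table = pd.DataFrame([{"test": "chi_square_sex", "statistic": stat, "p": p}])

    # score correlations within patients (MCI + AD pooled), covariate-adjusted
    patients = [s for s in cohort if s.group in ("MCI", "AD")]
    pc_rows = []
    if len(patients) >= 8:
        pidx = [order.index(s.subject_id) for s in patients]
        pcov = cov.iloc[pidx].reset_index(drop=True)
        measures: dict[str, pd.Series] = {}
        for cls in CLASSES:
            sub = density_table[density_table["class"] == cls].set_index("subject_id")
            measures[f"density_{cls}"] = sub["density"]
        for scope in SCOPES:
            sub = coupling_table[coupling_table["scope"] == scope].set_index("subject_id")
            measures[f"coupling_{scope}"] = sub["r"]
        pids = [s.subject_id for s in patients]
        for mname, series in measures.items():
            x = series.reindex(pids).to_numpy(float)
            for score in SCORE_NAMES:
                y = np.array([s.scores.get(score, np.nan) for s in patients])
                keep = np.isfinite(x) & np.isfinite(y)
                if keep.sum() <= 5:
                    continue
                try:
                    res = partial_pearson(
                        x[keep], y[keep], pcov[keep].reset_index(drop=True),
                        x_name=mname, y_name=score,
                    )
                except ValueError as exc:
                    log.warning("partial correlation %s~%s skipped: %s",
                                mname, score, exc)
                    continue
                pc_rows.append(
                    {"x": mname, "y": score, "r": res.r, "p": res.p, "n": res.n,
                     "covariates": ",".join(res.covariates)}
                )

    return {
        "ancova": pd.DataFrame(ancova_rows),
        "ancova_pairwise": pd.DataFrame(pairwise_rows),
        "sex_chi_square": sex_table,
        "partial_correlations": pd.DataFrame(pc_rows),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all tables under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_or_simulate(config)
    if config.generator is not None:
        write_cohort(cohort, out / "cohort")

    metric_table, nodal_table = metrics_stage(cohort)
    metric_table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    nodal_table.to_csv(out / "nodal_efficiency.tsv", sep="\t", index=False)

    mean_deg = consensus_mean_degree(cohort)
    mean_deg.rename_axis("node_label").to_csv(out / "mean_degrees.tsv", sep="\t")
    hubs = select_hubs(mean_deg, config.hub_rule)
    (out / "hubs.txt").write_text(
        f"# rule: {hubs.selection_rule}\n" + "\n".join(hubs.hub_labels) + "\n"
    )

    density_table = cohort_classification(cohort, hubs)
    density_table.to_csv(out / "edge_classes.tsv", sep="\t", index=False)

    coupling_table = cohort_coupling(cohort, hubs, min_edges=config.coupling_min_edges)
    coupling_table.to_csv(out / "coupling.tsv", sep="\t", index=False)

    if config.compute_curves:
        curves, curve_table = curves_stage(cohort, config)
        curve_table.to_csv(out / "richclub_curves.tsv", sep="\t", index=False)
        cov = covariate_frame(cohort)
        groups_map = {s.subject_id: s.group for s in cohort}
        for value in ("phi", "phi_norm"):
            try:
                tbl = curve_groups_test(curves, groups_map, cov, value=value)
            except ValueError as exc:
                log.warning("curve test on %s skipped: %s", value, exc)
                continue
            tbl.to_csv(out / f"curve_tests_{value}.tsv", sep="\t", index=False)

    tables = stats_stage(cohort, density_table, metric_table, coupling_table)
    for name, tbl in tables.items():
        tbl.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "scfc_version": __version__,
        "seed": config.seed,
        "hub_rule": config.hub_rule,
        "n_nulls": config.n_nulls,
        "swaps_per_edge": config.swaps_per_edge,
        "coupling_min_edges": config.coupling_min_edges,
        "n_subjects": len(cohort),
        "n_hubs": len(hubs),
        "generator": (config.generator.to_dict() if config.generator else None),
        "cohort_path": config.cohort_path,
    }
    with open(out / "run_manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    log.info("pipeline complete: %s", out)
    return out
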