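"""Delimited-text file formats for cohorts, matrices, and configuration.

Everything is plain text: square matrices as whitespace-delimited numeric
tables, node labels one per line, subject metadata as a tab-separated
table, and a YAML manifest tying a cohort directory together.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .construct import sc_from_streamlines
from .containers import (
    SCORE_NAMES,
    CohortTable,
    FunctionalNetwork,
    StreamlineCountMatrix,
    SubjectRecord,
    ValidationError,
)
from .synthetic import GeneratorConfig

MANIFEST_NAME = "manifest.yaml"


def write_matrix(path: str | os.PathLike, a: np.ndarray) -> None:
    a = np.asarray(a)
    fmt = "%d" if np.issubdtype(a.dtype, np.integer) else "%.10g"
    np.savetxt(path, a, fmt=fmt)


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    a = np.loadtxt(path)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{path}: expected a square matrix, got shape {a.shape}")
    return a


def write_labels(path: str | os.PathLike, labels) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def read_labels(path: str | os.PathLike) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def load_generator_config(path: str | os.PathLike) -> GeneratorConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return GeneratorConfig.from_dict(data)


def save_generator_config(config: GeneratorConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def write_cohort(cohort: CohortTable, outdir: str | os.PathLike) -> Path:
    """Write one matrix file per subject per modality plus metadata/manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_labels(outdir / "labels.txt", cohort.labels)
    meta_rows = []
    manifest_subjects = []
    for s in cohort:
        files = {}
        if s.sc_counts is not None:
            files["sc_counts"] = f"{s.subject_id}.sc_counts.txt"
            files["areas"] = f"{s.subject_id}.areas.txt"
            write_matrix(outdir / files["sc_counts"], s.sc_counts.counts)
            np.savetxt(outdir / files["areas"], s.sc_counts.surface_areas, fmt="%.10g")
        else:
            files["sc_weights"] = f"{s.subject_id}.sc_weights.txt"
            write_matrix(outdir / files["sc_weights"], s.sc.weights)
        files["fc"] = f"{s.subject_id}.fc.txt"
        write_matrix(outdir / files["fc"], s.fc.weights)
        manifest_subjects.append({"subject_id": s.subject_id, "group": s.group,
                                  "files": files})
        meta_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                **{k: s.scores.get(k, np.nan) for k in SCORE_NAMES},
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    manifest = {
        "n_nodes": len(cohort.labels),
        "labels": "labels.txt",
        "metadata": "metadata.tsv",
        "subjects": manifest_subjects,
        "provenance": _yaml_safe(cohort.provenance),
    }
    with open(outdir / MANIFEST_NAME, "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return outdir / MANIFEST_NAME


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_cohort(
    manifest_path: str | os.PathLike, on_error: str = "raise", min_count: int = 3
) -> tuple[CohortTable, list[dict]]:
    """Load a cohort from its manifest.

    Returns ``(cohort, errors)``.  With ``on_error="collect"``, subjects
    that fail validation are skipped and reported in ``errors`` (each entry
    names the subject and the offending file); with ``"raise"`` the first
    failure raises.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    root = manifest_path.parent
    with open(manifest_path) as f:
        manifest = yaml.safe_load(f)
    labels = read_labels(root / manifest["labels"])
    meta = pd.read_csv(root / manifest["metadata"], sep="\t").set_index("subject_id")

    subjects, errors = [], []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        try:
            files = entry["files"]
            if "sc_counts" in files:
                counts = read_matrix(root / files["sc_counts"])
                areas = np.loadtxt(root / files["areas"])
                m = StreamlineCountMatrix(
                    counts=counts.astype(np.int64), surface_areas=areas, labels=labels
                )
                sc = sc_from_streamlines(m, min_count=min_count)
            else:
                m = None
                from .containers import StructuralNetwork

                sc = StructuralNetwork(
                    weights=read_matrix(root / files["sc_weights"]), labels=labels
                )
            fc = FunctionalNetwork(weights=read_matrix(root / files["fc"]), labels=labels)
            row = meta.loc[sid]
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=entry["group"],
                    sc_counts=m,
                    sc=sc,
                    fc=fc,
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    education=float(row["education"]),
                    scores={k: float(row[k]) for k in SCORE_NAMES if k in row},
                )
            )
        except (ValidationError, ValueError, OSError, KeyError) as exc:
            if on_error == "raise":
                raise ValidationError(f"subject {sid}: {exc}") from exc
            errors.append({"subject_id": sid, "error": str(exc)})
    provenance = dict(manifest.get("provenance") or {})
    if errors:
        provenance["load_errors"] = errors
    return CohortTable(subjects=subjects, provenance=provenance), errors
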