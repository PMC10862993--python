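"""Delimited-text I/O for cohorts, feature matrices, and results.

All tabular files are headered UTF-8 CSV/TSV with '.' as the decimal mark:
phenotypes as CSV with a fixed column set, feature matrices as TSV with a
``subject_id`` index column, feature metadata as TSV, and truth/reports as
JSON. Timecourses are TSV with one row per timepoint and node labels as
the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cpmkit.cohort import SyntheticCohort
from cpmkit.connectome import FeatureMatrix, NodeTimecourses

__all__ = [
    "PHENOTYPE_COLUMNS",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_phenotypes",
    "read_phenotypes",
    "write_cohort",
    "read_cohort",
    "write_timecourses",
    "read_timecourses",
]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "outcome_baseline",
    "outcome_post",
    "age",
    "sex",
    "scanner",
    "fd_mean",
    "fd_pct_above",
]


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, sep="\t")
    if fm.feature_meta is not None:
        meta_path = Path(path).with_suffix(".meta.tsv")
        fm.feature_meta.to_csv(meta_path, sep="\t", index=False)


def read_feature_matrix(path: str | Path, feature_kind: str = "edge") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    meta_path = Path(path).with_suffix(".meta.tsv")
    meta = pd.read_csv(meta_path, sep="\t") if meta_path.exists() else None
    return FeatureMatrix(
        df.to_numpy(dtype=float), [str(s) for s in df.index], feature_kind, meta
    )


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in phenotypes.columns]
    phenotypes[cols].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(PHENOTYPE_COLUMNS) - {"scanner"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing required column(s): {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in phenotype file")
    return df


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort's feature TSVs, phenotype CSV, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "baseline": out / "features_baseline.tsv",
        "followup": out / "features_followup.tsv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    write_feature_matrix(cohort.baseline_features, paths["baseline"])
    write_feature_matrix(cohort.followup_features, paths["followup"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2) + "\n")
    return paths


def read_cohort(out_dir: str | Path, feature_kind: str = "edge") -> SyntheticCohort:
    out = Path(out_dir)
    truth = json.loads((out / "truth.json").read_text()) if (out / "truth.json").exists() else {}
    return SyntheticCohort(
        read_feature_matrix(out / "features_baseline.tsv", feature_kind),
        read_feature_matrix(out / "features_followup.tsv", feature_kind),
        read_phenotypes(out / "phenotypes.csv"),
        truth,
    )


def write_timecourses(tc: NodeTimecourses, path: str | Path) -> None:
    pd.DataFrame(tc.values, columns=tc.node_labels).to_csv(path, sep="\t", index=False)


def read_timecourses(
    path: str | Path, network_labels: list[str] | None = None
) -> NodeTimecourses:
    df = pd.read_csv(path, sep="\t")
    return NodeTimecourses(
        df.to_numpy(dtype=float), [str(c) for c in df.columns], network_labels
    )
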