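"""Data ingestion, expression pre-filtering, and run-report output.

Matrices are CSV/TSV with a header row of feature names and one row per
sample; the first column is the sample identifier.  Labels come in a second
file with matching identifiers, coded 0/1 or as two string levels (mapped to
0/1 by sorted order).  Rows are aligned by identifier join, so file order
does not matter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Dataset

logger = logging.getLogger(__name__)

__all__ = ["load_matrix", "load_dataset", "filter_genes", "save_report"]

REPORT_COLUMNS = ["subset", "members", "frequency", "error_rate", "amlp", "auroc", "auprc"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_matrix(path) -> pd.DataFrame:
    """Feature matrix as a DataFrame (samples x features, ID index)."""
    df = _read_table(path)
    if df.isna().any().any():
        cells = [f"{r}:{c}" for r, c in zip(*np.nonzero(df.isna().to_numpy()))]
        raise ValueError(f"matrix contains missing values at cells {cells[:20]}")
    return df


def load_dataset(matrix_path, labels_path, covariate_columns=None) -> Dataset:
    """Assemble a Dataset from a feature matrix file and a labels file.

    String labels are mapped to 0/1 by sorted order (e.g. "high" -> 0,
    "low" -> 1); ``covariate_columns`` names matrix columns moved to the end
    of the feature block so callers can address them as unpenalized columns.
    """
    mat = load_matrix(matrix_path)
    lab = _read_table(labels_path)
    if lab.shape[1] != 1:
        raise ValueError("labels file must have exactly one label column besides the ID")
    missing = set(mat.index) ^ set(lab.index)
    if missing:
        raise ValueError(f"sample IDs do not match between matrix and labels: {sorted(missing)[:10]}")
    lab = lab.loc[mat.index]
    raw = lab.iloc[:, 0]
    levels = sorted(raw.unique())
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    if set(levels) == {0, 1}:
        y = raw.to_numpy().astype(int)
    else:
        mapping = {levels[0]: 0, levels[1]: 1}
        logger.info("label mapping by sorted order: %s", mapping)
        y = raw.map(mapping).to_numpy()
    if covariate_columns:
        order = [c for c in mat.columns if c not in covariate_columns] + list(covariate_columns)
        mat = mat[order]
    X = np.column_stack([np.ones(mat.shape[0]), mat.to_numpy(dtype=float)])
    return Dataset(X=X, y=y, feature_names=list(mat.columns))


def filter_genes(matrix: pd.DataFrame, cv_min: float = 5.0, mean_min: float = 3.0,
                 exponentiate: bool = False) -> pd.DataFrame:
    """Univariate expression pre-filter: keep gene j if CV_j >= cv_min OR mean_j >= mean_min.

    CV = sd/mean, computed on the values as provided (set ``exponentiate`` to
    first map log2 values back to the raw scale for the CV criterion).  A
    zero-mean gene has undefined CV and is judged by the mean criterion only.
    """
    vals = matrix.to_numpy(dtype=float)
    cv_vals = np.exp2(vals) if exponentiate else vals
    mean_for_cv = cv_vals.mean(axis=0)
    sd = cv_vals.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_for_cv != 0, sd / mean_for_cv, np.nan)
    zero_mean = mean_for_cv == 0
    if zero_mean.any():
        logger.info("%d genes with zero mean: CV undefined, mean criterion only", int(zero_mean.sum()))
    means = vals.mean(axis=0)
    keep = (np.nan_to_num(cv, nan=-np.inf) >= cv_min) | (means >= mean_min)
    return matrix.loc[:, keep]


def save_report(report, metrics: dict, chain_summary: dict, outdir, config: dict | None = None) -> dict:
    """Write subsets.json / subsets.csv / diagnostics.json (+ resolved config).

    ``report`` is a FeatureSubsetReport; ``metrics`` maps each subset tuple to
    a MetricSet.  The CSV follows the fixed column schema REPORT_COLUMNS with
    feature members named, one row per subset, ordered by frequency.
    Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = chain_summary.get("feature_names")

    rows = []
    payload = []
    for rank, (members, freq) in enumerate(report.subsets, start=1):
        member_names = [names[j] for j in members] if names else [str(j) for j in members]
        m = metrics.get(members)
        md = m.as_dict() if m is not None else {k: None for k in ("error_rate", "amlp", "auroc", "auprc")}
        rows.append({
            "subset": rank,
            "members": ";".join(member_names),
            "frequency": freq,
            **md,
        })
        payload.append({
            "rank": rank,
            "members": list(members),
            "member_names": member_names,
            "frequency": freq,
            "metrics": md,
        })

    paths = {}
    paths["subsets_json"] = outdir / "subsets.json"
    paths["subsets_json"].write_text(json.dumps({
        "n_draws": report.n_draws,
        "discarded_features": list(report.discarded),
        "unassigned_mass": report.unassigned_mass,
        "subsets": payload,
    }, indent=2))
    paths["subsets_csv"] = outdir / "subsets.csv"
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(paths["subsets_csv"], index=False)
    paths["diagnostics"] = outdir / "diagnostics.json"
    diag = {k: v for k, v in chain_summary.items() if k != "feature_names"}
    paths["diagnostics"].write_text(json.dumps(diag, indent=2, default=float))
    if config is not None:
        paths["config"] = outdir / "config.yaml"
        paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths
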