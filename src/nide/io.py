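"""Reading expression matrices and writing analysis results.

The matrix file is tab-delimited (comma autodetected), genes as rows, the
first column holding gene ids and the header row holding sample names.  The
group file is a two-column table mapping sample name to group label.  Values
are consumed as-is: log transformation is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .decisions import (DEFAULT_KAPPA_GRID, PosteriorSummary, ROCCurve,
                        bayes_rates)
from .model import ExpressionDataset

__all__ = ["read_dataset", "write_results"]

log = logging.getLogger(__name__)


def _read_table(path: Path) -> pd.DataFrame:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    sep = "\t"
    if "\t" not in head and "," in head:
        sep = ","
        log.info("%s: no tabs in header, falling back to comma delimiter", path)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_dataset(matrix_path, groups_path) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from matrix + group-label files.

    Groups are ordered by first appearance in the group file; every matrix
    sample must be assigned to exactly one group and each group must have at
    least two samples.  No imputation: any non-numeric or missing cell is an
    error naming the offending row and column.
    """
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    df = _read_table(matrix_path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {matrix_path}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {matrix_path}")

    groups = pd.read_csv(groups_path, sep=None, engine="python", header=None,
                         comment="#", skipinitialspace=True)
    if groups.shape[1] != 2:
        raise ValueError(f"{groups_path} must have two columns "
                         "(sample, group label)")
    assignment = dict(zip(groups[0].astype(str), groups[1].astype(str)))
    missing = [s for s in df.columns if s not in assignment]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no group assignment")

    group_names: list[str] = []
    for s in df.columns:
        g = assignment[s]
        if g not in group_names:
            group_names.append(g)
    group_of = np.array([group_names.index(assignment[s]) for s in df.columns],
                        dtype=np.int64)
    return ExpressionDataset(body.to_numpy(dtype=float), list(df.index.astype(str)),
                             group_names, group_of)


def write_results(summary: PosteriorSummary, out_dir,
                  roc: ROCCurve | None = None,
                  kappa_grid=DEFAULT_KAPPA_GRID,
                  manifest: dict | None = None,
                  force: bool = False) -> dict[str, Path]:
    """Write per-gene results, threshold decisions, ROC points and a manifest.

    Refuses to overwrite an existing populated directory unless ``force``.
    """
    if summary.n_genes == 0:
        raise ValueError("empty gene set: nothing to write")
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty (use force=True / --force)")
    out_dir.mkdir(parents=True, exist_ok=True)

    k = summary.pairwise_pi.shape[1]
    res = pd.DataFrame({"gene_id": summary.gene_ids, "pi": summary.pi})
    for s in range(k):
        for t in range(s + 1, k):
            suffix = f"_{s + 1}{t + 1}" if k > 2 else ""
            res[f"pi_pair{suffix}"] = summary.pairwise_pi[:, s, t]
            res[f"mean_diff{suffix}"] = summary.mean_diff[:, s, t]
    reports = []
    for kap in kappa_grid:
        rep = bayes_rates(summary, kap)
        res[f"call_at_{kap:g}"] = rep.calls.astype(int)
        reports.append(rep)
    written["results"] = out_dir / "results.tsv"
    res.to_csv(written["results"], sep="\t", index=False)

    dec = pd.DataFrame([{"kappa": r.kappa, "n_called": r.n_called,
                         "bFDR": r.bFDR, "bTNR": r.bTNR, "bFNR": r.bFNR,
                         "bFPR": r.bFPR, "bTPR": r.bTPR,
                         "no_calls": r.no_calls} for r in reports])
    written["decisions"] = out_dir / "decisions.tsv"
    dec.to_csv(written["decisions"], sep="\t", index=False)

    if roc is not None:
        written["roc"] = out_dir / "roc.tsv"
        pd.DataFrame(roc.points, columns=["bFPR", "bTPR"]).to_csv(
            written["roc"], sep="\t", index=False)

    info = dict(manifest or {})
    info.setdefault("n_genes", summary.n_genes)
    info["rhat_max"] = max((v for v in summary.rhat.values()
                            if np.isfinite(v)), default=None)
    if roc is not None:
        info["auc"] = roc.auc
    written["manifest"] = out_dir / "manifest.json"
    written["manifest"].write_text(json.dumps(info, indent=2, default=str))
    return written
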