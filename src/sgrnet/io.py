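"""Readers and writers for the package's plain-text formats.

Time series are TSV/CSV tables (T rows x N ROI columns, optional header of
ROI labels); connectivity matrices are written both as a labeled square TSV
and as an (roi_i, roi_j, weight) edge list for i < j; cohorts are described
by a manifest TSV with columns (subject_id, timeseries_path, group_label).
Numbers are serialized with 17 significant digits so write/read round-trips
are exact.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BoldTimeSeries, ConnectivityMatrix, SyntheticCohort

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_connectivity",
    "write_connectivity",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "load_aal116_labels",
]

_FLOAT_FMT = "%.17g"


def _detect_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_timeseries(path: str | Path, subject_id: str | None = None) -> BoldTimeSeries:
    """Read a T x N time-series table; header row of ROI labels is optional."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    first = lines[0].split(delim)
    has_header = not all(_is_number(tok) for tok in first)
    labels = [tok.strip() for tok in first] if has_header else None
    rows = []
    ncol = len(first)
    for k, ln in enumerate(lines[1 if has_header else 0:], start=2 if has_header else 1):
        toks = ln.split(delim)
        if len(toks) != ncol:
            raise ValueError(f"{path}: ragged row {k}: {len(toks)} fields, expected {ncol}")
        row = []
        for c, tok in enumerate(toks, start=1):
            try:
                row.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {k}, column {c}: {tok!r}"
                ) from None
        rows.append(row)
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 volumes, got {len(rows)}")
    return BoldTimeSeries(
        data=np.asarray(rows, dtype=float),
        subject_id=subject_id or path.stem,
        roi_labels=labels,
    )


def write_timeseries(ts: BoldTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(ts.roi_labels)
        for row in ts.data:
            w.writerow([_FLOAT_FMT % v for v in row])


def write_connectivity(
    w: ConnectivityMatrix,
    path_matrix: str | Path,
    path_edgelist: str | Path | None = None,
) -> None:
    """Write the labeled square matrix TSV and, optionally, the i<j edge list.

    Edge-list rows are emitted for every i < j pair, including zero weights
    (the zeros are meaningful for sparse estimators)."""
    path_matrix = Path(path_matrix)
    with open(path_matrix, "w", newline="") as fh:
        out = csv.writer(fh, delimiter="\t")
        out.writerow(w.roi_labels)
        for row in w.weights:
            out.writerow([_FLOAT_FMT % v for v in row])
    if path_edgelist is not None:
        with open(path_edgelist, "w", newline="") as fh:
            out = csv.writer(fh, delimiter="\t")
            out.writerow(["roi_i", "roi_j", "weight"])
            n = w.n_rois
            for i in range(n):
                for j in range(i + 1, n):
                    out.writerow(
                        [w.roi_labels[i], w.roi_labels[j], _FLOAT_FMT % w.weights[i, j]]
                    )


def read_connectivity(path: str | Path, estimator_tag: str = "PC") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(
        weights=df.to_numpy(dtype=float),
        roi_labels=[str(c) for c in df.columns],
        estimator_tag=estimator_tag,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns subject_id, timeseries_path, group_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "timeseries_path", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write per-subject TSVs, a manifest, and the ground-truth edge lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    names = {0: "NC", 1: "MCI"}
    for ts, lab in zip(cohort.subjects, cohort.labels):
        fname = f"{ts.subject_id}.tsv"
        write_timeseries(ts, outdir / fname)
        rows.append(
            {"subject_id": ts.subject_id, "timeseries_path": fname,
             "group_label": names[int(lab)]}
        )
    manifest = outdir / "manifest.tsv"
    write_manifest(pd.DataFrame(rows), manifest)
    truth = {
        "planted_edges": [[int(i), int(j)] for i, j in cohort.planted_edges],
        "seed": int(cohort.seed),
        "support_a": [
            [int(i), int(j)]
            for i, j in zip(*np.nonzero(np.triu(cohort.truth_a.support, k=1)))
        ],
        "support_b": [
            [int(i), int(j)]
            for i, j in zip(*np.nonzero(np.triu(cohort.truth_b.support, k=1)))
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest


def load_aal116_labels() -> pd.DataFrame:
    """Bundled AAL-116 ROI name table (index, abbreviation) for labeling."""
    with resources.files("sgrnet.data").joinpath("aal116_rois.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
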