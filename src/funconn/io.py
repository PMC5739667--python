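"""Plain-text I/O: time-series TSV, matrix TSV, tidy curves, reports.

Conventions
-----------
* Time-series TSV: one file per subject, columns = ROI abbreviations in
  node-label order, rows = time points.
* Cohort manifest TSV: subject_id, group, file (path relative to the
  manifest's directory).
* Matrix TSV: ROI abbreviations as header, N data rows, 10 significant
  digits (round-trip exact at that precision).
* Tidy curve TSV: subject_id, group, metric, sparsity (or the literal
  "auc"), value.
* BrainNet-Viewer-style exports: ``.node`` (x y z color size label) and
  ``.edge`` (N x N matrix) plain-text files.

All user-facing tables use 1-based region indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .labels import NodeLabelTable
from .synthetic import BehaviorTable, Cohort, TimeSeriesPanel

MATRIX_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Time-series panels


def write_panel_tsv(panel: TimeSeriesPanel, path, labels: NodeLabelTable) -> None:
    if panel.n_rois != len(labels):
        raise ValueError(
            f"panel {panel.subject_id!r} has {panel.n_rois} regions, "
            f"label table has {len(labels)}"
        )
    df = pd.DataFrame(panel.data, columns=labels.abbreviations)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel_tsv(
    path, labels: NodeLabelTable, subject_id: str, group: str
) -> TimeSeriesPanel:
    df = pd.read_csv(path, sep="\t")
    expected = labels.abbreviations
    missing = set(expected) - set(df.columns)
    extra = set(df.columns) - set(expected)
    if missing or extra:
        raise ValueError(
            f"{path}: ROI columns do not match the label table "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    df = df[expected]  # reorder to label-table order
    return TimeSeriesPanel(subject_id=subject_id, group=group, data=df.to_numpy(float))


def write_cohort(cohort: Cohort, out_dir, labels: NodeLabelTable) -> None:
    """Write per-subject TSVs, a manifest, the behaviour table and the truth record."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for panel in cohort.panels:
        rel = f"timeseries/{panel.subject_id}.tsv"
        write_panel_tsv(panel, out / rel, labels)
        rows.append({"subject_id": panel.subject_id, "group": panel.group, "file": rel})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.behavior.table.to_csv(out / "behavior.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    write_json(cohort.truth, out / "truth.json")


def read_cohort_dir(path, labels: NodeLabelTable) -> list[TimeSeriesPanel]:
    """Load panels listed in ``manifest.tsv`` under ``path``."""
    root = Path(path)
    manifest = root / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {root}")
    df = pd.read_csv(manifest, sep="\t")
    panels = []
    for row in df.itertuples():
        f = root / row.file
        if not f.exists():
            raise FileNotFoundError(
                f"manifest lists {row.file} for subject {row.subject_id}, "
                "but the file is missing"
            )
        panels.append(read_panel_tsv(f, labels, row.subject_id, row.group))
    return panels


def read_behavior_tsv(path) -> BehaviorTable:
    return BehaviorTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Connectivity matrices


def write_matrix_tsv(m: ConnectivityMatrix, path, labels: NodeLabelTable) -> None:
    if m.n_rois != len(labels):
        raise ValueError("matrix size does not match the label table")
    pd.DataFrame(m.values, columns=labels.abbreviations).to_csv(
        path, sep="\t", index=False, float_format=MATRIX_FMT
    )


def read_matrix_tsv(
    path, labels: NodeLabelTable, subject_id: str = "sub", rectified: bool = False
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != labels.abbreviations:
        raise ValueError(f"{path}: header does not match the label table")
    return ConnectivityMatrix(
        values=df.to_numpy(float), subject_id=subject_id, rectified=rectified
    )


# ---------------------------------------------------------------------------
# Tidy metric tables


def curves_to_frame(records: list[dict]) -> pd.DataFrame:
    """Assemble tidy rows {subject_id, group, metric, sparsity, value}."""
    return pd.DataFrame(records, columns=["subject_id", "group", "metric",
                                          "sparsity", "value"])


def write_tidy_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tidy_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JSON reports (deterministic byte layout)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# BrainNet-Viewer-style exports


def write_node_file(
    path,
    labels: NodeLabelTable,
    sizes: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> None:
    """Write a ``.node`` file: x y z color size label (tab-separated).

    ``subset`` restricts output to the given 0-based region indices.
    """
    coords = labels.coordinates()
    n = len(labels)
    sizes = np.ones(n) if sizes is None else np.asarray(sizes, dtype=float)
    colors = np.ones(n) if colors is None else np.asarray(colors, dtype=float)
    idx = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    abbrevs = labels.abbreviations
    with open(path, "w") as fh:
        for i in idx:
            x, y, z = coords[i]
            fh.write(
                f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{colors[i]:g}\t{sizes[i]:g}\t{abbrevs[i]}\n"
            )


def write_edge_file(path, matrix: np.ndarray) -> None:
    """Write a ``.edge`` file: a whitespace-separated N x N matrix."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%g", delimiter="\t")
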