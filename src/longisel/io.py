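"""Readers and writers for the delimited inputs and JSON/TSV outputs.

Features arrive as a wide delimited table (first column ``subject_id``,
one numeric column per feature).  Scores arrive in long/tidy format with
columns ``subject_id, time_label, score_name, value`` so that the number of
time points and score types is extensible.  Missing values are rejected
outright — no imputation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, ScoreTensor
from .optimizer import FitResult
from .pipeline import PredictionReport

__all__ = [
    "read_feature_table",
    "read_scores",
    "wide_scores_to_long",
    "write_report",
    "read_report",
    "write_weights",
    "write_region_table",
]

SCORE_COLUMNS = ["subject_id", "time_label", "score_name", "value"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a wide feature table into a :class:`FeatureMatrix`.

    Column order is preserved; duplicate subject ids, missing cells and
    non-numeric cells are all rejected with a message naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a subject_id column plus >= 1 feature")
    id_col = df.columns[0]
    subject_ids = df[id_col].astype(str).tolist()
    dup = df[id_col][df[id_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    feature_names = [str(c) for c in df.columns[1:]]
    values = np.empty((len(df), len(feature_names)))
    for j, col in enumerate(df.columns[1:]):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            row = bad[0]
            cell = df[col].iloc[row]
            kind = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
            raise ValueError(
                f"{path}: {kind} at row {row + 2} (subject {subject_ids[row]!r}), "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return FeatureMatrix(values, subject_ids, feature_names)


def read_scores(
    path: str | Path,
    subject_order: list[str] | None = None,
    time_order: list[str] | None = None,
    score_order: list[str] | None = None,
) -> ScoreTensor:
    """Read long-format scores into a dense (T, S, C) tensor.

    Every (subject, time, score) combination must appear exactly once.
    ``subject_order`` (typically the paired feature table's ids) fixes row
    alignment; time and score orderings default to first appearance in the
    file.  Unknown subjects and missing combinations raise with the
    offending keys listed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing_cols = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    if df["value"].isna().any():
        row = int(np.flatnonzero(df["value"].isna().to_numpy())[0])
        raise ValueError(f"{path}: non-numeric or missing value at row {row + 2}")

    file_subjects = list(dict.fromkeys(df["subject_id"]))
    if subject_order is None:
        subject_order = file_subjects
    else:
        unknown = sorted(set(file_subjects) - set(subject_order))
        if unknown:
            raise ValueError(f"{path}: unknown subject(s) {unknown[:5]}")
    if time_order is None:
        time_order = list(dict.fromkeys(df["time_label"]))
    if score_order is None:
        score_order = list(dict.fromkeys(df["score_name"]))

    s_idx = {v: i for i, v in enumerate(subject_order)}
    t_idx = {v: i for i, v in enumerate(time_order)}
    c_idx = {v: i for i, v in enumerate(score_order)}
    bad_time = sorted(set(df["time_label"]) - set(time_order))
    if bad_time:
        raise ValueError(f"{path}: unknown time label(s) {bad_time}")
    bad_score = sorted(set(df["score_name"]) - set(score_order))
    if bad_score:
        raise ValueError(f"{path}: unknown score name(s) {bad_score}")

    shape = (len(time_order), len(subject_order), len(score_order))
    values = np.full(shape, np.nan)
    seen = np.zeros(shape, dtype=bool)
    for sid, tl, sn, val in zip(
        df["subject_id"], df["time_label"], df["score_name"], df["value"]
    ):
        pos = (t_idx[tl], s_idx[sid], c_idx[sn])
        if seen[pos]:
            raise ValueError(f"{path}: duplicate entry for ({sid}, {tl}, {sn})")
        seen[pos] = True
        values[pos] = val
    if not seen.all():
        gaps = np.argwhere(~seen)
        listed = ", ".join(
            f"({subject_order[s]}, {time_order[t]}, {score_order[c]})"
            for t, s, c in gaps[:5]
        )
        raise ValueError(
            f"{path}: {gaps.shape[0]} missing (subject, time, score) "
            f"combination(s), e.g. {listed}"
        )
    return ScoreTensor(values, list(time_order), list(score_order), list(subject_order))


def wide_scores_to_long(
    wide: pd.DataFrame, time_label: str, id_col: str = "subject_id"
) -> pd.DataFrame:
    """Convenience converter: one wide table per time point -> tidy rows."""
    melted = wide.melt(id_vars=[id_col], var_name="score_name", value_name="value")
    melted.insert(1, "time_label", time_label)
    return melted[SCORE_COLUMNS]


def _dump_json(payload: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_report(report: PredictionReport, path: str | Path) -> None:
    """Serialize a cross-validation report as deterministic JSON."""
    _dump_json(report.to_dict(), Path(path))


def read_report(path: str | Path) -> PredictionReport:
    return PredictionReport.from_dict(json.loads(Path(path).read_text()))


def write_weights(
    result: FitResult,
    path: str | Path,
    feature_names: list[str],
    time_labels: list[str],
    score_names: list[str],
    config: dict | None = None,
) -> None:
    """Serialize a single fit: weights (T x F x C), trace and row norms."""
    payload = {
        "schema_version": 1,
        "feature_names": feature_names,
        "time_labels": time_labels,
        "score_names": score_names,
        "weights": result.weights.per_time.tolist(),
        "row_norms": [float(v) for v in result.row_norms],
        "objective_trace": [float(v) for v in result.objective_trace],
        "n_iter": result.n_iter,
        "converged": result.converged,
        "config": config or {},
    }
    _dump_json(payload, Path(path))


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the region stability report as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
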