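"""Core data containers shared across the package.

All numerical payloads are plain :class:`numpy.ndarray` objects; the
dataclasses below only add identifier bookkeeping and shape validation so
that downstream code can rely on consistent alignment between subjects,
features, time points and score types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureMatrix",
    "Normalization",
    "ScoreTensor",
    "WeightStack",
]


@dataclass
class Normalization:
    """Per-column affine statistics (mean, sd) learned from reference rows.

    Applying the same statistics to held-out rows guarantees that no
    information from evaluation subjects leaks into the transform.
    """

    mean: np.ndarray  # shape (F,)
    sd: np.ndarray  # shape (F,), strictly positive

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Transform rows of ``values`` with the stored statistics."""
        values = np.asarray(values, dtype=float)
        return (values - self.mean) / self.sd


@dataclass
class FeatureMatrix:
    """Baseline design matrix: one row per subject, one column per feature."""

    values: np.ndarray  # shape (S, F)
    subject_ids: list[str]
    feature_names: list[str]
    normalization: Normalization | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        s, f = self.values.shape
        if len(self.subject_ids) != s:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {s} rows"
            )
        if len(self.feature_names) != f:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {f} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreTensor:
    """Clinical scores stacked over time: values[t, s, c].

    ``values`` has shape (T, S, C) with subjects aligned row-for-row to the
    paired :class:`FeatureMatrix`.
    """

    values: np.ndarray  # shape (T, S, C)
    time_labels: list[str]
    score_names: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("score tensor must be 3-D (time, subject, score)")
        t, s, c = self.values.shape
        if len(self.time_labels) != t:
            raise ValueError(f"{len(self.time_labels)} time labels for T={t}")
        if len(self.score_names) != c:
            raise ValueError(f"{len(self.score_names)} score names for C={c}")
        if self.subject_ids is not None and len(self.subject_ids) != s:
            raise ValueError(f"{len(self.subject_ids)} subject ids for S={s}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score tensor contains non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_scores(self) -> int:
        return self.values.shape[2]

    def subset_subjects(self, rows: np.ndarray) -> "ScoreTensor":
        ids = None
        if self.subject_ids is not None:
            ids = [self.subject_ids[i] for i in np.atleast_1d(rows)]
        return ScoreTensor(
            self.values[:, rows, :], self.time_labels, self.score_names, ids
        )


@dataclass
class WeightStack:
    """Per-time-point weight matrices and their row-wise unfolding.

    ``per_time`` has shape (T, F, C).  The unfolding concatenates the T
    slices column-wise into an F x (C*T) matrix so that row i collects every
    coefficient feature i receives across all time points and score types.
    """

    per_time: np.ndarray  # shape (T, F, C)

    def __post_init__(self) -> None:
        self.per_time = np.asarray(self.per_time, dtype=float)
        if self.per_time.ndim != 3:
            raise ValueError("weight stack must be 3-D (time, feature, score)")

    @property
    def n_timepoints(self) -> int:
        return self.per_time.shape[0]

    @property
    def n_features(self) -> int:
        return self.per_time.shape[1]

    @property
    def n_scores(self) -> int:
        return self.per_time.shape[2]

    @property
    def unfolded(self) -> np.ndarray:
        """F x (C*T) column-wise concatenation [W(1) | ... | W(T)]."""
        return np.concatenate(list(self.per_time), axis=1)

    @classmethod
    def from_unfolded(
        cls, unfolded: np.ndarray, n_timepoints: int
    ) -> "WeightStack":
        """Inverse of :attr:`unfolded`; round-trip is the identity."""
        unfolded = np.asarray(unfolded, dtype=float)
        f, ct = unfolded.shape
        if ct % n_timepoints != 0:
            raise ValueError(
                f"cannot split {ct} columns into {n_timepoints} time points"
            )
        c = ct // n_timepoints
        per_time = np.stack(
            [unfolded[:, t * c : (t + 1) * c] for t in range(n_timepoints)]
        )
        return cls(per_time)

    def row_norms(self) -> np.ndarray:
        """Euclidean norm of each unfolded row, length F."""
        return np.linalg.norm(self.unfolded, axis=1)
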