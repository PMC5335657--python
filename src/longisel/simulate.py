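"""Synthetic longitudinal cohorts with the structure the model assumes.

The generator plants a sparse common feature support shared by every time
point and score type, temporally drifting weights, correlated score
columns, block-correlated features and Gaussian observation noise — the
three relational structures (feature-feature, subject-subject via shared
latent signal, score-score) that the graph regularizers target.  It exists
purely as a test harness: no claim is made that its distributions resemble
any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, ScoreTensor, WeightStack
from .graphs import z_normalize

__all__ = ["SimulationSpec", "SimulatedCohort", "generate", "write_fixture"]

_BLOCK_SIZE = 10  # features per correlated block

DEFAULT_TIME_LABELS = ["baseline", "M06", "M12", "M24"]
DEFAULT_SCORE_NAMES = ["score_a", "score_b"]


@dataclass
class SimulationSpec:
    """Knobs of the generator; defaults mirror a desk-scale cohort."""

    n_subjects: int = 200
    n_features: int = 93
    n_scores: int = 2
    n_timepoints: int = 4
    support_size: int = 10
    feature_block_corr: float = 0.3
    temporal_drift: float = 0.1
    score_corr: float = 0.6
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size > self.n_features:
            raise ValueError("support_size cannot exceed n_features")
        if not 0 <= self.feature_block_corr < 1:
            raise ValueError("feature_block_corr must be in [0, 1)")
        if not 0 <= self.score_corr < 1:
            raise ValueError("score_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.n_subjects, self.n_features, self.n_scores, self.n_timepoints) < 1:
            raise ValueError("all dimensions must be positive")


@dataclass
class SimulatedCohort:
    x: FeatureMatrix
    y: ScoreTensor
    w_true: WeightStack
    support_true: np.ndarray  # sorted feature indices with nonzero rows
    group_labels: list[str] = field(default_factory=list)  # NC / MCI / AD


def _block_correlated_features(rng: np.random.Generator, s: int, f: int, rho: float) -> np.ndarray:
    """Gaussian features in blocks of 10 with within-block correlation rho."""
    x = np.empty((s, f))
    for start in range(0, f, _BLOCK_SIZE):
        stop = min(start + _BLOCK_SIZE, f)
        width = stop - start
        shared = rng.standard_normal((s, 1))
        noise = rng.standard_normal((s, width))
        x[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
    return x


def _correlated_support_weights(
    rng: np.random.Generator,
    k: int,
    c: int,
    score_corr: float,
    x_support: np.ndarray,
) -> np.ndarray:
    """k x c weight columns whose noiseless signals have correlation score_corr.

    A shared latent direction g and per-score orthogonalized residuals are
    combined as sqrt(r) g + sqrt(1-r) h_c with {g, h_c} orthonormalized to a
    common squared length k, fixing the target Gram matrix exactly.  The
    combination is then whitened against the in-sample covariance of the
    support columns of X so that the realized signal correlation matches the
    request regardless of feature-block correlation, instead of drifting
    with the random support draw.
    """
    s = x_support.shape[0]
    raw = rng.standard_normal((k, c + 1))
    if k >= c + 1:
        basis, _ = np.linalg.qr(raw)  # k x (c+1) orthonormal columns
        basis = basis * np.sqrt(k)  # each column now has squared norm k
    else:  # tiny supports: fall back to the unorthogonalized construction
        basis = raw
    g = basis[:, 0]
    v = np.empty((k, c))
    for j in range(c):
        v[:, j] = np.sqrt(score_corr) * g + np.sqrt(1.0 - score_corr) * basis[:, j + 1]
    m = (x_support.T @ x_support) / s
    try:
        chol = np.linalg.cholesky(m)
        return np.linalg.solve(chol.T, v)
    except np.linalg.LinAlgError:  # degenerate support columns
        return v


def generate(spec: SimulationSpec) -> SimulatedCohort:
    """Draw a reproducible cohort from the generative model.

    The observation model is Y(t) = X W_true(t) + noise with
    W_true(t) = (1 + drift*(t-1)) * W_true(1) plus a small support-restricted
    perturbation, so later time points carry larger signal.  Observation
    noise shares the score-score correlation so the requested correlation
    survives the noise level.  Group labels are terciles of the first
    noiseless baseline score (low = NC, high = AD).
    """
    rng = np.random.default_rng(spec.seed)
    s, f, c, t_pts = spec.n_subjects, spec.n_features, spec.n_scores, spec.n_timepoints
    k = spec.support_size

    raw = _block_correlated_features(rng, s, f, spec.feature_block_corr)
    subject_ids = [f"sub{i:04d}" for i in range(s)]
    feature_names = [f"roi{j:03d}" for j in range(f)]
    x = FeatureMatrix(raw, subject_ids, feature_names)
    if s >= 2:
        x = z_normalize(x)

    support = np.sort(rng.choice(f, size=k, replace=False))
    if c > 1:
        w_support = _correlated_support_weights(
            rng, k, c, spec.score_corr, x.values[:, support]
        )
    else:
        w_support = rng.standard_normal((k, 1))

    per_time = np.zeros((t_pts, f, c))
    for t in range(t_pts):
        scale = 1.0 + spec.temporal_drift * t
        jitter = 0.05 * rng.standard_normal((k, c)) if t > 0 else 0.0
        per_time[t][support] = scale * w_support + jitter
    w_true = WeightStack(per_time)

    y = np.empty((t_pts, s, c))
    r = spec.score_corr if c > 1 else 0.0
    for t in range(t_pts):
        shared_noise = rng.standard_normal((s, 1))
        own_noise = rng.standard_normal((s, c))
        noise = spec.noise_sd * (np.sqrt(r) * shared_noise + np.sqrt(1.0 - r) * own_noise)
        y[t] = x.values @ per_time[t] + noise

    time_labels = (
        DEFAULT_TIME_LABELS[:t_pts]
        if t_pts <= len(DEFAULT_TIME_LABELS)
        else [f"T{t + 1}" for t in range(t_pts)]
    )
    score_names = (
        DEFAULT_SCORE_NAMES[:c]
        if c <= len(DEFAULT_SCORE_NAMES)
        else [f"score_{j}" for j in range(c)]
    )
    scores = ScoreTensor(y, time_labels, score_names, subject_ids)

    baseline_signal = x.values @ per_time[0][:, 0]
    order = np.argsort(baseline_signal, kind="stable")
    labels = np.empty(s, dtype=object)
    thirds = np.array_split(order, 3)
    for name, idx in zip(["NC", "MCI", "AD"], thirds):
        labels[idx] = name

    return SimulatedCohort(
        x=x,
        y=scores,
        w_true=w_true,
        support_true=support,
        group_labels=list(labels),
    )


def write_fixture(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the CSV files the readers consume.

    Emits ``features.csv`` (subject_id + one column per feature),
    ``scores.csv`` (long format: subject_id, time_label, score_name, value)
    and ``truth.json`` (planted support, true weights, group labels).
    Returns the paths keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    features_path = directory / "features.csv"
    feat = pd.DataFrame(cohort.x.values, columns=cohort.x.feature_names)
    feat.insert(0, "subject_id", cohort.x.subject_ids)
    feat.to_csv(features_path, index=False, float_format="%.17g")

    scores_path = directory / "scores.csv"
    rows = []
    y = cohort.y
    for t, tl in enumerate(y.time_labels):
        for s, sid in enumerate(cohort.x.subject_ids):
            for c, sn in enumerate(y.score_names):
                rows.append((sid, tl, sn, y.values[t, s, c]))
    pd.DataFrame(
        rows, columns=["subject_id", "time_label", "score_name", "value"]
    ).to_csv(scores_path, index=False, float_format="%.17g")

    truth_path = directory / "truth.json"
    truth = {
        "support_true": [int(i) for i in cohort.support_true],
        "w_true": cohort.w_true.per_time.tolist(),
        "group_labels": cohort.group_labels,
        "time_labels": y.time_labels,
        "score_names": y.score_names,
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return {"features": features_path, "scores": scores_path, "truth": truth_path}
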