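"""Heat-kernel similarity graphs, graph Laplacians and l2,1 reweighting.

Similarity between two vectors a, b is ``exp(-||a - b||^2)`` (optionally
``exp(-||a - b||^2 / (2 sigma^2))`` when a bandwidth is supplied), mapping
squared Euclidean distance into (0, 1].  Three graphs are built from the
data: feature-feature (over columns of X), subject-subject (over rows of
X), and score-score (over columns of Y at one time point).  Each graph
yields an unnormalized Laplacian L = D - S, whose quadratic form penalizes
disagreement between similar nodes.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FeatureMatrix, Normalization

__all__ = [
    "z_normalize",
    "feature_similarity",
    "subject_similarity",
    "score_similarity",
    "laplacian",
    "l21_reweight_diag",
]


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def z_normalize(
    features: FeatureMatrix,
    reference_rows: np.ndarray | list[int] | None = None,
) -> FeatureMatrix:
    """Column-wise z-scoring with statistics taken from ``reference_rows``.

    Every column is transformed by subtracting the mean and dividing by the
    sample standard deviation (ddof=1) computed on the reference rows only;
    held-out rows are transformed with the same statistics.  The fitted
    statistics are stored on the returned matrix (``.normalization``) so
    they can be re-applied to new subjects.

    Parameters
    ----------
    features
        Matrix to normalize.
    reference_rows
        Row indices used to compute the statistics.  ``None`` means all rows.

    Raises
    ------
    ValueError
        If a reference column has zero standard deviation (the offending
        column is named in the message).
    """
    values = features.values
    if reference_rows is None:
        reference_rows = np.arange(values.shape[0])
    reference_rows = np.asarray(reference_rows, dtype=int)
    if reference_rows.size == 0:
        raise ValueError("reference_rows must be non-empty")
    ref = values[reference_rows]
    mean = ref.mean(axis=0)
    # ddof=1 requires >= 2 rows; with a single reference row sd is undefined.
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 reference rows for a standard deviation")
    sd = ref.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = features.feature_names[zero[0]]
        raise ValueError(f"zero-variance column {name!r} cannot be z-normalized")
    norm = Normalization(mean=mean, sd=sd)
    return FeatureMatrix(
        values=norm.apply(values),
        subject_ids=list(features.subject_ids),
        feature_names=list(features.feature_names),
        normalization=norm,
    )


def _heat_kernel(rows: np.ndarray, sigma: float | None) -> np.ndarray:
    """Pairwise heat-kernel similarity between the rows of ``rows``.

    Squared distances are computed via the Gram-matrix identity and clipped
    at zero to absorb round-off; the result is exactly symmetric with unit
    diagonal.
    """
    rows = np.asarray(rows, dtype=float)
    gram = rows @ rows.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    if sigma is not None:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        d2 = d2 / (2.0 * sigma**2)
    k = np.exp(-d2)
    k = 0.5 * (k + k.T)
    np.fill_diagonal(k, 1.0)
    return k


def feature_similarity(features, sigma: float | None = None) -> np.ndarray:
    """F x F heat-kernel similarity between feature columns of X."""
    x = _as_values(features)
    if x.shape[1] < 2:
        raise ValueError("feature similarity requires at least 2 features")
    return _heat_kernel(x.T, sigma)


def subject_similarity(features, sigma: float | None = None) -> np.ndarray:
    """S x S heat-kernel similarity between subject rows of X."""
    x = _as_values(features)
    if x.shape[0] < 2:
        raise ValueError("subject similarity requires at least 2 subjects")
    return _heat_kernel(x, sigma)


def score_similarity(scores_at_t: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """C x C heat-kernel similarity between score columns at one time point.

    A single score type yields the 1x1 matrix [[1]].
    """
    y = np.asarray(scores_at_t, dtype=float)
    if y.ndim != 2:
        raise ValueError("scores_at_t must be a 2-D (subjects x scores) matrix")
    if y.shape[1] == 1:
        return np.ones((1, 1))
    return _heat_kernel(y.T, sigma)


def laplacian(graph: np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian L = D - S of a similarity matrix.

    D is the diagonal matrix of row sums of S.  The unit self-similarity on
    the diagonal of S cancels (D_ii - S_ii), so keeping it is equivalent to
    removing self-loops.  Rows of L sum to zero and L is PSD.
    """
    s = np.asarray(graph, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity graph must be square")
    if not np.allclose(s, s.T, atol=1e-12, rtol=0.0):
        raise ValueError("similarity graph must be symmetric")
    degrees = s.sum(axis=1)
    lap = np.diag(degrees) - s
    return 0.5 * (lap + lap.T)


def l21_reweight_diag(unfolded_weights: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Diagonal IRLS reweighting matrix for the l2,1 row-sparsity penalty.

    Entry i is ``1 / (2 * max(||w_i||_2, epsilon))`` where w_i is row i of
    the unfolded weight matrix; the quadratic form Tr(W^T D W) then
    majorizes the (clipped) sum of row norms, driving whole rows toward
    zero.  ``epsilon`` guards the subgradient singularity at zero rows.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    w = np.asarray(unfolded_weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("unfolded weights must be a 2-D matrix")
    norms = np.linalg.norm(w, axis=1)
    return np.diag(1.0 / (2.0 * np.maximum(norms, epsilon)))
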