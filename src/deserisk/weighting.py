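"""Indicator weighting: AHP (subjective), entropy (objective), and their combination.

The combined weight of indicator j is the normalized product
W_j = W1_j * W2_j / sum_j(W1_j * W2_j) of its subjective and objective weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError

# Saaty's random consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56,
    14: 1.57, 15: 1.59,
}

CONSISTENCY_THRESHOLD = 0.1


@dataclass
class WeightVector:
    """Named, normalized weights: sum(w) = 1; entries >= 0."""

    names: list[str]
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if len(self.names) != self.w.size:
            raise ValidationError("names and weights differ in length")
        if (self.w < 0).any():
            raise ValidationError("weights must be non-negative")
        total = self.w.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"weights sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.w[self.names.index(name)])

    @classmethod
    def from_raw(cls, names: list[str], raw: np.ndarray) -> "WeightVector":
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise DegenerateInputError("raw weights sum to zero")
        return cls(list(names), raw / total)


def _validate_pairwise(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("pairwise matrix must be square")
    if m.shape[0] < 2:
        raise ValidationError("pairwise matrix must be at least 2x2")
    if (m <= 0).any():
        raise ValidationError("pairwise matrix entries must be positive")
    if not np.allclose(np.diag(m), 1.0):
        raise ValidationError("pairwise matrix diagonal must be 1")
    if not np.allclose(m * m.T, 1.0, rtol=1e-6):
        raise ValidationError("pairwise matrix is not reciprocal (m[i,j] != 1/m[j,i])")
    return m


def ahp_weights(
    matrix: np.ndarray, names: list[str] | None = None
) -> tuple[WeightVector, float]:
    """Analytic Hierarchy Process weights from a reciprocal pairwise matrix.

    Returns the normalized principal eigenvector and the consistency ratio
    CR = ((lambda_max - n) / (n - 1)) / RI; CR >= 0.1 flags an inconsistent
    matrix (the weights are still returned — the caller decides).
    """
    m = _validate_pairwise(matrix)
    n = m.shape[0]
    eigvals, eigvecs = np.linalg.eig(m)
    principal = np.argmax(eigvals.real)
    lam = float(eigvals[principal].real)
    vec = np.abs(eigvecs[:, principal].real)
    names = list(names) if names is not None else [f"i{k}" for k in range(n)]
    weights = WeightVector.from_raw(names, vec)
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX.get(n)
    if ri is None:
        raise ValidationError(f"no random consistency index tabulated for order {n}")
    cr = 0.0 if ri == 0 else ci / ri
    # numerical jitter can put lambda_max marginally below n
    cr = max(cr, 0.0)
    return weights, cr


def entropy_weights(
    matrix: np.ndarray, names: list[str] | None = None
) -> WeightVector:
    """Entropy weights from an (n units x m indicators) decision matrix.

    For each indicator j: p_ij = x_ij / sum_i x_ij,
    e_j = -(1 / ln n) * sum_i p_ij ln p_ij (with 0 ln 0 := 0),
    divergence d_j = 1 - e_j, and w_j = d_j / sum_j d_j. Indicators whose
    column is constant carry no information and get weight 0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("decision matrix must be 2-D")
    n, m = x.shape
    if n < 2:
        raise ValidationError("decision matrix needs at least 2 evaluation units")
    if (x < 0).any():
        raise ValidationError("decision matrix entries must be non-negative")
    col_sums = x.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValidationError("every indicator column must have a positive sum")
    p = x / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e
    d[np.isclose(d, 0.0, atol=1e-12)] = 0.0
    if d.sum() <= 0:
        raise DegenerateInputError(
            "all indicator columns are constant — no information for entropy weighting"
        )
    names = list(names) if names is not None else [f"i{k}" for k in range(m)]
    return WeightVector.from_raw(names, d)


def combine_weights(subjective: WeightVector, objective: WeightVector) -> WeightVector:
    """Combined weights: elementwise product of the two vectors, renormalized."""
    if subjective.names != objective.names:
        raise ValidationError("subjective and objective weights name different indicators")
    product = subjective.w * objective.w
    if product.sum() <= 0:
        raise DegenerateInputError("product of weight vectors sums to zero")
    return WeightVector.from_raw(subjective.names, product)


def decision_matrix_from_layers(
    layers, max_cells: int = 10_000, seed: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build an entropy decision matrix from normalized grid layers.

    Evaluation units are grid cells, subsampled (seeded) to at most
    ``max_cells`` jointly-valid cells for tractability. Layers must already
    be normalized to [0, 1].
    """
    from .grid import require_shared_grid

    layers = list(layers)
    require_shared_grid(layers)
    valid = ~np.logical_or.reduce([l.nodata_mask for l in layers])
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        raise DegenerateInputError("fewer than 2 jointly valid cells")
    if idx.size > max_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_cells, replace=False))
    cols = [l.values.ravel()[idx] for l in layers]
    return np.column_stack(cols), [l.name for l in layers]
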