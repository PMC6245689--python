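"""Gaussian-copula mutual information and resampling significance.

Pairwise MI is estimated, after a rank-based copula transform of each
transcript's profile, as ``0.5 * log(var_x * var_y / det(C))`` with ``C``
the 2x2 covariance matrix — algebraically ``-0.5 * log(1 - rho^2)`` for
the Pearson correlation ``rho``.  Values are in nats.

Significance is assessed against a pooled null: the full matrix is
recomputed on data whose rows are independently permuted, all pair values
are pooled over permutations, and observed entries below the ``1 - alpha``
null quantile are zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, TranscriptID

__all__ = [
    "MIMatrix",
    "copula_transform",
    "gaussian_mi",
    "mi_matrix",
    "significance_mask",
    "MI_CAP",
]

#: finite stand-in for infinite MI on perfectly collinear pairs
MI_CAP = 1e6

# 1 - rho^2 below this is treated as collinear (det of the normalized
# covariance numerically zero)
_COLLINEAR_EPS = 1e-12


@dataclass
class MIMatrix:
    """Symmetric pairwise MI with a significance mask.

    ``M`` stores the masked values used for inference: non-significant
    entries are 0.  ``raw`` keeps the unmasked estimates, ``significant``
    the boolean mask (all-true before :func:`significance_mask` runs).
    """

    ids: list[TranscriptID]
    M: np.ndarray
    significant: np.ndarray
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if self.M.shape != (len(self.ids), len(self.ids)):
            raise ValueError("MI matrix shape does not match id list")
        if self.raw is None:
            self.raw = self.M.copy()

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, transcript: TranscriptID | str) -> int:
        key = str(transcript)
        for i, t in enumerate(self.ids):
            if str(t) == key:
                return i
        raise KeyError(key)


def copula_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each transcript profile by its normalized ranks.

    Values become ``rank / (n_samples + 1)`` with average ranks on ties,
    so outputs lie strictly inside (0, 1).  A constant row maps to all
    0.5 and triggers a warning.
    """
    values = matrix.values
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant transcript profile(s); "
            "copula transform maps them to 0.5",
            stacklevel=2,
        )
    ranks = stats.rankdata(values, axis=1, method="average")
    return matrix.with_values(ranks / (values.shape[1] + 1))


def _mi_from_r2(r2: float) -> float:
    if 1.0 - r2 < _COLLINEAR_EPS:
        return MI_CAP
    return -0.5 * float(np.log1p(-r2))


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """MI of a bivariate Gaussian fitted to (x, y), in nats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("constant vector: MI undefined")
    cov = np.cov(x, y, ddof=1)[0, 1]
    r2 = (cov * cov) / (vx * vy)
    if 1.0 - r2 < _COLLINEAR_EPS:
        warnings.warn("collinear pair: MI capped", stacklevel=2)
    return _mi_from_r2(min(r2, 1.0))


def _pairwise_mi(values: np.ndarray) -> np.ndarray:
    """Full MI matrix from row profiles (diagonal set to 0)."""
    if (values.std(axis=1) == 0).any():
        raise ValueError("constant transcript profile: MI undefined")
    r = np.corrcoef(values)
    r2 = np.clip(r * r, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        m = -0.5 * np.log1p(-r2)
    m[1.0 - r2 < _COLLINEAR_EPS] = MI_CAP
    np.fill_diagonal(m, 0.0)
    return m


def mi_matrix(matrix: ExpressionMatrix) -> MIMatrix:
    """Pairwise MI over all transcript pairs (O(n^2) evaluations)."""
    if matrix.n_transcripts < 2:
        raise ValueError("need at least 2 transcripts")
    m = _pairwise_mi(matrix.values)
    return MIMatrix(list(matrix.transcripts), m, np.ones_like(m, dtype=bool))


def significance_mask(
    mi: MIMatrix,
    data: ExpressionMatrix,
    n_perm: int = 30,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MIMatrix:
    """Zero MI entries not exceeding the pooled permutation-null quantile.

    Each of the ``n_perm`` rounds permutes every transcript's sample order
    independently and recomputes the full MI matrix; all off-diagonal
    values are pooled into one null distribution.  An observed entry is
    significant iff it exceeds that pool's ``1 - alpha`` quantile.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if [str(t) for t in mi.ids] != [str(t) for t in data.transcripts]:
        raise ValueError("MI matrix and data transcripts differ")

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(mi.n, k=1)
    null = np.empty((n_perm, iu[0].size))
    for p in range(n_perm):
        shuffled = rng.permuted(data.values, axis=1)
        null[p] = _pairwise_mi(shuffled)[iu]
    threshold = float(np.quantile(null.ravel(), 1.0 - alpha))

    significant = mi.raw > threshold
    np.fill_diagonal(significant, False)
    masked = np.where(significant, mi.raw, 0.0)
    return MIMatrix(list(mi.ids), masked, significant, raw=mi.raw.copy())


def null_threshold(
    data: ExpressionMatrix,
    n_perm: int = 30,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """The pooled-null ``1 - alpha`` MI quantile for ``data`` (diagnostic)."""
    rng = np.random.default_rng(seed)
    n = data.n_transcripts
    iu = np.triu_indices(n, k=1)
    pool = []
    for _ in range(n_perm):
        shuffled = rng.permuted(data.values, axis=1)
        pool.append(_pairwise_mi(shuffled)[iu])
    return float(np.quantile(np.concatenate(pool), 1.0 - alpha))
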