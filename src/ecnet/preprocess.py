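"""Quantile normalization and differential-expression filtering.

The preprocessing pipeline normalizes each condition's intensity matrix so
all samples share a common distribution, then keeps transcripts that are
differentially expressed between the two conditions (paired test p-value
below ``alpha`` and at least ``min_lfc`` log2 units of change).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import DEResult, ExpressionMatrix, TranscriptID

__all__ = [
    "quantile_normalize",
    "differential_expression",
    "de_transcripts",
    "count_couples",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common per-rank mean distribution.

    Each column's value at rank k is replaced by the mean, across columns,
    of the k-th smallest values.  Tied input values receive the mean of the
    target values over their tied ranks (average-rank convention), so the
    transform is well defined and idempotent.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")

    target = np.sort(values, axis=0).mean(axis=1)  # per-rank means, ranks 1..n

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(target)
        ranked[order] = target
        # tied inputs get the mean of the target values at their tied ranks
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=ranked)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked
    return matrix.with_values(out)


def differential_expression(
    mat_H: ExpressionMatrix,
    mat_60: ExpressionMatrix,
    alpha: float = 0.01,
    min_lfc: float = 1.0,
) -> list[DEResult]:
    """Paired two-sided t-test per transcript across matched samples.

    The log fold change is the mean of (second condition minus first) in
    log2 units.  A transcript is flagged differentially expressed iff
    ``p_value < alpha`` and ``|log_fold_change| >= min_lfc``.
    """
    ids_H = [str(t) for t in mat_H.transcripts]
    ids_60 = [str(t) for t in mat_60.transcripts]
    if ids_H != ids_60:
        raise ValueError("transcript lists differ between conditions")
    if mat_H.n_samples != mat_60.n_samples:
        raise ValueError("conditions must have the same number of paired samples")
    if mat_H.n_samples < 3:
        raise ValueError("paired test undefined with fewer than 3 pairs")

    diff = mat_60.values - mat_H.values
    lfc = diff.mean(axis=1)
    # t-statistic on the paired differences; constant-difference rows get
    # p=1 when the mean difference is 0, p=0 otherwise (exact shift)
    sd = diff.std(axis=1, ddof=1)
    n = diff.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / (sd / np.sqrt(n))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    zero_sd = sd == 0
    pvals[zero_sd & (lfc == 0)] = 1.0
    pvals[zero_sd & (lfc != 0)] = 0.0

    results = []
    for i, t in enumerate(mat_H.transcripts):
        p = float(pvals[i])
        l = float(lfc[i])
        flag = (p < alpha) and (abs(l) >= min_lfc)
        results.append(DEResult(t, p, l, flag))
    return results


def de_transcripts(results: list[DEResult]) -> list[TranscriptID]:
    """Transcripts flagged differentially expressed."""
    return [r.transcript for r in results if r.is_de]


def count_couples(de: list[DEResult] | list[TranscriptID]) -> int:
    """Number of base genes whose sense and anti-sense are both in the list."""
    ids = [r.transcript if isinstance(r, DEResult) else r for r in de]
    sense = {t.base_id for t in ids if t.is_sense}
    anti = {t.base_id for t in ids if t.is_antisense}
    return len(sense & anti)
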