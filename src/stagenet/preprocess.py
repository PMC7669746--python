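"""Gene filtering and between-sample normalisation for count matrices.

Two steps prepare raw counts for differential expression and mutual-
information estimation: a mean-expression filter (keep genes with
across-sample mean strictly above a threshold, applied to raw counts),
and TMM (trimmed mean of M-values) scale factors followed by a log2-CPM
transform.  TMM corrects RNA composition bias between libraries: for
each sample, per-gene log2 expression ratios (M) against a reference
sample are doubly trimmed (30% on M, 5% on average abundance A), and
the factor is two to the inverse-variance-weighted mean of the
surviving M values, with all factors rescaled to geometric mean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import ExpressionMatrix, StagenetError

__all__ = [
    "NormalizationResult",
    "filter_by_mean",
    "tmm_factors",
    "log_cpm",
    "normalize",
]


@dataclass
class NormalizationResult:
    normalized: ExpressionMatrix
    scale_factors: dict[str, float]


def filter_by_mean(matrix: ExpressionMatrix, threshold: float = 10.0) -> ExpressionMatrix:
    """Keep genes whose across-all-samples mean is strictly > ``threshold``.

    Sample set and gene order are preserved.  An empty result is a
    warning, not an error.
    """
    means = matrix.values.mean(axis=1)
    keep = means > threshold
    if not keep.any():
        warnings.warn(
            f"mean filter (> {threshold}) removed every gene", stacklevel=2
        )
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(matrix.values[keep, :], genes, list(matrix.sample_ids))


def tmm_factors(
    matrix: ExpressionMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> dict[str, float]:
    """TMM normalisation factors, one per sample, geometric mean 1.

    ``reference`` defaults to the sample whose upper-quartile
    (of counts scaled by library size) is closest to the mean
    upper-quartile.  Genes with a zero count in either the sample or
    the reference are excluded from the trimmed mean.
    """
    counts = matrix.values
    if matrix.n_samples < 2:
        raise StagenetError("tmm_factors needs >= 2 samples")
    if (counts < 0).any():
        raise StagenetError("tmm_factors expects raw nonnegative counts")
    lib = counts.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot <= 0:
            raise StagenetError(
                f"sample {matrix.sample_ids[j]!r} has all-zero counts"
            )
    if reference is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(matrix.n_samples)])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in matrix.sample_ids:
            raise StagenetError(f"unknown reference sample {reference!r}")
        ref_idx = matrix.sample_ids.index(reference)

    log_factors = np.zeros(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref_idx:
            continue
        log_factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return {s: float(f) for s, f in zip(matrix.sample_ids, factors)}


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """Weighted, doubly trimmed mean of per-gene log2 ratios (one sample vs ref)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 0.0
    p_obs = obs[ok] / n_obs
    p_ref = ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    # Asymptotic (delta-method) variance of M under binomial sampling.
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.allclose(m, m[0]):
        return float(m[0])
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if abs(f) < 1e-6:
        f = 0.0
    return float(f)


def log_cpm(
    matrix: ExpressionMatrix,
    factors: dict[str, float],
    prior_count: float = 1.0,
) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (library_size * factor) * 1e6);
    strictly monotone in the count within each sample.
    """
    missing = [s for s in matrix.sample_ids if s not in factors]
    if missing:
        raise StagenetError(f"missing scale factors for samples: {missing}")
    f = np.array([factors[s] for s in matrix.sample_ids])
    if (f <= 0).any() or not np.isfinite(f).all():
        bad = matrix.sample_ids[int(np.argmin(f))]
        raise StagenetError(f"nonpositive or non-finite scale factor for sample {bad!r}")
    if (matrix.values < 0).any():
        raise StagenetError("log_cpm expects raw nonnegative counts")
    lib = matrix.values.sum(axis=0) * f
    vals = np.log2((matrix.values + prior_count) / lib[None, :] * 1e6)
    return ExpressionMatrix(vals, list(matrix.gene_ids), list(matrix.sample_ids))


def normalize(
    matrix: ExpressionMatrix,
    min_mean: float = 10.0,
    prior_count: float = 1.0,
) -> NormalizationResult:
    """Mean filter (on raw counts) + TMM + log2-CPM, the standard prep."""
    filtered = filter_by_mean(matrix, min_mean)
    factors = tmm_factors(filtered)
    return NormalizationResult(log_cpm(filtered, factors, prior_count), factors)
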