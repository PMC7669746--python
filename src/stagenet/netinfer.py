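"""Mutual-information co-expression estimation and ranked sparsification.

Co-expression between two genes is scored by the mutual information of
their expression profiles after equal-frequency discretisation into
B = floor(sqrt(n)) bins (ties broken by original sample index, so the
partition — and therefore every downstream ranking — is deterministic
without a seed).  The plug-in estimate

    I(X;Y) = sum_ij p(i,j) log2[ p(i,j) / (p(i) p(j)) ]

over the BxB contingency table is the default; a Miller–Madow
bias-corrected variant is available.  Equal-frequency binning makes the
estimate invariant under strictly increasing transforms of either
profile, which is what makes MI a robust co-expression score.

Networks are sparsified by rank: the top-N highest-MI pairs, with
deterministic lexicographic tie-breaking, so cut-offs are nested
prefixes of one ranking.  An optional data-processing-inequality (DPI)
pruning step removes, in every gene triangle, the weakest edge when it
falls below the smaller of the other two (within a tolerance) — the
classic indirect-interaction filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ExpressionMatrix, MIRankedEdgeList, StagenetError

__all__ = [
    "MIEstimatorConfig",
    "equal_frequency_bins",
    "mi_from_joint",
    "mutual_information",
    "mi_matrix",
    "dpi_prune",
    "top_n",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Discretisation and estimator choices for MI.

    ``n_bins``: explicit bin count (>= 2) or ``"sqrt_n"`` for
    floor(sqrt(n)).  ``estimator``: ``"plugin"`` or ``"miller_madow"``.
    MI is always reported in bits (log base 2).
    """

    n_bins: int | str = "sqrt_n"
    estimator: str = "plugin"

    def __post_init__(self) -> None:
        if isinstance(self.n_bins, str):
            if self.n_bins != "sqrt_n":
                raise StagenetError(f"n_bins: unknown rule {self.n_bins!r}")
        elif self.n_bins < 2:
            raise StagenetError("n_bins: must be >= 2 when explicit")
        if self.estimator not in ("plugin", "miller_madow"):
            raise StagenetError(f"estimator: unknown estimator {self.estimator!r}")

    def bins_for(self, n: int) -> int:
        if self.n_bins == "sqrt_n":
            return max(2, int(np.sqrt(n)))
        return int(self.n_bins)


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Deterministic equal-frequency bin index for every value.

    Values are ranked by a stable sort (ties keep original index
    order) and rank r maps to bin floor(r * n_bins / n), giving bins
    whose sizes differ by at most one.
    """
    x = np.asarray(x)
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def mi_from_joint(counts: np.ndarray, miller_madow: bool = False) -> float:
    """Mutual information (bits) of a joint contingency table of counts."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        raise StagenetError("contingency table has no observations")
    p = c / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))
    if miller_madow:
        kx = int(np.count_nonzero(px))
        ky = int(np.count_nonzero(py))
        kxy = int(np.count_nonzero(p))
        mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n * _LN2)
    return max(mi, 0.0)


def mutual_information(
    x: Sequence[float], y: Sequence[float], config: MIEstimatorConfig | None = None
) -> float:
    """MI (bits) between two expression profiles; symmetric, >= 0.

    A constant profile carries no information: returns 0 with a warning.
    """
    config = config or MIEstimatorConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StagenetError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 8:
        raise StagenetError(f"need >= 8 observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant profile: MI defined as 0", stacklevel=2)
        return 0.0
    b = config.bins_for(x.size)
    bx = equal_frequency_bins(x, b)
    by = equal_frequency_bins(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    return mi_from_joint(joint, miller_madow=config.estimator == "miller_madow")


def mi_matrix(
    matrix: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    config: MIEstimatorConfig | None = None,
) -> MIRankedEdgeList:
    """All-pairs MI over (a subset of) samples, as a ranked edge list.

    Constant genes contribute zero-MI edges, matching the pairwise
    definition.  The per-pair loop uses a precomputed c*log2(c) table
    over integer cell counts, so a few tens of thousands of gene pairs
    take well under a second.
    """
    config = config or MIEstimatorConfig()
    sub = matrix if samples is None else matrix.subset_samples(list(samples))
    n = sub.n_samples
    if n < 8:
        raise StagenetError(f"need >= 8 samples, got {n}")
    b = config.bins_for(n)
    n_genes = sub.n_genes
    values = sub.values
    const = np.array([np.all(values[i] == values[i, 0]) for i in range(n_genes)])
    binned = np.empty((n_genes, n), dtype=np.int64)
    for i in range(n_genes):
        binned[i] = equal_frequency_bins(values[i], b)

    # H = log2(n) - (1/n) sum_c c*log2(c); table over possible counts.
    tbl = np.zeros(n + 1)
    cc = np.arange(1, n + 1, dtype=float)
    tbl[1:] = cc * np.log2(cc)
    log2n = np.log2(n)
    h_marg = np.array([
        log2n - tbl[np.bincount(binned[i], minlength=b)].sum() / n
        for i in range(n_genes)
    ])
    mm = config.estimator == "miller_madow"
    k_marg = np.array([
        np.count_nonzero(np.bincount(binned[i], minlength=b)) for i in range(n_genes)
    ])

    records: list[tuple[str, str, float]] = []
    genes = sub.gene_ids
    for i in range(n_genes):
        bi = binned[i] * b
        for j in range(i + 1, n_genes):
            if const[i] or const[j]:
                records.append((genes[i], genes[j], 0.0))
                continue
            joint = np.bincount(bi + binned[j], minlength=b * b)
            h_joint = log2n - tbl[joint].sum() / n
            mi = h_marg[i] + h_marg[j] - h_joint
            if mm:
                k_joint = np.count_nonzero(joint)
                mi += ((k_marg[i] - 1) + (k_marg[j] - 1) - (k_joint - 1)) / (2.0 * n * _LN2)
            records.append((genes[i], genes[j], max(float(mi), 0.0)))
    return MIRankedEdgeList.from_records(records)


def dpi_prune(edges: MIRankedEdgeList, tolerance: float = 0.0) -> MIRankedEdgeList:
    """Data-processing-inequality pruning of indirect edges.

    For every gene triangle the weakest edge is marked for removal when
    its MI is below (1 - tolerance) times the smaller of the other two;
    all marked edges are removed simultaneously after scanning every
    triangle.  Edges outside any triangle are always kept.
    """
    if not (0.0 <= tolerance < 1.0):
        raise StagenetError("tolerance must be in [0, 1)")
    mi: dict[tuple[str, str], float] = {(a, b): w for a, b, w in edges}
    adj: dict[str, set[str]] = {}
    for a, b, _ in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    doomed: set[tuple[str, str]] = set()
    for a, b, _ in edges.edges:
        # Each triangle handled exactly once, at its lexicographically
        # smallest edge (a < b < c).
        for c in adj[a] & adj[b]:
            if c <= b:
                continue
            trio = [(mi[(a, b)], (a, b)), (mi[(b, c)], (b, c)), (mi[(a, c)], (a, c))]
            trio.sort(key=lambda t: t[0])
            weakest, second = trio[0], trio[1]
            if weakest[0] < (1.0 - tolerance) * second[0]:
                doomed.add(weakest[1])
    return MIRankedEdgeList([e for e in edges.edges if (e[0], e[1]) not in doomed])


def top_n(edges: MIRankedEdgeList, n: int) -> MIRankedEdgeList:
    """The N highest-MI edges; a prefix of the canonical ranking."""
    return edges.top(n)
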