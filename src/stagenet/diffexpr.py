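"""Differential expression, signature comparison and progressive genes.

All tests run on the normalised (log2-CPM) matrix.  A contrast's log2
fold change is the difference of group means on the log2 scale; the
p-value comes from a two-sided Welch t-test, corrected across genes by
Benjamini–Hochberg, and a gene is called over/under-expressed when
|LFC| exceeds the threshold (default 2.0 vs control, 0.5 for the
relaxed multi-group contrasts) at FDR < alpha.  Signature similarity
between contrasts is Spearman's rank correlation of the LFC vectors.

Progressive genes — genes tracking disease progression — are those
whose per-phenotype means are strictly monotone across the ordered
stages *and* whose every consecutive-stage difference is significant by
a two-sided Mann–Whitney rank-sum test, BH-adjusted jointly across all
gene x consecutive-pair tests.  (Stage groups are unpaired patient
sets, hence the rank-sum rather than the signed-rank form.)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, StagenetError, StageLabels

__all__ = [
    "DEResult",
    "ProgressiveGene",
    "bh_adjust",
    "differential_expression",
    "multi_group_contrasts",
    "rank_correlation",
    "progressive_genes",
]


@dataclass
class DEResult:
    """Per-gene LFC / p / FDR / status for one phenotype contrast."""

    gene_ids: list[str]
    lfc: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray
    status: np.ndarray  # 'over' | 'under' | 'ns'
    contrast: str
    baseline: str
    lfc_threshold: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "lfc": self.lfc,
                "p": self.p_value,
                "fdr": self.fdr,
                "status": self.status,
            }
        )

    def genes_with_status(self, status: str) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.status) if s == status]


@dataclass
class ProgressiveGene:
    """A gene strictly monotone in mean across the ordered phenotypes."""

    gene: str
    direction: str  # 'up' | 'down'
    means: list[float]  # ordered control -> last stage
    p_values: list[float]  # consecutive-pair rank-sum p-values
    fdrs: list[float]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values per gene row; degenerate rows get
    p = 1 when the means agree and p = 0 when they differ with zero
    within-group variance."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        diff = a.mean(axis=1) - b.mean(axis=1)
        p[bad] = np.where(np.isclose(diff[bad], 0.0), 1.0, 0.0)
    return p


def differential_expression(
    normalized: ExpressionMatrix,
    labels: StageLabels,
    contrast_phenotype: str,
    lfc_threshold: float = 2.0,
    alpha: float = 0.05,
    baseline_phenotype: str | None = None,
) -> DEResult:
    """One contrast (phenotype vs control unless overridden) for all genes."""
    baseline = labels.control if baseline_phenotype is None else baseline_phenotype
    for ph in (contrast_phenotype, baseline):
        if ph not in labels.phenotypes:
            raise StagenetError(f"phenotype {ph!r} absent from labels")
    ca = normalized.subset_samples(labels.samples(contrast_phenotype)).values
    cb = normalized.subset_samples(labels.samples(baseline)).values
    if ca.shape[1] < 2 or cb.shape[1] < 2:
        raise StagenetError("both groups need >= 2 samples")
    lfc = ca.mean(axis=1) - cb.mean(axis=1)
    p = _welch(ca, cb)
    fdr = bh_adjust(p)
    sig = fdr < alpha
    status = np.where(
        sig & (lfc > lfc_threshold),
        "over",
        np.where(sig & (lfc < -lfc_threshold), "under", "ns"),
    )
    return DEResult(
        list(normalized.gene_ids), lfc, p, fdr, status,
        contrast_phenotype, baseline, lfc_threshold, alpha,
    )


def multi_group_contrasts(
    normalized: ExpressionMatrix,
    labels: StageLabels,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> dict[tuple[str, str], DEResult]:
    """Every unordered phenotype pair at the relaxed LFC threshold.

    Each contrast gets its own BH correction across genes.
    """
    phenos = labels.phenotypes
    if len(phenos) < 2:
        raise StagenetError("need >= 2 phenotypes for multi-group contrasts")
    out: dict[tuple[str, str], DEResult] = {}
    for pa, pb in itertools.combinations(phenos, 2):
        out[(pa, pb)] = differential_expression(
            normalized, labels, pb, lfc_threshold, alpha, baseline_phenotype=pa
        )
    return out


def rank_correlation(de_a: DEResult, de_b: DEResult) -> float:
    """Spearman rank correlation of the two LFC vectors (average ranks)."""
    if de_a.gene_ids != de_b.gene_ids:
        shared = [g for g in de_a.gene_ids if g in set(de_b.gene_ids)]
        if len(shared) < 3:
            raise StagenetError(f"need >= 3 shared genes, got {len(shared)}")
        ia = {g: i for i, g in enumerate(de_a.gene_ids)}
        ib = {g: i for i, g in enumerate(de_b.gene_ids)}
        xa = de_a.lfc[[ia[g] for g in shared]]
        xb = de_b.lfc[[ib[g] for g in shared]]
    else:
        if len(de_a.gene_ids) < 3:
            raise StagenetError(f"need >= 3 shared genes, got {len(de_a.gene_ids)}")
        xa, xb = de_a.lfc, de_b.lfc
    return float(stats.spearmanr(xa, xb).statistic)


def progressive_genes(
    normalized: ExpressionMatrix,
    labels: StageLabels,
    ordered_phenotypes: list[str] | tuple[str, ...],
    alpha: float = 0.05,
) -> list[ProgressiveGene]:
    """Genes strictly monotone in mean with all consecutive steps significant.

    Mann–Whitney tests for every gene and every consecutive phenotype
    pair are BH-adjusted jointly (genes x pairs) before applying
    ``alpha``.
    """
    order = list(ordered_phenotypes)
    if len(order) < 3:
        raise StagenetError("need >= 3 ordered phenotypes")
    unknown = [ph for ph in order if ph not in labels.phenotypes]
    if unknown:
        raise StagenetError(f"phenotypes absent from labels: {unknown}")
    groups = []
    for ph in order:
        vals = normalized.subset_samples(labels.samples(ph)).values
        if vals.shape[1] < 2:
            raise StagenetError(f"phenotype {ph!r} has < 2 samples")
        groups.append(vals)
    n_genes = normalized.n_genes
    n_pairs = len(order) - 1
    means = np.column_stack([g.mean(axis=1) for g in groups])  # genes x phenotypes

    pvals = np.empty((n_genes, n_pairs))
    for j in range(n_pairs):
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                groups[j], groups[j + 1], axis=1, alternative="two-sided"
            )
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0
        pvals[:, j] = p
    fdr = bh_adjust(pvals.ravel()).reshape(n_genes, n_pairs)

    out: list[ProgressiveGene] = []
    diffs = np.diff(means, axis=1)
    up = (diffs > 0).all(axis=1)
    down = (diffs < 0).all(axis=1)
    sig = (fdr < alpha).all(axis=1)
    for i in range(n_genes):
        if sig[i] and (up[i] or down[i]):
            out.append(
                ProgressiveGene(
                    gene=normalized.gene_ids[i],
                    direction="up" if up[i] else "down",
                    means=[float(m) for m in means[i]],
                    p_values=[float(v) for v in pvals[i]],
                    fdrs=[float(v) for v in fdr[i]],
                )
            )
    return out
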