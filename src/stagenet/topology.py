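"""Chromosomal topology of co-expression networks.

Edges are classified *cis-* (both genes on one chromosome) or *trans-*
(inter-chromosome, "long-range" co-expression).  The per-chromosome
cis-rate is the number of cis edges on that chromosome divided by the
number of that chromosome's genes present in the network — a ratio
that can exceed 1 on cis-dense chromosomes; the global cis fraction
n_cis / (n_cis + n_trans) is reported alongside.  Degree distributions
p(k) are fitted to a power law y = a*k^b by nonlinear least squares
(initialised from the log-log ordinary least-squares solution), with
the Pearson correlation of fitted vs observed values and R-square as
goodness-of-fit summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .core import AnnotatedNetwork, GeneAnnotation, MIRankedEdgeList, StagenetError

__all__ = [
    "CisTransSummary",
    "PowerLawFit",
    "classify_edges",
    "cis_trans_summary",
    "degree_distribution",
    "fit_power_law",
    "largest_component",
]


@dataclass
class CisTransSummary:
    """Network-wide and per-chromosome cis/trans counts.

    ``per_chromosome`` maps (normalised) chromosome label to
    (cis_edges, genes_in_network, cis_rate).
    """

    n_cis: int
    n_trans: int
    per_chromosome: dict[str, tuple[int, int, float]]

    @property
    def n_edges(self) -> int:
        return self.n_cis + self.n_trans

    @property
    def cis_fraction(self) -> float:
        """Global n_cis / (n_cis + n_trans)."""
        if self.n_edges == 0:
            raise StagenetError("empty network has no cis fraction")
        return self.n_cis / self.n_edges

    def to_dict(self) -> dict:
        return {
            "n_cis": self.n_cis,
            "n_trans": self.n_trans,
            "cis_fraction": self.cis_fraction if self.n_edges else None,
            "per_chromosome": {
                c: {"cis_edges": ce, "genes_in_network": g, "cis_rate": r}
                for c, (ce, g, r) in self.per_chromosome.items()
            },
        }


@dataclass
class PowerLawFit:
    """Parameters of y = a*k^b fitted to a degree distribution."""

    a: float
    b: float
    correlation: float
    r_square: float

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "correlation": self.correlation,
                "r_square": self.r_square}


def classify_edges(
    edges: MIRankedEdgeList, annotation: GeneAnnotation
) -> AnnotatedNetwork:
    """Flag every edge cis or trans against the chromosome annotation.

    Chromosome labels compare after optional ``chr`` prefix stripping
    and case folding, so GENCODE- and UCSC-style annotations mix freely.
    """
    missing = sorted({g for a, b, _ in edges for g in (a, b) if g not in annotation})
    if missing:
        raise StagenetError(f"genes missing from annotation: {missing}")
    pairs = [(a, b) for a, b, _ in edges]
    mi = [w for _, _, w in edges]
    flags = [annotation.same_chromosome(a, b) for a, b in pairs]
    return AnnotatedNetwork(pairs, mi, flags, annotation)


def cis_trans_summary(network: AnnotatedNetwork) -> CisTransSummary:
    """Count cis/trans edges globally and per chromosome.

    A chromosome's cis-rate divides its cis edges by its genes present
    in the network (any chromosome with at least one network gene
    appears, even at zero cis edges).
    """
    ann = network.annotation
    genes_per_chrom: dict[str, int] = {}
    for node in network.nodes:
        c = ann.normalized(node)
        genes_per_chrom[c] = genes_per_chrom.get(c, 0) + 1
    cis_per_chrom: dict[str, int] = {c: 0 for c in genes_per_chrom}
    n_cis = 0
    for (a, _b), is_cis in zip(network.edges, network.flags):
        if is_cis:
            n_cis += 1
            cis_per_chrom[ann.normalized(a)] += 1
    per_chromosome = {
        c: (cis_per_chrom[c], genes_per_chrom[c], cis_per_chrom[c] / genes_per_chrom[c])
        for c in sorted(genes_per_chrom)
    }
    return CisTransSummary(n_cis, len(network.edges) - n_cis, per_chromosome)


def degree_distribution(network: AnnotatedNetwork) -> dict[int, float]:
    """Empirical p(k) over node degrees (all network nodes have k >= 1)."""
    if not network.edges:
        raise StagenetError("degree distribution of an empty network is undefined")
    deg: dict[str, int] = {}
    for a, b in network.edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    n = len(deg)
    counts: dict[int, int] = {}
    for k in deg.values():
        counts[k] = counts.get(k, 0) + 1
    return {k: counts[k] / n for k in sorted(counts)}


def fit_power_law(dist: dict[int, float]) -> PowerLawFit:
    """Nonlinear least-squares fit of p(k) = a*k^b on the (k, p(k)) points.

    Initialised from the log-log OLS solution over positive points;
    accepts either normalised probabilities or raw counts on the y
    axis.  On non-convergence the error message reports the log-log
    fallback estimates.
    """
    ks = np.array(sorted(dist), dtype=float)
    ps = np.array([dist[int(k)] for k in ks], dtype=float)
    if ks.size < 3:
        raise StagenetError(f"need >= 3 distinct degrees, got {ks.size}")
    if (ks <= 0).any() or (ps < 0).any():
        raise StagenetError("degrees must be positive and p(k) nonnegative")
    pos = ps > 0
    if pos.sum() < 3:
        raise StagenetError("need >= 3 points with positive p(k)")
    slope, intercept = np.polyfit(np.log(ks[pos]), np.log(ps[pos]), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)
    try:
        (a, b), _ = curve_fit(
            lambda k, a, b: a * np.power(k, b),
            ks, ps, p0=(a0, b0), maxfev=20000,
        )
    except RuntimeError as exc:
        raise StagenetError(
            f"power-law fit did not converge; log-log fallback a={a0:.6g}, b={b0:.6g}"
        ) from exc
    fitted = a * np.power(ks, b)
    ss_res = float(np.sum((ps - fitted) ** 2))
    ss_tot = float(np.sum((ps - ps.mean()) ** 2))
    r_square = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.allclose(fitted, fitted[0]) or np.allclose(ps, ps[0]):
        correlation = 1.0 if np.allclose(ps, fitted) else 0.0
    else:
        correlation = float(pearsonr(fitted, ps)[0])
    return PowerLawFit(float(a), float(b), correlation, min(r_square, 1.0))


def largest_component(network: AnnotatedNetwork) -> AnnotatedNetwork:
    """The maximal connected component by node count.

    Ties go to the component containing the lexicographically smallest
    node label, so the choice is deterministic.
    """
    if not network.nodes:
        raise StagenetError("empty network has no components")
    g = nx.Graph()
    g.add_edges_from(network.edges)
    components = [set(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), min(c)))
    keep = components[0]
    idx = [i for i, (a, b) in enumerate(network.edges) if a in keep]
    return AnnotatedNetwork(
        [network.edges[i] for i in idx],
        [network.mi[i] for i in idx],
        [network.flags[i] for i in idx],
        network.annotation,
    )
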