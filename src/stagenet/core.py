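"""Core in-memory containers shared by every pipeline stage.

The pipeline moves four kinds of objects around: a genes-by-samples
expression matrix, a gene->chromosome annotation, a sample->phenotype
labelling, and ranked mutual-information edge lists (plus their
chromosome-classified form).  All of them are small, validated
dataclasses; file parsing/serialisation lives in :mod:`stagenet.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "StagenetError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneAnnotation",
    "StageLabels",
    "MIRankedEdgeList",
    "AnnotatedNetwork",
    "canonical_pair",
    "normalize_chromosome",
]


class StagenetError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(StagenetError):
    """An in-memory object violates its contract."""


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered gene pair in canonical (lexicographic) form.

    Raises
    ------
    ValidationError
        If the two genes are identical (self-loops are never valid edges).
    """
    if gene_a == gene_b:
        raise ValidationError(f"self-loop edge on gene {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def normalize_chromosome(label: str) -> str:
    """Canonicalise a chromosome label across annotation dialects.

    Strips an optional leading ``chr`` (any case) and case-folds, so
    ``"chr1"``/``"1"`` and ``"chrX"``/``"x"`` compare equal.  Anything
    else is kept verbatim: labels are otherwise opaque strings.
    """
    lab = label.strip()
    if lab[:3].lower() == "chr":
        lab = lab[3:]
    return lab.casefold()


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with aligned identifier lists.

    Holds either raw nonnegative counts or normalised (log2-CPM, hence
    possibly negative) values; values must be finite with no missing
    entries.  Operations that require counts check nonnegativity
    themselves.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids):
            raise ValidationError(
                f"row count {n_g} != number of gene ids {len(self.gene_ids)}"
            )
        if n_s != len(self.sample_ids):
            raise ValidationError(
                f"column count {n_s} != number of sample ids {len(self.sample_ids)}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = _first_duplicate(ids)
                raise ValidationError(f"duplicate {name} id {dup!r}")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values contain NaN or infinity")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(sample_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows, :], list(gene_ids), list(self.sample_ids))


@dataclass
class GeneAnnotation:
    """Mapping gene id -> chromosome label (labels are opaque strings)."""

    chromosomes: dict[str, str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.chromosomes

    def __getitem__(self, gene: str) -> str:
        return self.chromosomes[gene]

    def normalized(self, gene: str) -> str:
        return normalize_chromosome(self.chromosomes[gene])

    def same_chromosome(self, gene_a: str, gene_b: str) -> bool:
        return self.normalized(gene_a) == self.normalized(gene_b)

    @property
    def genes(self) -> list[str]:
        return list(self.chromosomes)


@dataclass
class StageLabels:
    """Sample -> phenotype labelling with a designated control phenotype.

    Phenotype order follows first appearance in the mapping, which is
    the generation / file order; the control label must be present.
    """

    mapping: dict[str, str]
    control: str

    def __post_init__(self) -> None:
        if self.control not in set(self.mapping.values()):
            raise ValidationError(
                f"control phenotype {self.control!r} has no samples"
            )

    @property
    def phenotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for ph in self.mapping.values():
            seen.setdefault(ph, None)
        return list(seen)

    def samples(self, phenotype: str) -> list[str]:
        if phenotype not in set(self.mapping.values()):
            raise ValidationError(f"unknown phenotype {phenotype!r}")
        return [s for s, ph in self.mapping.items() if ph == phenotype]


@dataclass
class MIRankedEdgeList:
    """Undirected weighted gene pairs ranked by descending mutual information.

    Canonical form: each pair stored with ``gene_a < gene_b``
    (lexicographic), the list sorted by MI descending with ties broken
    by ``(gene_a, gene_b)`` lexicographic — so top-N cut-offs are
    deterministic even under tied MI values.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "MIRankedEdgeList":
        """Canonicalise pair order, validate, and sort ranked."""
        seen: dict[tuple[str, str], float] = {}
        for a, b, mi in records:
            mi = float(mi)
            if not np.isfinite(mi) or mi < 0:
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) has invalid MI {mi!r} (must be finite, >= 0)"
                )
            pair = canonical_pair(str(a), str(b))
            if pair in seen:
                raise ValidationError(f"duplicate edge for pair {pair}")
            seen[pair] = mi
        edges = sorted(
            ((a, b, mi) for (a, b), mi in seen.items()),
            key=lambda e: (-e[2], e[0], e[1]),
        )
        return cls(edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.edges)

    def top(self, n: int) -> "MIRankedEdgeList":
        """The ``min(n, len)`` highest-MI edges (prefix of the ranking)."""
        if n < 1:
            raise ValidationError(f"top-N cutoff must be >= 1, got {n}")
        return MIRankedEdgeList(self.edges[:n])

    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out


@dataclass
class AnnotatedNetwork:
    """Edge list joined with chromosome annotation; each edge cis or trans.

    ``flags[i]`` is True when both endpoints of ``edges[i]`` share a
    (normalised) chromosome label — an intra-chromosome *cis-*
    interaction; False marks an inter-chromosome *trans-* interaction.
    """

    edges: list[tuple[str, str]]
    mi: list[float]
    flags: list[bool]
    annotation: GeneAnnotation

    def __post_init__(self) -> None:
        if not (len(self.edges) == len(self.mi) == len(self.flags)):
            raise ValidationError("edges, mi and flags must be aligned")
        for a, b in self.edges:
            if a not in self.annotation or b not in self.annotation:
                raise ValidationError(f"edge ({a!r}, {b!r}) has unannotated endpoint")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_cis(self) -> int:
        return int(sum(self.flags))

    @property
    def n_trans(self) -> int:
        return len(self.edges) - self.n_cis

    def edge_flag(self, i: int) -> str:
        return "cis" if self.flags[i] else "trans"


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate present")
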