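"""Edge-set intersections across phenotype networks and across cut-offs.

Networks are compared as sets of canonical unordered gene pairs (MI
values are ignored for membership), always at matched top-N sizes so
proportions are comparable.  The headline objects are the sub-network
of edges shared by *every* phenotype, the tumor-only ("cancer-only")
sub-network present in every non-control network but absent from
control, and the per-network specific edges — plus how the shared
proportions behave as the cut-off sweeps across network sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import MIRankedEdgeList, StagenetError

__all__ = [
    "IntersectionResult",
    "CutoffCurve",
    "intersect",
    "intersection_curve",
    "pairwise_divergence",
]

Edge = tuple[str, str]


@dataclass
class IntersectionResult:
    """Exact set algebra over a named collection of edge sets."""

    totals: dict[str, int]
    shared_all: set[Edge]
    group_specific: dict[str, set[Edge]]
    pairwise_shared: dict[tuple[str, str], int]
    regions: dict[frozenset, set[Edge]]
    cancer_only: set[Edge] | None = None

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_dict(self) -> dict:
        return {
            "totals": dict(self.totals),
            "n_shared_all": len(self.shared_all),
            "n_specific": {k: len(v) for k, v in self.group_specific.items()},
            "pairwise_shared": {f"{a}|{b}": n for (a, b), n in self.pairwise_shared.items()},
            "n_cancer_only": None if self.cancer_only is None else len(self.cancer_only),
            "regions": {"|".join(sorted(k)): len(v) for k, v in self.regions.items()},
        }


@dataclass
class CutoffCurve:
    """Shared-edge proportions as the top-N cut-off grows."""

    points: list[tuple[int, float, float]]  # (cutoff, shared_all, cancer_only)

    def cutoffs(self) -> list[int]:
        return [n for n, _, _ in self.points]

    def shared_all(self) -> list[float]:
        return [p for _, p, _ in self.points]

    def cancer_only(self) -> list[float]:
        return [q for _, _, q in self.points]


def intersect(
    networks: Mapping[str, set[Edge]], control_name: str | None = None
) -> IntersectionResult:
    """All Venn regions of a named collection of edge sets.

    ``cancer_only`` (edges in every non-control set, absent from
    control) is computed only when ``control_name`` is given.
    """
    if len(networks) < 2:
        raise StagenetError("need >= 2 networks to intersect")
    if control_name is not None and control_name not in networks:
        raise StagenetError(f"unknown control network {control_name!r}")
    names = list(networks)
    universe: set[Edge] = set().union(*networks.values())
    regions: dict[frozenset, set[Edge]] = {}
    for edge in universe:
        member = frozenset(n for n in names if edge in networks[n])
        regions.setdefault(member, set()).add(edge)
    all_names = frozenset(names)
    shared_all = set(regions.get(all_names, set()))
    group_specific = {n: set(regions.get(frozenset([n]), set())) for n in names}
    pairwise = {
        (a, b): len(networks[a] & networks[b])
        for a, b in itertools.combinations(names, 2)
    }
    cancer_only: set[Edge] | None = None
    if control_name is not None:
        tumor = [n for n in names if n != control_name]
        cancer_only = set.intersection(*(networks[n] for n in tumor)) - networks[control_name]
    return IntersectionResult(
        totals={n: len(networks[n]) for n in names},
        shared_all=shared_all,
        group_specific=group_specific,
        pairwise_shared=pairwise,
        regions=regions,
        cancer_only=cancer_only,
    )


def intersection_curve(
    ranked: Mapping[str, MIRankedEdgeList],
    cutoffs: Sequence[int],
    control_name: str | None = None,
) -> CutoffCurve:
    """Shared-all and cancer-only proportions at each top-N cut-off.

    Each proportion is the region size divided by the cut-off N, the
    matched size of every thresholded network.
    """
    cuts = list(cutoffs)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise StagenetError("cutoffs must be strictly increasing")
    points: list[tuple[int, float, float]] = []
    for n in cuts:
        sets = {name: edges.top(n).pairs() for name, edges in ranked.items()}
        res = intersect(sets, control_name)
        shared = len(res.shared_all) / n
        cancer = len(res.cancer_only) / n if res.cancer_only is not None else float("nan")
        points.append((n, shared, cancer))
    return CutoffCurve(points)


def pairwise_divergence(a: set[Edge], b: set[Edge]) -> float:
    """1 - |a & b| / |a| for two equal-size edge sets.

    The fraction of a network's edges not shared with the other — 0 for
    identical networks, 1 for disjoint ones.
    """
    if len(a) != len(b):
        raise StagenetError(f"edge sets must be equal size, got {len(a)} vs {len(b)}")
    if not a:
        raise StagenetError("divergence of empty edge sets is undefined")
    return 1.0 - len(a & b) / len(a)
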