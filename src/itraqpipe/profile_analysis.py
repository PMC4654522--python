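"""Set analytics over identifications and clustering of expression profiles.

Covers the three-stage Venn decomposition per tissue, tissue-specificity set
algebra, the shared-identification overlap percentage used to compare the
isobaric-label results with an orthogonal 2DE protein list, hierarchical
clustering of log2 ratio profiles, and classification of regulation patterns
across the stage-wise contrasts of the two tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quant_io import IdentificationSets
from .ratio_quant import (
    CALL_DOWN,
    CALL_UP,
    ComparisonResult,
    RatioMatrix,
)

# ---------------------------------------------------------------------- #
# Venn decomposition over the three stages of one tissue


@dataclass
class VennDecomposition:
    """Exact 7-cell partition of three per-stage identification sets.

    Cell keys are sorted stage tuples, e.g. ``(10,)`` for only-10DAP,
    ``(10, 20)`` for 10&20-but-not-33, ``(10, 20, 33)`` for the common core.
    """

    tissue: str
    stages: tuple[int, ...]
    cells: dict[tuple[int, ...], frozenset[str]]

    def count(self, *stages: int) -> int:
        return len(self.cells[tuple(sorted(stages))])

    def counts(self) -> dict[tuple[int, ...], int]:
        return {k: len(v) for k, v in self.cells.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def stage_total(self, stage: int) -> int:
        """Marginal: size of the full identification set of one stage."""
        return sum(len(v) for k, v in self.cells.items() if stage in k)

    def stage_specific_counts(self) -> dict[int, int]:
        return {s: self.count(s) for s in self.stages}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": "&".join(f"{s}DAP" for s in k), "count": len(v)}
            for k, v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def stage_venn(sets: IdentificationSets, tissue: str) -> VennDecomposition:
    """Decompose a tissue's three per-stage sets into the 7 disjoint Venn cells."""
    stages = tuple(sets.stages(tissue))
    if len(stages) != 3:
        raise ValueError(
            f"tissue {tissue!r} has {len(stages)} stage sets; need exactly 3"
        )
    by_stage = {s: sets.get(tissue, s) for s in stages}
    universe = frozenset().union(*by_stage.values())
    cells: dict[tuple[int, ...], set[str]] = {}
    for r in (1, 2, 3):
        from itertools import combinations

        for combo in combinations(stages, r):
            cells[tuple(combo)] = set()
    for acc in universe:
        member = tuple(s for s in stages if acc in by_stage[s])
        cells[member].add(acc)
    return VennDecomposition(
        tissue=tissue,
        stages=stages,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


def tissue_specific_sets(
    sets: IdentificationSets,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(pericarp_only, endosperm_only, shared) over the per-tissue stage unions.

    The three sets partition the overall nonredundant union.
    """
    pericarp = sets.tissue_union("pericarp")
    endosperm = sets.tissue_union("endosperm")
    shared = pericarp & endosperm
    return (pericarp - shared, endosperm - shared, shared)


def overlap_percentage(n_shared: int, n_total: int) -> float:
    """Percentage of one identification list recovered by another, to 2 dp.

    Used for the cross-method check against a 2DE spot list: of ``n_total``
    proteins identified by the orthogonal method, ``n_shared`` were also in
    the isobaric-label list.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_shared <= n_total):
        raise ValueError("n_shared must lie in [0, n_total]")
    return round(100.0 * n_shared / n_total, 2)


def set_overlap_percentage(query: Iterable[str], reference: Iterable[str]) -> float:
    """``overlap_percentage`` computed from explicit accession sets."""
    q = set(query)
    return overlap_percentage(len(q & set(reference)), len(q))


# ---------------------------------------------------------------------- #
# hierarchical clustering of log2 ratio profiles


@dataclass
class ClusterResult:
    """Deterministic agglomerative merge tree over protein log2 profiles."""

    metric: str
    linkage_method: str
    leaves: list[str]  # clusterable proteins, input (lexicographic) order
    linkage: np.ndarray  # scipy linkage matrix
    excluded: list[str]  # masked or zero-variance profiles

    def merges(self) -> list[tuple[frozenset[str], float]]:
        """Ordered (member set, height) per merge; heights are non-decreasing."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([p]) for i, p in enumerate(self.leaves)
        }
        out = []
        n = len(self.leaves)
        for k, (a, b, h, _) in enumerate(self.linkage):
            members = clusters[int(a)] | clusters[int(b)]
            clusters[n + k] = members
            out.append((members, float(h)))
        return out

    def canonical_merges(self) -> list[tuple[tuple[str, ...], float]]:
        """Serialization-stable view: sorted member tuples with rounded heights."""
        return [(tuple(sorted(m)), round(h, 10)) for m, h in self.merges()]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaves[i] for i in order]

    def newick(self) -> str:
        """Newick text with children ordered by smallest leaf label (canonical)."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node) -> tuple[str, str]:
            if node.is_leaf():
                label = self.leaves[node.id]
                return label, label
            left, lmin = fmt(node.left)
            right, rmin = fmt(node.right)
            if rmin < lmin:
                left, right = right, left
                lmin = rmin
            return f"({left},{right}):{node.dist:.6g}", lmin

        text, _ = fmt(tree)
        return text + ";"

    def write(self, tree_path: str | Path, matrix: pd.DataFrame | None = None,
              ordered_matrix_path: str | Path | None = None) -> None:
        Path(tree_path).write_text(self.newick() + "\n")
        if matrix is not None and ordered_matrix_path is not None:
            matrix.loc[self.leaf_order()].to_csv(
                ordered_matrix_path, sep="\t", index_label="accession",
                lineterminator="\n",
            )


def cluster_profiles(
    matrix: RatioMatrix,
    metric: str = "correlation",
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster fully-observed log2 ratio profiles.

    Pearson-correlation distance with average linkage by default, mirroring the
    common defaults of the classic Cluster 3.0 workflow.  Proteins with any
    masked cell, or with zero profile variance (correlation undefined), are
    excluded and reported.
    """
    log2 = matrix.log2()
    full = log2.dropna(axis=0, how="any")
    excluded = [p for p in matrix.proteins if p not in set(full.index)]
    if metric == "correlation":
        variances = full.var(axis=1, ddof=0)
        flat = variances[variances == 0.0].index.tolist()
        excluded += flat
        full = full.drop(index=flat)
    if len(full) < 2:
        raise ValueError(
            f"need at least 2 clusterable profiles, have {len(full)} "
            f"({len(excluded)} excluded)"
        )
    # lexicographic leaf order makes the tree independent of input order
    full = full.loc[sorted(full.index)]
    dist = pdist(full.values, metric=metric)
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    Z = hierarchy.linkage(dist, method=linkage_method)
    return ClusterResult(
        metric=metric,
        linkage_method=linkage_method,
        leaves=list(full.index),
        linkage=Z,
        excluded=sorted(excluded),
    )


# ---------------------------------------------------------------------- #
# regulation-pattern classification across tissues

MODE_INTERSECTION = "intersection"
MODE_UNION = "union"

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NONE = "none"
STATUS_MIXED = "mixed"

#: stage-wise contrasts per tissue under the default six-sample design
TISSUE_STAGE_COMPARISONS = {
    "pericarp": ("N2/N1", "N3/N2"),
    "endosperm": ("N5/N4", "N6/N5"),
}


@dataclass
class PatternPartition:
    """Cross-tissue regulation classes over per-tissue direction statuses.

    ``tissue_status[t][acc]`` is up/down (consistently or at-least-once DE in
    that direction, per mode), mixed (union mode: both directions seen), or
    none.  ``classes`` maps (pericarp_status, endosperm_status) pairs to the
    member sets; the named accessors expose the classes the study reports.
    """

    mode: str
    tissue_status: dict[str, dict[str, str]]
    classes: dict[tuple[str, str], frozenset[str]]

    def class_members(self, pericarp: str, endosperm: str) -> frozenset[str]:
        return self.classes.get((pericarp, endosperm), frozenset())

    @property
    def both_down(self) -> frozenset[str]:
        return self.class_members(STATUS_DOWN, STATUS_DOWN)

    @property
    def both_up(self) -> frozenset[str]:
        return self.class_members(STATUS_UP, STATUS_UP)

    @property
    def endosperm_only_up(self) -> frozenset[str]:
        return self.class_members(STATUS_NONE, STATUS_UP)

    @property
    def pericarp_only_up(self) -> frozenset[str]:
        return self.class_members(STATUS_UP, STATUS_NONE)

    @property
    def endosperm_only_down(self) -> frozenset[str]:
        return self.class_members(STATUS_NONE, STATUS_DOWN)

    @property
    def pericarp_only_down(self) -> frozenset[str]:
        return self.class_members(STATUS_DOWN, STATUS_NONE)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pericarp": p,
                "endosperm": e,
                "count": len(members),
            }
            for (p, e), members in sorted(self.classes.items())
        ]
        return pd.DataFrame(rows)


def _tissue_direction(calls: list[pd.Series], acc: str, mode: str) -> str:
    states = [c.get(acc, None) for c in calls]
    n_up = sum(1 for s in states if s == CALL_UP)
    n_down = sum(1 for s in states if s == CALL_DOWN)
    if mode == MODE_INTERSECTION:
        if n_up == len(states):
            return STATUS_UP
        if n_down == len(states):
            return STATUS_DOWN
        return STATUS_NONE
    # union mode
    if n_up and n_down:
        return STATUS_MIXED
    if n_up:
        return STATUS_UP
    if n_down:
        return STATUS_DOWN
    return STATUS_NONE


def regulation_patterns(
    comparisons: Mapping[str, ComparisonResult],
    mode: str = MODE_INTERSECTION,
    tissue_comparisons: Mapping[str, Sequence[str]] = TISSUE_STAGE_COMPARISONS,
) -> PatternPartition:
    """Classify proteins by direction of regulation in each tissue.

    Intersection mode requires the same DE direction in *all* of a tissue's
    stage contrasts; union mode requires it in at least one (a protein DE in
    both directions within a tissue is 'mixed').  Cross-tissue classes are the
    cartesian statuses; proteins with status none in both tissues are not
    classified.
    """
    if mode not in (MODE_INTERSECTION, MODE_UNION):
        raise ValueError(f"unknown mode {mode!r}")
    tissue_calls: dict[str, list[pd.Series]] = {}
    universe: set[str] = set()
    for tissue, cids in tissue_comparisons.items():
        calls = []
        for cid in cids:
            if cid not in comparisons:
                raise KeyError(f"comparison {cid!r} required for tissue {tissue!r}")
            calls.append(comparisons[cid].calls)
            universe.update(comparisons[cid].calls.index)
        tissue_calls[tissue] = calls

    tissues = list(tissue_comparisons)
    status: dict[str, dict[str, str]] = {t: {} for t in tissues}
    classes: dict[tuple[str, str], set[str]] = {}
    for acc in sorted(universe):
        sig = tuple(_tissue_direction(tissue_calls[t], acc, mode) for t in tissues)
        for t, s in zip(tissues, sig):
            status[t][acc] = s
        if all(s == STATUS_NONE for s in sig):
            continue
        classes.setdefault(sig, set()).add(acc)

    return PatternPartition(
        mode=mode,
        tissue_status=status,
        classes={k: frozenset(v) for k, v in classes.items()},
    )
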