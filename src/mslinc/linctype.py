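"""Staged correlation-based feature selection for the Linctype marker panel.

The panel is the union of four stages of marker selection over the filtered
FPKM matrix:

1. CFS + best-first search against the binary cancer/control labelling;
2. the same search restricted to stage-1 output against the six-class
   labelling (five tumor subtypes + control);
3. per subtype, a one-vs-rest search over features not already selected;
4. the transcripts with the most extreme (lowest / highest) mean expression
   across the cancer samples.

CFS scores a feature subset S by Merit(S) = k*mean(SU_cf) /
sqrt(k + k(k-1)*mean(SU_ff)) where SU is the symmetrical uncertainty of
equal-frequency discretised expression, balancing class relevance against
between-feature redundancy.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import TUMOR_GROUPS

__all__ = [
    "discretize",
    "symmetrical_uncertainty",
    "cfs_merit",
    "CfsEvaluator",
    "best_first_search",
    "LinctypePanel",
    "select_linctype",
]


def discretize(values: Sequence[float], bins: int = 3) -> np.ndarray:
    """Equal-frequency binning into ``bins`` labels (0-based).

    Bin edges are the within-bin maxima of the sorted values; values equal
    to an edge fall in the lower bin, so permuting the samples permutes the
    labels identically and a constant vector maps to a single bin.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.sort(values)
    edges = [order[max(0, int(round(n * k / bins)) - 1)] for k in range(1, bins)]
    return np.searchsorted(np.asarray(edges), values, side="left").astype(np.int64)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X;Y) = 2*I(X;Y) / (H(X)+H(Y)) on discrete labels, natural log.

    Ranges over [0, 1]; 0 for independent (product-form) tables and for any
    constant argument, 1 when each variable determines the other.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    hx = _entropy(x)
    hy = _entropy(y)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    hxy = float(-(joint[joint > 0] * np.log(joint[joint > 0])).sum())
    mi = max(hx + hy - hxy, 0.0)
    return min(2.0 * mi / (hx + hy), 1.0)


def cfs_merit(su_cf: Sequence[float], su_ff_mean: float) -> float:
    """CFS merit from the mean feature-class SU values and the mean pairwise
    feature-feature SU of the subset (k = len(su_cf))."""
    k = len(su_cf)
    if k == 0:
        raise ValueError("merit of an empty subset is undefined")
    r_cf = float(np.mean(su_cf))
    denom = math.sqrt(k + k * (k - 1) * su_ff_mean)
    return k * r_cf / denom


class CfsEvaluator:
    """Caches discretised features and SU values for CFS merit evaluation."""

    def __init__(self, features: pd.DataFrame, labels: Sequence, bins: int = 3):
        """``features``: transcripts x samples; ``labels``: one per sample."""
        self.ids = list(features.index)
        self._bins = {
            fid: discretize(features.loc[fid].to_numpy(), bins) for fid in self.ids
        }
        self._class = np.unique(np.asarray(labels), return_inverse=True)[1]
        self._su_cf: dict[str, float] = {}
        self._su_ff: dict[frozenset, float] = {}

    def su_cf(self, fid: str) -> float:
        if fid not in self._su_cf:
            self._su_cf[fid] = symmetrical_uncertainty(self._bins[fid], self._class)
        return self._su_cf[fid]

    def su_ff(self, f1: str, f2: str) -> float:
        key = frozenset((f1, f2))
        if key not in self._su_ff:
            self._su_ff[key] = symmetrical_uncertainty(self._bins[f1], self._bins[f2])
        return self._su_ff[key]

    def merit(self, subset: Sequence[str]) -> float:
        subset = list(subset)
        if not subset:
            return 0.0
        su_cf = [self.su_cf(f) for f in subset]
        k = len(subset)
        if k == 1:
            return cfs_merit(su_cf, 0.0)
        pair_sum = sum(
            self.su_ff(subset[i], subset[j])
            for i in range(k)
            for j in range(i + 1, k)
        )
        return cfs_merit(su_cf, pair_sum / (k * (k - 1) / 2))


def best_first_search(
    evaluator: CfsEvaluator,
    max_stale: int = 5,
    candidates: Sequence[str] | None = None,
) -> tuple[list[str], float]:
    """Forward best-first search over the feature-subset lattice.

    Starts from the empty set, expands by single-feature addition, keeps an
    open list ordered by merit and stops after ``max_stale`` consecutive
    expansions that fail to improve the best merit seen.  Ties break by
    feature id, making the search fully deterministic.  Returns the best
    subset (sorted) and its merit; the subset may be empty when no feature
    carries any class information.
    """
    pool = sorted(candidates) if candidates is not None else sorted(evaluator.ids)
    if not pool:
        raise ValueError("best_first_search requires a non-empty feature list")
    start: frozenset = frozenset()
    open_heap: list[tuple[float, tuple, frozenset]] = [(0.0, (), start)]
    closed: set[frozenset] = set()
    best_subset, best_merit = start, 0.0
    stale = 0
    while open_heap and stale < max_stale:
        _, _, node = heapq.heappop(open_heap)
        if node in closed:
            continue
        closed.add(node)
        improved = False
        for fid in pool:
            if fid in node:
                continue
            child = node | {fid}
            if child in closed:
                continue
            merit = evaluator.merit(sorted(child))
            heapq.heappush(open_heap, (-merit, tuple(sorted(child)), child))
            if merit > best_merit + 1e-10:
                best_subset, best_merit = child, merit
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
    return sorted(best_subset), best_merit


@dataclass
class LinctypePanel:
    """Ordered marker panel with per-member stage provenance."""

    members: list[str]
    provenance: dict[str, list[str]]
    stage_sizes: dict[str, int]
    stage_merits: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.members,
                "provenance": [";".join(self.provenance[m]) for m in self.members],
            }
        )


def select_linctype(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    n_low: int = 6,
    n_high: int = 3,
    bins: int = 3,
    max_stale: int = 5,
) -> LinctypePanel:
    """Construct the Linctype panel by the four-stage selection.

    ``matrix`` is the low-expression-filtered FPKM matrix; ``meta`` must
    label every sample with a group covering all five tumor subtypes and at
    least one control group.  Provenance tags are ``two_class``,
    ``six_class``, ``subtype_specific:<subtype>``, ``extreme_low`` and
    ``extreme_high``; a member may carry several.
    """
    groups = meta.loc[matrix.columns, "group"]
    is_tumor = groups.isin(TUMOR_GROUPS)
    missing = set(TUMOR_GROUPS) - set(groups[is_tumor])
    if missing or not (~is_tumor).any():
        raise ValueError(
            f"metadata must cover all five subtypes and a control group "
            f"(missing: {sorted(missing) or 'controls'})"
        )
    log_expr = np.log2(matrix + 1.0)

    provenance: dict[str, list[str]] = {}
    merits: dict[str, float] = {}

    def tag(ids, label):
        for fid in ids:
            provenance.setdefault(fid, []).append(label)

    # stage 1: cancer vs control
    two_class = np.where(is_tumor, "cancer", "control")
    ev1 = CfsEvaluator(log_expr, two_class, bins)
    stage1, merits["two_class"] = best_first_search(ev1, max_stale)
    tag(stage1, "two_class")

    # stage 2: six classes, restricted to stage-1 output
    six_class = np.where(is_tumor, groups, "control")
    stage2: list[str] = []
    if stage1:
        ev2 = CfsEvaluator(log_expr.loc[stage1], six_class, bins)
        stage2, merits["six_class"] = best_first_search(ev2, max_stale)
        tag(stage2, "six_class")

    # stage 3: per-subtype one-vs-rest over features not already selected in
    # stages 1-2; the five searches are independent of each other, so the
    # outcome does not depend on subtype order
    selected = set(stage1) | set(stage2)
    remaining = [fid for fid in log_expr.index if fid not in selected]
    stage3: dict[str, list[str]] = {}
    for subtype in TUMOR_GROUPS:
        if not remaining:
            stage3[subtype] = []
            continue
        ovr = np.where(groups == subtype, subtype, "rest")
        ev3 = CfsEvaluator(log_expr.loc[remaining], ovr, bins)
        picked, merits[f"subtype_specific:{subtype}"] = best_first_search(ev3, max_stale)
        stage3[subtype] = picked
        tag(picked, f"subtype_specific:{subtype}")

    # stage 4: expression extremes among cancer samples
    cancer_mean = log_expr.loc[:, is_tumor.to_numpy()].mean(axis=1).sort_values(kind="stable")
    low = list(cancer_mean.index[:n_low]) if n_low else []
    high = list(cancer_mean.index[::-1][:n_high]) if n_high else []
    tag(low, "extreme_low")
    tag(high, "extreme_high")

    members = list(provenance)
    stage_sizes = {
        "two_class": len(stage1),
        "six_class": len(stage2),
        **{f"subtype_specific:{s}": len(v) for s, v in stage3.items()},
        "extreme_low": len(low),
        "extreme_high": len(high),
    }
    return LinctypePanel(members, provenance, stage_sizes, merits)
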