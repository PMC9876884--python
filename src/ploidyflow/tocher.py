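"""Tocher clustering (optimized) on Euclidean distances.

The Tocher method partitions accessions with a data-driven inclusion
limit theta: the largest nearest-neighbour distance over all accessions.
Groups are seeded from the closest ungrouped pair; the candidate whose
mean distance to the current group is smallest is admitted while that
mean stays within theta; when no candidate fits, the group closes and a
new one is seeded.  The "optimized" variant adds a reassignment pass:
each accession may move to the group that lowers its mean within-group
distance, and passes repeat to a fixed point.

A move is accepted only when it (i) strictly lowers the mover's own mean
within-group distance, (ii) lands it at a mean distance <= theta to the
target group, and (iii) does not increase the total over accessions of
mean within-group distance.  Condition (iii) makes the refinement
monotone in the total objective (a per-item improvement alone can raise
other members' means).  Ties in seeding, admission and target choice are
broken by ascending id.

Clustering here is univariate (2C or GC% evaluated separately), so the
Euclidean distance reduces to |v_i - v_j|; the grouping is invariant to
positive rescaling of the variable only up to theta, which rescales with
it — memberships are scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

__all__ = ["DistanceMatrix", "TocherGrouping", "euclidean_distances", "tocher_optimized"]

_EPS = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if (d < 0).any() or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))


@dataclass(frozen=True)
class TocherGrouping:
    groups: tuple[tuple[str, ...], ...]  # partition of ids
    theta: float
    group_mean_intra: tuple[float, ...]  # mean pairwise distance per group
    admission_means: tuple[tuple[float, ...], ...]  # per group, per admitted member

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def assignment(self) -> dict[str, int]:
        return {i: g for g, members in enumerate(self.groups) for i in members}


def euclidean_distances(values: Sequence[tuple[str, float]]) -> DistanceMatrix:
    """Pairwise Euclidean distances for one variable: d(i,j) = |v_i - v_j|."""
    if len(values) < 1:
        raise ValueError("need at least one value")
    ids = [str(i) for i, _ in values]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in values")
    v = np.array([x for _, x in values], float)
    return DistanceMatrix(tuple(ids), np.abs(v[:, None] - v[None, :]))


def _mean_to_group(d: np.ndarray, i: int, group: list[int]) -> float:
    others = [j for j in group if j != i]
    if not others:
        return 0.0
    return float(d[i, others].mean())


def _total_objective(d: np.ndarray, groups: list[list[int]]) -> float:
    return sum(_mean_to_group(d, i, g) for g in groups for i in g)


def tocher_optimized(dm: DistanceMatrix, refine: bool = True, max_passes: int = 200) -> TocherGrouping:
    """Partition ids by the (optimized) Tocher method.

    theta is computed once from the full matrix as the maximum over ids of
    the nearest-neighbour distance.  With ``refine=False`` only the
    classical sequential construction runs.
    """
    n = len(dm.ids)
    d = dm.d
    # preference order for tie-breaking: ascending id
    pref = sorted(range(n), key=lambda i: dm.ids[i])
    rank = {i: r for r, i in enumerate(pref)}

    if n == 1:
        return TocherGrouping(((dm.ids[0],),), 0.0, (0.0,), ((0.0,),))

    nn = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1)
    theta = float(nn.max())

    ungrouped = set(range(n))
    groups: list[list[int]] = []
    admissions: list[list[float]] = []
    while ungrouped:
        if len(ungrouped) == 1:
            i = next(iter(ungrouped))
            groups.append([i])
            admissions.append([0.0])
            break
        rem = sorted(ungrouped, key=lambda i: rank[i])
        best_pair, best_d = None, np.inf
        for ai, i in enumerate(rem):
            for j in rem[ai + 1:]:
                if d[i, j] < best_d - _EPS:
                    best_pair, best_d = (i, j), d[i, j]
        if best_d > theta + _EPS:
            # every remaining pair exceeds theta: all singletons
            for i in rem:
                groups.append([i])
                admissions.append([0.0])
            break
        group = list(best_pair)
        adm = [0.0, float(best_d)]
        ungrouped -= set(group)
        while ungrouped:
            cand = sorted(ungrouped, key=lambda i: rank[i])
            means = [(float(d[i, group].mean()), i) for i in cand]
            m, i = min(means, key=lambda t: (t[0], rank[t[1]]))
            if m <= theta + _EPS:
                group.append(i)
                adm.append(m)
                ungrouped.discard(i)
            else:
                break
        groups.append(group)
        admissions.append(adm)

    if refine and len(groups) > 1:
        total = _total_objective(d, groups)
        for _ in range(max_passes):
            moved = False
            for i in pref:
                gi = next(g for g, mem in enumerate(groups) if i in mem)
                if len(groups[gi]) == 1 and len(groups) == 1:
                    continue
                own = _mean_to_group(d, i, groups[gi])
                best = None
                for gj, mem in enumerate(groups):
                    if gj == gi or not mem:
                        continue
                    m = float(d[i, mem].mean())
                    if m < own - _EPS and m <= theta + _EPS:
                        if best is None or m < best[0] - _EPS:
                            best = (m, gj)
                if best is None:
                    continue
                _, gj = best
                trial = [list(g) for g in groups]
                trial[gi].remove(i)
                trial[gj].append(i)
                trial = [g for g in trial if g]
                new_total = _total_objective(d, trial)
                if new_total <= total + _EPS:
                    groups = trial
                    total = new_total
                    moved = True
            if not moved:
                break
        admissions = None  # recomputed below for refined groups

    # order groups by their lowest-ranked member for stable output
    order = sorted(range(len(groups)), key=lambda g: min(rank[i] for i in groups[g]))
    groups = [sorted(groups[g], key=lambda i: rank[i]) for g in order]
    if admissions is None:
        admissions = [
            [_mean_to_group(d, i, g[: k + 1]) for k, i in enumerate(g)] for g in groups
        ]
    else:
        admissions = [admissions[g] for g in order]

    intra = []
    for g in groups:
        if len(g) < 2:
            intra.append(0.0)
        else:
            idx = np.array(g)
            sub = d[np.ix_(idx, idx)]
            intra.append(float(sub[np.triu_indices(len(g), 1)].mean()))

    return TocherGrouping(
        groups=tuple(tuple(dm.ids[i] for i in g) for g in groups),
        theta=theta,
        group_mean_intra=tuple(intra),
        admission_means=tuple(tuple(a) for a in admissions),
    )
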