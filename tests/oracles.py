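"""Independent reference implementations used as test oracles.

These deliberately take different computational routes from the library code
they check: the merged-segment axis comes from a numpy eigen-decomposition
(the library accumulates a closed-form 2x2 scatter), and the merge schedule
is an exhaustive enumeration of every pairwise merge order rather than the
library's deterministic index-order scan.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from helipick.trace_extraction import LineSegment, _mergeable

Member = Tuple[float, float, float, float]


def pca_merge_members(members: Sequence[Member]) -> Member:
    """Merged segment from constituents via numpy PCA of their endpoints."""
    M = np.asarray(members, dtype=float)
    d = M[:, 2:] - M[:, :2]
    w = np.hypot(d[:, 0], d[:, 1])
    keep = w > 0
    Mk, wk = M[keep], w[keep]
    mids = 0.5 * (Mk[:, :2] + Mk[:, 2:])
    c = (mids * wk[:, None]).sum(0) / wk.sum()
    pts = np.vstack([M[:, :2], M[:, 2:]])
    centred = (np.vstack([Mk[:, :2], Mk[:, 2:]]) - c)
    wgt = np.concatenate([wk, wk]) * 0.5
    scatter = (centred * wgt[:, None]).T @ centred
    evals, evecs = np.linalg.eigh(scatter)
    u = evecs[:, int(np.argmax(evals))]
    t = (pts - c) @ u
    p1 = c + t.min() * u
    p2 = c + t.max() * u
    return (float(p1[0]), float(p1[1]), float(p2[0]), float(p2[1]))


def _segment_for(state: FrozenSet[int], base: Sequence[Member]) -> LineSegment:
    members = [base[k] for k in sorted(state)]
    if len(members) == 1:
        return LineSegment(*members[0])
    seg = LineSegment(*pca_merge_members(members))
    seg._members = tuple(sorted(members))
    return seg


def enumerate_fixed_points(
    base: Sequence[Member], merge_angle_deg: float, merge_dist: float
) -> Tuple[Set[FrozenSet[FrozenSet[int]]], Dict]:
    """All partitions reachable by exhausting pairwise merges in any order.

    Returns the set of reachable fixed-point partitions (each a frozenset of
    frozensets of original segment indices) and a memo mapping partitions to
    their constructed segments.
    """
    results: Set[FrozenSet[FrozenSet[int]]] = set()
    seen: Set[Tuple[FrozenSet[int], ...]] = set()
    segs_memo: Dict[FrozenSet[int], LineSegment] = {}

    def seg_of(state: FrozenSet[int]) -> LineSegment:
        if state not in segs_memo:
            segs_memo[state] = _segment_for(state, base)
        return segs_memo[state]

    def rec(partition: Tuple[FrozenSet[int], ...]):
        if partition in seen:
            return
        seen.add(partition)
        cur = [seg_of(s) for s in partition]
        pairs = [
            (i, j)
            for i in range(len(cur))
            for j in range(i + 1, len(cur))
            if _mergeable(cur[i], cur[j], merge_angle_deg, merge_dist)
        ]
        if not pairs:
            results.add(frozenset(partition))
            return
        for i, j in pairs:
            merged = partition[i] | partition[j]
            rest = [partition[k] for k in range(len(partition)) if k not in (i, j)]
            rec(tuple(sorted(rest + [merged], key=lambda s: tuple(sorted(s)))))

    rec(tuple(frozenset([k]) for k in range(len(base))))
    return results, segs_memo


def canonical_endpoints(segments: Sequence[LineSegment], ndigits: int = 6):
    """Order-independent canonical form of a segment set for comparison."""
    out = []
    for s in segments:
        ends = sorted(
            [(round(s.x1, ndigits), round(s.y1, ndigits)),
             (round(s.x2, ndigits), round(s.y2, ndigits))]
        )
        out.append(tuple(ends))
    return tuple(sorted(out))


def segment_sets_close(a, b, tol: float = 1e-6) -> bool:
    """Compare two canonical segment tuples with a coordinate tolerance."""
    if len(a) != len(b):
        return False
    return all(
        abs(u - v) <= tol
        for sa, sb in zip(a, b)
        for pa, pb in zip(sa, sb)
        for u, v in zip(pa, pb)
    )


def random_merge_instance(rng: np.random.Generator) -> List[Member]:
    """A random merging test case of at most five segments.

    Half the instances are near-collinear chains with jittered angles, gaps
    and lateral offsets (the configuration merging exists for); the rest are
    unstructured random segments.
    """
    n = int(rng.integers(1, 6))
    segs: List[Member] = []
    if rng.random() < 0.5:
        x0, y0 = rng.uniform(0, 50, 2)
        th = rng.uniform(0, np.pi)
        s = 0.0
        for _ in range(n):
            length = rng.uniform(5, 20)
            gap = rng.uniform(-2, 6)
            dth = th + rng.uniform(-0.12, 0.12)
            off = rng.uniform(-2, 2)
            px = x0 + (s + gap) * np.cos(th) - off * np.sin(th)
            py = y0 + (s + gap) * np.sin(th) + off * np.cos(th)
            qx = px + length * np.cos(dth)
            qy = py + length * np.sin(dth)
            segs.append((float(px), float(py), float(qx), float(qy)))
            s += gap + length
    else:
        for _ in range(n):
            x1, y1 = rng.uniform(0, 100, 2)
            length = rng.uniform(5, 30)
            th = rng.uniform(0, np.pi)
            segs.append(
                (float(x1), float(y1),
                 float(x1 + length * np.cos(th)), float(y1 + length * np.sin(th)))
            )
    return segs
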