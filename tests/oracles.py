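"""Independent brute-force reference implementations for the summary measures.

Everything here is deliberately written the slow, obvious way — python loops
over voxel tuples, breadth-first searches over explicit sets, scipy.linalg
(not numpy.linalg) for the SVD — so it shares no code path with the package.
``tail=+1`` reproduces the standard upper-tail rules; ``tail=-1`` applies the
mirrored (lower-tail) rules used by the sign-flip invariance check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import scipy.linalg
from scipy import stats as sps


def voxels_of(mask: np.ndarray) -> list[tuple[int, int, int]]:
    return [tuple(int(i) for i in v) for v in np.argwhere(mask)]


def neighbors26(v, shape):
    x, y, z = v
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[i] < shape[i] for i in range(3)):
                    yield nb


def bfs_component(members: set, start) -> set:
    """26-connected component of ``start`` within ``members``."""
    seen = {start}
    queue = deque([start])
    shape = (10**9, 10**9, 10**9)
    while queue:
        v = queue.popleft()
        for nb in neighbors26(v, shape):
            if nb in members and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen


def oracle_peak(t: np.ndarray, roi: np.ndarray, tail: int = 1):
    """Exhaustive-scan argmax of tail*t with lexicographic tie break."""
    vox = voxels_of(roi)
    return sorted(vox, key=lambda v: (-tail * t[v], v))[0]


def _candidates(t, roi, df, variant, p, tail):
    vox = voxels_of(roi)
    if variant == "A":
        return vox
    crit = sps.t.ppf(1.0 - p, df)
    return [v for v in vox if tail * t[v] > crit]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def oracle_measure(
    measure_id: int,
    beta: np.ndarray,
    t: np.ndarray,
    roi: np.ndarray,
    df: int,
    grid,
    variant: str = "A",
    p: float = 0.05,
    q: float | None = None,
    n: int | None = None,
    radius_mm: float | None = None,
    corr_r: float | None = None,
    series: np.ndarray | None = None,
    tail: int = 1,
):
    """Brute-force value of one measure, or None when missing."""
    cand = _candidates(t, roi, df, variant, p, tail)
    roi_vox = voxels_of(roi)
    peak = oracle_peak(t, roi, tail)

    if measure_id in (1, 2):
        if not cand:
            return None
        vals = [beta[v] for v in cand]
        return float(np.mean(vals) if measure_id == 1 else np.median(vals))

    if measure_id == 3:
        if not cand:
            return None
        M = np.array([series[v] - np.mean(series[v]) for v in cand]).T  # T x V
        _, _, vt = scipy.linalg.svd(M, full_matrices=False)
        w = vt[0]
        if w.sum() < 0:
            w = -w
        return float(sum(wi * beta[v] for wi, v in zip(w, cand)) / w.sum())

    if measure_id == 4:
        if not cand:
            return None
        k = math.ceil(q / 100.0 * len(cand))
        top = sorted(cand, key=lambda v: (-tail * t[v], v))[:k]
        return float(np.mean([beta[v] for v in top]))

    if measure_id == 5:
        return float(beta[peak])

    if measure_id == 6:
        target = min(n, len(roi_vox))
        roi_set = set(roi_vox)
        grown = {peak}
        while len(grown) < target:
            frontier = [
                v
                for v in roi_set - grown
                if any(nb in grown for nb in neighbors26(v, beta.shape))
            ]
            if not frontier:
                break
            grown.add(sorted(frontier, key=lambda v: (-tail * t[v], v))[0])
        return float(np.mean([beta[v] for v in grown]))

    if measure_id == 7:
        center = grid.ijk_to_mm(peak)
        keep = [
            v
            for v in cand
            if np.linalg.norm(grid.ijk_to_mm(v) - center) <= radius_mm
        ]
        if not keep:
            return None
        return float(np.mean([beta[v] for v in keep]))

    if measure_id == 8:
        if not cand:
            return None
        kept = {v for v in cand if _corr(series[v], series[peak]) >= corr_r}
        if np.std(series[peak]) > 0:
            kept.add(peak)
        if peak not in kept:
            return None
        comp = bfs_component(kept, peak)
        return float(np.mean([beta[v] for v in comp]))

    if measure_id in (9, 10):
        supra = set(_candidates(t, roi, df, "B", p, tail))
        if not supra:
            return None
        comp = bfs_component(supra, peak)
        if measure_id == 9:
            return float(np.mean([beta[v] for v in comp]))
        return float(len(comp))

    raise ValueError(measure_id)
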