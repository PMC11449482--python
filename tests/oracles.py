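"""Naive brute-force reference implementations used as test oracles.

Each function here recomputes a pipeline primitive by the most direct
method available (explicit window loops, python sorting, per-threshold
relabeling) so the optimized implementations can be checked bit-for-bit
on small inputs.  These are deliberately slow and independent of the
package's code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from skimage.measure import label as sk_label


def naive_grey_opening_2d(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion then dilation with explicit loops; out-of-bounds ignored."""
    h, w = img.shape
    fh, fw = footprint.shape
    rh, rw = fh // 2, fw // 2
    offsets = [(i - rh, j - rw) for i in range(fh) for j in range(fw) if footprint[i, j]]

    def erode(a):
        out = np.empty_like(a, dtype=float)
        for y in range(h):
            for x in range(w):
                vals = [
                    a[y + dy, x + dx]
                    for dy, dx in offsets
                    if 0 <= y + dy < h and 0 <= x + dx < w
                ]
                out[y, x] = min(vals)
        return out

    def dilate(a):
        out = np.empty_like(a, dtype=float)
        for y in range(h):
            for x in range(w):
                vals = [
                    a[y + dy, x + dx]
                    for dy, dx in offsets
                    if 0 <= y + dy < h and 0 <= x + dx < w
                ]
                out[y, x] = max(vals)
        return out

    return dilate(erode(np.asarray(img, dtype=float)))


def naive_tophat_2d(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float) - naive_grey_opening_2d(img, footprint)


def naive_median_2d(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Sorted-window median with edge replication (matches mode='nearest')."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    fh, fw = footprint.shape
    rh, rw = fh // 2, fw // 2
    padded = np.pad(img, ((rh, rh), (rw, rw)), mode="edge")
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            window = padded[y : y + fh, x : x + fw][footprint.astype(bool)]
            out[y, x] = np.median(np.sort(window))
    return out


def naive_binary_opening_3d(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Binary erosion + dilation with explicit loops, zero-padded border."""
    mask = np.asarray(mask, dtype=bool)
    sz, sy, sx = selem.shape
    rz, ry, rx = sz // 2, sy // 2, sx // 2
    offsets = [
        (i - rz, j - ry, k - rx)
        for i in range(sz)
        for j in range(sy)
        for k in range(sx)
        if selem[i, j, k]
    ]
    nz, ny, nx = mask.shape

    def inside(z, y, x):
        return 0 <= z < nz and 0 <= y < ny and 0 <= x < nx

    eroded = np.zeros_like(mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                eroded[z, y, x] = all(
                    inside(z + dz, y + dy, x + dx) and mask[z + dz, y + dy, x + dx]
                    for dz, dy, dx in offsets
                )
    dilated = np.zeros_like(mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                dilated[z, y, x] = any(
                    inside(z + dz, y + dy, x + dx) and eroded[z + dz, y + dy, x + dx]
                    for dz, dy, dx in offsets
                )
    return dilated


def threshold_components(volume: np.ndarray, threshold: float) -> list[frozenset]:
    """26-connected components of ``volume >= threshold`` as voxel sets."""
    lab = sk_label(np.asarray(volume) >= threshold, connectivity=3)
    comps = []
    for i in range(1, lab.max() + 1):
        comps.append(frozenset(map(tuple, np.argwhere(lab == i))))
    return comps


def naive_mser_selection(
    volume: np.ndarray,
    levels: int,
    volume_min: int,
    volume_max: int,
    delta: int,
) -> list[frozenset]:
    """Independent set-based reimplementation of the stable-region pick.

    Builds the per-threshold component forest with python dicts/sets,
    scores stability (ancestor side via parents, descendant side via
    single-child chains, one-sided fallbacks, 0 when isolated) and
    greedily accepts candidates by (stability, volume, level) subject to
    pairwise non-nesting.
    """
    volume = np.asarray(volume, dtype=float)
    nonzero = volume[volume > 0]
    if nonzero.size == 0 or np.ptp(volume) == 0:
        return []
    thresholds = np.unique(np.linspace(float(nonzero.min()), float(nonzero.max()), levels))
    per_level = [threshold_components(volume, t) for t in thresholds]
    nodes = []  # (level, comp_set)
    parent: list[int] = []
    for li, comps in enumerate(per_level):
        for comp in comps:
            nid = len(nodes)
            nodes.append((li, comp))
            if li == 0:
                parent.append(-1)
            else:
                rep = next(iter(comp))
                pl = [
                    j
                    for j, (lj, cj) in enumerate(nodes)
                    if lj == li - 1 and rep in cj
                ]
                parent.append(pl[0])
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        children.setdefault(p, []).append(i)

    def ancestor(i, steps):
        for _ in range(steps):
            i = parent[i]
            if i < 0:
                return None
        return i

    def descendant(i, steps):
        for _ in range(steps):
            ch = children.get(i, [])
            if len(ch) != 1:
                return None
            i = ch[0]
        return i

    def score(i):
        v = len(nodes[i][1])
        a, d = ancestor(i, delta), descendant(i, delta)
        if a is not None and d is not None:
            return abs(len(nodes[a][1]) - len(nodes[d][1])) / v
        if a is not None:
            return abs(len(nodes[a][1]) - v) / v
        if d is not None:
            return abs(v - len(nodes[d][1])) / v
        return 0.0

    cands = [
        i for i in range(len(nodes)) if volume_min <= len(nodes[i][1]) <= volume_max
    ]
    cands.sort(key=lambda i: (score(i), len(nodes[i][1]), nodes[i][0]))
    chosen: list[int] = []
    for c in cands:
        ok = True
        for a in chosen:
            ca, cc = nodes[a][1], nodes[c][1]
            if cc <= ca or ca <= cc:
                ok = False
                break
        if ok:
            chosen.append(c)
    return [nodes[i][1] for i in chosen]


def naive_knn(points: np.ndarray, labels: list[int], k: int) -> dict[int, list[int]]:
    """Full-sort kNN with (distance, label) keys, self excluded."""
    out = {}
    for i, p in enumerate(points):
        cand = []
        for j, q in enumerate(points):
            if j == i:
                continue
            cand.append((math.dist(p, q), labels[j]))
        cand.sort()
        out[labels[i]] = [lab for _, lab in cand[:k]]
    return out


def naive_pearson(x, y) -> tuple[float, float]:
    """Definitional Pearson r and two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    r = num / den
    r_clip = max(min(r, 1.0), -1.0)
    if abs(r_clip) == 1.0:
        return r, 0.0
    t = r_clip * math.sqrt((n - 2) / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p
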