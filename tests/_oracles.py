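"""Independent brute-force reference implementations.

Everything here is written as plainly as possible (explicit loops, BFS,
sort-based order statistics) and shares no code with the package, so tests
can compare the vectorized implementations against an exhaustive check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

AXIS_UNITS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def bf_boundary_mask(labels: np.ndarray) -> np.ndarray:
    nx, ny, nz = labels.shape
    mask = np.zeros_like(labels, dtype=bool)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                here = labels[x, y, z]
                for dx, dy, dz in AXIS_UNITS + [(-1, 0, 0), (0, -1, 0), (0, 0, -1)]:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                        if labels[u, v, w] != here:
                            mask[x, y, z] = True
                            break
    return mask


def bf_faces(labels: np.ndarray):
    """All differing-ID adjacent voxel pairs: (pair, axis, lower-voxel)."""
    nx, ny, nz = labels.shape
    faces = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                for axis, (dx, dy, dz) in enumerate(AXIS_UNITS):
                    u, v, w = x + dx, y + dy, z + dz
                    if u < nx and v < ny and w < nz:
                        a, b = labels[x, y, z], labels[u, v, w]
                        if a != b:
                            pair = (int(min(a, b)), int(max(a, b)))
                            faces.append((pair, axis, (x, y, z), (u, v, w)))
    return faces


def bf_contacts(labels: np.ndarray):
    """Contacts as {(pair): [component dicts]} via BFS over 26-neighbors.

    Each component dict has 'voxels' (frozenset) and 'face_counts' (tuple).
    """
    faces = bf_faces(labels)
    per_pair: dict = {}
    for pair, axis, lo, hi in faces:
        d = per_pair.setdefault(pair, {"voxels": set(), "faces": []})
        d["voxels"].update([lo, hi])
        d["faces"].append((axis, lo))

    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    result = []
    for pair, d in per_pair.items():
        todo = set(d["voxels"])
        comps = []
        while todo:
            start = todo.pop()
            comp = {start}
            queue = deque([start])
            while queue:
                x, y, z = queue.popleft()
                for dx, dy, dz in neighbors:
                    nb = (x + dx, y + dy, z + dz)
                    if nb in todo:
                        todo.discard(nb)
                        comp.add(nb)
                        queue.append(nb)
            comps.append(comp)
        for comp in comps:
            counts = [0, 0, 0]
            for axis, lo in d["faces"]:
                if lo in comp:
                    counts[axis] += 1
            result.append(
                {"pair": pair, "voxels": frozenset(comp), "face_counts": tuple(counts)}
            )
    return result


def bf_percentile(values, q: float) -> float:
    """Linear-interpolation percentile from sorted order statistics."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n == 1:
        return s[0]
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def bf_min_distance(points_a, points_b) -> float:
    best = math.inf
    for a in points_a:
        for b in points_b:
            d = math.dist([float(x) for x in a], [float(x) for x in b])
            best = min(best, d)
    return best


def bf_confusion(predicted, truth):
    """(tp, fp, fn) by direct set arithmetic; 'AMBIGUOUS' counts nowhere."""
    tp = fp = 0
    for cid in predicted:
        if truth[cid] == "SYNAPTIC":
            tp += 1
        elif truth[cid] == "NON_SYNAPTIC":
            fp += 1
    fn = sum(
        1 for cid, lbl in truth.items() if lbl == "SYNAPTIC" and cid not in set(predicted)
    )
    return tp, fp, fn


def bf_fill_background(labels: np.ndarray, pitch) -> np.ndarray:
    """Nearest-segment assignment in physical units, ties to the smaller ID."""
    nx, ny, nz = labels.shape
    sites = [
        (x, y, z, int(labels[x, y, z]))
        for x in range(nx)
        for y in range(ny)
        for z in range(nz)
        if labels[x, y, z] != 0
    ]
    out = labels.copy()
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] != 0:
                    continue
                best = None
                for sx, sy, sz, sid in sites:
                    d = (
                        ((x - sx) * pitch[0]) ** 2
                        + ((y - sy) * pitch[1]) ** 2
                        + ((z - sz) * pitch[2]) ** 2
                    )
                    if best is None or (d, sid) < best:
                        best = (d, sid)
                out[x, y, z] = best[1]
    return out


def random_voronoi_labels(rng: np.random.Generator, dims, n_segments: int) -> np.ndarray:
    """Small saturated label volume: nearest of n random sites (index space)."""
    sites = np.stack(
        [rng.integers(0, d, size=n_segments) for d in dims], axis=1
    ).astype(float)
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1)
    d2 = ((grid[..., None, :] - sites) ** 2).sum(axis=-1)
    return (np.argmin(d2, axis=-1) + 1).astype(np.int32)
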