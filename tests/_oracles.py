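"""Brute-force reference implementations used only by the test suite.

These are deliberately naive — exhaustive threshold sweeps, explicit
priority-queue flooding, sort-based statistics — and independent of the
library code paths they check.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from scipy import ndimage as ndi


def mser_bruteforce(
    q: np.ndarray,
    delta: int = 5,
    min_size: int = 5,
    max_size: int | None = 20000,
    max_variation: float = 0.5,
) -> np.ndarray:
    """Union of maximally stable extremal regions by exhaustive threshold sweep.

    Builds the component tree explicitly: for every threshold t in 1..255,
    the 26-connected components of ``{q >= t}`` are collected as frozensets;
    a component's variation compares it with the component containing it at
    its first appearance threshold minus *delta* (the full voxel set when
    that threshold drops to 0 or below). The whole-volume root is never a
    region.
    """
    q = np.asarray(q).astype(int)
    structure = np.ones((3,) * q.ndim, dtype=int)
    all_voxels = frozenset(range(q.size))

    comps_at: dict[int, list[frozenset]] = {}
    containing: dict[int, dict[int, frozenset]] = {}  # t -> voxel -> component
    for t in range(1, 256):
        lab, n = ndi.label(q >= t, structure=structure)
        flat = lab.ravel()
        comps = []
        cont = {}
        for k in range(1, n + 1):
            voxels = frozenset(np.flatnonzero(flat == k).tolist())
            comps.append(voxels)
            for v in voxels:
                cont[v] = voxels
        comps_at[t] = comps
        containing[t] = cont

    def component_at(t: int, voxel: int) -> frozenset:
        if t <= 0:
            return all_voxels
        return containing[t].get(voxel, all_voxels)

    # distinct nodes with their first appearance threshold
    first_seen: dict[frozenset, int] = {}
    for t in range(1, 256):
        for c in comps_at[t]:
            if c not in first_seen:
                first_seen[c] = t
    nodes = {c: a for c, a in first_seen.items() if c != all_voxels}

    def parent_of(c: frozenset) -> frozenset:
        rep = next(iter(c))
        return component_at(nodes[c] - 1, rep)

    def variation(c: frozenset) -> float:
        rep = next(iter(c))
        grown = component_at(nodes[c] - delta, rep)
        return (len(grown) - len(c)) / len(c)

    var = {c: variation(c) for c in nodes}
    children: dict[frozenset, list[frozenset]] = {c: [] for c in nodes}
    parent_map = {}
    for c in nodes:
        p = parent_of(c)
        parent_map[c] = p
        if p in nodes:
            children[p].append(c)

    selected = []
    for c in nodes:
        p = parent_map[c]
        parent_var = var[p] if p in nodes else np.inf
        child_var = min((var[ch] for ch in children[c]), default=np.inf)
        if (
            var[c] <= parent_var
            and var[c] <= child_var
            and var[c] <= max_variation
            and len(c) >= min_size
            and (max_size is None or len(c) <= max_size)
        ):
            selected.append(c)

    mask = np.zeros(q.size, dtype=bool)
    for c in selected:
        mask[list(c)] = True
    return mask.reshape(q.shape)


def flood_watershed(
    image: np.ndarray,
    markers: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Seeded watershed by explicit priority flooding (26-connectivity).

    Pops the lowest-value voxel (insertion order breaks ties), labels each
    unlabelled masked neighbour with the popping voxel's label and pushes
    it at its own image value — the classical hierarchical-queue flooding.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(markers).copy().astype(np.int64)
    mask = np.asarray(mask, dtype=bool)
    shape = image.shape
    offsets = [
        off for off in itertools.product((-1, 0, 1), repeat=image.ndim)
        if any(off)
    ]
    heap: list[tuple[float, int, tuple[int, ...]]] = []
    counter = itertools.count()
    for idx in zip(*np.nonzero((labels > 0) & mask)):
        heapq.heappush(heap, (image[idx], next(counter), idx))
    while heap:
        _, _, idx = heapq.heappop(heap)
        lab = labels[idx]
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(i < 0 or i >= s for i, s in zip(nb, shape)):
                continue
            if mask[nb] and labels[nb] == 0:
                labels[nb] = lab
                heapq.heappush(heap, (image[nb], next(counter), nb))
    labels[~mask] = 0
    return labels


def local_maxima_bruteforce(volume: np.ndarray) -> list[tuple[int, ...]]:
    """All voxels >= every 26-neighbour, by direct scanning."""
    volume = np.asarray(volume, dtype=float)
    out = []
    for idx in np.ndindex(volume.shape):
        v = volume[idx]
        is_max = True
        for off in itertools.product((-1, 0, 1), repeat=volume.ndim):
            if not any(off):
                continue
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= i < s for i, s in zip(nb, volume.shape)):
                if volume[nb] > v:
                    is_max = False
                    break
        if is_max:
            out.append(idx)
    return out


def percentile99_sorted(values: np.ndarray) -> float:
    """99th percentile with linear interpolation, from an explicit sort."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = 0.99 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def rayleigh_fwhm(scale: float) -> float:
    """FWHM of a Rayleigh density, solved numerically on a fine grid.

    The pairwise distance of two points scattered with an isotropic 2D
    Gaussian of sigma is Rayleigh with scale sigma * sqrt(2); this is the
    closed-form law behind the intra-cluster distance peak.
    """
    r = np.linspace(0.0, 10 * scale, 200001)
    pdf = (r / scale**2) * np.exp(-(r**2) / (2 * scale**2))
    half = pdf.max() / 2.0
    above = np.flatnonzero(pdf >= half)
    return float(r[above[-1]] - r[above[0]])
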