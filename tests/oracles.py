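"""Brute-force reference implementations used as independent oracles.

These apply the neighbourhood/distance definitions literally — explicit
offset enumeration and all-pairs distances — and share no code with the
package's scipy/skimage-backed implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def neighbour_offsets(connectivity: int) -> list:
    """Neighbour offsets of a voxel for 6/18/26-connectivity."""
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(c) for c in d)
        if connectivity == 6 and manhattan == 1:
            offs.append(d)
        elif connectivity == 18 and manhattan <= 2:
            offs.append(d)
        elif connectivity == 26:
            offs.append(d)
    return offs


def _shift(mask: np.ndarray, off: tuple) -> np.ndarray:
    """Mask translated by ``off``, zero-filled at the borders."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for axis, o in enumerate(off):
        n = mask.shape[axis]
        src.append(slice(max(0, -o), min(n, n - o)))
        dst.append(slice(max(0, o), min(n, n + o)))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def brute_dilate(mask: np.ndarray, steps: int, connectivity: int) -> np.ndarray:
    """Neighbourhood expansion applied ``steps`` times."""
    out = mask.copy()
    for _ in range(steps):
        cur = out.copy()
        for off in neighbour_offsets(connectivity):
            out |= _shift(cur, off)
    return out


def brute_surface_faces(mask: np.ndarray) -> set:
    """Per-voxel double loop over foreground voxels and the 6 directions."""
    faces = set()
    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in neighbour_offsets(6):
            nz, ny, nx = z + dz, y + dy, x + dx
            outside = not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2])
            if outside or not mask[nz, ny, nx]:
                faces.add((int(z), int(y), int(x), int(dz), int(dy), int(dx)))
    return faces


def brute_contact_faces(seed: np.ndarray, soil: np.ndarray, connectivity: int) -> int:
    """For each seed surface face, test whether any soil voxel lies within
    the structuring-element neighbourhood of the owning voxel."""
    shape = seed.shape
    n_contact = 0
    for z, y, x, *_ in brute_surface_faces(seed):
        hit = False
        for dz, dy, dx in neighbour_offsets(connectivity) + [(0, 0, 0)]:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if soil[nz, ny, nx]:
                    hit = True
                    break
        n_contact += hit
    return n_contact


def brute_chebyshev_shell(seed: np.ndarray, width: int) -> np.ndarray:
    """All-pairs Chebyshev distance thresholding (no distance transform)."""
    seed_coords = np.argwhere(seed)
    bg_coords = np.argwhere(~seed)
    shell = np.zeros_like(seed)
    for chunk in np.array_split(bg_coords, max(1, len(bg_coords) // 2048)):
        # chebyshev distance of each bg voxel to its nearest seed voxel
        d = np.abs(chunk[:, None, :] - seed_coords[None, :, :]).max(axis=2).min(axis=1)
        sel = chunk[(d >= 1) & (d <= width)]
        shell[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return shell


def brute_euclidean_shell(seed: np.ndarray, width: int) -> np.ndarray:
    seed_coords = np.argwhere(seed).astype(float)
    bg_coords = np.argwhere(~seed)
    shell = np.zeros_like(seed)
    for chunk in np.array_split(bg_coords, max(1, len(bg_coords) // 2048)):
        diff = chunk[:, None, :].astype(float) - seed_coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
        sel = chunk[(d >= 1) & (d <= width)]
        shell[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return shell


def has_enclosed_background_brute(mask: np.ndarray) -> bool:
    """Flood-fill (6-connected) the background from the grid boundary; any
    unreached background voxel is an enclosed cavity."""
    from collections import deque

    shape = mask.shape
    reached = np.zeros(shape, dtype=bool)
    queue = deque()
    for z, y, x in np.argwhere(~mask):
        if 0 in (z, y, x) or z == shape[0] - 1 or y == shape[1] - 1 or x == shape[2] - 1:
            if not reached[z, y, x]:
                reached[z, y, x] = True
                queue.append((z, y, x))
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in neighbour_offsets(6):
            nz, ny, nx = z + dz, y + dy, x + dx
            if (
                0 <= nz < shape[0]
                and 0 <= ny < shape[1]
                and 0 <= nx < shape[2]
                and not mask[nz, ny, nx]
                and not reached[nz, ny, nx]
            ):
                reached[nz, ny, nx] = True
                queue.append((nz, ny, nx))
    return bool((~mask & ~reached).any())


def random_scene(rng: np.random.Generator, max_side: int = 20):
    """A random small scene: a blobby seed mask plus disjoint soil."""
    shape = tuple(rng.integers(8, max_side + 1, size=3))
    seed = rng.random(shape) < rng.uniform(0.05, 0.3)
    # grow the seed a little so it has some structure
    seed = brute_dilate(seed, 1, 26) if rng.random() < 0.5 else seed
    soil = (rng.random(shape) < rng.uniform(0.1, 0.5)) & ~seed
    if not seed.any():
        seed[tuple(s // 2 for s in shape)] = True
    return seed, soil
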