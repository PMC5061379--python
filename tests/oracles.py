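"""Independent brute-force oracles used to check the pipeline's fast paths.

These deliberately avoid the morphological-operation route taken by the
package: ring membership is decided per pixel from explicit pairwise
distances, and seeded assignment from per-seed breadth-first searches.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial.distance import cdist


def _metric_name(metric: str) -> str:
    return {"chebyshev": "chebyshev", "manhattan": "cityblock"}[metric]


def brute_force_pm_ring(cell_mask: np.ndarray, width: int, metric: str = "chebyshev") -> np.ndarray:
    """Pixels of the cell whose distance to the nearest non-cell pixel is <= width.

    Pixels beyond the image border count as non-cell.  Computed by explicit
    pairwise distances between every cell pixel and every non-cell pixel of
    the padded image.
    """
    pad = width + 1
    padded = np.pad(cell_mask, pad, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    ring = np.zeros_like(cell_mask, dtype=bool)
    if fg.size == 0:
        return ring
    d = cdist(fg, bg, metric=_metric_name(metric)).min(axis=1)
    sel = fg[d <= width] - pad
    ring[sel[:, 0], sel[:, 1]] = True
    return ring


def brute_force_peri_ring(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray, width: int, metric: str = "chebyshev"
) -> np.ndarray:
    """Cell pixels outside the nucleus within distance <= width of any nucleus pixel."""
    cand = np.argwhere(cell_mask & ~nucleus_mask)
    nuc = np.argwhere(nucleus_mask)
    ring = np.zeros_like(cell_mask, dtype=bool)
    if cand.size == 0 or nuc.size == 0:
        return ring
    d = cdist(cand, nuc, metric=_metric_name(metric)).min(axis=1)
    sel = cand[d <= width]
    ring[sel[:, 0], sel[:, 1]] = True
    return ring


_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def geodesic_distance(foreground: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Chebyshev geodesic distance from a seed set, BFS within the foreground."""
    dist = np.full(foreground.shape, np.inf)
    q: deque[tuple[int, int]] = deque()
    for r, c in np.argwhere(seed_mask & foreground):
        dist[r, c] = 0
        q.append((r, c))
    n_rows, n_cols = foreground.shape
    while q:
        r, c = q.popleft()
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and foreground[rr, cc]:
                if dist[rr, cc] > dist[r, c] + 1:
                    dist[rr, cc] = dist[r, c] + 1
                    q.append((rr, cc))
    return dist


def nearest_seed_distances(foreground: np.ndarray, seed_labels: np.ndarray) -> dict[int, np.ndarray]:
    """Per-seed geodesic distance maps over the foreground."""
    out = {}
    for lab in np.unique(seed_labels[seed_labels > 0]):
        out[int(lab)] = geodesic_distance(foreground, seed_labels == lab)
    return out


def random_blob_pair(
    rng: np.random.Generator, shape: tuple[int, int] = (64, 64)
) -> tuple[np.ndarray, np.ndarray]:
    """A random connected cell-like blob and a nucleus blob inside it.

    Built by thresholding smoothed noise; the nucleus is an eroded core of
    the cell.  Retries internally until both masks are non-empty.
    """
    for _ in range(100):
        noise = ndi.gaussian_filter(rng.standard_normal(shape), sigma=rng.uniform(3, 7))
        mask = noise > np.quantile(noise, rng.uniform(0.75, 0.92))
        labels, n = ndi.label(mask, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        cell = labels == (int(np.argmax(sizes)) + 1)
        if cell.sum() < 30:
            continue
        core = ndi.binary_erosion(cell, np.ones((3, 3), bool), iterations=2, border_value=0)
        labels, n = ndi.label(core, structure=np.ones((3, 3), bool))
        if n == 0:
            # tiny cell: single interior-most pixel as nucleus
            dist = ndi.distance_transform_cdt(cell, metric="chessboard")
            nucleus = np.zeros_like(cell)
            r, c = np.unravel_index(np.argmax(dist), dist.shape)
            nucleus[r, c] = True
        else:
            sizes = np.bincount(labels.ravel())[1:]
            nucleus = labels == (int(np.argmax(sizes)) + 1)
        return cell, nucleus
    raise RuntimeError("could not generate a random blob pair")
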