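"""Brute-force oracles kept deliberately independent of the package internals.

Morphology is implemented here by direct neighbourhood scans over voxel
coordinates, and component labelling by an explicit flood fill, so that the
package's scipy-based operators can be checked against a second, slower
route.
"""

from __future__ import annotations

import numpy as np

FACE_OFFSETS = [
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
]
CUBE_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def offsets(connectivity: int):
    return FACE_OFFSETS if connectivity == 6 else CUBE_OFFSETS


def brute_erode(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Keep a voxel iff every neighbour is inside the mask (outside grid = background)."""
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for idx in np.argwhere(mask):
        keep = True
        for off in offsets(connectivity):
            n = idx + off
            if (n < 0).any() or (n >= shape).any() or not mask[tuple(n)]:
                keep = False
                break
        out[tuple(idx)] = keep
    return out


def brute_dilate(mask: np.ndarray, connectivity: int) -> np.ndarray:
    out = mask.copy()
    shape = mask.shape
    for idx in np.argwhere(mask):
        for off in offsets(connectivity):
            n = idx + off
            if (n >= 0).all() and (n < shape).all():
                out[tuple(n)] = True
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Integer component labels by explicit flood fill, 0 = background."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in np.argwhere(mask):
        if labels[tuple(start)]:
            continue
        current += 1
        stack = [tuple(start)]
        labels[tuple(start)] = current
        while stack:
            v = stack.pop()
            for off in offsets(connectivity):
                n = tuple(np.add(v, off))
                if (
                    all(0 <= n[d] < mask.shape[d] for d in range(3))
                    and mask[n]
                    and not labels[n]
                ):
                    labels[n] = current
                    stack.append(n)
    return labels


def brute_min_distance(target: np.ndarray, query_points: np.ndarray) -> np.ndarray:
    """All-pairs minimum Euclidean distance from each query point to the target set."""
    tpts = np.argwhere(target).astype(float)
    out = np.empty(len(query_points))
    for i, q in enumerate(query_points.astype(float)):
        out[i] = np.sqrt(((tpts - q) ** 2).sum(axis=1).min())
    return out


def lstsq_arm_coefficient(table) -> float:
    """Plain least-squares oracle for the adjusted arm effect (no library model object)."""
    y = table["followup"].to_numpy(dtype=float)
    cols = [
        np.ones(len(table)),
        (table["arm"] == "active").to_numpy(dtype=float),
        table["baseline"].to_numpy(dtype=float),
        table["age_band"].to_numpy(dtype=float),
        table["gender"].to_numpy(dtype=float),
        table["centre"].to_numpy(dtype=float),
        table["edss_band"].to_numpy(dtype=float),
    ]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])
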