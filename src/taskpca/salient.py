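"""Salient regions of a component image.

Voxels whose loadings fall beyond the 1st or above the 99th percentile of the
masked-voxel distribution are salient; connected clusters of at least 32 such
voxels (18-connectivity by default) are tabulated with their size, peak
loading and peak position in MNI millimetres via the image affine.
Percentiles use the linear-interpolation definition over masked voxels only,
with strict inequalities, so values exactly at a cutpoint are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "percentile_threshold",
    "extract_clusters",
    "voxel_to_mni",
    "mni_to_voxel",
    "Cluster",
    "cluster_table",
    "salient_clusters",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def percentile_threshold(
    image: np.ndarray,
    mask: np.ndarray,
    q_low: float = 1.0,
    q_high: float = 99.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary maps of the high and low tails of the masked loading distribution.

    Returns ``(high, low)``: voxels strictly above the ``q_high`` percentile
    and strictly below the ``q_low`` percentile of in-mask values.  A constant
    image is degenerate and rejected.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask must share shape")
    if not m.any():
        raise ValueError("mask is empty")
    vals = img[m]
    if np.ptp(vals) == 0.0:
        # degenerate: no tails exist
        return np.zeros_like(m), np.zeros_like(m)
    hi_cut = np.percentile(vals, q_high)
    lo_cut = np.percentile(vals, q_low)
    high = m & (img > hi_cut)
    low = m & (img < lo_cut)
    return high, low


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold cluster."""

    sign: str  # "high" or "low"
    size: int
    peak_index: tuple[int, int, int]
    peak_mni: tuple[float, float, float]
    peak_value: float


def voxel_to_mni(voxel_index, affine: np.ndarray) -> np.ndarray:
    """Map a 0-based voxel index to millimetre coordinates via the affine."""
    idx = np.asarray(voxel_index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("voxel index must be length 3")
    return (np.asarray(affine) @ np.append(idx, 1.0))[:3]


def mni_to_voxel(mni_mm, affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_mni`, rounded to the nearest voxel."""
    inv = np.linalg.inv(np.asarray(affine))
    out = inv @ np.append(np.asarray(mni_mm, dtype=float), 1.0)
    return np.round(out[:3]).astype(int)


def extract_clusters(
    binary_map: np.ndarray,
    image: np.ndarray,
    affine: np.ndarray,
    sign: str = "high",
    min_extent: int = 32,
    connectivity: int = 18,
) -> list[Cluster]:
    """Connected components of a binary map, dropping small clusters.

    ``connectivity`` is 6 (faces), 18 (faces+edges, the default) or 26
    (faces+edges+corners).  The peak is the in-cluster voxel of largest
    absolute loading, ties broken by the smallest C-order linear index.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    bmap = np.asarray(binary_map).astype(bool)
    img = np.asarray(image, dtype=float)
    if bmap.shape != img.shape:
        raise ValueError("binary map and image must share shape")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n_labels = ndimage.label(bmap, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        where = labels == lab
        size = int(where.sum())
        if size < min_extent:
            continue
        flat = np.flatnonzero(where.ravel())
        vals = np.abs(img.ravel()[flat])
        peak_flat = flat[int(np.argmax(vals))]  # argmax: first max = smallest index
        peak_idx = np.unravel_index(peak_flat, img.shape)
        clusters.append(
            Cluster(
                sign=sign,
                size=size,
                peak_index=tuple(int(i) for i in peak_idx),
                peak_mni=tuple(float(v) for v in voxel_to_mni(peak_idx, affine)),
                peak_value=float(img[peak_idx]),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def salient_clusters(
    image: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    q_low: float = 1.0,
    q_high: float = 99.0,
    min_extent: int = 32,
    connectivity: int = 18,
) -> list[Cluster]:
    """Full salient-region extraction: percentile tails, then extent filtering."""
    high, low = percentile_threshold(image, mask, q_low=q_low, q_high=q_high)
    out = extract_clusters(high, image, affine, "high", min_extent, connectivity)
    out += extract_clusters(low, image, affine, "low", min_extent, connectivity)
    return out


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster report: one row per cluster, peak position in MNI mm."""
    return pd.DataFrame(
        {
            "cluster": np.arange(1, len(clusters) + 1),
            "tail": [c.sign for c in clusters],
            "size_voxels": [c.size for c in clusters],
            "mni_x": [c.peak_mni[0] for c in clusters],
            "mni_y": [c.peak_mni[1] for c in clusters],
            "mni_z": [c.peak_mni[2] for c in clusters],
            "peak_value": [c.peak_value for c in clusters],
        }
    )
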