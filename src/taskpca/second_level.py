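"""Second-level PCA over first-level component images.

As a control against classification bias from reliance on reference patterns,
the selected first-level component images of one condition are stacked as the
rows of a new matrix (one row per image, one column per masked voxel) and
decomposed with the same double-centered SVD used at the first level.  The
classes this produces are orthogonal by construction; if the reference-based
classification is sound, the leading second-level component reproduces the
dominant mean component image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import volume_correlation
from .pca import ComponentSet, DataMatrix, decompose, residualize

__all__ = ["SecondLevelResult", "second_level_pca"]


@dataclass
class SecondLevelResult:
    """Second-level component set plus vccs of PC1 with reference images."""

    components: ComponentSet
    variance_fractions: np.ndarray
    pc1_vccs: dict[str, float]

    @property
    def pc1_image(self) -> np.ndarray:
        return self.components.eigenimages[0]

    @property
    def pc1_variance_fraction(self) -> float:
        return float(self.variance_fractions[0])


def second_level_pca(
    component_images: np.ndarray,
    mask: np.ndarray | None = None,
    references: dict[str, np.ndarray] | None = None,
    normalize: bool = True,
) -> SecondLevelResult:
    """Decompose a stack of component images; correlate PC1 with references.

    ``component_images`` is n_images x masked-voxels.  Images are unit-
    normalised before stacking (disable with ``normalize=False``) so that
    acquisitions with larger raw loadings do not dominate.  PC1 is sign-
    aligned to the best-matching reference before its vccs are reported.
    """
    imgs = np.asarray(component_images, dtype=float)
    if imgs.ndim != 2:
        raise ValueError("component_images must be 2-D (images x voxels)")
    if imgs.shape[0] < 3:
        raise ValueError("second-level PCA needs at least 3 images")
    if normalize:
        norms = np.linalg.norm(imgs, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-norm component image")
        imgs = imgs / norms
    n_vox = imgs.shape[1]
    data = DataMatrix(values=imgs, mask=np.ones(n_vox, dtype=bool))
    comps = decompose(residualize(data), mask=mask)
    pc1 = comps.eigenimages[0]
    vccs: dict[str, float] = {}
    if references:
        raw = {name: volume_correlation(pc1, ref) for name, ref in references.items()}
        best = max(raw, key=lambda k: abs(raw[k]))
        if raw[best] < 0:
            comps.eigenimages[0] = -pc1
            comps.eigenvariates[:, 0] *= -1
            pc1 = comps.eigenimages[0]
        vccs = {name: volume_correlation(pc1, ref) for name, ref in references.items()}
    return SecondLevelResult(
        components=comps,
        variance_fractions=comps.variance_fractions,
        pc1_vccs=vccs,
    )
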