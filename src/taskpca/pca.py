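"""Double-centered PCA of a masked fMRI time series.

Each acquisition is arranged as a frames x masked-voxels matrix.  Removing the
row means (per-frame global signal), column means (per-voxel baseline) and
restoring the grand mean leaves a residual matrix whose row, column and grand
means all vanish; its singular value decomposition yields, per component, a
spatial loading pattern over masked voxels (the eigenimage), a unit-norm time
course (the eigenvariate, a.k.a. temporal expression coefficient) and a
singular value whose square is proportional to the fraction of variance the
component describes.

Voxel ordering inside the matrix is x-fastest (Fortran raveling of the mask),
fixed and documented so eigenimages are comparable across acquisitions that
share a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AcquisitionId",
    "DataMatrix",
    "ResidualMatrix",
    "PrincipalComponent",
    "ComponentSet",
    "build_data_matrix",
    "residualize",
    "decompose",
    "kaiser_guttman",
    "mask_order_indices",
    "scatter_to_volume",
]

#: components with singular value below this fraction of the largest are
#: treated as numerically null and dropped
RANK_TOL = 1e-10


@dataclass(frozen=True)
class AcquisitionId:
    """Identifies one scan: subject, condition and repeat run."""

    subject: str
    condition: str
    run: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.subject}/{self.condition}/run-{self.run}"


def mask_order_indices(mask: np.ndarray) -> np.ndarray:
    """Flat (Fortran-order) indices of in-mask voxels, x-fastest."""
    m = np.asarray(mask).astype(bool)
    return np.flatnonzero(m.ravel(order="F"))


@dataclass
class DataMatrix:
    """frames x masked-voxels data matrix for one acquisition."""

    values: np.ndarray
    mask: np.ndarray
    acquisition: AcquisitionId | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("data matrix must be 2-D (frames x voxels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("data matrix contains non-finite values")
        if self.values.shape[1] != int(np.asarray(self.mask).astype(bool).sum()):
            raise ValueError("column count must equal mask cardinality")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ResidualMatrix:
    """Double-centered data matrix; row/column/grand means vanish."""

    values: np.ndarray
    source: DataMatrix | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PrincipalComponent:
    """One component: spatial pattern, time course and variance share."""

    index: int
    eigenimage: np.ndarray
    eigenvariate: np.ndarray
    singular_value: float
    variance_fraction: float


@dataclass
class ComponentSet:
    """Ordered SVD components of one residual matrix.

    ``eigenvariates`` is frames x k (columns unit-norm, orthogonal),
    ``eigenimages`` is k x voxels (rows unit-norm, orthogonal),
    ``singular_values`` non-increasing.
    """

    eigenvariates: np.ndarray
    eigenimages: np.ndarray
    singular_values: np.ndarray
    mask: np.ndarray | None = None
    acquisition: AcquisitionId | None = None
    total_variance: float = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(s) > 1e-12 * max(s[0], 1.0) if s.size > 1 else [False]):
            raise ValueError("singular values must be non-increasing")
        self.singular_values = s
        self.total_variance = float(np.sum(s**2))

    def __len__(self) -> int:
        return int(self.singular_values.size)

    def __iter__(self) -> Iterator[PrincipalComponent]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> PrincipalComponent:
        return PrincipalComponent(
            index=i,
            eigenimage=self.eigenimages[i],
            eigenvariate=self.eigenvariates[:, i],
            singular_value=float(self.singular_values[i]),
            variance_fraction=float(self.variance_fractions[i]),
        )

    @property
    def variance_fractions(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum() if s2.sum() > 0 else s2

    @property
    def n_frames(self) -> int:
        return self.eigenvariates.shape[0]


def build_data_matrix(
    image4d: np.ndarray, mask: np.ndarray, acquisition: AcquisitionId | None = None
) -> DataMatrix:
    """Extract the frames x masked-voxels matrix from a 4D array.

    ``image4d`` is indexed (x, y, z, t); columns follow the fixed x-fastest
    voxel ordering of :func:`mask_order_indices`.
    """
    img = np.asarray(image4d)
    m = np.asarray(mask).astype(bool)
    if img.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if img.shape[:3] != m.shape:
        raise ValueError(f"image grid {img.shape[:3]} != mask grid {m.shape}")
    if not m.any():
        raise ValueError("mask is empty")
    idx = mask_order_indices(m)
    n_t = img.shape[3]
    flat = img.reshape(-1, n_t, order="F")  # voxels (x-fastest) x frames
    values = flat[idx].T.astype(float)
    return DataMatrix(values=values, mask=m, acquisition=acquisition)


def scatter_to_volume(vector: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter a masked-voxel vector back into a 3D volume (zeros elsewhere)."""
    m = np.asarray(mask).astype(bool)
    vol = np.zeros(m.size, dtype=float)
    vol[mask_order_indices(m)] = np.asarray(vector, dtype=float)
    return vol.reshape(m.shape, order="F")


def residualize(data: DataMatrix) -> ResidualMatrix:
    """Double-center: subtract row and column means, restore the grand mean."""
    x = data.values
    row = x.mean(axis=1, keepdims=True)
    col = x.mean(axis=0, keepdims=True)
    grand = x.mean()
    return ResidualMatrix(values=x - row - col + grand, source=data)


def _sign_fix(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient each component so its largest-|loading| voxel is positive
    peak = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), peak])
    signs[signs == 0] = 1.0
    return u * signs, vt * signs[:, None]


def decompose(
    residual: ResidualMatrix,
    method: str = "auto",
    rank_tol: float = RANK_TOL,
    mask: np.ndarray | None = None,
    acquisition: AcquisitionId | None = None,
) -> ComponentSet:
    """Thin SVD of the residual matrix into principal components.

    ``method='direct'`` runs the full SVD; ``method='gram'`` diagonalises the
    small frames x frames matrix R R^T and recovers eigenimages as
    ``R^T u / s`` -- algebraically identical and much cheaper when voxels
    vastly outnumber frames.  ``'auto'`` picks ``'gram'`` when
    voxels > 4 x frames.  Components with singular value below
    ``rank_tol`` x the largest are dropped as numerically degenerate.
    """
    r = np.asarray(residual.values, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residual matrix contains non-finite values")
    n_t, n_v = r.shape
    if method == "auto":
        method = "gram" if n_v > 4 * n_t else "direct"
    if method == "direct":
        u, s, vt = np.linalg.svd(r, full_matrices=False)
    elif method == "gram":
        g = r @ r.T
        w, q = np.linalg.eigh(g)  # ascending
        w = w[::-1]
        q = q[:, ::-1]
        s = np.sqrt(np.clip(w, 0.0, None))
        # the Gram route cannot resolve singular values below ~sqrt(eps)*s0
        rank_tol = max(rank_tol, 1e-7)
        keep0 = s > (rank_tol * s[0] if s[0] > 0 else np.inf)
        u = q
        vt = np.zeros((n_t, n_v))
        nz = np.flatnonzero(keep0)
        vt[nz] = (r.T @ q[:, nz] / s[nz]).T
    else:
        raise ValueError(f"unknown method {method!r}")
    if s.size and s[0] > 0:
        keep = s > rank_tol * s[0]
        u, s, vt = u[:, keep], s[keep], vt[keep]
    u, vt = _sign_fix(u, vt)
    src = residual.source
    return ComponentSet(
        eigenvariates=u,
        eigenimages=vt,
        singular_values=s,
        mask=mask if mask is not None else (src.mask if src is not None else None),
        acquisition=acquisition
        if acquisition is not None
        else (src.acquisition if src is not None else None),
    )


def kaiser_guttman(components: ComponentSet | Sequence[float]) -> np.ndarray:
    """Indices of components whose variance strictly exceeds the mean variance.

    Operates on squared singular values; with all variances equal nothing is
    retained (strict inequality).
    """
    if isinstance(components, ComponentSet):
        s2 = components.singular_values**2
    else:
        s2 = np.asarray(components, dtype=float) ** 2
    if s2.size == 0:
        raise ValueError("empty component set")
    return np.flatnonzero(s2 > s2.mean())
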