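"""NIfTI, TSV and CSV persistence for analysis objects."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .pca import ComponentSet, scatter_to_volume

__all__ = [
    "load_image4d",
    "load_mask",
    "save_image",
    "save_component_set",
    "load_component_table",
]


def load_image4d(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4D NIfTI; returns (data array (x,y,z,t), affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D image")
    return data, img.affine


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D 0/1 mask NIfTI; returns (boolean array, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D mask")
    return data > 0, img.affine


def save_image(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an array as NIfTI-1, preserving the dtype (bool becomes uint8)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def save_component_set(
    components: ComponentSet,
    mask: np.ndarray,
    affine: np.ndarray,
    out_dir,
    stem: str = "components",
    n_images: int | None = None,
) -> None:
    """Persist a component set: eigenimages as 4D NIfTI, time courses as CSV.

    ``n_images`` caps how many eigenimages are scattered into the NIfTI (all
    eigenvariates and singular values are always written).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = len(components) if n_images is None else min(n_images, len(components))
    vols = np.stack(
        [scatter_to_volume(components.eigenimages[i], mask) for i in range(k)], axis=-1
    )
    save_image(vols, affine, out / f"{stem}_eigenimages.nii.gz")
    ev = pd.DataFrame(
        components.eigenvariates,
        columns=[f"pc{i + 1}" for i in range(len(components))],
    )
    ev.to_csv(out / f"{stem}_eigenvariates.csv", index=False)
    pd.DataFrame(
        {
            "component": np.arange(len(components)),
            "singular_value": components.singular_values,
            "variance_fraction": components.variance_fractions,
        }
    ).to_csv(out / f"{stem}_singular_values.csv", index=False)


def load_component_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
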