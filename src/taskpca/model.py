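"""Model/results interface for per-acquisition event-related PCA.

``EventRelatedPCA`` bundles one acquisition's data matrix with its task
design; ``fit()`` performs the double-centered SVD, scores every component's
correlation with the modeled hemodynamic response, applies the
Bonferroni-corrected selection and the Kaiser-Guttman variance screen, and
returns an ``EventRelatedPCAResults`` carrying the component set, the ecc
records and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TaskDesign
from .hrf import ModeledResponse, PowerSpectrum, modeled_response, power_spectrum
from .pca import (
    AcquisitionId,
    ComponentSet,
    DataMatrix,
    build_data_matrix,
    decompose,
    kaiser_guttman,
    residualize,
)
from .selection import EccRecord, select_task_related, selection_table

__all__ = ["EventRelatedPCA", "EventRelatedPCAResults"]


class EventRelatedPCA:
    """Principal-component model of one event-related acquisition.

    Parameters
    ----------
    data
        frames x masked-voxels :class:`DataMatrix`, or a 4D (x, y, z, t)
        array combined with ``mask``.
    design
        The acquisition's :class:`TaskDesign`; frame count must match.
    mask
        3D boolean mask, required when ``data`` is a 4D array.

    Examples
    --------
    >>> model = EventRelatedPCA(matrix, design)
    >>> res = model.fit(alpha=0.01)
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: DataMatrix | np.ndarray,
        design: TaskDesign,
        mask: np.ndarray | None = None,
        acquisition: AcquisitionId | None = None,
    ) -> None:
        if isinstance(data, DataMatrix):
            self.data = data
        else:
            arr = np.asarray(data)
            if arr.ndim != 4:
                raise ValueError("data must be a DataMatrix or a 4D array")
            if mask is None:
                raise ValueError("a mask is required with 4D array input")
            self.data = build_data_matrix(arr, mask, acquisition=acquisition)
        if acquisition is not None:
            self.data.acquisition = acquisition
        if self.data.n_frames != design.n_frames:
            raise ValueError(
                f"data has {self.data.n_frames} frames but the design expects "
                f"{design.n_frames}"
            )
        self.design = design
        self.response: ModeledResponse = modeled_response(design)

    @classmethod
    def from_images(
        cls,
        image_path,
        mask_path,
        design: TaskDesign,
        acquisition: AcquisitionId | None = None,
    ) -> "EventRelatedPCA":
        """Build the model from NIfTI files on disk."""
        from .io import load_image4d, load_mask

        data, _ = load_image4d(image_path)
        mask, _ = load_mask(mask_path)
        return cls(data, design, mask=mask, acquisition=acquisition)

    def fit(self, alpha: float = 0.01, method: str = "auto") -> "EventRelatedPCAResults":
        """Decompose, score and select; returns the results object."""
        components = decompose(residualize(self.data), method=method)
        records = select_task_related(components, self.response, alpha=alpha)
        kg = kaiser_guttman(components)
        return EventRelatedPCAResults(
            model=self,
            components=components,
            ecc_records=records,
            kaiser_guttman_indices=kg,
            alpha=alpha,
        )


@dataclass
class EventRelatedPCAResults:
    """Fitted per-acquisition PCA: components, selection and diagnostics."""

    model: EventRelatedPCA
    components: ComponentSet
    ecc_records: list[EccRecord]
    kaiser_guttman_indices: np.ndarray
    alpha: float

    @property
    def task_related(self) -> list[EccRecord]:
        """Components whose |ecc| exceeds the Bonferroni-corrected critical r."""
        return [r for r in self.ecc_records if r.significant]

    @property
    def n_task_related(self) -> int:
        return len(self.task_related)

    @property
    def critical_r(self) -> float:
        return self.ecc_records[0].critical_r

    def eigenimage(self, index: int) -> np.ndarray:
        return self.components.eigenimages[index]

    def eigenvariate(self, index: int) -> np.ndarray:
        return self.components.eigenvariates[:, index]

    def component_spectrum(self, index: int) -> PowerSpectrum:
        """Power spectrum of one component's temporal expression coefficient."""
        return power_spectrum(self.eigenvariate(index), self.model.design.tr)

    def selection_table(self) -> pd.DataFrame:
        return selection_table(self.ecc_records, acquisition=self.components.acquisition)

    def summary(self, top: int = 10) -> str:
        """Printable per-acquisition report in the statsmodels tradition."""
        acq = self.components.acquisition
        lines = [
            "Event-related PCA results",
            "=" * 60,
            f"acquisition:        {acq if acq is not None else '<unnamed>'}",
            f"frames x voxels:    {self.model.data.n_frames} x {self.model.data.n_voxels}",
            f"components:         {len(self.components)}",
            f"Kaiser-Guttman:     first {len(self.kaiser_guttman_indices)} retained",
            f"critical |ecc|:     {self.critical_r:.3f} "
            f"(alpha={self.alpha}, Bonferroni m={self.ecc_records[0].df}, "
            f"df={self.ecc_records[0].df})",
            f"task-related PCs:   {self.n_task_related}",
            "-" * 60,
            f"{'PC':>4} {'ecc':>8} {'var %':>7} {'task-related':>13}",
        ]
        order = np.argsort([-abs(r.ecc) for r in self.ecc_records])[:top]
        vf = self.components.variance_fractions
        for i in order:
            r = self.ecc_records[i]
            lines.append(
                f"{r.component + 1:>4} {r.ecc:>8.3f} {100 * vf[r.component]:>7.2f} "
                f"{'yes' if r.significant else 'no':>13}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)
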