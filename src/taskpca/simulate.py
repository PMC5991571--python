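"""Ground-truth-known synthetic event-related fMRI datasets.

The generator emulates the statistical structure of a smoothed, spatially
normalized event-related acquisition: two embedded spatial networks -- a
dominant "motor control" pattern (I) and a weaker, anticorrelated
"distraction" pattern (II) -- expressed along the modeled hemodynamic
response, a condition factor (verum/placebo) scaling their gains, and
spatially smoothed AR(1) Gaussian noise.  Every downstream stage of the
analysis can therefore be exercised against known truth.

The signal model for one acquisition is::

    data[t, v] = g_I  * pattern_I[v]  * s1(t)
               + g_II * pattern_II[v] * s2(t)
               + noise[t, v]

with ``s1`` the unit-norm modeled response of the task design and ``s2``
the unit-norm distraction time course: the response with flipped sign
(pattern II waxes as directed motor control wanes) diluted by a stronger
slow sinusoidal drift, ``s2 = unit(-s1 + drift_amplitude * drift)``.  The
dilution keeps |corr(s1, s2)| modest, so the SVD can separate the two
networks, while pattern II remains genuinely but weakly task-related
(|ecc| around 0.3-0.4) and anticorrelated in both time and space -- the
reported structure of the distraction network.

Acquisitions come in two attentional states.  Most are *attentive*: pattern
II is weak (``gain_II``) and stays buried in the noise.  With a
condition-dependent probability (``distraction_prob``) an acquisition is
*distracted*: pattern II expresses strongly (``distracted_gain_ii`` times
the acquisition's pattern-I gain) while pattern I may be damped
(``distracted_gain_i_factor``).  Pattern II
therefore surfaces irregularly and more often under placebo, which is the
condition effect the analysis is meant to detect.  ``noise`` is an
AR(1)-in-time Gaussian field smoothed with the same FWHM as the signal.
Patterns and time courses are unit-norm, so each gain is exactly the
singular value its pattern contributes to the noiseless residual matrix; per
acquisition both gains are additionally scaled by one shared lognormal
factor (``gain_cv``) emulating between-subject/run expression variability.

All randomness flows from one top-level seed through a documented
per-acquisition derivation: ``SeedSequence([master_seed, subject_index,
condition_index, run_index])``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .design import TaskDesign, generate_task_design
from .hrf import modeled_response
from .pca import AcquisitionId, DataMatrix, mask_order_indices, scatter_to_volume

__all__ = [
    "VolumeGeometry",
    "GroundTruth",
    "DatasetConfig",
    "ellipsoid_mask",
    "generate_pattern_templates",
    "simulate_acquisition",
    "simulate_acquisition_matrix",
    "simulate_dataset",
    "calibrate_noise_sigma",
    "acquisition_seed",
    "default_geometry",
    "reduced_geometry",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VolumeGeometry:
    """Image grid and voxel-index -> millimetre (MNI) transform."""

    dims: tuple[int, int, int] = (79, 95, 68)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if self.affine is None:
            # radiological MNI-style affine: x flipped, grid centered
            dx, dy, dz = self.voxel_size_mm
            nx, ny, nz = self.dims
            aff = np.array(
                [
                    [-dx, 0, 0, dx * (nx - 1) / 2.0],
                    [0, dy, 0, -dy * (ny - 1) / 2.0],
                    [0, 0, dz, -dz * (nz - 1) / 2.0],
                    [0, 0, 0, 1.0],
                ]
            )
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
                raise ValueError("affine must be an invertible 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def smoothing_sigma_voxels(self, fwhm_mm: float) -> tuple[float, ...]:
        return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in self.voxel_size_mm)


def default_geometry() -> VolumeGeometry:
    """The study-scale grid: 79 x 95 x 68 voxels of 2 mm."""
    return VolumeGeometry()


def reduced_geometry(scale: float = 0.5) -> VolumeGeometry:
    """A proportionally reduced grid for fast runs (default half resolution)."""
    dims = tuple(max(8, int(round(d * scale))) for d in (79, 95, 68))
    return VolumeGeometry(dims=dims)


def ellipsoid_mask(geometry: VolumeGeometry, fraction: float = 0.9) -> np.ndarray:
    """Brain-like ellipsoidal mask filling ``fraction`` of each grid half-axis."""
    nx, ny, nz = geometry.dims
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = fraction * cx, fraction * cy, fraction * cz
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Injected spatial patterns and their per-condition gains.

    ``pattern_images`` are masked-voxel vectors (x-fastest order), unit-norm
    over the mask.  ``condition_gains`` maps condition name to
    ``(gain_I, gain_II)``.
    """

    pattern_images: tuple[np.ndarray, np.ndarray]
    condition_gains: dict[str, tuple[float, float]]
    noise_sigma: float = 1.0
    noise_ar1: float = 0.3
    smoothing_fwhm_mm: float = 8.0
    drift_amplitude: float = 2.5
    drift_freq_hz: float = 0.012
    gain_cv: float = 0.15
    distraction_prob: dict[str, float] = field(
        default_factory=lambda: {"placebo": 0.35, "verum": 0.15}
    )
    distracted_gain_ii: float = 1.4
    distracted_gain_i_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        for p in self.pattern_images:
            n = np.linalg.norm(p)
            if abs(n - 1.0) > 1e-6:
                raise ValueError("pattern images must be unit-norm over the mask")


#: blob centers as fractions of the grid (x, y, z) and relative amplitudes
PATTERN_I_BLOBS = [((0.30, 0.35, 0.75), 1.0), ((0.38, 0.30, 0.68), 0.7), ((0.50, 0.45, 0.80), 0.5)]
PATTERN_II_BLOBS = [((0.50, 0.75, 0.65), 1.0), ((0.45, 0.85, 0.40), 0.8), ((0.60, 0.80, 0.45), 0.6)]


def _blob_image(
    geometry: VolumeGeometry,
    mask: np.ndarray,
    blobs,
    blob_fwhm_mm: float,
    rng: np.random.Generator,
    jitter_voxels: float = 0.0,
) -> np.ndarray:
    vol = np.zeros(geometry.dims)
    dims = np.asarray(geometry.dims)
    for center_frac, amp in blobs:
        center = np.asarray(center_frac) * (dims - 1)
        if jitter_voxels > 0:
            center = center + rng.normal(0.0, jitter_voxels, size=3)
        idx = np.round(center).astype(int)
        clipped = np.clip(idx, 0, dims - 1)
        if not mask[tuple(clipped)]:
            warnings.warn(
                f"blob center {tuple(idx)} falls outside the mask; clipping to mask",
                stacklevel=3,
            )
            in_mask = np.argwhere(mask)
            nearest = in_mask[np.argmin(((in_mask - clipped) ** 2).sum(axis=1))]
            clipped = nearest
        vol[tuple(clipped)] += amp
    sigma = geometry.smoothing_sigma_voxels(blob_fwhm_mm)
    return ndimage.gaussian_filter(vol, sigma)


def generate_pattern_templates(
    geometry: VolumeGeometry,
    mask: np.ndarray,
    seed: int | None = None,
    blobs_i=PATTERN_I_BLOBS,
    blobs_ii=PATTERN_II_BLOBS,
    blob_fwhm_mm: float = 12.0,
    anticorrelation: float = 0.4,
    jitter_voxels: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two smoothed multi-blob patterns, unit-norm over the mask.

    Pattern II optionally carries a negative copy of pattern I scaled by
    ``anticorrelation`` (a shared-support sign flip), making the two patterns
    negatively volume-correlated as the study's two networks are; set it to 0
    for uncorrelated supports.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    vol_i = _blob_image(geometry, m, blobs_i, blob_fwhm_mm, rng, jitter_voxels)
    vol_ii = _blob_image(geometry, m, blobs_ii, blob_fwhm_mm, rng, jitter_voxels)
    p1 = vol_i.ravel(order="F")[mask_order_indices(m)]
    p1 = p1 - p1.mean()
    p1 /= np.linalg.norm(p1)
    p2 = vol_ii.ravel(order="F")[mask_order_indices(m)]
    p2 = p2 - p2.mean()
    p2 /= np.linalg.norm(p2)
    if anticorrelation:
        p2 = p2 - anticorrelation * p1 / np.linalg.norm(p1)
        p2 /= np.linalg.norm(p2)
    return p1, p2


def acquisition_seed(
    master_seed: int, subject_index: int, condition_index: int, run_index: int
) -> np.random.SeedSequence:
    """Documented per-acquisition seed derivation."""
    return np.random.SeedSequence([int(master_seed), subject_index, condition_index, run_index])


def _smoothed_ar1_noise(
    n_frames: int,
    geometry: VolumeGeometry,
    mask_idx: np.ndarray,
    sigma: float,
    ar1: float,
    smoothing_fwhm_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1)-in-time, spatially smoothed Gaussian noise, in-mask frames x voxels.

    The field is standardised (per realisation, over in-mask voxels) so the
    marginal voxel standard deviation equals ``sigma``.
    """
    sm_sigma = geometry.smoothing_sigma_voxels(smoothing_fwhm_mm)
    out = np.empty((n_frames, mask_idx.size))
    state = None
    innov = np.sqrt(1.0 - ar1 * ar1)
    for t in range(n_frames):
        eps = rng.standard_normal(geometry.dims)
        if smoothing_fwhm_mm > 0:
            eps = ndimage.gaussian_filter(eps, sm_sigma)
        if state is None:
            state = eps
        else:
            state = ar1 * state + innov * eps
        out[t] = state.ravel(order="F")[mask_idx]
    sd = out.std()
    if sd > 0:
        out *= sigma / sd
    return out


def _pattern_time_courses(
    design: TaskDesign, ground_truth: GroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm time courses of the two patterns for one acquisition.

    Pattern I follows the modeled response; pattern II expresses against it,
    diluted by a slow drift whose phase is drawn per acquisition.
    """
    s1 = modeled_response(design).values
    s1 = s1 / max(np.linalg.norm(s1), 1e-30)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = np.sin(2.0 * np.pi * ground_truth.drift_freq_hz * design.frame_times + phase)
    drift = drift - drift.mean()
    drift /= max(np.linalg.norm(drift), 1e-30)
    s2 = -s1 + ground_truth.drift_amplitude * drift
    s2 = s2 / max(np.linalg.norm(s2), 1e-30)
    return s1, s2


def simulate_acquisition_matrix(
    design: TaskDesign,
    ground_truth: GroundTruth,
    condition: str,
    geometry: VolumeGeometry,
    mask: np.ndarray,
    seed: np.random.SeedSequence | int | None = None,
    acquisition: AcquisitionId | None = None,
) -> tuple[DataMatrix, dict]:
    """Simulate one acquisition directly as a frames x masked-voxels matrix.

    Cheaper than materialising the 4D volume; the matrix uses the same
    x-fastest voxel ordering as :func:`taskpca.pca.build_data_matrix`.
    """
    if condition not in ground_truth.condition_gains:
        raise ValueError(f"no gains defined for condition {condition!r}")
    m = np.asarray(mask).astype(bool)
    rng = np.random.default_rng(seed)
    gain_i, gain_ii = ground_truth.condition_gains[condition]
    distracted = bool(rng.random() < ground_truth.distraction_prob.get(condition, 0.0))
    if distracted:
        # distraction strength scales with the subject's overall
        # responsiveness, keeping the pattern II : pattern I ratio fixed
        gain_ii = ground_truth.distracted_gain_ii * gain_i
        gain_i = gain_i * ground_truth.distracted_gain_i_factor
    if ground_truth.gain_cv > 0:
        # one shared lognormal factor per acquisition (scan quality / arousal):
        # scales both patterns, leaving their gain ratio fixed
        cv = ground_truth.gain_cv
        sigma_ln = np.sqrt(np.log1p(cv * cv))
        factor = float(np.exp(rng.normal(-sigma_ln**2 / 2.0, sigma_ln)))
        gain_i, gain_ii = gain_i * factor, gain_ii * factor
    s1, s2 = _pattern_time_courses(design, ground_truth, rng)
    p1, p2 = ground_truth.pattern_images
    values = gain_i * np.outer(s1, p1) + gain_ii * np.outer(s2, p2)
    if ground_truth.noise_sigma > 0:
        values = values + _smoothed_ar1_noise(
            design.n_frames,
            geometry,
            mask_order_indices(m),
            ground_truth.noise_sigma,
            ground_truth.noise_ar1,
            ground_truth.smoothing_fwhm_mm,
            rng,
        )
    meta = {
        "condition": condition,
        "gain_I": float(gain_i),
        "gain_II": float(gain_ii),
        "nominal_gain_I": ground_truth.condition_gains[condition][0],
        "nominal_gain_II": ground_truth.condition_gains[condition][1],
        "noise_sigma": ground_truth.noise_sigma,
        "noise_ar1": ground_truth.noise_ar1,
        "smoothing_fwhm_mm": ground_truth.smoothing_fwhm_mm,
        "drift_amplitude": ground_truth.drift_amplitude,
        "drift_freq_hz": ground_truth.drift_freq_hz,
        "distracted": distracted,
        "tr": design.tr,
        "n_frames": design.n_frames,
        "n_events": design.n_events,
        "seed": _seed_repr(seed),
    }
    return DataMatrix(values=values, mask=m, acquisition=acquisition), meta


def _seed_repr(seed) -> list | int | None:
    if isinstance(seed, np.random.SeedSequence):
        return [int(v) for v in np.atleast_1d(seed.entropy)]
    return seed


def simulate_acquisition(
    design: TaskDesign,
    ground_truth: GroundTruth,
    condition: str,
    geometry: VolumeGeometry,
    mask: np.ndarray,
    seed: np.random.SeedSequence | int | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate one acquisition as a 4D (x, y, z, t) array plus metadata."""
    matrix, meta = simulate_acquisition_matrix(
        design, ground_truth, condition, geometry, mask, seed
    )
    vol4 = np.zeros(geometry.dims + (design.n_frames,))
    for t in range(design.n_frames):
        vol4[..., t] = scatter_to_volume(matrix.values[t], mask)
    return vol4, meta


def calibrate_noise_sigma(
    design: TaskDesign,
    geometry: VolumeGeometry,
    mask: np.ndarray,
    ground_truth_like: GroundTruth,
    reference_gain: float,
    target_snr: float = 1.0,
    seed: int = 0,
) -> float:
    """Noise level giving a requested component signal-to-noise ratio.

    Component SNR is defined as the ratio of the signal singular value
    (``reference_gain``, since patterns and response are unit-norm) to the
    leading singular value of a pure-noise residual matrix at unit voxel
    sigma.  One noise realisation is simulated to measure the latter; the
    returned sigma makes the ratio ``target_snr``.
    """
    m = np.asarray(mask).astype(bool)
    noise = _smoothed_ar1_noise(
        design.n_frames,
        geometry,
        mask_order_indices(m),
        1.0,
        ground_truth_like.noise_ar1,
        ground_truth_like.smoothing_fwhm_mm,
        np.random.default_rng(seed),
    )
    noise -= noise.mean(axis=0, keepdims=True)
    noise -= noise.mean(axis=1, keepdims=True) - noise.mean()
    top = np.sqrt(np.linalg.eigvalsh(noise @ noise.T)[-1])
    return float(reference_gain / (target_snr * top))


@dataclass
class DatasetConfig:
    """Study conditions for a simulated two-condition dataset.

    Defaults mirror the emulated study: 10 subjects, two conditions
    (placebo/verum) with a 30% verum gain advantage for pattern I and more
    pattern II in placebo, two runs each, 224 frames at TR 2 s, 6 s events
    with 8-12 s gaps, 8 mm smoothing, and noise calibrated to component
    SNR ~= 1 at the placebo pattern-I gain.
    """

    n_subjects: int = 10
    n_runs: int = 2
    conditions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"placebo": (1.0, 0.35), "verum": (1.3, 0.35)}
    )
    distraction_prob: dict[str, float] = field(
        default_factory=lambda: {"placebo": 0.35, "verum": 0.15}
    )
    distracted_gain_ii: float = 1.4
    distracted_gain_i_factor: float = 1.0
    n_frames: int = 224
    tr: float = 2.0
    event_duration: float = 6.0
    gap_range: tuple[float, float] = (8.0, 12.0)
    noise_ar1: float = 0.3
    smoothing_fwhm_mm: float = 8.0
    drift_amplitude: float = 2.5
    drift_freq_hz: float = 0.012
    gain_cv: float = 0.15
    target_snr: float = 1.0
    noise_sigma: float | None = None  # None: calibrate to target_snr
    anticorrelation: float = 0.4
    mask_fraction: float = 0.9


def simulate_dataset(
    config: DatasetConfig,
    geometry: VolumeGeometry,
    master_seed: int,
):
    """Generate a full two-condition dataset lazily.

    Returns ``(mask, ground_truth, designs, acquisitions)`` where
    ``acquisitions`` is a generator of ``(AcquisitionId, DataMatrix, meta)``.
    Each acquisition draws its own task design and noise from the documented
    per-acquisition seed; pattern templates derive from the master seed alone
    so the ground truth is shared across the dataset.
    """
    mask = ellipsoid_mask(geometry, config.mask_fraction)
    p1, p2 = generate_pattern_templates(
        geometry, mask, seed=master_seed, anticorrelation=config.anticorrelation
    )
    proto = GroundTruth(
        pattern_images=(p1, p2),
        condition_gains=dict(config.conditions),
        noise_sigma=1.0,
        noise_ar1=config.noise_ar1,
        smoothing_fwhm_mm=config.smoothing_fwhm_mm,
        drift_amplitude=config.drift_amplitude,
        drift_freq_hz=config.drift_freq_hz,
        gain_cv=config.gain_cv,
        distraction_prob=dict(config.distraction_prob),
        distracted_gain_ii=config.distracted_gain_ii,
        distracted_gain_i_factor=config.distracted_gain_i_factor,
    )
    calib_design = generate_task_design(
        n_frames=config.n_frames,
        tr=config.tr,
        event_duration=config.event_duration,
        gap_range=config.gap_range,
        seed=master_seed,
    )
    if config.noise_sigma is not None:
        sigma = config.noise_sigma
    else:
        ref_gain = min(g[0] for g in config.conditions.values())
        sigma = calibrate_noise_sigma(
            calib_design, geometry, mask, proto, ref_gain, config.target_snr, seed=master_seed
        )
    truth = GroundTruth(
        pattern_images=(p1, p2),
        condition_gains=dict(config.conditions),
        noise_sigma=sigma,
        noise_ar1=config.noise_ar1,
        smoothing_fwhm_mm=config.smoothing_fwhm_mm,
        drift_amplitude=config.drift_amplitude,
        drift_freq_hz=config.drift_freq_hz,
        gain_cv=config.gain_cv,
        distraction_prob=dict(config.distraction_prob),
        distracted_gain_ii=config.distracted_gain_ii,
        distracted_gain_i_factor=config.distracted_gain_i_factor,
    )
    cond_names = list(config.conditions)
    designs: dict[AcquisitionId, TaskDesign] = {}

    def acquisitions():
        for s in range(config.n_subjects):
            for ci, cond in enumerate(cond_names):
                for run in range(config.n_runs):
                    ss = acquisition_seed(master_seed, s, ci, run)
                    child = ss.spawn(2)
                    design = generate_task_design(
                        n_frames=config.n_frames,
                        tr=config.tr,
                        event_duration=config.event_duration,
                        gap_range=config.gap_range,
                        seed=child[0],
                    )
                    acq = AcquisitionId(subject=f"sub-{s + 1:02d}", condition=cond, run=run + 1)
                    designs[acq] = design
                    matrix, meta = simulate_acquisition_matrix(
                        design, truth, cond, geometry, mask, seed=child[1], acquisition=acq
                    )
                    meta["subject"] = acq.subject
                    meta["run"] = acq.run
                    yield acq, design, matrix, meta

    return mask, truth, designs, acquisitions()


def write_ground_truth_sidecar(truth: GroundTruth, config: DatasetConfig, path) -> None:
    """JSON sidecar recording the generator parameters of a dataset."""
    payload = {
        "condition_gains": {k: list(v) for k, v in truth.condition_gains.items()},
        "noise_sigma": truth.noise_sigma,
        "noise_ar1": truth.noise_ar1,
        "smoothing_fwhm_mm": truth.smoothing_fwhm_mm,
        "drift_amplitude": truth.drift_amplitude,
        "drift_freq_hz": truth.drift_freq_hz,
        "gain_cv": truth.gain_cv,
        "distraction_prob": dict(truth.distraction_prob),
        "distracted_gain_ii": truth.distracted_gain_ii,
        "distracted_gain_i_factor": truth.distracted_gain_i_factor,
        "n_subjects": config.n_subjects,
        "n_runs": config.n_runs,
        "n_frames": config.n_frames,
        "tr": config.tr,
        "event_duration": config.event_duration,
        "gap_range": list(config.gap_range),
        "target_snr": config.target_snr,
        "anticorrelation": config.anticorrelation,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
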