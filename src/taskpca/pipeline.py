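"""Group analysis and the reproducible end-to-end pipeline.

``GroupAnalysis`` consumes per-acquisition fits: it pools the task-related
components of every acquisition, classifies them against the two reference
patterns, builds the per-condition mean component images (MCIs), runs the
second-level PCAs, the condition-comparison statistics and the salient-region
extraction.  ``run_pipeline`` wires the synthetic-data generator to a
``GroupAnalysis`` under a single seed and writes every ledger, image and
manifest into a run directory.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .classify import (
    DEFAULT_EFFECTIVE_DF,
    DEFAULT_VCC_THRESHOLD,
    ClassificationResult,
    ComponentRecord,
    MeanComponentImage,
    classification_table,
    classify_components,
    mean_component_image,
    volume_correlation,
)
from .design import TaskDesign, write_events_tsv
from .group_stats import (
    fisher_compare_correlations,
    fisher_exact_2x2,
    mahalanobis_analysis,
    mann_whitney,
    unpaired_t,
)
from .hrf import modeled_response, power_spectrum
from .model import EventRelatedPCA
from .pca import AcquisitionId, DataMatrix, scatter_to_volume
from .salient import cluster_table, salient_clusters
from .second_level import SecondLevelResult, second_level_pca
from .simulate import DatasetConfig, VolumeGeometry, reduced_geometry, simulate_dataset

__all__ = ["RunConfig", "GroupAnalysis", "GroupResults", "run_pipeline", "load_config"]

log = logging.getLogger("taskpca")

PATTERNS = ("I", "II")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    out_dir: str = "taskpca_run"
    seed: int = 0
    grid_scale: float = 0.5
    alpha: float = 0.01
    vcc_threshold: float = DEFAULT_VCC_THRESHOLD
    effective_df: int = DEFAULT_EFFECTIVE_DF
    ambiguity_delta: float = 0.05
    q_low: float = 1.0
    q_high: float = 99.0
    min_extent: int = 32
    connectivity: int = 18
    save_images: bool = True
    dataset: DatasetConfig = field(default_factory=DatasetConfig)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ds_raw = raw.pop("dataset", {})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    ds_known = set(DatasetConfig.__dataclass_fields__)
    ds_unknown = set(ds_raw) - ds_known
    if ds_unknown:
        raise ValueError(f"unknown dataset config keys: {sorted(ds_unknown)}")
    if "conditions" in ds_raw:
        ds_raw["conditions"] = {k: tuple(v) for k, v in ds_raw["conditions"].items()}
    if "gap_range" in ds_raw:
        ds_raw["gap_range"] = tuple(ds_raw["gap_range"])
    return RunConfig(dataset=DatasetConfig(**ds_raw), **raw)


class GroupAnalysis:
    """Classify pooled task-related components and compare conditions.

    Parameters
    ----------
    reference1, reference2
        Masked-voxel reference images for patterns I and II.
    conditions
        Ordered condition names; the second is treated as the active (verum)
        arm in condition-comparison statistics.
    """

    def __init__(
        self,
        reference1: np.ndarray,
        reference2: np.ndarray,
        conditions: tuple[str, str] = ("placebo", "verum"),
        vcc_threshold: float = DEFAULT_VCC_THRESHOLD,
        effective_df: int = DEFAULT_EFFECTIVE_DF,
        ambiguity_delta: float = 0.05,
        alpha: float = 0.01,
    ) -> None:
        self.reference1 = np.asarray(reference1, dtype=float)
        self.reference2 = np.asarray(reference2, dtype=float)
        self.conditions = conditions
        self.vcc_threshold = vcc_threshold
        self.effective_df = effective_df
        self.ambiguity_delta = ambiguity_delta
        self.alpha = alpha
        self.records: list[ComponentRecord] = []
        self.designs: dict[AcquisitionId, TaskDesign] = {}
        self.n_acquisitions = 0
        self._selection_tables: list[pd.DataFrame] = []

    def add_acquisition(
        self, matrix: DataMatrix, design: TaskDesign, acquisition: AcquisitionId
    ) -> int:
        """Fit one acquisition and pool its task-related components.

        Returns the number of task-related components found.
        """
        res = EventRelatedPCA(matrix, design, acquisition=acquisition).fit(alpha=self.alpha)
        self.designs[acquisition] = design
        self.n_acquisitions += 1
        self._selection_tables.append(res.selection_table())
        for rec in res.task_related:
            self.records.append(
                ComponentRecord(
                    acquisition=acquisition,
                    component=rec.component,
                    ecc=rec.ecc,
                    eigenimage=res.eigenimage(rec.component),
                    eigenvariate=res.eigenvariate(rec.component),
                )
            )
        log.info("fit %s: %d task-related PCs", acquisition, res.n_task_related)
        return res.n_task_related

    def run(self) -> "GroupResults":
        """Classify, average, decompose at second level and test."""
        if not self.records:
            raise ValueError("no task-related components pooled; nothing to classify")
        classified = classify_components(
            self.records,
            self.reference1,
            self.reference2,
            threshold=self.vcc_threshold,
            ambiguity_delta=self.ambiguity_delta,
        )
        mcis: dict[tuple[str, str], MeanComponentImage] = {}
        for cond in self.conditions:
            for pat in PATTERNS:
                try:
                    mcis[(cond, pat)] = mean_component_image(classified, pat, cond)
                except ValueError:
                    log.warning("no retained components for %s pattern %s", cond, pat)
        second_level: dict[str, SecondLevelResult] = {}
        refs = {"reference_I": self.reference1, "reference_II": self.reference2}
        for cond in self.conditions:
            imgs = [
                r.record.eigenimage
                for r in classified
                if r.record.acquisition.condition == cond
            ]
            if len(imgs) >= 3:
                cond_refs = dict(refs)
                if (cond, "I") in mcis:
                    cond_refs[f"MCI_{cond}_I"] = mcis[(cond, "I")].image
                second_level[cond] = second_level_pca(np.asarray(imgs), references=cond_refs)
        stats = self._condition_stats(classified, mcis)
        return GroupResults(
            analysis=self,
            classified=classified,
            mcis=mcis,
            second_level=second_level,
            stats=stats,
            selection=pd.concat(self._selection_tables, ignore_index=True)
            if self._selection_tables
            else pd.DataFrame(),
        )

    # -- statistics ---------------------------------------------------------

    def _cell(self, classified, cond, pat) -> list[ClassificationResult]:
        return [
            r
            for r in classified
            if r.retained and r.assigned_pattern == pat and r.record.acquisition.condition == cond
        ]

    def _condition_stats(self, classified, mcis) -> dict:
        c0, c1 = self.conditions  # baseline (placebo), active (verum)
        out: dict[str, dict | None] = {}
        for pat in PATTERNS:
            a = [r.record.ecc for r in self._cell(classified, c1, pat)]
            b = [r.record.ecc for r in self._cell(classified, c0, pat)]
            key = f"mann_whitney_ecc_pattern_{pat}"
            if len(a) >= 3 and len(b) >= 3:
                u, p = mann_whitney(np.abs(a), np.abs(b))
                out[key] = {"U": u, "p": p, "n_active": len(a), "n_baseline": len(b)}
            else:
                out[key] = None
        ref = {"I": self.reference1, "II": self.reference2}
        for pat in PATTERNS:
            a = [abs(r.best_vcc) for r in self._cell(classified, c1, pat)]
            b = [abs(r.best_vcc) for r in self._cell(classified, c0, pat)]
            key = f"t_test_vcc_pattern_{pat}"
            if len(a) >= 2 and len(b) >= 2:
                t, p = unpaired_t(a, b)
                out[key] = {"t": t, "p": p}
            else:
                out[key] = None
            key = f"fisher_z_mci_vcc_pattern_{pat}"
            if (c1, pat) in mcis and (c0, pat) in mcis:
                r1 = volume_correlation(mcis[(c1, pat)].image, ref[pat])
                r2 = volume_correlation(mcis[(c0, pat)].image, ref[pat])
                n = self.effective_df + 3
                z, p = fisher_compare_correlations(r1, n, r2, n)
                out[key] = {"r_active": r1, "r_baseline": r2, "z": z, "p": p}
            else:
                out[key] = None
        counts = [
            [len(self._cell(classified, c1, "I")), len(self._cell(classified, c0, "I"))],
            [len(self._cell(classified, c1, "II")), len(self._cell(classified, c0, "II"))],
        ]
        try:
            out["fisher_exact_counts"] = {
                "table": counts,
                "p": fisher_exact_2x2(counts),
            }
        except ValueError:
            out["fisher_exact_counts"] = None
        # joint (ecc, vcc) comparison for the variable pattern II
        pts = {}
        for cond in (c1, c0):
            cell = self._cell(classified, cond, "II")
            pts[cond] = np.array([[abs(r.record.ecc), abs(r.best_vcc)] for r in cell])
        if len(pts[c1]) >= 3 and len(pts[c0]) >= 3:
            mres = mahalanobis_analysis(pts[c1], pts[c0])
            out["mahalanobis_pattern_II"] = {
                "p": mres.p_value,
                "reference_condition": c1,
                "mean": mres.mean.tolist(),
            }
        else:
            out["mahalanobis_pattern_II"] = None
        return out


@dataclass
class GroupResults:
    """Everything the group analysis produced."""

    analysis: GroupAnalysis
    classified: list[ClassificationResult]
    mcis: dict[tuple[str, str], MeanComponentImage]
    second_level: dict[str, SecondLevelResult]
    stats: dict
    selection: pd.DataFrame

    def classification_table(self) -> pd.DataFrame:
        return classification_table(self.classified)

    def counts_table(self) -> pd.DataFrame:
        """Bookkeeping of components per condition, pattern and exclusion reason."""
        df = self.classification_table()
        return (
            df.groupby(["condition", "assigned_pattern", "exclusion_reason"])
            .size()
            .rename("n")
            .reset_index()
        )

    def mci_vcc(self, condition: str, pattern: str, image: np.ndarray) -> float:
        return volume_correlation(self.mcis[(condition, pattern)].image, image)

    def summary(self) -> str:
        lines = [
            "Group PCA analysis",
            "=" * 64,
            f"acquisitions fitted:     {self.analysis.n_acquisitions}",
            f"task-related components: {len(self.analysis.records)}",
            f"vcc threshold:           {self.analysis.vcc_threshold}",
        ]
        df = self.classification_table()
        for cond in self.analysis.conditions:
            sub = df[df.condition == cond]
            n_ret = {
                p: int(((sub.assigned_pattern == p) & (sub.exclusion_reason == "retained")).sum())
                for p in PATTERNS
            }
            lines.append(
                f"  {cond:<10} task-related {len(sub):>3}   retained I: {n_ret['I']:>3} "
                f"  retained II: {n_ret['II']:>3}"
            )
        for (cond, pat), mci in sorted(self.mcis.items()):
            lines.append(
                f"  {mci.label}: {len(mci.contributors)} contributors"
            )
        for cond, sl in self.second_level.items():
            vccs = ", ".join(f"{k}={v:.2f}" for k, v in sl.pc1_vccs.items())
            lines.append(
                f"  second-level {cond}: PC1 variance "
                f"{100 * sl.pc1_variance_fraction:.1f}%  ({vccs})"
            )
        for name, res in self.stats.items():
            if res is None:
                lines.append(f"  {name}: not computable")
            elif "p" in res:
                lines.append(f"  {name}: p = {res['p']:.4g}")
        lines.append("=" * 64)
        return "\n".join(lines)


def run_pipeline(config: RunConfig, geometry: VolumeGeometry | None = None) -> Path:
    """Simulate, decompose, select, classify, aggregate, test and report.

    Deterministic for a given config and seed.  Returns the run directory,
    which holds the selection/classification/counts ledgers, MCI images,
    second-level summaries, cluster tables, the stats report, mean-eigenvariate
    spectra and a machine-readable manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logging.basicConfig(level=logging.INFO)
    file_handler = logging.FileHandler(out / "run.log")
    log.addHandler(file_handler)
    stage = "simulate"
    try:
        if geometry is None:
            geometry = reduced_geometry(config.grid_scale)
        mask, truth, designs, acquisitions = simulate_dataset(
            config.dataset, geometry, master_seed=config.seed
        )
        group = GroupAnalysis(
            reference1=truth.pattern_images[0],
            reference2=truth.pattern_images[1],
            conditions=tuple(config.dataset.conditions),
            vcc_threshold=config.vcc_threshold,
            effective_df=config.effective_df,
            ambiguity_delta=config.ambiguity_delta,
            alpha=config.alpha,
        )
        stage = "decompose/select"
        first_design = None
        for acq, design, matrix, meta in acquisitions:
            if first_design is None:
                first_design = design
            group.add_acquisition(matrix, design, acq)
        stage = "classify/aggregate/stats"
        results = group.run()
        stage = "report"
        _write_outputs(out, config, geometry, mask, results, first_design)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    finally:
        log.removeHandler(file_handler)
        file_handler.close()
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def _write_outputs(out, config, geometry, mask, results: GroupResults, design) -> None:
    from .io import save_image

    results.selection.to_csv(out / "selection.csv", index=False)
    results.classification_table().to_csv(out / "classification.csv", index=False)
    results.counts_table().to_csv(out / "counts.csv", index=False)
    if design is not None:
        write_events_tsv(design, out / "events_example.tsv")
    spectra_rows = []
    cluster_frames = []
    for (cond, pat), mci in results.mcis.items():
        if config.save_images:
            vol = scatter_to_volume(mci.image, mask)
            save_image(vol, geometry.affine, out / f"{mci.label}.nii.gz")
        spec = power_spectrum(mci.mean_eigenvariate, config.dataset.tr)
        spectra_rows.append(
            pd.DataFrame(
                {
                    "label": mci.label,
                    "frequency_hz": spec.frequencies,
                    "power": spec.power,
                }
            )
        )
        vol = scatter_to_volume(mci.image, mask)
        ct = cluster_table(
            salient_clusters(
                vol,
                mask,
                geometry.affine,
                q_low=config.q_low,
                q_high=config.q_high,
                min_extent=config.min_extent,
                connectivity=config.connectivity,
            )
        )
        ct.insert(0, "image", mci.label)
        cluster_frames.append(ct)
    if design is not None:
        resp = modeled_response(design)
        spec = power_spectrum(resp.values, design.tr)
        spectra_rows.append(
            pd.DataFrame(
                {"label": "modeled_response", "frequency_hz": spec.frequencies, "power": spec.power}
            )
        )
    if spectra_rows:
        pd.concat(spectra_rows, ignore_index=True).to_csv(out / "spectra.csv", index=False)
    if cluster_frames:
        pd.concat(cluster_frames, ignore_index=True).to_csv(out / "clusters.csv", index=False)
    sl_rows = []
    for cond, sl in results.second_level.items():
        row = {
            "condition": cond,
            "pc1_variance_fraction": sl.pc1_variance_fraction,
        }
        row.update({f"pc1_vcc_{k}": v for k, v in sl.pc1_vccs.items()})
        sl_rows.append(row)
    pd.DataFrame(sl_rows).to_csv(out / "second_level.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(results.stats, fh, indent=2, default=_json_default)
    manifest = {
        "package": "taskpca",
        "version": _pkg_version,
        "seed": config.seed,
        "grid": list(geometry.dims),
        "stages": [
            "simulate",
            "decompose",
            "select",
            "classify",
            "aggregate",
            "second_level",
            "clusters",
            "stats",
            "report",
        ],
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "dataset"},
            "dataset": asdict(config.dataset),
        },
        "counts": {
            "acquisitions": results.analysis.n_acquisitions,
            "task_related": len(results.analysis.records),
            "retained": int(sum(r.retained for r in results.classified)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
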