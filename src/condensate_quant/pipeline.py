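"""Per-image and per-series orchestration.

``analyze_image`` is the single-image workflow (median filter → mode
background subtraction → intensity-weighted histogram → 2/3/4-component
Gaussian-sum fits → adjusted-R² selection → mean+3·SD segmentation → objects
and phase metrics); ``analyze_series`` maps it over an image collection and
runs the concentration-dependence analysis. ``run_image``/``run_series`` are
the file-based entry points used by the CLI.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .behaviour import BehaviourVerdict, VERDICT_METRICS, binned_profile, correlate_metrics, series_table
from .config import RunConfig
from .core import CondensateQuantError, VolumetricImage
from .gmm import (
    CompartmentSegmentation,
    GmmCurveFit,
    background_ceiling_from_image,
    fit_candidates,
    segment_compartments,
    select_model,
)
from .io import load_volumetric, save_volumetric
from .metrics import CondensateObject, PhaseMetrics, compute_phase_metrics, label_condensates
from .preprocessing import median_filter_3d, subtract_mode_background, weighted_intensity_histogram

__all__ = ["ImageReport", "analyze_image", "analyze_series", "run_image", "run_series"]

log = logging.getLogger(__name__)


@dataclass
class ImageReport:
    image_id: str
    mode_background: float
    candidate_fits: dict[int, GmmCurveFit]
    fit: GmmCurveFit
    segmentation: CompartmentSegmentation
    objects: list[CondensateObject]
    metrics: PhaseMetrics

    def summary(self) -> dict:
        return {
            "image_id": self.image_id,
            "mode_background": self.mode_background,
            "k_selected": self.fit.k,
            "adjusted_r_square": {k: f.adjusted_r_square for k, f in self.candidate_fits.items()},
            "converged": {k: f.converged for k, f in self.candidate_fits.items()},
            "components": [
                {"weight": c.weight, "mean": c.mean, "sd": c.sd} for c in self.fit.components
            ],
            "nucleus_threshold": self.segmentation.nucleus_threshold,
            "condensate_threshold": self.segmentation.condensate_threshold,
            "metrics": self.metrics.as_dict(),
        }


def analyze_image(
    img: VolumetricImage, config: RunConfig | None = None, image_id: str = "image"
) -> ImageReport:
    """Run the full single-image characterisation on an in-memory stack."""
    cfg = config or RunConfig()
    filtered = median_filter_3d(img, cfg.median_kernel)
    corrected, mode_value = subtract_mode_background(filtered)
    hist = weighted_intensity_histogram(corrected, cfg.n_bins, cfg.histogram_weighting)
    ceiling = background_ceiling_from_image(corrected.data, cfg.background_ceiling_quantile)
    fits = fit_candidates(
        hist,
        cfg.k_candidates,
        n_starts=cfg.n_starts,
        rng_seed=cfg.rng_seed,
        max_nfev=cfg.max_nfev,
        background_ceiling=ceiling,
    )
    fit = select_model(fits, tol=cfg.selection_tol)
    seg = segment_compartments(corrected, fit)
    objects = label_condensates(corrected, seg, cfg.min_size)
    metrics = compute_phase_metrics(corrected, seg, objects)
    return ImageReport(
        image_id=image_id,
        mode_background=mode_value,
        candidate_fits=fits,
        fit=fit,
        segmentation=seg,
        objects=objects,
        metrics=metrics,
    )


def analyze_series(
    images: Iterable[VolumetricImage],
    config: RunConfig | None = None,
    image_ids: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, BehaviourVerdict, list[ImageReport], dict[str, str]]:
    """Characterise every image and run the cross-image analysis.

    Per-image failures are collected (id → reason), not fatal; fewer than 3
    successes raise."""
    cfg = config or RunConfig()
    reports: list[ImageReport] = []
    failures: dict[str, str] = {}
    for i, img in enumerate(images):
        iid = image_ids[i] if image_ids is not None else f"img{i:03d}"
        try:
            reports.append(analyze_image(img, cfg, image_id=iid))
        except (CondensateQuantError, ValueError) as exc:
            failures[iid] = str(exc)
            log.warning("image %s failed: %s", iid, exc)
    if len(reports) < 3:
        raise CondensateQuantError(
            f"only {len(reports)} of {len(reports) + len(failures)} images analysable "
            f"(need >= 3); failures: {failures}"
        )
    table = series_table([r.metrics for r in reports], [r.image_id for r in reports])
    table["k_selected"] = [r.fit.k for r in reports]
    table["adj_r2"] = [r.fit.adjusted_r_square for r in reports]
    verdict = correlate_metrics(
        table,
        p_threshold=cfg.p_threshold,
        r_flat=cfg.r_flat,
        rel_change_threshold=cfg.rel_change_threshold,
    )
    return table, verdict, reports, failures


def _write_image_outputs(report: ImageReport, out_dir: Path, cfg: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{report.image_id}_report.json").write_text(
        json.dumps(report.summary(), indent=2)
    )
    if report.objects:
        pd.DataFrame([vars(o) for o in report.objects]).to_csv(
            out_dir / f"{report.image_id}_objects.csv", index=False
        )
    if cfg.write_masks:
        import tifffile

        tifffile.imwrite(
            out_dir / f"{report.image_id}_masks.tif",
            (
                report.segmentation.nucleus_mask.astype(np.uint8)
                + report.segmentation.condensate_mask.astype(np.uint8)
            ),
        )


def run_image(path: Path | str, config: RunConfig | None = None, out_dir: Path | str | None = None) -> ImageReport:
    """Characterise one TIFF stack; optionally write the JSON/CSV report."""
    cfg = config or RunConfig()
    path = Path(path)
    img = load_volumetric(path, voxel_size=cfg.voxel_size)
    report = analyze_image(img, cfg, image_id=path.stem)
    if out_dir is not None:
        _write_image_outputs(report, Path(out_dir), cfg)
    return report


def run_series(
    paths: Sequence[Path | str],
    config: RunConfig | None = None,
    out_dir: Path | str | None = None,
):
    """Characterise a series of TIFF stacks and classify its phase behaviour.

    Unreadable files are logged and skipped like any other per-image failure.
    """
    cfg = config or RunConfig()
    images, ids, failures0 = [], [], {}
    for p in paths:
        p = Path(p)
        try:
            images.append(load_volumetric(p, voxel_size=cfg.voxel_size))
            ids.append(p.stem)
        except Exception as exc:  # unreadable input is a per-file failure
            failures0[p.stem] = f"unreadable: {exc}"
            log.warning("could not read %s: %s", p, exc)
    table, verdict, reports, failures = analyze_series(images, cfg, ids)
    failures = {**failures0, **failures}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv")
        objects = [
            {"image_id": r.image_id, **vars(o)} for r in reports for o in r.objects
        ]
        pd.DataFrame(objects).to_csv(out / "objects.csv", index=False)
        (out / "verdict.json").write_text(json.dumps(verdict.as_dict(), indent=2))
        for metric in VERDICT_METRICS:
            binned_profile(table, metric, cfg.profile_bins).to_csv(
                out / f"profile_{metric}.csv", index=False
            )
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=2))
    return table, verdict, reports, failures
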