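"""Pipeline orchestration: configuration, logging, and end-to-end runs.

Two entry points:

* :func:`run_image_pipeline` — bright-field + FISH stacks → segmentation →
  spot detection → per-cell counts → fluorescence extrapolation → report.
* :func:`run_counts_pipeline` — an existing per-cell count table → polar θ
  statistics, burst-size inference, and population statistics.

Every report records the configuration and seed used, so a rerun with the
same config is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from . import burst, imgquant, polar, popstats

logger = logging.getLogger("thfish")

__all__ = [
    "RunConfig",
    "load_config",
    "run_counts_pipeline",
    "run_image_pipeline",
    "report_to_json",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AnalysisSection(_Section):
    ifng_on_threshold: int = 20
    il4_on_threshold: int = 50
    r_min: float = 10.0
    resolvable_max: int = 200
    no_correlation_cut: float = 0.1
    u_index_cut: float = 0.7
    n_bins: int = 10
    burst_on_threshold: float = 0.0


class SegmentationSection(_Section):
    canny_sigma: float = 2.0
    min_area_px: int = 500
    max_area_px: int | None = None


class DetectionSection(_Section):
    sigma_px: float = 1.5
    threshold: float | None = None  # None = automatic plateau selection


class RunConfig(_Section):
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 0
    log_level: str = "INFO"
    brightfield: str | None = None
    channels: dict[str, str] = {}
    counts_csv: str | None = None
    out_csv: str | None = None
    out_report: str | None = None
    analysis: AnalysisSection = AnalysisSection()
    segmentation: SegmentationSection = SegmentationSection()
    detection: DetectionSection = DetectionSection()
    regime: dict | None = None
    scene: dict | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return RunConfig(**data)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %-22s %.2f s", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def _read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:  # pandas messages carry the line number
        raise ValueError(f"malformed CSV {path}: {e}") from None
    if df.empty:
        raise ValueError(f"empty count table: {path}")
    return df


def run_counts_pipeline(counts: pd.DataFrame | str | Path, config: RunConfig) -> dict:
    """Polar, burst, and population statistics on a per-cell count table."""
    if not isinstance(counts, pd.DataFrame):
        counts = _read_counts(counts)
    if counts.empty:
        raise ValueError("empty count table")
    cfg = config.analysis
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "n_cells": int(len(counts)),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if {"tbx21", "gata3"}.issubset(counts.columns):
        with _stage("polar"):
            tab = polar.polar_table(counts["tbx21"].to_numpy(), counts["gata3"].to_numpy())
            kept, n_excl = polar.filter_r(tab, r_min=cfg.r_min)
            if len(kept):
                summ = polar.theta_summary(
                    kept["theta"].to_numpy(), n_excluded=n_excl, n_bins=cfg.n_bins
                )
                d_unif, p_unif = polar.uniformity_test(kept["theta"].to_numpy())
                report["polar"] = {
                    "n_kept": summ.n_kept,
                    "n_excluded": summ.n_excluded,
                    "median_theta": summ.median_theta,
                    "u_index": summ.u_index,
                    "hist_densities": summ.densities.tolist(),
                    "hist_edges": summ.bin_edges.tolist(),
                    "uniformity_D": d_unif,
                    "uniformity_p": p_unif,
                    "consistent_with_uniform": bool(p_unif > 0.01),
                    "u_shaped": bool(summ.u_index > cfg.u_index_cut),
                }

    report["burst_fits"] = {}
    for gene in ("ifng", "il4", "tbx21", "gata3"):
        if gene not in counts.columns:
            continue
        try:
            with _stage(f"burst fit {gene}"):
                fit = burst.fit_gamma(
                    counts[gene].to_numpy(), on_threshold=cfg.burst_on_threshold
                )
            report["burst_fits"][gene] = {
                "shape_a": fit.shape_a,
                "scale_b": fit.scale_b,
                "burst_size": burst.burst_size(fit),
                "n_fit": fit.n_fit,
                "loglik": fit.loglik,
            }
        except ValueError as e:
            report["burst_fits"][gene] = {"error": str(e)}

    with _stage("population stats"):
        pop: dict = {}
        for gene, thr in (("ifng", cfg.ifng_on_threshold), ("il4", cfg.il4_on_threshold)):
            if gene in counts.columns:
                pop[f"on_fraction_{gene}"] = popstats.on_fraction(counts[gene].to_numpy(), thr)
        if {"x_um", "y_um"}.issubset(counts.columns):
            pos = counts[["x_um", "y_um"]].to_numpy()
            for gene, tf, thr in (
                ("ifng", "tbx21", cfg.ifng_on_threshold),
                ("il4", "gata3", cfg.il4_on_threshold),
            ):
                if gene not in counts.columns or tf not in counts.columns:
                    continue
                try:
                    d = popstats.nearest_producer_distance(
                        pos, counts[gene].to_numpy(), thr
                    )
                    pop[f"nearest_{gene}_producer"] = popstats.distance_correlation_check(
                        counts[tf].to_numpy(), d, cfg.no_correlation_cut
                    )
                except ValueError as e:
                    pop[f"nearest_{gene}_producer"] = {"error": str(e)}
        for gene, tf in (("ifng", "tbx21"), ("il4", "gata3")):
            if gene in counts.columns and tf in counts.columns:
                try:
                    ci = popstats.conditional_invariance(
                        counts[tf].to_numpy(), counts[gene].to_numpy()
                    )
                    pop[f"conditional_invariance_{tf}_given_{gene}"] = {
                        "max_D": ci["max_D"],
                        "min_p_adj": ci["min_p_adj"],
                        "invariant": ci["invariant"],
                    }
                except ValueError as e:
                    pop[f"conditional_invariance_{tf}_given_{gene}"] = {"error": str(e)}
        report["popstats"] = pop
    return report


def run_image_pipeline(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Full imaging pipeline: stacks → per-cell table → count-table report.

    ``config.brightfield`` and ``config.channels`` (gene → TIFF path) must be
    set.  Returns the per-cell quantification table and the report dict.
    """
    if config.brightfield is None or not config.channels:
        raise ValueError("image pipeline requires brightfield and channels paths")
    bf_path = Path(config.brightfield)
    if not bf_path.exists():
        raise FileNotFoundError(f"brightfield stack not found: {bf_path}")
    stacks: dict[str, imgquant.ImageStack] = {}
    for gene, p in config.channels.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"channel {gene}: stack not found: {p}")
        stacks[gene] = imgquant.ImageStack(
            tifffile.imread(p), pixel_size_um=0.13, channel=gene
        )
    bf = imgquant.ImageStack(tifffile.imread(bf_path), pixel_size_um=0.13, channel="brightfield")

    seg = config.segmentation
    with _stage("segment_cells"):
        mask = imgquant.segment_cells(
            bf,
            canny_sigma=seg.canny_sigma,
            min_area_px=seg.min_area_px,
            max_area_px=seg.max_area_px,
        )
    if mask.n_cells == 0:
        raise RuntimeError(f"no cells segmented in {bf_path}")

    all_spots: list[imgquant.Spot] = []
    for gene, stack in stacks.items():
        with _stage(f"detect_spots {gene}"):
            thr = config.detection.threshold
            spots = imgquant.detect_spots(stack, sigma_px=config.detection.sigma_px, threshold=thr)
        all_spots.extend(spots)

    with _stage("assign_spots"):
        counts, n_bg = imgquant.assign_spots(all_spots, mask)
        logger.info("%d spots on background discarded", n_bg)

    with _stage("quantify_fluorescence"):
        fluor_central = {g: imgquant.quantify_fluorescence(s, mask) for g, s in stacks.items()}
        fluor_sum = {g: imgquant.quantify_fluorescence(s, mask, z_mode="sum") for g, s in stacks.items()}

    cents = mask.centroids()
    px = bf.pixel_size_um
    cells = pd.DataFrame(
        {
            "cell_id": mask.cell_ids,
            "area_px": mask.areas(),
            "x_um": cents[:, 1] * px,
            "y_um": cents[:, 0] * px,
        }
    )
    for gene in stacks:
        col = counts[gene].reindex(mask.cell_ids).fillna(0).to_numpy() if gene in counts else np.zeros(mask.n_cells)
        cells[f"{gene}_count"] = col.astype(float)
        cells[f"{gene}_fluor"] = [fluor_central[gene][i] for i in mask.cell_ids]
        with _stage(f"extrapolate {gene}"):
            try:
                fl = np.array([fluor_sum[gene][i] for i in mask.cell_ids])
                new_counts, slope = imgquant.extrapolate_counts(
                    cells[f"{gene}_count"].to_numpy(), fl, config.analysis.resolvable_max
                )
                cells[f"{gene}_count"] = new_counts
            except ValueError as e:
                logger.info("extrapolation skipped for %s: %s", gene, e)

    table = cells.rename(columns={f"{g}_count": g for g in stacks})
    report = run_counts_pipeline(table, config)
    report["segmentation"] = {"n_cells": mask.n_cells}
    report["spots_on_background"] = int(n_bg)

    if config.out_csv:
        cells.to_csv(config.out_csv, index=False)
    if config.out_report:
        report_to_json(report, config.out_report)
    return cells, report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
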