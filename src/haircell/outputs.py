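"""End-to-end analysis runs, per-cell CSV tables, overlays, batch mode.

`analyze_image` chains the full pipeline on one micrograph: tiling →
per-tile detection → merge (confidence rejection + NMS + optional
path-distance filter) → automated or manual cochlear path → Greenwood
frequency assignment → cochleogram. `run_batch` applies it over folders;
`run_pieces`/`combine_pieces` implement the multi-piece workflow where a
cochlea dissected into several pieces is analyzed piecewise with manual
paths and recombined apex→base into one cochleogram.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import tiling
from .detection import ReferenceDetector
from .errors import InputError
from .frequency import (
    DEFAULT_BIN_SIZE_PERCENT,
    DEFAULT_SPECIES,
    Cochleogram,
    CellRecord,
    GreenwoodParams,
    assign_frequencies,
    build_cochleogram,
    get_params,
)
from .image_io import MultiChannelImage, load_image
from .merge import MergeConfig, merge_detections
from .path_estimation import CochlearPath, estimate_path, load_manual_path, project_cells, swap_apex

logger = logging.getLogger("haircell")

IMAGE_SUFFIXES = (".tif", ".tiff", ".png", ".jpg", ".jpeg")

CSV_COLUMNS = [
    "cell_id", "label", "score",
    "box_row0", "box_col0", "box_row1", "box_col1",
    "centroid_row", "centroid_col",
    "distance_um_from_apex", "percent_from_apex", "frequency_khz",
    "distance_to_path_um",
]


@dataclass
class AnalysisConfig:
    """Every effective parameter of one analysis run."""

    tile_size: int = tiling.DEFAULT_TILE_SIZE
    overlap: float = tiling.DEFAULT_OVERLAP
    skip_blank: bool = False
    blank_min_intensity: float = tiling.DEFAULT_BLANK_MIN_INTENSITY
    blank_min_fraction: float = tiling.DEFAULT_BLANK_MIN_FRACTION
    backend: str = "reference"
    weights: Optional[str] = None
    blob_sigma_px: float = 1.5
    min_peak: float = 0.2
    cell_threshold: float = 0.3
    nms_threshold: float = 0.30
    path_filter_um: Optional[float] = None
    estimate_path: bool = True
    curve_path: Optional[str] = None
    path_channel: Optional[int] = None
    path_threshold: Optional[float] = None
    swap_apex: bool = False
    species: str = DEFAULT_SPECIES
    greenwood_override: Optional[tuple] = None  # (A, a, k)
    bin_size_percent: float = DEFAULT_BIN_SIZE_PERCENT
    pixel_size_nm: float = 288.0
    seed: int = 0

    def greenwood(self) -> GreenwoodParams:
        if self.greenwood_override is not None:
            A, a, k = self.greenwood_override
            return GreenwoodParams(A=A, a=a, k=k, species="custom")
        return get_params(self.species)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    """Finalized cells, path, cochleogram, and the config that produced them."""

    cells: list  # CellRecord
    path: Optional[CochlearPath]
    cochleogram: Optional[Cochleogram]
    config_snapshot: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    detections: list = field(default_factory=list)  # merged Detections
    n_tiles: int = 0
    n_tiles_skipped: int = 0


def _make_backend(config: AnalysisConfig, img: MultiChannelImage):
    if config.backend == "reference":
        soma = img.channel_with_role("cell_body", default=0)
        bundle = img.channel_with_role("bundle", default=img.n_channels - 1)
        return ReferenceDetector(
            blob_sigma_px=config.blob_sigma_px,
            min_peak=config.min_peak,
            bundle_channel=bundle,
            soma_channel=soma,
        )
    if config.backend == "learned":
        from .detection import load_learned_backend

        return load_learned_backend(config.weights)
    raise InputError(f"unknown backend {config.backend!r}")


def detect_cells(img: MultiChannelImage, config: AnalysisConfig) -> tuple:
    """Tile, detect, and merge; returns (detections, n_tiles, n_skipped)."""
    backend = _make_backend(config, img)
    tiles = tiling.plan_tiles(*img.shape, tile_size=config.tile_size, overlap_fraction=config.overlap)
    raw = []
    skipped = 0
    for tile in tiles:
        crop = tile.extract(img.pixels)
        if config.skip_blank and tiling.is_blank(
            crop, config.blank_min_intensity, config.blank_min_fraction
        ):
            skipped += 1
            continue
        for det in backend.detect(crop):
            raw.append(tiling.to_global(det, tile))
    merge_cfg = MergeConfig(
        score_threshold=config.cell_threshold,
        nms_iou_threshold=config.nms_threshold,
        max_path_distance_um=None,  # applied later, once the path exists
    )
    merged = merge_detections(raw, merge_cfg)
    return merged, len(tiles), skipped


def analyze_detections(
    dets: list,
    path: Optional[CochlearPath],
    config: AnalysisConfig,
    warnings_list: Optional[list] = None,
) -> AnalysisReport:
    """Post-detection analysis: path filtering, projection, frequency, bins."""
    warnings_list = list(warnings_list or [])
    cells: list = []
    cochleogram = None
    if path is not None:
        if config.path_filter_um is not None:
            from .merge import filter_by_path_distance

            before = len(dets)
            dets = filter_by_path_distance(dets, path, config.path_filter_um)
            if before != len(dets):
                logger.info("path-distance filter removed %d detections", before - len(dets))
        projections = project_cells(dets, path)
        cells = assign_frequencies(projections, config.greenwood(), total_length_um=path.total_length_um)
        cochleogram = build_cochleogram(cells, config.bin_size_percent)
        if path.apex_tie_flag:
            warnings_list.append("apex inference ambiguous; verify apex/base designation")
    else:
        # no path: emit records without tonotopic fields
        for i, det in enumerate(sorted(dets, key=lambda d: d.centroid), start=1):
            cells.append(
                CellRecord(
                    cell_id=i, label=det.label, centroid=det.centroid,
                    percent_from_apex=float("nan"), distance_um_from_apex=float("nan"),
                    frequency_khz=float("nan"), score=det.score, box=det.box,
                )
            )
    return AnalysisReport(
        cells=cells, path=path, cochleogram=cochleogram,
        config_snapshot=config.snapshot(), warnings=warnings_list, detections=list(dets),
    )


def analyze_image(img: MultiChannelImage, config: AnalysisConfig) -> AnalysisReport:
    """Full pipeline on one loaded image."""
    merged, n_tiles, skipped = detect_cells(img, config)
    path = None
    warns: list = []
    if config.curve_path:
        path = load_manual_path(config.curve_path, img.pixel_size_nm)
    elif config.estimate_path:
        path = estimate_path(
            img, channel=config.path_channel, threshold=config.path_threshold, seed=config.seed
        )
    if path is not None and config.swap_apex:
        path = swap_apex(path)
    report = analyze_detections(merged, path, config, warns)
    report.n_tiles = n_tiles
    report.n_tiles_skipped = skipped
    return report


def report_to_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for c in report.cells:
        rows.append(
            dict(
                cell_id=c.cell_id, label=c.label, score=round(c.score, 4),
                box_row0=c.box[0] if c.box else float("nan"),
                box_col0=c.box[1] if c.box else float("nan"),
                box_row1=c.box[2] if c.box else float("nan"),
                box_col1=c.box[3] if c.box else float("nan"),
                centroid_row=c.centroid[0], centroid_col=c.centroid[1],
                distance_um_from_apex=(
                    round(c.distance_um_from_apex, 1) if np.isfinite(c.distance_um_from_apex) else None
                ),
                percent_from_apex=(
                    round(c.percent_from_apex, 3) if np.isfinite(c.percent_from_apex) else None
                ),
                frequency_khz=(
                    round(c.frequency_khz, 2) if np.isfinite(c.frequency_khz) else None
                ),
                distance_to_path_um=(
                    round(c.distance_to_path_um, 1)
                    if c.distance_to_path_um is not None and np.isfinite(c.distance_to_path_um)
                    else None
                ),
            )
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_csv(report: AnalysisReport, path) -> Path:
    """Per-cell table: one row per finalized cell, RFC-4180, UTF-8.

    Tonotopic columns are left empty when no path was available.
    """
    path = Path(path)
    try:
        report_to_frame(report).to_csv(path, index=False, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write CSV to {path}: {exc}") from exc
    return path


def read_cells_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"cell table not found: {path}")
    return pd.read_csv(path)


def render_overlay(img: MultiChannelImage, report: AnalysisReport, out_path=None, annotate: bool = True):
    """Diagnostic overlay: IHC yellow squares, OHC green circles, the path
    as a blue line, the apex as a teal circle and the base as a red one.

    Returns the matplotlib figure; the caller may save or close it.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    rgb = np.zeros((*img.shape, 3))
    soma = img.channel_with_role("cell_body", default=0)
    bundle = img.channel_with_role("bundle", default=img.n_channels - 1)
    rgb[..., 2] = img.pixels[soma]
    rgb[..., 0] = img.pixels[bundle]
    ax.imshow(rgb)

    ihc = [c for c in report.cells if c.label == "IHC"]
    ohc = [c for c in report.cells if c.label == "OHC"]
    if ihc:
        ax.scatter([c.centroid[1] for c in ihc], [c.centroid[0] for c in ihc],
                   s=30, marker="s", facecolors="none", edgecolors="yellow", label="IHC")
    if ohc:
        ax.scatter([c.centroid[1] for c in ohc], [c.centroid[0] for c in ohc],
                   s=30, marker="o", facecolors="none", edgecolors="lime", label="OHC")
    if annotate and 0 < len(report.cells) <= 300:
        for c in report.cells:
            text = f"{c.cell_id}"
            if np.isfinite(c.frequency_khz):
                text += f"\n{c.distance_um_from_apex:.1f}um\n{c.frequency_khz:.2f}kHz"
            ax.annotate(text, (c.centroid[1], c.centroid[0]), fontsize=4, color="white")
    if report.path is not None:
        ax.plot(report.path.points[:, 1], report.path.points[:, 0], color="blue", lw=1.0)
        ax.scatter([report.path.apex_point[1]], [report.path.apex_point[0]],
                   s=80, color="teal", zorder=5, label="apex")
        ax.scatter([report.path.base_point[1]], [report.path.base_point[0]],
                   s=80, color="red", zorder=5, label="base")
    ax.set_axis_off()
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
    return fig


def plot_cochleogram(cochleogram: Cochleogram, out_path=None):
    """Per-class cell counts vs percent cochlear length (apex at 0%)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    centers = cochleogram.bin_centers
    axes[0].bar(centers, cochleogram.counts_ihc, width=cochleogram.bin_size_percent, color="goldenrod")
    axes[0].set_ylabel("IHC count")
    axes[1].bar(centers, cochleogram.counts_ohc, width=cochleogram.bin_size_percent, color="seagreen")
    axes[1].set_ylabel("OHC count")
    axes[1].set_xlabel("distance from apex (% of cochlear length)")
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
    return fig


def combine_pieces(reports: list, bin_size_percent: float = DEFAULT_BIN_SIZE_PERCENT) -> tuple:
    """Combine per-piece reports (given in apex→base order) into one
    cochleogram over the concatenated length.

    Pieces contribute cumulative arc length in the declared order; piece
    ordering is the user's responsibility. Returns ``(cells, cochleogram)``
    with globally renumbered cell ids and global percent positions.
    """
    if not reports:
        raise InputError("no piece reports to combine")
    lengths = []
    for rep in reports:
        if rep.path is None:
            raise InputError("every piece needs a (manual) path to combine")
        lengths.append(rep.path.total_length_um)
    total = float(sum(lengths))
    offsets = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    combined = []
    for rep, offset in zip(reports, offsets):
        for c in rep.cells:
            global_um = offset + c.percent_from_apex / 100.0 * rep.path.total_length_um
            combined.append(
                dataclasses.replace(
                    c,
                    percent_from_apex=global_um / total * 100.0,
                    distance_um_from_apex=global_um,
                )
            )
    combined.sort(key=lambda c: c.percent_from_apex)
    for i, c in enumerate(combined, start=1):
        c.cell_id = i
    return combined, build_cochleogram(combined, bin_size_percent)


def find_images(inputs) -> list:
    paths = []
    for item in np.atleast_1d(inputs):
        p = Path(item)
        if p.is_dir():
            paths.extend(sorted(q for q in p.rglob("*") if q.suffix.lower() in IMAGE_SUFFIXES))
        elif p.suffix.lower() in IMAGE_SUFFIXES:
            paths.append(p)
    return paths


def run_batch(inputs, config: AnalysisConfig, out_dir, curve_paths: Optional[list] = None, overlays: bool = True) -> dict:
    """Analyze every image under *inputs*; write CSV/overlay/config per image.

    With *curve_paths* (one manual path per image, apex→base piece order)
    the multi-piece workflow runs instead: per-piece CSVs plus one combined
    cochleogram. Per-image failures are logged and skipped, never fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = find_images(inputs)
    if not images:
        raise InputError(f"no readable images found under {inputs}")
    if curve_paths is not None and len(curve_paths) != len(images):
        raise InputError("multi-piece mode needs exactly one curve file per image")

    reports = {}
    for i, img_path in enumerate(images):
        cfg = dataclasses.replace(config)
        if curve_paths is not None:
            cfg.curve_path = str(curve_paths[i])
        try:
            img = load_image(img_path, pixel_size_nm=config.pixel_size_nm)
            if img.n_channels >= 2 and not img.channel_roles:
                img.channel_roles = {0: "cell_body", 1: "bundle"}
            report = analyze_image(img, cfg)
        except Exception as exc:
            logger.warning("skipping %s: %s", img_path.name, exc)
            continue
        stem = img_path.stem
        write_csv(report, out_dir / f"{stem}_cells.csv")
        with open(out_dir / f"{stem}_config.json", "w", encoding="utf-8") as fh:
            json.dump(report.config_snapshot, fh, indent=2, default=str)
        if overlays:
            import matplotlib.pyplot as plt

            fig = render_overlay(img, report, out_path=out_dir / f"{stem}_overlay.png")
            plt.close(fig)
            if report.cochleogram is not None:
                fig = plot_cochleogram(report.cochleogram, out_path=out_dir / f"{stem}_cochleogram.png")
                plt.close(fig)
        logger.info(
            "%s: %d cells (%d tiles, %d skipped blank)",
            img_path.name, len(report.cells), report.n_tiles, report.n_tiles_skipped,
        )
        reports[str(img_path)] = report

    if curve_paths is not None and len(reports) > 1:
        cells, combined = combine_pieces(list(reports.values()), config.bin_size_percent)
        frame = report_to_frame(
            AnalysisReport(cells=cells, path=None, cochleogram=combined)
        )
        frame.to_csv(out_dir / "combined_cells.csv", index=False)
        import matplotlib.pyplot as plt

        fig = plot_cochleogram(combined, out_path=out_dir / "combined_cochleogram.png")
        plt.close(fig)
    return reports
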