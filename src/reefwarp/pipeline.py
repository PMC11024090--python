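"""Full pipeline composition, failure taxonomy, and batch processing.

``transform_reefscape`` chains the seven stages — undistort, detect
horizon, remove roll, detect source plane, detect perspective grid, draw
grid, brute-force search — and reports every stage outcome.  ``run_batch``
processes a folder of images with per-image isolation: one image's failure
is recorded and never aborts the batch.
"""

from __future__ import annotations

import enum
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import errors as err
from .calibration import CameraModel, undistort_image
from .config import PipelineConfig
from .geometry import largest_rect_in_mask, warp_image
from .grid import (
    PerspectiveGrid,
    build_perspective_grid,
    candidate_vanishing_points,
    detect_line_segments,
    filter_candidate_lines,
    overall_vanishing_point,
    select_vanishing_line,
)
from .horizon import EdgeMap, HorizonLine, build_edge_map, detect_horizon
from .ipm import SearchResult, overlay_grid, search_compression_factor
from .roll import remove_roll
from .source_plane import (
    anisotropy_profile,
    define_source_plane,
    select_anisotropy_index,
)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class FailureCode(enum.Enum):
    NO_WATER_COLUMN = "NO_WATER_COLUMN"
    NO_HORIZON = "NO_HORIZON"
    HORIZON_OFF_LEFT_EDGE = "HORIZON_OFF_LEFT_EDGE"
    INSUFFICIENT_EDGES = "INSUFFICIENT_EDGES"
    NO_CANDIDATE_LINES = "NO_CANDIDATE_LINES"
    NO_VANISHING_POINT = "NO_VANISHING_POINT"
    SEARCH_NON_CONVERGENCE = "SEARCH_NON_CONVERGENCE"
    RESOLUTION_TOO_LOW = "RESOLUTION_TOO_LOW"
    CALIBRATION_MISSING = "CALIBRATION_MISSING"
    UNREADABLE_INPUT = "UNREADABLE_INPUT"


@dataclass
class FailureReason:
    code: FailureCode
    message: str
    stage: str


_ERROR_CODES: list[tuple[type, FailureCode]] = [
    (err.NoWaterColumnError, FailureCode.NO_WATER_COLUMN),
    (err.HorizonOffLeftEdgeError, FailureCode.HORIZON_OFF_LEFT_EDGE),
    (err.NoHorizonError, FailureCode.NO_HORIZON),
    (err.InsufficientEdgesError, FailureCode.INSUFFICIENT_EDGES),
    (err.NoCandidateLinesError, FailureCode.NO_CANDIDATE_LINES),
    (err.NoVanishingLineError, FailureCode.NO_CANDIDATE_LINES),
    (err.NoVanishingPointError, FailureCode.NO_VANISHING_POINT),
    (err.GridLostError, FailureCode.SEARCH_NON_CONVERGENCE),
    (err.SearchNonConvergenceError, FailureCode.SEARCH_NON_CONVERGENCE),
    (err.ResolutionTooLowError, FailureCode.RESOLUTION_TOO_LOW),
    (err.CalibrationMissingError, FailureCode.CALIBRATION_MISSING),
]

_STAGE_FALLBACK = {
    "read": FailureCode.UNREADABLE_INPUT,
    "resolution": FailureCode.RESOLUTION_TOO_LOW,
    "undistort": FailureCode.CALIBRATION_MISSING,
    "horizon": FailureCode.NO_HORIZON,
    "roll": FailureCode.NO_HORIZON,
    "source_plane": FailureCode.INSUFFICIENT_EDGES,
    "grid": FailureCode.NO_CANDIDATE_LINES,
    "search": FailureCode.SEARCH_NON_CONVERGENCE,
}


def classify_failure(stage: str, error: Exception) -> FailureReason:
    """Deterministic stage x error -> failure-code mapping."""
    for etype, code in _ERROR_CODES:
        if isinstance(error, etype):
            return FailureReason(code=code, message=str(error), stage=stage)
    code = _STAGE_FALLBACK.get(stage, FailureCode.UNREADABLE_INPUT)
    return FailureReason(code=code, message=f"{type(error).__name__}: {error}", stage=stage)


@dataclass
class PipelineResult:
    """Everything a caller needs to interpret or reproduce one transform."""

    search: SearchResult
    horizon: HorizonLine
    leveled_horizon: HorizonLine
    anisotropy_index: int
    index_converged: bool
    vp: tuple[float, float]
    grid: PerspectiveGrid
    to_original: np.ndarray      # leveled-frame coords -> input-image coords
    plane_top_row: int
    plane_size: tuple[int, int]  # (width, height) of the source plane

    @property
    def homography_total(self) -> np.ndarray:
        """Input-image coordinates -> transformed top-down coordinates."""
        T = np.eye(3)
        T[1, 2] = -self.plane_top_row
        return self.search.homography @ T @ np.linalg.inv(self.to_original)

    def sidecar(self) -> dict:
        return {
            "x_cf": self.search.x_cf,
            "grid_angle": self.search.grid_angle_at_stop,
            "n_iterations": self.search.n_iterations,
            "homography": [round(float(v), 10) for v in self.search.homography.ravel()],
            "horizon": {"slope": self.horizon.slope, "intercept": self.horizon.intercept},
            "anisotropy_index": self.anisotropy_index,
            "anisotropy_index_converged": self.index_converged,
            "vanishing_point": [float(self.vp[0]), float(self.vp[1])],
            "plane_top_row": self.plane_top_row,
        }


def transform_reefscape(
    img: np.ndarray,
    cam: CameraModel | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full perspective-removal pipeline on one image.

    Raises a typed error from :mod:`reefwarp.errors` when a stage cannot
    proceed; use :func:`classify_failure` to map it to a failure code.
    """
    cfg = config or PipelineConfig()
    h, w = img.shape[:2]
    if h * w < cfg.min_megapixels * 1e6:
        raise err.ResolutionTooLowError(
            f"{w}x{h} = {w * h / 1e6:.2f} MP below the "
            f"{cfg.min_megapixels} MP minimum"
        )
    if cam is not None and cam.has_distortion:
        und, mask = undistort_image(img, cam)
        rect = largest_rect_in_mask(mask)
        x0, y0 = int(rect.tl[0]), int(rect.tl[1])
        x1, y1 = int(rect.br[0]), int(rect.br[1])
        work = und[y0:y1, x0:x1]
    else:
        work = img

    horizon = detect_horizon(work, cfg)
    leveled, flat_horizon, to_original = remove_roll(work, horizon)

    edges = build_edge_map(leveled, "standard", cfg)
    profile = anisotropy_profile(edges, flat_horizon.intercept, cfg)
    selection = select_anisotropy_index(profile, cfg)
    plane = define_source_plane(leveled, selection.row, flat_horizon.intercept)

    # the same standard edge map serves line detection, with edges above the
    # horizon removed (aquatic life and surface reflections)
    grid_edges = EdgeMap(edges.data.copy(), edges.mode, edges.orientations)
    ys = np.arange(grid_edges.data.shape[0])[:, None]
    xs = np.arange(grid_edges.data.shape[1])[None, :]
    grid_edges.data[ys < flat_horizon.line.y_at(xs)] = False

    segments = detect_line_segments(grid_edges, cfg)
    H_lev, W_lev = leveled.shape[:2]
    left, right = filter_candidate_lines(
        segments, flat_horizon, W_lev, H_lev, cfg.seed, cfg
    )
    cands = candidate_vanishing_points(left, right, flat_horizon, W_lev, H_lev, cfg)
    vp = overall_vanishing_point(cands)
    plane_h = H_lev - selection.row
    vline = select_vanishing_line(
        left + right,
        vp,
        selection.row,
        cfg,
        bounds=(0.0, float(selection.row), float(W_lev), float(H_lev)),
    )
    grid = build_perspective_grid(vline, W_lev, vp)

    plane_with_grid = overlay_grid(plane.image, grid, y_offset=selection.row, config=cfg)
    grid_pts = np.array(
        [
            [grid.vanishing_line.p1[0], grid.vanishing_line.p1[1] - selection.row],
            [grid.vanishing_line.p2[0], grid.vanishing_line.p2[1] - selection.row],
            [grid.horizontal_line.p1[0], grid.horizontal_line.p1[1] - selection.row],
            [grid.horizontal_line.p2[0], grid.horizontal_line.p2[1] - selection.row],
        ]
    )
    search = search_compression_factor(
        plane_with_grid, W_lev, plane_h, config=cfg, grid_points=grid_pts
    )
    # final output: the clean plane warped by the found homography
    clean = warp_image(plane.image, search.homography, (W_lev, plane_h))
    search.transformed = clean
    return PipelineResult(
        search=search,
        horizon=horizon,
        leveled_horizon=flat_horizon,
        anisotropy_index=selection.row,
        index_converged=selection.converged,
        vp=vp,
        grid=grid,
        to_original=to_original,
        plane_top_row=selection.row,
        plane_size=(W_lev, plane_h),
    )


# ----------------------------------------------------------------------
# batch processing


@dataclass
class ImageRecord:
    name: str
    status: str                 # "processed" | "failed"
    failure: FailureReason | None = None
    sidecar: dict | None = None


@dataclass
class RunReport:
    n_input: int
    n_processed: int
    n_failed: int
    records: list[ImageRecord] = field(default_factory=list)

    @property
    def process_rate(self) -> float:
        return self.n_processed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_processed": self.n_processed,
            "n_failed": self.n_failed,
            "process_rate": self.process_rate,
            "records": [
                {
                    "name": r.name,
                    "status": r.status,
                    "failure": (
                        {
                            "code": r.failure.code.value,
                            "stage": r.failure.stage,
                            "message": r.failure.message,
                        }
                        if r.failure
                        else None
                    ),
                }
                for r in self.records
            ],
        }


def _process_one(
    path: Path, out_dir: Path, cam: CameraModel | None, cfg: PipelineConfig
) -> ImageRecord:
    stage = "read"
    try:
        img = iio.imread(path)
        stage = "pipeline"
        result = transform_reefscape(img, cam, cfg)
        out_path = out_dir / f"{path.stem}_topdown.png"
        iio.imwrite(out_path, result.search.transformed.astype(np.uint8))
        side = result.sidecar()
        side["seed"] = cfg.seed
        (out_dir / f"{path.stem}_topdown.json").write_text(json.dumps(side, indent=2))
        return ImageRecord(name=path.name, status="processed", sidecar=side)
    except Exception as exc:  # noqa: BLE001 - per-image isolation is the contract
        if stage == "pipeline":
            stage = getattr(exc, "stage", _infer_stage(exc))
        reason = classify_failure(stage, exc)
        return ImageRecord(name=path.name, status="failed", failure=reason)


def _infer_stage(exc: Exception) -> str:
    mapping = {
        err.ResolutionTooLowError: "resolution",
        err.CalibrationMissingError: "undistort",
        err.NoWaterColumnError: "horizon",
        err.NoHorizonError: "horizon",
        err.HorizonOffLeftEdgeError: "horizon",
        err.InsufficientEdgesError: "source_plane",
        err.NoCandidateLinesError: "grid",
        err.NoVanishingLineError: "grid",
        err.NoVanishingPointError: "grid",
        err.GridLostError: "search",
        err.SearchNonConvergenceError: "search",
    }
    for etype, stage in mapping.items():
        if isinstance(exc, etype):
            return stage
    return "pipeline"


def worker_count(cpu_percent: float) -> int:
    """floor(percentage x available CPUs), minimum one worker."""
    n_cpu = os.cpu_count() or 1
    return max(1, math.floor(cpu_percent / 100.0 * n_cpu))


def run_batch(
    input_dir: str | Path,
    output_dir: str | Path,
    cam: CameraModel | None = None,
    config: PipelineConfig | None = None,
    cpu_percent: float = 100.0,
) -> RunReport:
    """Process every image in ``input_dir``; failures never abort the batch.

    Images are independent work units; they are processed in sorted name
    order so the report is deterministic for a given (inputs, config, seed).
    """
    cfg = config or PipelineConfig()
    in_path, out_path = Path(input_dir), Path(output_dir)
    if not in_path.is_dir():
        raise FileNotFoundError(f"input folder {in_path} does not exist")
    out_path.mkdir(parents=True, exist_ok=True)
    files = sorted(
        p for p in in_path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    n_workers = worker_count(cpu_percent)
    records: list[ImageRecord] = []
    if n_workers == 1:
        for p in files:
            records.append(_process_one(p, out_path, cam, cfg))
    else:
        import multiprocessing as mp

        with mp.get_context("spawn").Pool(n_workers) as pool:
            records = pool.starmap(
                _process_one, [(p, out_path, cam, cfg) for p in files]
            )
    n_ok = sum(1 for r in records if r.status == "processed")
    report = RunReport(
        n_input=len(files),
        n_processed=n_ok,
        n_failed=len(files) - n_ok,
        records=records,
    )
    (out_path / "run_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
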