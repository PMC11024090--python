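"""Pipeline configuration: every tunable named in the module design notes.

Values are defaults chosen for typical survey imagery; all are overridable
via YAML (see :meth:`PipelineConfig.from_yaml`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- edge maps ---
    gaussian_sigma: float = 2.0          # blur before gradient work, px
    canny_low: float = 50.0              # hysteresis thresholds, 8-bit units
    canny_high: float = 150.0
    adaptive_block: int = 51             # adaptive mean-threshold window, px
    adaptive_offset: float = 3.0         # must exceed local mean by this (8-bit units)
    # --- horizon ---
    density_radius_frac: float = 0.01    # density window radius, fraction of diagonal
    density_radius_min: int = 5
    n_water_samples: int = 100           # zero-density pixels sampled for water line
    zscore_threshold: float = 2.5        # y-coordinate outlier cut, single pass
    max_horizon_points: int = 2000       # contour subsampling cap for the final fit
    # --- source plane ---
    anisotropy_cap: float = 1e6          # value returned when orientation variance ~ 0
    profile_smooth_window: int = 5       # moving-average window on the anisotropy curve
    # --- perspective grid ---
    hough_threshold: int = 10            # relaxed: many small lines
    hough_min_length: int = 25
    hough_line_gap: int = 3
    angle_min_mid: float = 10.0          # deg; horizon in the middle third of height
    angle_min_top: float = 25.0          # deg; horizon in the top third
    angle_max: float = 80.0              # deg
    horizon_band_frac: float = 0.01      # VP candidates must lie this close to horizon
    vp_width_frac: float = 0.25          # central width window for VP candidates
    min_vanishing_line_px: float = 500.0
    # --- brute-force search ---
    step_x_cf: float = 0.005
    angle_tol_deg: float = 0.5
    grid_thickness: int = 9
    grid_color: tuple[int, int, int] = (255, 255, 0)   # reserved pure yellow
    hue_band: float = 10.0 / 180.0       # HSV segmentation half-width (hue in [0,1])
    sat_min: float = 0.5                 # tolerant of interpolation blending at
    val_min: float = 0.5                 # strong compression; hue gate carries
                                         # the selectivity against scene colours
    # --- pipeline ---
    min_megapixels: float = 0.75
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_color"] = list(self.grid_color)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_color" in d:
            d["grid_color"] = tuple(d["grid_color"])
        return cls(**d)
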