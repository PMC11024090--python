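"""Source-plane detection via the texture-anisotropy profile.

Perspective foreshortening flattens edge orientations toward the horizon:
far texture appears as near-horizontal streaks (high anisotropy), while
close texture shows orientations spread across the full (-90, 90] degree
range (low anisotropy).  Anisotropy is measured as the reciprocal variance
of edge-tangent orientations,

    A = 1 / var(arctan(grad E)),

inside a full-width window that slides from the horizon down to half the
image height.  The "anisotropy index" — the first row at which the
normalised profile's derivative reaches -1 — marks the onset of rapid
information loss; rows above it are excessively foreshortened and are
excluded from the transformable source plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .errors import InsufficientEdgesError
from .geometry import Quad
from .horizon import EdgeMap


@dataclass
class AnisotropyProfile:
    rows: np.ndarray          # absolute row indices, strictly increasing
    values: np.ndarray        # anisotropy normalised to [0, 1]
    raw_values: np.ndarray    # unnormalised A
    carried_rows: np.ndarray  # rows whose window had < 2 edge pixels


@dataclass
class SourcePlane:
    quad: Quad
    top_row: int
    image: np.ndarray


class IndexSelection(NamedTuple):
    row: int
    converged: bool  # False when the -1 crossing was never reached


def anisotropy(orientations: np.ndarray, cap: float = 1e6) -> float:
    """Reciprocal variance of edge orientations; ``cap`` at zero variance.

    Orientations are radians in (-pi/2, pi/2].  A perfectly aligned window
    has zero variance and would send A to infinity; it is capped instead.
    """
    o = np.asarray(orientations, dtype=float)
    if o.size < 2:
        raise InsufficientEdgesError("need at least two orientation samples")
    var = float(np.var(o))
    if var < 1e-6:
        return float(cap)
    return 1.0 / var


def anisotropy_profile(
    edges: EdgeMap,
    horizon_y: float,
    config: PipelineConfig | None = None,
) -> AnisotropyProfile:
    """Per-row anisotropy of a standard edge map below the horizon.

    The window spans the full width, has height equal to one fifth of the
    horizon-to-bottom distance, and slides row by row from the horizon to
    half the image height.  Rows whose window holds fewer than two edge
    pixels carry the previous row's value.
    """
    cfg = config or PipelineConfig()
    if edges.orientations is None:
        raise ValueError("edge map lacks orientation data (build via build_edge_map)")
    H = edges.data.shape[0]
    if not (0 <= horizon_y < H - 2):
        raise ValueError("horizon must lie above the image bottom")
    start = int(math.ceil(max(horizon_y, 0.0)))
    stop = H // 2
    if stop <= start:
        raise ValueError("no rows between horizon and half image height")
    win_h = max(int(round((H - horizon_y) / 5.0)), 2)

    e = edges.data
    theta = np.where(e, edges.orientations, 0.0)
    # per-row sums -> windowed sums via cumulative sums
    n_row = e.sum(axis=1).astype(float)
    s_row = theta.sum(axis=1)
    q_row = (theta * theta).sum(axis=1)
    cn = np.concatenate([[0.0], np.cumsum(n_row)])
    cs = np.concatenate([[0.0], np.cumsum(s_row)])
    cq = np.concatenate([[0.0], np.cumsum(q_row)])

    rows = np.arange(start, stop)
    raw = np.empty(len(rows))
    carried = []
    prev = None
    for k, r in enumerate(rows):
        r1 = min(r + win_h, H)
        n = cn[r1] - cn[r]
        if n < 2:
            carried.append(r)
            raw[k] = prev if prev is not None else 0.0
            continue
        s = cs[r1] - cs[r]
        q = cq[r1] - cq[r]
        var = q / n - (s / n) ** 2
        raw[k] = cfg.anisotropy_cap if var < 1e-6 else 1.0 / var
        prev = raw[k]
    span = raw.max() - raw.min()
    values = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return AnisotropyProfile(
        rows=rows,
        values=values,
        raw_values=raw,
        carried_rows=np.asarray(carried, dtype=int),
    )


def select_anisotropy_index(
    profile: AnisotropyProfile, config: PipelineConfig | None = None
) -> IndexSelection:
    """Row where the normalised profile's derivative crosses -1.

    The profile is smoothed with a short moving average and differentiated
    by central differences in normalised (row, anisotropy) space.  The
    rapid-information-loss zone is the first contiguous run of rows whose
    derivative is at or below -1.  When that zone begins away from the
    horizon (the profile is flat first, as in a curve like 1 - r^2), its
    first row — the -1 crossing — is returned.  When the zone abuts the
    horizon itself (a convex profile whose cliff starts immediately), the
    zone's exit row is returned instead: the loss region is above it, and
    cropping there yields the largest source plane that excludes it.  If
    the curve never steepens to -1, the row of minimum derivative is
    returned and flagged as a fallback.
    """
    cfg = config or PipelineConfig()
    if len(profile.rows) < 5:
        raise ValueError("profile too short to differentiate")
    smooth = ndimage.uniform_filter1d(
        profile.values, size=cfg.profile_smooth_window, mode="nearest"
    )
    x = (profile.rows - profile.rows[0]) / max(profile.rows[-1] - profile.rows[0], 1)
    deriv = np.gradient(smooth, x)
    steep = np.nonzero(deriv <= -1.0)[0]
    if len(steep) == 0:
        return IndexSelection(row=int(profile.rows[np.argmin(deriv)]), converged=False)
    upper = steep[x[steep] <= 0.5 + 1e-9]
    if len(upper):
        # rapid-loss zone abuts or spans the upper profile: crop at its
        # deepest upper-half row so the whole zone is excluded
        return IndexSelection(row=int(profile.rows[upper[-1]]), converged=True)
    # curve flat first, steepening late: the first -1 crossing marks where
    # loss begins (the concave case, e.g. a curve like 1 - r^2 at r = 0.5)
    return IndexSelection(row=int(profile.rows[steep[0]]), converged=True)


def define_source_plane(img: np.ndarray, index: int, horizon_y: float | None = None) -> SourcePlane:
    """Crop rows [index, H) as the transformable source plane.

    The plane spans the full image width; its bottom corners are the bottom
    corners of the image itself.
    """
    H, W = img.shape[:2]
    if horizon_y is not None and index <= horizon_y:
        raise ValueError(
            f"source-plane top row {index} must lie below the horizon ({horizon_y:.1f})"
        )
    if not (0 < index < H):
        raise ValueError(f"source-plane top row {index} outside the image")
    quad = Quad((0.0, float(index)), (float(W), float(index)), (float(W), float(H)), (0.0, float(H)))
    return SourcePlane(quad=quad, top_row=int(index), image=img[index:, :].copy())
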