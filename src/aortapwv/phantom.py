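"""Rasterized in-plane velocity-map phantom (AP/FH component pair).

The phantom emulates a double-oblique-sagittal view of the aorta: an
ascending segment, a half-annulus arch and a descending segment, with a
parabolic velocity cross-profile and a systolic wave front whose arrival is
delayed by arc-position / wave-speed.  The per-pixel velocity vector points
along the local centerline tangent and is split into its AP (row) and FH
(column) components, clipped to the velocity-encoding limit.  The lumen
polygon is emitted as the ground-truth contour so the geometric pipeline
(centerline extraction, chord sampling, projection, foot detection, transit
regression) can be exercised end to end against a known wave speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from skimage.draw import polygon2mask

from .cohort import CohortConfig, SubjectTruth, waveform_template
from .errors import ConfigError
from .geometry import LumenContour, VelocityMapSeries

__all__ = ["PhantomDataset", "rasterize_maps"]

#: Velocity-encoding limit of the emulated acquisition (m/s).
DEFAULT_VENC = 1.5


@dataclass(frozen=True)
class PhantomDataset:
    """Rasterized AP/FH series with the geometry that generated them."""

    maps_ap: VelocityMapSeries
    maps_fh: VelocityMapSeries
    contour: LumenContour
    centerline_points_mm: np.ndarray
    centerline_arc_m: np.ndarray
    ascending_hint_mm: np.ndarray
    descending_hint_mm: np.ndarray
    pwv_m_per_s: float
    rr_s: float


def _phantom_centerline(
    arch_radius_mm: float, ascending_mm: float, descending_mm: float, step_mm: float
) -> np.ndarray:
    """Polyline: ascending limb, half-annulus arch over the top, descending."""
    r = arch_radius_mm
    asc_y = np.arange(-ascending_mm, 0.0, step_mm)
    asc = np.column_stack([np.full_like(asc_y, -r), asc_y])
    n_arc = max(2, int(np.ceil(np.pi * r / step_mm)))
    theta = np.linspace(np.pi, 0.0, n_arc)
    arch = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    desc_y = np.arange(-step_mm, -descending_mm - step_mm / 2, -step_mm)
    desc = np.column_stack([np.full_like(desc_y, r), desc_y])
    return np.vstack([asc, arch, desc])


def rasterize_maps(
    truth: SubjectTruth,
    config: CohortConfig,
    *,
    pixel_mm: float = 1.0,
    arch_radius_mm: float = 35.0,
    tube_radius_mm: float = 10.0,
    ascending_mm: float = 40.0,
    descending_mm: float = 80.0,
    margin_mm: float = 8.0,
    grid_shape: tuple[int, int] | None = None,
    venc_m_per_s: float = DEFAULT_VENC,
    profile: str = "parabolic",
    time_profile: str = "waveform",
    rng: np.random.Generator | None = None,
) -> PhantomDataset:
    """Rasterize a propagating-wave aorta phantom into AP/FH map series.

    ``profile="flat"`` replaces the parabolic cross-profile by a uniform
    one; ``time_profile="static"`` freezes the amplitude at the subject's
    peak value (useful for geometric unit checks).  ``grid_shape`` (rows,
    cols) may pin the output size; if the phantom does not fit, a
    :class:`ConfigError` is raised.
    """
    config.validate()
    truth.validate(config.rho)
    rr = truth.rr_s
    cl = _phantom_centerline(arch_radius_mm, ascending_mm, descending_mm, step_mm=1.0)
    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    arc_mm = np.r_[0.0, np.cumsum(seg)]
    tangents = np.gradient(cl, arc_mm, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    lumen = LineString(cl).buffer(tube_radius_mm, cap_style="flat", quad_segs=24)
    ext = np.asarray(lumen.exterior.coords)

    minx, miny = ext.min(axis=0) - margin_mm
    maxx, maxy = ext.max(axis=0) + margin_mm
    n_rows = int(np.ceil((maxy - miny) / pixel_mm)) + 1
    n_cols = int(np.ceil((maxx - minx) / pixel_mm)) + 1
    if grid_shape is not None:
        if grid_shape[0] < n_rows or grid_shape[1] < n_cols:
            raise ConfigError("phantom exceeds the requested grid")
        n_rows, n_cols = grid_shape
    # shift so that the planar origin is the top-left pixel center
    shift = np.array([minx, miny])
    cl_px = cl - shift
    ext_px = ext - shift

    verts = np.column_stack([ext_px[:, 1] / pixel_mm, ext_px[:, 0] / pixel_mm])
    mask = polygon2mask((n_rows, n_cols), verts)
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols * pixel_mm, rows * pixel_mm])  # (x, y) mm

    tree = cKDTree(cl_px)
    r_dist, idx = tree.query(pts)
    s_m = arc_mm[idx] / 1000.0
    tang = tangents[idx]
    if profile == "parabolic":
        cross = np.clip(1.0 - (r_dist / tube_radius_mm) ** 2, 0.0, None)
    elif profile == "flat":
        cross = np.ones_like(r_dist)
    else:
        raise ConfigError("profile must be 'parabolic' or 'flat'")

    n_ph = config.cmr_phases_per_cycle
    dt = rr / n_ph
    t_ph = np.arange(n_ph) * dt
    amp = truth.velocity_amp_m_per_s
    v_loc = truth.pwv_local_m_per_s

    frames_ap = np.zeros((n_ph, n_rows, n_cols))
    frames_fh = np.zeros((n_ph, n_rows, n_cols))
    for k, tk in enumerate(t_ph):
        if time_profile == "waveform":
            mag = amp * waveform_template((tk - s_m / v_loc) / rr, config.shape) * cross
        elif time_profile == "static":
            mag = amp * cross
        else:
            raise ConfigError("time_profile must be 'waveform' or 'static'")
        if rng is not None and config.velocity_noise_sd > 0:
            mag = mag + rng.normal(0.0, config.velocity_noise_sd, mag.shape)
        vx = mag * tang[:, 0]
        vy = mag * tang[:, 1]
        frames_fh[k, rows, cols] = np.clip(vx, -venc_m_per_s, venc_m_per_s)
        frames_ap[k, rows, cols] = np.clip(vy, -venc_m_per_s, venc_m_per_s)

    spacing = (pixel_mm, pixel_mm)
    contour = LumenContour(slice_id=0, phase_id=0, polygon=ext_px)
    return PhantomDataset(
        maps_ap=VelocityMapSeries("AP", frames_ap, spacing, t_ph, venc_m_per_s),
        maps_fh=VelocityMapSeries("FH", frames_fh, spacing, t_ph, venc_m_per_s),
        contour=contour,
        centerline_points_mm=cl_px,
        centerline_arc_m=arc_mm / 1000.0,
        ascending_hint_mm=cl_px[0].copy(),
        descending_hint_mm=cl_px[-1].copy(),
        pwv_m_per_s=v_loc,
        rr_s=rr,
    )
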