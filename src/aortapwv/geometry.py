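"""Aortic lumen geometry: centerline, chord sampling and velocity projection.

Workflow for in-plane velocity-encoded acquisitions: the lumen is outlined
once as a closed polygon (mm), the vessel centerline is extracted from the
polygon, 200 equidistant chords perpendicular to the centerline are placed
along it, the anterior-posterior (AP) and feet-head (FH) velocity components
are sampled along each chord and projected onto the local centerline
direction, and the per-chord maximum of the projected velocity over the
cardiac phases yields one velocity-time curve per chord.

Coordinate convention: contours and velocity maps share one planar mm frame
with the origin at the top-left pixel center; the row index (y) increases in
the AP direction and the column index (x) in the FH direction.

The centerline is found as the minimal-cost geodesic between two hinted
endpoints through the rasterized lumen, with per-pixel cost equal to the
inverse distance-to-boundary; the cost ridge coincides with the medial axis,
so the path runs along the vessel middle for elongated curved bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates, uniform_filter1d
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from skimage.draw import polygon2mask
from skimage.graph import route_through_array

from .errors import ConfigError, DegenerateGeometryError, GeometryError
from .waveforms import SampledWaveform

__all__ = [
    "LumenContour",
    "Centerline",
    "Chord",
    "VelocityMapSeries",
    "centerline_from_contour",
    "sample_chords",
    "project_velocity",
    "chord_velocity_curves",
    "roi_max_velocity_curve",
    "lumen_area_series",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class LumenContour:
    """Closed lumen outline: ordered planar points in mm."""

    slice_id: int
    phase_id: int
    polygon: np.ndarray  # (N, 2) of (x_mm, y_mm)

    def __post_init__(self) -> None:
        pts = np.asarray(self.polygon, dtype=float)
        object.__setattr__(self, "polygon", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise DegenerateGeometryError("contour needs >= 3 planar points")

    def shapely(self) -> Polygon:
        poly = Polygon(self.polygon)
        if not poly.is_valid:
            raise DegenerateGeometryError("self-intersecting lumen contour")
        if poly.area <= 0:
            raise DegenerateGeometryError("contour has non-positive area")
        return poly

    @property
    def area_mm2(self) -> float:
        """Enclosed (shoelace) area in mm^2."""
        return float(self.shapely().area)


@dataclass(frozen=True)
class Centerline:
    """Vessel centerline: points (mm), cumulative arc length (m), tangents.

    Tangents are unit vectors oriented from the ascending towards the
    descending aorta (i.e. from the first hinted endpoint to the second).
    """

    points: np.ndarray  # (M, 2) mm
    arc_length_m: np.ndarray  # (M,)
    tangents: np.ndarray  # (M, 2) unit

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.arc_length_m) > 0):
            raise DegenerateGeometryError("arc lengths must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise DegenerateGeometryError("tangents must be unit vectors")

    @property
    def length_m(self) -> float:
        return float(self.arc_length_m[-1])

    def point_at(self, s_m: float) -> np.ndarray:
        s = np.clip(s_m, 0.0, self.length_m)
        return np.array(
            [
                np.interp(s, self.arc_length_m, self.points[:, 0]),
                np.interp(s, self.arc_length_m, self.points[:, 1]),
            ]
        )

    def tangent_at(self, s_m: float) -> np.ndarray:
        s = np.clip(s_m, 0.0, self.length_m)
        t = np.array(
            [
                np.interp(s, self.arc_length_m, self.tangents[:, 0]),
                np.interp(s, self.arc_length_m, self.tangents[:, 1]),
            ]
        )
        n = np.linalg.norm(t)
        if n == 0:
            raise DegenerateGeometryError("degenerate tangent")
        return t / n


@dataclass(frozen=True)
class Chord:
    """Sampling chord: arc position, lumen-clipped endpoints, tangent."""

    s_m: float
    endpoints: np.ndarray  # (2, 2) mm
    direction: np.ndarray  # unit centerline tangent at s_m, planar (x, y)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


@dataclass(frozen=True)
class VelocityMapSeries:
    """Per-phase 2-D velocity maps of one encoding direction.

    ``frames`` has shape (n_phases, n_rows, n_cols) in m/s;
    ``pixel_spacing_mm`` is (row, col).  Values are bounded by the velocity
    encoding limit ``venc_m_per_s`` (phase-contrast velocities beyond VENC
    alias and cannot occur in reconstructed maps).
    """

    component: str  # "AP", "FH" or "through_plane"
    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    phase_times_s: np.ndarray
    venc_m_per_s: float

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        pt = np.asarray(self.phase_times_s, dtype=float)
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "phase_times_s", pt)
        if fr.ndim != 3:
            raise ConfigError("frames must be (phases, rows, cols)")
        if pt.size != fr.shape[0] or not np.all(np.diff(pt) > 0):
            raise ConfigError("phase times must match frames and strictly increase")
        if self.venc_m_per_s <= 0:
            raise ConfigError("venc must be > 0")
        if np.max(np.abs(fr)) > self.venc_m_per_s + 1e-9:
            raise ConfigError("velocity exceeds the encoding limit (VENC)")

    @property
    def n_phases(self) -> int:
        return int(self.frames.shape[0])


def _rasterize(poly: Polygon, pixel_mm: float, pad_px: int = 2):
    minx, miny, maxx, maxy = poly.bounds
    x0 = minx - pad_px * pixel_mm
    y0 = miny - pad_px * pixel_mm
    n_cols = int(np.ceil((maxx - x0) / pixel_mm)) + pad_px + 1
    n_rows = int(np.ceil((maxy - y0) / pixel_mm)) + pad_px + 1
    ext = np.asarray(poly.exterior.coords)
    # polygon2mask wants (row, col) vertices; pixel (r, c) center is at
    # (x0 + c*pixel, y0 + r*pixel)
    verts = np.column_stack([(ext[:, 1] - y0) / pixel_mm, (ext[:, 0] - x0) / pixel_mm])
    mask = polygon2mask((n_rows, n_cols), verts)
    for ring in poly.interiors:
        hole = np.asarray(ring.coords)
        hv = np.column_stack([(hole[:, 1] - y0) / pixel_mm, (hole[:, 0] - x0) / pixel_mm])
        mask &= ~polygon2mask((n_rows, n_cols), hv)
    return mask, x0, y0


def centerline_from_contour(
    contour: LumenContour,
    endpoints_hint: Sequence[Sequence[float]],
    *,
    pixel_mm: float = 0.5,
    smooth_window: int = 5,
    spacing_mm: float = 0.5,
) -> Centerline:
    """Extract the vessel centerline from a lumen contour.

    The polygon is rasterized at ``pixel_mm`` resolution; the Euclidean
    distance transform gives the distance-to-boundary of every lumen pixel,
    and the centerline is the minimal-cost path (cost = 1/distance,
    8-connected geometric steps) between the lumen pixels nearest the two
    hinted endpoints.  The path is smoothed with a moving average
    (``smooth_window`` points) and resampled to uniform arc spacing.

    Raises
    ------
    DegenerateGeometryError
        Invalid polygon, or a lumen region too thin to rasterize.
    """
    poly = contour.shapely()
    hints = np.asarray(endpoints_hint, dtype=float)
    if hints.shape != (2, 2):
        raise GeometryError("endpoints_hint must be two planar points")
    mask, x0, y0 = _rasterize(poly, pixel_mm)
    if not np.any(mask):
        raise DegenerateGeometryError("lumen region vanishes at raster resolution")
    edt = distance_transform_edt(mask) * pixel_mm
    if float(edt.max()) < pixel_mm:
        raise DegenerateGeometryError("zero-width lumen region")
    cost = np.where(mask, 1.0 / np.maximum(edt, 1e-6), 1e9)

    rows, cols = np.nonzero(mask)
    px = x0 + cols * pixel_mm
    py = y0 + rows * pixel_mm
    ends = []
    for hint in hints:
        i = int(np.argmin((px - hint[0]) ** 2 + (py - hint[1]) ** 2))
        ends.append((int(rows[i]), int(cols[i])))
    if ends[0] == ends[1]:
        raise DegenerateGeometryError("endpoint hints collapse to one pixel")
    path, _ = route_through_array(
        cost, ends[0], ends[1], fully_connected=True, geometric=True
    )
    pts = np.array([[x0 + c * pixel_mm, y0 + r * pixel_mm] for r, c in path])
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("centerline path degenerate")
    if smooth_window > 1 and pts.shape[0] > smooth_window:
        pts = uniform_filter1d(pts, size=smooth_window, axis=0, mode="nearest")
    # drop consecutive duplicates
    keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    length = float(arc[-1])
    if length <= 0:
        raise DegenerateGeometryError("centerline has zero length")
    n_out = max(2, int(round(length / spacing_mm)) + 1)
    s_new = np.linspace(0.0, length, n_out)
    res = np.column_stack(
        [np.interp(s_new, arc, pts[:, 0]), np.interp(s_new, arc, pts[:, 1])]
    )
    # keep every point inside (or snap boundary grazes from smoothing back on)
    buffered = poly.buffer(1e-9)
    for i, p in enumerate(res):
        pt = Point(p)
        if not buffered.covers(pt):
            d = poly.exterior.distance(pt)
            if d > 0.5 * pixel_mm:
                raise DegenerateGeometryError("centerline leaves the lumen polygon")
            from shapely.ops import nearest_points

            res[i] = np.asarray(nearest_points(poly, pt)[0].coords[0])
    # tangents from central differences over a ~2 mm half-baseline: immune to
    # residual stair-step wiggle of the raster path and curvature-unbiased
    # (a chord of a circular arc is parallel to the tangent at its midpoint)
    m = res.shape[0]
    w = max(1, min(int(round(2.0 / spacing_mm)), (m - 1) // 2))
    hi_i = np.minimum(np.arange(m) + w, m - 1)
    lo_i = np.maximum(np.arange(m) - w, 0)
    tang = res[hi_i] - res[lo_i]
    norms = np.linalg.norm(tang, axis=1)
    if np.any(norms == 0):
        raise DegenerateGeometryError("degenerate centerline tangents")
    tang = tang / norms[:, None]
    seg2 = np.linalg.norm(np.diff(res, axis=0), axis=1)
    arc2 = np.r_[0.0, np.cumsum(seg2)]
    return Centerline(points=res, arc_length_m=arc2 / 1000.0, tangents=tang)


def sample_chords(
    centerline: Centerline, contour: LumenContour, n: int = 200
) -> list[Chord]:
    """Place ``n`` equidistant chords perpendicular to the centerline.

    Chords sit at arc fractions k/(n-1), k = 0..n-1 (endpoints included;
    n = 1 degenerates to s = 0).  Each chord is the maximal segment through
    its centerline point, perpendicular to the local tangent, clipped to the
    lumen polygon.
    """
    if n < 1:
        raise GeometryError("need n >= 1 chords")
    poly = contour.shapely()
    L = centerline.length_m
    fracs = np.array([0.0]) if n == 1 else np.arange(n) / (n - 1)
    diag = float(
        np.hypot(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    )
    chords: list[Chord] = []
    for f in fracs:
        s = f * L
        p = centerline.point_at(s)
        t = centerline.tangent_at(s)
        normal = np.array([-t[1], t[0]])
        line = LineString([p - 2 * diag * normal, p + 2 * diag * normal])
        inter = line.intersection(poly)
        segs: list[LineString]
        if inter.is_empty:
            segs = []
        elif isinstance(inter, LineString):
            segs = [inter]
        elif isinstance(inter, MultiLineString):
            segs = list(inter.geoms)
        else:  # GeometryCollection with points etc.
            segs = [g for g in getattr(inter, "geoms", []) if isinstance(g, LineString)]
        pt = Point(p)
        own = [g for g in segs if g.distance(pt) < 1e-9]
        if not own:
            raise DegenerateGeometryError(
                f"chord at s={s:.4f} m does not intersect the lumen"
            )
        seg = max(own, key=lambda g: g.length)
        coords = np.asarray(seg.coords)
        e1, e2 = coords[0], coords[-1]
        a = float(np.dot(e1 - p, normal))
        b = float(np.dot(e2 - p, normal))
        if a * b > 1e-12:
            raise DegenerateGeometryError(
                f"chord at s={s:.4f} m does not reach the boundary on both sides"
            )
        chords.append(Chord(s_m=float(s), endpoints=np.array([e1, e2]), direction=t))
    return chords


def project_velocity(v_ap, v_fh, direction, *, tol: float = _UNIT_TOL):
    """Project AP/FH velocity components onto a unit direction.

    ``direction`` carries (AP, FH) components; the result is the signed
    scalar product, positive for flow from the ascending toward the
    descending aorta.  Accepts scalars or broadcastable arrays.
    """
    d = np.asarray(direction, dtype=float)
    if d.shape != (2,):
        raise GeometryError("direction must be a planar 2-vector")
    if abs(float(np.linalg.norm(d)) - 1.0) > tol:
        raise GeometryError("direction must be a unit vector")
    return np.asarray(v_ap) * d[0] + np.asarray(v_fh) * d[1]


def _uniform_dt(phase_times: np.ndarray) -> float:
    d = np.diff(phase_times)
    if d.size == 0:
        raise GeometryError("need >= 2 phases")
    if np.max(np.abs(d - d.mean())) > 1e-9 + 1e-6 * d.mean():
        raise GeometryError("phase times must be uniformly spaced")
    return float(d.mean())


def chord_velocity_curves(
    maps_ap: VelocityMapSeries,
    maps_fh: VelocityMapSeries,
    chords: Sequence[Chord],
    *,
    rr_s: float,
    step_mm: float = 0.5,
) -> list[SampledWaveform]:
    """Maximal projected velocity along each chord, per cardiac phase.

    For every chord and phase the AP and FH maps are sampled by bilinear
    interpolation at ``step_mm`` intervals along the chord, projected onto
    the chord's centerline direction, and the signed maximum over the chord
    is kept; the result is one velocity-time curve per chord.
    """
    if maps_ap.component != "AP" or maps_fh.component != "FH":
        raise GeometryError("expected an AP series and an FH series")
    if maps_ap.frames.shape != maps_fh.frames.shape:
        raise GeometryError("AP and FH series are not congruent in shape")
    if not np.allclose(maps_ap.phase_times_s, maps_fh.phase_times_s):
        raise GeometryError("AP and FH phase times differ")
    if maps_ap.pixel_spacing_mm != maps_fh.pixel_spacing_mm:
        raise GeometryError("AP and FH pixel spacings differ")
    dt = _uniform_dt(maps_ap.phase_times_s)
    sp_r, sp_c = maps_ap.pixel_spacing_mm
    n_phase, n_rows, n_cols = maps_ap.frames.shape

    coords_list = []
    slices = []
    dirs = []
    start = 0
    for ch in chords:
        e1, e2 = ch.endpoints
        length = float(np.linalg.norm(e2 - e1))
        n_pts = max(2, int(np.floor(length / step_mm)) + 1)
        pts = e1[None, :] + np.linspace(0, 1, n_pts)[:, None] * (e2 - e1)[None, :]
        rows = pts[:, 1] / sp_r
        cols = pts[:, 0] / sp_c
        if (
            rows.min() < -_UNIT_TOL
            or cols.min() < -_UNIT_TOL
            or rows.max() > n_rows - 1 + _UNIT_TOL
            or cols.max() > n_cols - 1 + _UNIT_TOL
        ):
            raise GeometryError("chord outside the velocity-map extent")
        coords_list.append(np.vstack([rows, cols]))
        slices.append((start, start + n_pts))
        # tangent (x, y) -> (AP, FH) = (y, x)
        dirs.append(np.array([ch.direction[1], ch.direction[0]]))
        start += n_pts
    coords = np.hstack(coords_list)

    out = np.empty((len(chords), n_phase))
    for k in range(n_phase):
        ap = map_coordinates(maps_ap.frames[k], coords, order=1, mode="nearest")
        fh = map_coordinates(maps_fh.frames[k], coords, order=1, mode="nearest")
        for i, (a, b) in enumerate(slices):
            proj = project_velocity(ap[a:b], fh[a:b], dirs[i])
            out[i, k] = np.max(proj)
    t0 = float(maps_ap.phase_times_s[0])
    return [
        SampledWaveform(
            start_time_s=t0,
            sample_interval_s=dt,
            values=out[i],
            kind="velocity",
            rr_s=rr_s,
        )
        for i in range(len(chords))
    ]


def roi_max_velocity_curve(
    maps: VelocityMapSeries,
    contours: LumenContour | Sequence[LumenContour],
    *,
    rr_s: float,
) -> SampledWaveform:
    """Per-phase maximum through-plane velocity inside an ROI contour.

    A single contour is applied to all phases; alternatively one contour per
    phase may be given.
    """
    n_phase, n_rows, n_cols = maps.frames.shape
    if isinstance(contours, LumenContour):
        contour_list = [contours] * n_phase
    else:
        contour_list = list(contours)
        if len(contour_list) != n_phase:
            raise GeometryError("need one contour per phase (or a single contour)")
    sp_r, sp_c = maps.pixel_spacing_mm
    dt = _uniform_dt(maps.phase_times_s)
    values = np.empty(n_phase)
    prev_key = None
    mask = None
    for k, c in enumerate(contour_list):
        key = id(c)
        if key != prev_key:
            verts = np.column_stack([c.polygon[:, 1] / sp_r, c.polygon[:, 0] / sp_c])
            mask = polygon2mask((n_rows, n_cols), verts)
            if not np.any(mask):
                raise GeometryError("ROI contour encloses no pixel")
            prev_key = key
        values[k] = np.max(maps.frames[k][mask])
    return SampledWaveform(
        start_time_s=float(maps.phase_times_s[0]),
        sample_interval_s=dt,
        values=values,
        kind="velocity",
        rr_s=rr_s,
    )


def lumen_area_series(
    contours: Sequence[LumenContour],
    phase_times_s: Sequence[float],
    *,
    rr_s: float,
) -> tuple[SampledWaveform, float, float]:
    """Per-phase lumen area (shoelace) and its distension.

    Returns ``(area_waveform_mm2, delta_A_mm2, A_min_mm2)`` with
    delta_A = max - min over the cardiac phases.
    """
    if len(contours) < 2:
        raise DegenerateGeometryError("need >= 2 phases for an area series")
    times = np.asarray(phase_times_s, dtype=float)
    if times.size != len(contours):
        raise GeometryError("phase times must match contours")
    areas = np.array([c.area_mm2 for c in contours])
    dt = _uniform_dt(times)
    wf = SampledWaveform(
        start_time_s=float(times[0]),
        sample_interval_s=dt,
        values=areas,
        kind="area",
        rr_s=rr_s,
    )
    return wf, float(areas.max() - areas.min()), float(areas.min())
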