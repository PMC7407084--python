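"""Cell morphometrics from 2D contours.

Rod-shaped bacteria are idealized as spherocylinders ("pills"): a cylinder of
radius R capped by two hemispheres, with pole-to-pole length L.  Given an
ordered boundary contour in µm, this module extracts the pole-to-pole midline,
the mean cell width (2R), the midline length (L), and the enclosed volume.

The width is measured as the summed perpendicular distances from midline
stations to the two boundary sides, excluding stations inside the polar caps
(where the caps bias the perpendicular chord) and stations at constriction
sites (septa, where the cell is dividing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import DataError, DegenerateShapeError, ParameterError

# Aspect ratio below which a contour is too round to define poles.
MIN_ASPECT_RATIO = 1.05
# Width fraction below which a midline station is treated as septal.
SEPTAL_FRAC = 0.8
# Default number of midline stations.
N_STATIONS = 25


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Ordered boundary of one cell, traced once; implicitly closed.

    Parameters
    ----------
    points : (n, 2) array of (x, y) positions in µm.
    cell_id : optional identifier carried through to output tables.
    """

    points: np.ndarray
    cell_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError("contour points must be an (n, 2) array")
        if len(pts) < 12:
            raise DataError("contour needs at least 12 points")
        if not np.all(np.isfinite(pts)):
            raise DataError("contour contains non-finite coordinates")
        # drop a duplicated closing point if present
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts
        if self.signed_area() == 0:
            raise DataError("contour encloses zero area")

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area())

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def is_simple(self) -> bool:
        """True if the boundary does not self-intersect."""
        return self.polygon().is_valid


@dataclass
class Midline:
    """Pole-to-pole central axis of a cell contour."""

    points: np.ndarray          # (m, 2) polyline in µm
    arclength: np.ndarray = field(init=False)  # cumulative, arclength[-1] = L
    degenerate: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise DataError("midline must be an (m>=2, 2) polyline")
        self.points = pts
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        if self.arclength[-1] <= 0:
            raise DataError("midline has zero length")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


@dataclass(frozen=True)
class CellShape:
    """Summary geometry of one cell: width 2R, length L, pill volume."""

    width: float       # µm
    length: float      # µm
    volume: float      # µm³
    radius: float      # µm, width / 2
    cell_id: str | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# exact spherocylinder boundary (shared with the synthetic generator)
# ---------------------------------------------------------------------------

def spherocylinder_boundary(
    radius: float, length: float, n_points: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Points and outward normals on an exact spherocylinder boundary.

    The shape is axis-aligned and centered at the origin: cylinder half-length
    c = length/2 - radius, hemispherical caps of the given radius.  Points are
    placed uniformly by arc length, starting at the bottom of the right cap
    and proceeding counterclockwise.

    Returns
    -------
    points, normals : two (n_points, 2) arrays.
    """
    if radius <= 0 or length < 2 * radius:
        raise ParameterError("need radius > 0 and length >= 2*radius")
    if n_points < 12:
        raise ParameterError("need at least 12 boundary points")
    R, c = float(radius), float(length) / 2.0 - float(radius)
    perimeter = 2.0 * math.pi * R + 4.0 * c
    s = np.arange(n_points) * perimeter / n_points
    pts = np.empty((n_points, 2))
    nrm = np.empty((n_points, 2))
    # segment arc-length boundaries
    b1 = math.pi * R            # right cap
    b2 = b1 + 2 * c             # top side
    b3 = b2 + math.pi * R       # left cap
    for i, si in enumerate(s):
        if si < b1:
            a = si / R - math.pi / 2.0
            pts[i] = (c + R * math.cos(a), R * math.sin(a))
            nrm[i] = (math.cos(a), math.sin(a))
        elif si < b2:
            pts[i] = (c - (si - b1), R)
            nrm[i] = (0.0, 1.0)
        elif si < b3:
            a = (si - b2) / R + math.pi / 2.0
            pts[i] = (-c + R * math.cos(a), R * math.sin(a))
            nrm[i] = (math.cos(a), math.sin(a))
        else:
            pts[i] = (-c + (si - b3), -R)
            nrm[i] = (0.0, -1.0)
    return pts, nrm


# ---------------------------------------------------------------------------
# midline
# ---------------------------------------------------------------------------

def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline at n points uniform in arc length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    u = np.linspace(0.0, cum[-1], n)
    x = np.interp(u, cum, pts[:, 0])
    y = np.interp(u, cum, pts[:, 1])
    return np.column_stack([x, y])


def _aspect_ratio(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Extent ratio along the principal axes and the major-axis direction."""
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    minor = evecs[:, np.argmin(evals)]
    ext_major = np.ptp(centered @ major)
    ext_minor = np.ptp(centered @ minor)
    if ext_minor <= 0:
        return np.inf, major
    return float(ext_major / ext_minor), major


def compute_midline(contour: Contour, n_stations: int = N_STATIONS,
                    n_refine: int = 1) -> Midline:
    """Extract the pole-to-pole midline of a rod-shaped contour.

    Poles are the farthest-apart pair of boundary points (exact for capped
    rods, where boundary curvature is constant over a whole cap and therefore
    does not localize the tip).  The contour is split at the poles into two
    side arcs, each arc is resampled uniformly by normalized arc length, and
    an initial midline is the pointwise mean of arc-length-paired side
    points.  ``n_refine`` relaxation passes (one by default; more can drift
    on strongly bent cells) move each interior station to the midpoint of
    the perpendicular boundary-to-boundary chord through it, correcting the
    pairing misalignment arc-length pairing leaves on bent cells; the cap
    regions are then rebuilt by extending the body midline tangentially to
    the boundary.  On a symmetric straight rod the result is exact.

    Contours with aspect ratio below ``MIN_ASPECT_RATIO`` are too round to
    define poles; a centroid-based principal-axis chord is returned with the
    ``degenerate`` flag set.
    """
    pts = contour.points
    aspect, major = _aspect_ratio(pts)
    if aspect < MIN_ASPECT_RATIO:
        return _fallback_axis(contour, major, n_stations)

    # farthest pair of boundary points
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if i > j:
        i, j = j, i
    n = len(pts)
    arc_a = pts[i:j + 1]                                   # i -> j forward
    arc_b = pts[np.r_[np.arange(j, n), np.arange(0, i + 1)]][::-1]  # i -> j
    # work at a fixed internal resolution: pairing wiggles scale with
    # station density, so the construction runs at N_STATIONS and the
    # result is only resampled to the requested output density at the end
    side_a = _resample_polyline(arc_a, N_STATIONS)
    side_b = _resample_polyline(arc_b, N_STATIONS)
    mid = 0.5 * (side_a + side_b)
    for _ in range(n_refine):
        mid = _relax_midline(mid, contour)
    mid = _extend_to_poles(mid, contour, N_STATIONS)
    if n_stations != N_STATIONS:
        mid = _resample_polyline(mid, n_stations)
    return Midline(points=mid)


def _extend_to_poles(mid: np.ndarray, contour: Contour,
                     n_stations: int) -> np.ndarray:
    """Replace the cap portions of the midline by tangential extensions.

    Arc-length pairing is unreliable inside the hemispherical caps (the two
    side arcs contain unequal cap shares on bent cells), so stations within
    one local half-width of each end are discarded and the midline is
    extended from the remaining body along its end tangents until it meets
    the boundary — the extension point is the pole.
    """
    widths = station_widths(contour, Midline(points=mid))
    if not np.any(np.isfinite(widths)):
        return mid
    w_med = float(np.nanmedian(widths))
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    body = (arc > w_med / 2.0) & (arc < arc[-1] - w_med / 2.0)
    if int(body.sum()) < 4:
        return mid
    pts = mid[body]
    boundary = contour.polygon().exterior
    reach = 4.0 * max(np.ptp(contour.points[:, 0]),
                      np.ptp(contour.points[:, 1]))

    def pole(p: np.ndarray, inward: np.ndarray) -> np.ndarray:
        d = inward / np.linalg.norm(inward)
        probe = LineString([p, p - reach * d])
        hits = probe.intersection(boundary)
        if hits.is_empty:
            return p
        best = None
        for g in getattr(hits, "geoms", [hits]):
            for xy in np.atleast_2d(np.asarray(g.coords)):
                t = float((p - xy) @ d)
                if t > 0 and (best is None or t < best[0]):
                    best = (t, xy)
        return np.asarray(best[1]) if best else p

    k = min(3, len(pts) - 1)
    p0 = pole(pts[0], pts[k] - pts[0])
    p1 = pole(pts[-1], pts[-1 - k] - pts[-1])
    full = np.vstack([p0, pts, p1])
    return _resample_polyline(full, n_stations)


def _relax_midline(mid: np.ndarray, contour: Contour) -> np.ndarray:
    """One relaxation pass: recentre stations on their perpendicular
    boundary chords, then resample uniformly by arc length.

    Stations inside the polar caps (closer to a pole than the local
    half-width), stations with oblique or missing chords, and displacements
    larger than half the typical half-width are left untouched — cap chords
    do not straddle the axis and would drag the midline sideways.
    """
    boundary = contour.polygon().exterior
    reach = 4.0 * max(np.ptp(contour.points[:, 0]),
                      np.ptp(contour.points[:, 1]))
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = np.gradient(mid, axis=0)
    m = len(mid)
    widths = np.full(m, np.nan)
    shifts = np.full(m, np.nan)
    nvecs = np.zeros((m, 2))
    for k in range(1, m - 1):
        t = tangents[k]
        norm = np.hypot(*t)
        if norm == 0:
            continue
        nvec = np.array([-t[1], t[0]]) / norm
        p = mid[k]
        probe = LineString([p - reach * nvec, p + reach * nvec])
        hits = probe.intersection(boundary)
        if hits.is_empty:
            continue
        offsets = []
        for g in getattr(hits, "geoms", [hits]):
            for xy in np.atleast_2d(np.asarray(g.coords)):
                offsets.append(float((xy - p) @ nvec))
        pos = [o for o in offsets if o > 0]
        neg = [o for o in offsets if o < 0]
        if pos and neg:
            widths[k] = min(pos) - max(neg)
            shifts[k] = (min(pos) + max(neg)) / 2.0
            nvecs[k] = nvec
    if not np.any(np.isfinite(widths)):
        return mid
    w_med = float(np.nanmedian(widths))
    out = mid.copy()
    dist_pole = np.minimum(arc, arc[-1] - arc)
    for k in range(1, m - 1):
        if not np.isfinite(shifts[k]):
            continue
        if dist_pole[k] < w_med / 2.0:          # inside a cap
            continue
        if widths[k] > 1.5 * w_med:             # oblique chord
            continue
        step = np.clip(shifts[k], -w_med / 4.0, w_med / 4.0)
        out[k] = mid[k] + nvecs[k] * step
    return _resample_polyline(out, m)


def _fallback_axis(contour: Contour, major: np.ndarray, n_stations: int) -> Midline:
    """Principal-axis chord through the centroid, for near-round contours."""
    centroid = contour.points.mean(axis=0)
    extent = np.ptp(contour.points @ major)
    probe = LineString([centroid - 2 * extent * major,
                        centroid + 2 * extent * major])
    chord = probe.intersection(contour.polygon())
    if chord.is_empty or chord.length == 0:
        raise DegenerateShapeError("cannot define an axis for this contour")
    coords = np.asarray(chord.coords) if hasattr(chord, "coords") else None
    if coords is None or len(coords) < 2:   # multi-part: take longest piece
        parts = sorted(chord.geoms, key=lambda g: g.length)
        coords = np.asarray(parts[-1].coords)
    axis = _resample_polyline(coords, n_stations)
    return Midline(points=axis, degenerate=True)


# ---------------------------------------------------------------------------
# width / length / volume
# ---------------------------------------------------------------------------

def cell_length(midline: Midline) -> float:
    """Pole-to-pole cell length: the arc length of the midline (µm)."""
    return midline.length


def station_widths(contour: Contour, midline: Midline) -> np.ndarray:
    """Perpendicular boundary-to-boundary width at each interior midline station.

    Stations where a perpendicular does not hit the boundary on both sides
    yield NaN.
    """
    pts = midline.points
    poly = contour.polygon()
    boundary = poly.exterior
    reach = 4.0 * max(np.ptp(contour.points[:, 0]), np.ptp(contour.points[:, 1]))
    widths = np.full(len(pts), np.nan)
    tangents = np.gradient(pts, axis=0)
    for k in range(1, len(pts) - 1):
        t = tangents[k]
        norm = np.hypot(*t)
        if norm == 0:
            continue
        nvec = np.array([-t[1], t[0]]) / norm
        p = pts[k]
        probe = LineString([p - reach * nvec, p + reach * nvec])
        hits = probe.intersection(boundary)
        if hits.is_empty:
            continue
        geoms = getattr(hits, "geoms", [hits])
        offsets = []
        for g in geoms:
            for xy in np.atleast_2d(np.asarray(g.coords)):
                offsets.append(float((xy - p) @ nvec))
        pos = [o for o in offsets if o > 0]
        neg = [-o for o in offsets if o < 0]
        if pos and neg:
            widths[k] = min(pos) + min(neg)
    return widths


def cell_width(
    contour: Contour,
    midline: Midline,
    septal_frac: float = SEPTAL_FRAC,
) -> float:
    """Mean cell width 2R (µm) from perpendicular midline-to-boundary chords.

    Stations within one local half-width of either pole are excluded (the
    hemispherical caps shorten the perpendicular chord there), as are septal
    stations whose width falls below ``septal_frac`` of the median width of
    the pole-excluded stations.
    """
    widths = station_widths(contour, midline)
    arc = midline.arclength
    total = midline.length
    valid = np.isfinite(widths)
    # pole exclusion: distance to the nearest pole must exceed the local
    # half-width measured at that station
    dist_pole = np.minimum(arc, total - arc)
    keep = valid & (dist_pole >= widths / 2.0)
    if not np.any(keep):
        raise DegenerateShapeError("no usable width stations after pole exclusion")
    med = float(np.median(widths[keep]))
    keep &= widths >= septal_frac * med
    if not np.any(keep):
        raise DegenerateShapeError("no usable width stations after septal exclusion")
    return float(np.mean(widths[keep]))


def pill_volume(width: float, length: float, formula: str = "spherocylinder") -> float:
    """Volume of a pill-shaped cell from its width 2R and length L (µm³).

    ``formula="spherocylinder"`` (default) is the geometric spherocylinder
    volume πR²(L − 2R) + (4/3)πR³.  ``formula="printed"`` doubles the cylinder
    term, 2πR²(L − 2R) + (4/3)πR³, reproducing a published variant of the
    formula verbatim; the two coincide in the sphere limit L = 2R.
    """
    if width <= 0:
        raise ParameterError("width must be positive")
    if length < width * (1.0 - 1e-12):
        raise ParameterError("length must be at least the width")
    R = width / 2.0
    L = max(length, width)
    caps = 4.0 / 3.0 * math.pi * R ** 3
    cyl = math.pi * R ** 2 * (L - 2.0 * R)
    if formula == "spherocylinder":
        return cyl + caps
    if formula == "printed":
        return 2.0 * cyl + caps
    raise ParameterError(f"unknown volume formula: {formula!r}")


def shape_from_contour(
    contour: Contour,
    formula: str = "spherocylinder",
    n_stations: int = N_STATIONS,
    septal_frac: float = SEPTAL_FRAC,
) -> CellShape:
    """Midline → width/length/volume for one contour; flags degenerate shapes."""
    midline = compute_midline(contour, n_stations=n_stations)
    width = cell_width(contour, midline, septal_frac=septal_frac)
    length = cell_length(midline)
    # a degenerate (near-round) shape can report length < width; clamp for
    # the volume formula but keep the raw measurements
    vol_length = max(length, width)
    volume = pill_volume(width, vol_length, formula=formula)
    return CellShape(
        width=width,
        length=length,
        volume=volume,
        radius=width / 2.0,
        cell_id=contour.cell_id,
        degenerate=midline.degenerate,
    )
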