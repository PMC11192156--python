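"""ImageJ-style shape descriptors for binary particles.

Computes, for each particle, the full measurement vector used by the
classifier: calibrated area, centroids, crack-boundary perimeter, bounding
box, moment-based fitted ellipse, circularity, Feret diameters by rotating
calipers on the convex hull, intensity statistics, aspect ratio, roundness
and solidity.

Conventions
-----------
* Lengths/areas are calibrated to mm via the scan dpi; Feret start
  coordinates stay in pixel corners (positional bookkeeping).
* Angles (ellipse and Feret) are reported in [0, 180) degrees measured
  counter-clockwise from the image x-axis with y flipped to mathematical
  orientation.
* Circularity is clamped at 1.0: the crack-boundary perimeter overestimates
  smooth perimeters, so near-circular particles would otherwise dip the
  statistic below its analytic value rather than exceed it.
* The fitted ellipse is rescaled so its area matches the particle area,
  which makes Round = 1/AR an exact identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .scanio import ScanImage, pixel_size_mm
from .segmentation import Particle, polygon_area

__all__ = [
    "MeasurementRecord",
    "MEASUREMENT_COLUMNS",
    "measure_particle",
    "measure_scan",
    "fit_ellipse",
    "feret_diameters",
    "shape_ratios",
    "intensity_stats",
]

# Column order of the measurement table consumed by the classifier.
MEASUREMENT_COLUMNS = [
    "Area", "X", "Y", "XM", "YM", "Perim", "BX", "BY", "Width", "Height",
    "Major", "Minor", "Angle", "Circ", "Feret", "IntDen", "Median",
    "Skew", "Kurt", "RawIntDen", "FeretX", "FeretY", "FeretAngle",
    "MinFeret", "AR", "Round", "Solidity",
]


@dataclass
class MeasurementRecord:
    Area: float
    X: float
    Y: float
    XM: float
    YM: float
    Perim: float
    BX: float
    BY: float
    Width: float
    Height: float
    Major: float
    Minor: float
    Angle: float
    Circ: float
    Feret: float
    IntDen: float
    Median: float
    Skew: Optional[float]
    Kurt: Optional[float]
    RawIntDen: float
    FeretX: float
    FeretY: float
    FeretAngle: float
    MinFeret: float
    AR: float
    Round: float
    Solidity: float
    tag: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _math_angle_deg(dx: float, dy_raster: float) -> float:
    """Angle of a direction vector in [0, 180), y-up orientation."""
    ang = math.degrees(math.atan2(-dy_raster, dx)) % 180.0
    return ang


def fit_ellipse(particle: Particle) -> tuple[float, float, float]:
    """Fit an ellipse by moments: (Major, Minor, Angle) in px / degrees.

    Second central moments of the pixel set treat each pixel as a unit
    square (adds 1/12 per axis).  Axes come from the eigen-decomposition
    and are rescaled by a common factor so the ellipse area equals the
    pixel count.  Isotropic particles get Angle = 0.
    """
    x = particle.cols + 0.5
    y = particle.rows + 0.5
    n = particle.pixel_count
    mu20 = float(np.var(x)) + 1.0 / 12.0
    mu02 = float(np.var(y)) + 1.0 / 12.0
    # y flipped to mathematical orientation for the angle convention
    mu11 = -float(np.mean((x - x.mean()) * (y - y.mean())))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    semi_major = 2.0 * math.sqrt(lam_major)
    semi_minor = 2.0 * math.sqrt(lam_minor)
    if semi_minor <= 0:
        semi_minor = semi_major if semi_major > 0 else 1.0
    scale = math.sqrt(n / (math.pi * semi_major * semi_minor))
    major = 2.0 * semi_major * scale
    minor = 2.0 * semi_minor * scale
    if math.isclose(lam_major, lam_minor, rel_tol=1e-9, abs_tol=1e-12):
        angle = 0.0
    else:
        vx, vy = evecs[:, 1]  # eigenvector of the larger eigenvalue, y-up
        angle = math.degrees(math.atan2(vy, vx)) % 180.0
    return major, minor, angle


def _hull_vertices(boundary: np.ndarray) -> np.ndarray:
    pts = np.unique(boundary, axis=0)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except Exception:  # collinear degenerate sets
        return pts
    return pts[hull.vertices]


def feret_diameters(
    boundary: np.ndarray,
) -> tuple[float, float, float, float, float]:
    """(Feret, FeretAngle, FeretX, FeretY, MinFeret) in pixel units.

    Feret is the maximum pairwise distance over convex-hull vertices;
    MinFeret is the minimum width over hull edges (rotating calipers).
    (FeretX, FeretY) is the endpoint of the maximal chord with the smaller
    y, ties broken by smaller x.
    """
    hull = _hull_vertices(np.asarray(boundary, dtype=float))
    if len(hull) == 1:
        return 0.0, 0.0, float(hull[0, 0]), float(hull[0, 1]), 0.0
    # max caliper: O(h^2) over hull vertices, deterministic tie-break
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    dmax = d2.max()
    ii, jj = np.nonzero(d2 == dmax)
    # canonical pair: smallest (sorted endpoint coordinates)
    pairs = sorted(
        (tuple(sorted([tuple(hull[i]), tuple(hull[j])])) for i, j in zip(ii, jj))
    )
    p, q = (np.array(v) for v in pairs[0])
    feret = math.sqrt(dmax)
    angle = _math_angle_deg(q[0] - p[0], q[1] - p[1])
    start = min((p, q), key=lambda v: (v[1], v[0]))
    # min caliper: width across each hull edge
    if len(hull) == 2:
        minferet = 0.0
    else:
        minferet = math.inf
        h = len(hull)
        for k in range(h):
            a = hull[k]
            b = hull[(k + 1) % h]
            e = b - a
            norm = math.hypot(e[0], e[1])
            if norm == 0:
                continue
            rel = hull - a
            dist = np.abs(e[0] * rel[:, 1] - e[1] * rel[:, 0]) / norm
            minferet = min(minferet, float(dist.max()))
    return feret, angle, float(start[0]), float(start[1]), minferet


def shape_ratios(
    area: float, perim: float, major: float, minor: float, hull_area: float
) -> tuple[float, float, float, float]:
    """(Circ, AR, Round, Solidity) from calibrated inputs.

    Circ = min(1, 4*pi*Area/Perim^2); AR = Major/Minor; Round = Minor/Major
    (identical to 4*Area/(pi*Major^2) under the area-matched ellipse fit);
    Solidity = Area/hull_area.
    """
    for name, v in (("area", area), ("perim", perim), ("major", major),
                    ("minor", minor), ("hull_area", hull_area)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    circ = min(1.0, 4.0 * math.pi * area / (perim * perim))
    ar = major / minor
    rnd = minor / major
    solidity = min(1.0, area / hull_area)
    return circ, ar, rnd, solidity


def _standardized_moment(values: np.ndarray, k: int) -> float:
    mu = values.mean()
    sd = values.std()
    return float(np.mean(((values - mu) / sd) ** k))


def intensity_stats(
    particle: Particle, image: ScanImage
) -> tuple[float, float, float, Optional[float], Optional[float], float, float]:
    """(IntDen, RawIntDen, Median, Skew, Kurt, XM, YM).

    IntDen = mean intensity x calibrated area; Skew/Kurt are the third and
    fourth standardized central moments, missing on zero-variance (binary)
    particles.  XM/YM are the intensity-weighted centroid in mm; on
    zero-weight or constant particles they fall back to the geometric
    centroid.
    """
    cal = image.pixel_size_mm()
    vals = image.pixels[particle.rows, particle.cols].astype(float)
    raw = float(vals.sum())
    area_mm2 = particle.pixel_count * cal * cal
    intden = float(vals.mean()) * area_mm2
    median = float(np.median(vals))
    if vals.std() == 0:
        skew = kurt = None
    else:
        skew = _standardized_moment(vals, 3)
        kurt = _standardized_moment(vals, 4) - 3.0
    x = (particle.cols + 0.5) * cal
    y = (particle.rows + 0.5) * cal
    if raw == 0 or vals.std() == 0:
        xm, ym = float(x.mean()), float(y.mean())
    else:
        xm = float(np.average(x, weights=vals))
        ym = float(np.average(y, weights=vals))
    return intden, raw, median, skew, kurt, xm, ym


def measure_particle(particle: Particle, image: ScanImage) -> MeasurementRecord:
    """Compute the full measurement vector for one particle."""
    cal = image.pixel_size_mm()
    n = particle.pixel_count
    area = n * cal * cal
    x_c = float((particle.cols + 0.5).mean()) * cal
    y_c = float((particle.rows + 0.5).mean()) * cal

    boundary = particle.boundary
    perim_px = float(len(boundary))  # unit-length axis-aligned edges
    perim = perim_px * cal

    r0, c0, r1, c1 = particle.bbox
    bx, by = c0 * cal, r0 * cal
    width = (c1 - c0 + 1) * cal
    height = (r1 - r0 + 1) * cal

    major_px, minor_px, angle = fit_ellipse(particle)
    major, minor = major_px * cal, minor_px * cal

    feret_px, feret_angle, feret_x, feret_y, minferet_px = feret_diameters(boundary)
    feret, minferet = feret_px * cal, minferet_px * cal

    hull = _hull_vertices(boundary)
    hull_area_px = abs(polygon_area(hull)) if len(hull) >= 3 else float(n)
    hull_area = hull_area_px * cal * cal

    circ, ar, rnd, solidity = shape_ratios(area, perim, major, minor, hull_area)
    intden, raw, median, skew, kurt, xm, ym = intensity_stats(particle, image)

    return MeasurementRecord(
        Area=area, X=x_c, Y=y_c, XM=xm, YM=ym, Perim=perim,
        BX=bx, BY=by, Width=width, Height=height,
        Major=major, Minor=minor, Angle=angle, Circ=circ,
        Feret=feret, IntDen=intden, Median=median, Skew=skew, Kurt=kurt,
        RawIntDen=raw, FeretX=feret_x, FeretY=feret_y,
        FeretAngle=feret_angle, MinFeret=minferet,
        AR=ar, Round=rnd, Solidity=solidity,
        tag=particle.source_tag or image.source_tag,
    )


def measure_scan(particles: Sequence[Particle], image: ScanImage) -> List[MeasurementRecord]:
    return [measure_particle(p, image) for p in particles]
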