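"""Particle extraction from binary scans.

Thresholds a scan, labels 8-connected foreground components, rejects
sub-seed debris by calibrated area, fills interior holes, and traces each
particle's crack boundary — the closed polygon along pixel edges separating
foreground from background.  Foreground uses 8-connectivity, background 4,
the standard particle-analysis convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .scanio import DARK_ON_LIGHT, ScanImage

__all__ = ["Particle", "binarize", "label_particles", "trace_boundary"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Particle:
    """One connected foreground component (holes filled)."""

    rows: np.ndarray  # pixel row coordinates
    cols: np.ndarray  # pixel col coordinates
    label_id: int
    source_tag: str = ""
    _boundary: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("particle pixel set must be non-empty")
        if len(self.rows) != len(self.cols):
            raise ValueError("rows and cols must have equal length")

    @property
    def pixel_count(self) -> int:
        return int(len(self.rows))

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), inclusive."""
        return (
            int(self.rows.min()),
            int(self.cols.min()),
            int(self.rows.max()),
            int(self.cols.max()),
        )

    @property
    def boundary(self) -> np.ndarray:
        """Crack-boundary polygon, (x, y) vertices, lazily traced."""
        if self._boundary is None:
            self._boundary = trace_boundary(self)
        return self._boundary

    def mask(self) -> np.ndarray:
        """Boolean mask of the particle cropped to its bounding box."""
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        m[self.rows - r0, self.cols - c0] = True
        return m


def binarize(image: ScanImage, method: str = "otsu", threshold: Optional[float] = None) -> np.ndarray:
    """Return a boolean foreground mask (True = seed side).

    Methods: ``otsu`` (between-class-variance maximising threshold),
    ``fixed`` (explicit threshold), ``none`` (image already binary; the
    nonzero level is taken as given and polarity decides which level is
    foreground).  A constant image under Otsu yields all-background.
    """
    px = image.pixels
    dark_fg = image.polarity == DARK_ON_LIGHT
    if method == "none":
        if not image.is_binary:
            raise ValueError("method 'none' requires an already-binary image")
        nonzero = px > 0
        return ~nonzero if dark_fg else nonzero
    if method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires a threshold value")
        if not 0 <= threshold <= max(255, px.max()):
            raise ValueError(f"threshold {threshold} out of range")
        t = threshold
    elif method == "otsu":
        if px.min() == px.max():  # degenerate histogram: nothing to separate
            return np.zeros_like(px, dtype=bool)
        t = threshold_otsu(px)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return px <= t if dark_fg else px > t


def label_particles(
    mask: np.ndarray,
    min_area_mm2: float = 0.2,
    pixel_size_mm: float = 25.4 / 600,
    source_tag: str = "",
) -> List[Particle]:
    """Label 8-connected components, fill holes, drop debris below
    ``min_area_mm2``, and return particles ordered top-to-bottom then
    left-to-right by bounding-box origin with labels from 1."""
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    px_area = pixel_size_mm * pixel_size_mm
    objects = ndimage.find_objects(labels)
    kept = []
    for lab, sl in enumerate(objects, start=1):
        comp = labels[sl] == lab
        comp = ndimage.binary_fill_holes(comp)
        if comp.sum() * px_area < min_area_mm2:
            continue
        rr, cc = np.nonzero(comp)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        kept.append((int(rows.min()), int(cols.min()), rows, cols))
    kept.sort(key=lambda t: (t[0], t[1]))
    return [
        Particle(rows=rows, cols=cols, label_id=i, source_tag=source_tag)
        for i, (_, _, rows, cols) in enumerate(kept, start=1)
    ]


def trace_boundary(particle: Particle) -> np.ndarray:
    """Trace the crack boundary of a particle as an (n, 2) array of (x, y)
    pixel-corner vertices.

    Edges are oriented with foreground on the left, so the shoelace area of
    the returned polygon is positive and equals the pixel count (holes are
    filled upstream).  At pinch corners — two foreground pixels touching
    only diagonally — the walk takes the right-most turn, which keeps the
    whole 8-connected component on a single (weakly simple) cycle.
    A single pixel traces to its unit square.
    """
    r0, c0, _, _ = particle.bbox
    m = particle.mask()
    h, w = m.shape
    pad = np.zeros((h + 2, w + 2), dtype=bool)
    pad[1:-1, 1:-1] = m

    # Directed edges (start -> end) in local corner coordinates (x, y),
    # oriented so that foreground lies to the left of travel.
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    rr, cc = np.nonzero(m)
    for r, c in zip(rr.tolist(), cc.tolist()):
        pr, pc = r + 1, c + 1
        if not pad[pr - 1, pc]:  # background above: top edge, +x
            edges.setdefault((c, r), []).append((c + 1, r))
        if not pad[pr + 1, pc]:  # bottom edge, -x
            edges.setdefault((c + 1, r + 1), []).append((c, r + 1))
        if not pad[pr, pc - 1]:  # left edge, -y
            edges.setdefault((c, r + 1), []).append((c, r))
        if not pad[pr, pc + 1]:  # right edge, +y
            edges.setdefault((c + 1, r), []).append((c + 1, r + 1))

    start = min(edges)
    poly = [start]
    prev_dir: Optional[tuple[int, int]] = None
    cur = start
    while True:
        outs = edges[cur]
        if len(outs) == 1 or prev_dir is None:
            nxt = outs[0]
        else:
            # right-most turn: most negative cross(prev_dir, candidate_dir)
            nxt = min(
                outs,
                key=lambda v: prev_dir[0] * (v[1] - cur[1])
                - prev_dir[1] * (v[0] - cur[0]),
            )
        outs.remove(nxt)
        if not outs:
            del edges[cur]
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        cur = nxt
        if cur == start and not edges.get(start):
            break
        poly.append(cur)

    verts = np.asarray(poly, dtype=float)
    verts[:, 0] += c0
    verts[:, 1] += r0
    return verts


def polygon_area(verts: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (x, y) vertices."""
    x = verts[:, 0]
    y = verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(verts: np.ndarray) -> float:
    """Total edge length of a closed polygon."""
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())
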