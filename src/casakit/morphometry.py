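"""Sperm-head shape descriptors on segmented blobs from stained stills.

Length and width are the maximum and minimum caliper (Feret) diameters of
the blob's convex hull, computed by rotating calipers.  Perimeter uses the
Crofton formula (4 directions), which is asymptotically unbiased for smooth
digital shapes — a plain boundary-polygon length overestimates a digital
disc's circumference by ~5 % and would push roughness visibly below 1.
The derived shape indices are:

* ellipticity = L/W          (>= 1)
* roughness   = 4πA/P²       (1 for a circle, lower for rough outlines)
* elongation  = (L−W)/(L+W)  (0 for a circle, → 1 for a needle)
* regularity  = πLW/(4A)     (1 for a perfect ellipse)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import perimeter_crofton

from .config import AnalysisSettings
from .tracking import CellBlob, segment_frame

__all__ = ["MorphometryResult", "feret_diameters", "measure_cell", "analyze_morphometry"]


@dataclass
class MorphometryResult:
    cell_id: int
    centroid: tuple[float, float]
    mean_gray: float
    area: float
    perimeter: float
    length: float
    width: float
    ellipticity: float
    roughness: float
    elongation: float
    regularity: float
    touches_border: bool


def feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """(max, min) caliper diameters of a 2-D point set via its convex hull.

    The maximum Feret diameter is the largest pairwise distance between hull
    vertices; the minimum is the smallest width over hull-edge-aligned
    calipers (the minimum width of the hull).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        d = float(np.linalg.norm(pts[-1] - pts[0]))
        return d, 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except Exception:  # degenerate (collinear) input
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return float(np.linalg.norm(hi - lo)), 0.0

    diffs = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())

    feret_min = np.inf
    n = len(verts)
    for i in range(n):
        edge = verts[(i + 1) % n] - verts[i]
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = (verts - verts[i]) @ normal
        width = proj.max() - proj.min()
        feret_min = min(feret_min, width)
    return feret_max, float(feret_min)


def measure_cell(
    blob: CellBlob,
    image: np.ndarray,
    mu: float,
    cell_id: int = 0,
) -> MorphometryResult:
    """Measure one blob on its source grayscale image; lengths in µm.

    A blob touching the image border is flagged (its outline is cut off and
    the measurements are unreliable) but still reported.
    """
    rows, cols = blob.coords[:, 0], blob.coords[:, 1]
    mean_gray = float(image[rows, cols].mean())
    area = blob.area_px * mu**2

    mask, _ = blob.local_mask()
    contour = blob.contour
    perimeter = perimeter_crofton(mask, directions=4) * mu
    feret_max, feret_min = feret_diameters(contour)
    length, width = feret_max * mu, feret_min * mu

    touches = bool(
        rows.min() == 0
        or cols.min() == 0
        or rows.max() == image.shape[0] - 1
        or cols.max() == image.shape[1] - 1
    )
    ellipticity = length / width if width > 0 else np.nan
    roughness = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan
    elongation = (length - width) / (length + width) if length + width > 0 else np.nan
    regularity = np.pi * length * width / (4.0 * area) if area > 0 else np.nan
    return MorphometryResult(
        cell_id=cell_id,
        centroid=blob.centroid,
        mean_gray=mean_gray,
        area=area,
        perimeter=perimeter,
        length=length,
        width=width,
        ellipticity=ellipticity,
        roughness=roughness,
        elongation=elongation,
        regularity=regularity,
        touches_border=touches,
    )


def _as_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        # Rec. 709 luminance, kept on the 0–255 scale
        return image[..., 0] * 0.2126 + image[..., 1] * 0.7152 + image[..., 2] * 0.0722
    return np.asarray(image, dtype=float)


def analyze_morphometry(
    image: np.ndarray,
    settings: AnalysisSettings,
    exclude: tuple[int, ...] = (),
) -> list[MorphometryResult]:
    """Segment a still and measure every accepted blob.

    Blobs outside the [min_cell_size, max_cell_size] window are dropped by
    segmentation; ``exclude`` removes cells by id after measurement — the
    semi-automated review step.  An image with no cells yields an empty
    report.
    """
    gray = _as_gray(image)
    blobs = segment_frame(gray, settings)
    results = [
        measure_cell(b, gray, settings.um_per_px, cell_id=i)
        for i, b in enumerate(blobs)
    ]
    return [r for r in results if r.cell_id not in set(exclude)]
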