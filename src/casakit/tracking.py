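"""Cell detection and frame-to-frame track linking.

Detection is a global Otsu threshold followed by 8-connected component
labelling and an area filter in µm².  Linking is greedy nearest-neighbour
within the user's search radius (``max_displacement``): candidate pairs
between consecutive frames are matched in ascending distance order, each
detection used at most once; a detection with no match within the radius
starts a new track, and a track with no match terminates.  There is no gap
closing — a missed detection ends the track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import find_contours

from .config import AnalysisSettings, ConfigError
from .tracks import Trajectory, TrackSet

__all__ = ["CellBlob", "segment_frame", "link_frames", "filter_tracks"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class CellBlob:
    """One segmented 8-connected component.

    ``centroid`` is the intensity-weighted centre in (x, y) pixel
    coordinates (sub-pixel); ``coords`` are the member pixels as (row, col).
    """

    centroid: tuple[float, float]
    area_px: int
    coords: np.ndarray

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}

    def local_mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Binary mask of the blob in its bounding box plus the box origin."""
        rmin, cmin = self.coords.min(axis=0)
        rmax, cmax = self.coords.max(axis=0)
        mask = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
        mask[self.coords[:, 0] - rmin, self.coords[:, 1] - cmin] = True
        return mask, (int(rmin), int(cmin))

    @property
    def contour(self) -> np.ndarray:
        """Ordered sub-pixel boundary, (M, 2) array of (x, y) coordinates."""
        mask, (rmin, cmin) = self.local_mask()
        padded = np.pad(mask.astype(float), 1)
        contours = find_contours(padded, 0.5)
        # the outer boundary is the longest contour
        rc = max(contours, key=len) - 1.0  # undo padding
        xy = np.column_stack([rc[:, 1] + cmin, rc[:, 0] + rmin])
        return xy


def segment_frame(frame: np.ndarray, settings: AnalysisSettings) -> list[CellBlob]:
    """Detect cells in one grayscale frame.

    Otsu global threshold (image inverted first when ``settings.foreground``
    is "dark"), 8-connected components, then the [min_cell_size,
    max_cell_size] area window in µm².  A blank (constant) frame yields an
    empty list.  Centroids are intensity-weighted and sub-pixel.
    """
    img = np.asarray(frame)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a 2-D grayscale image")
    img = img.astype(float)
    if settings.foreground == "dark":
        img = img.max() - img
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    binary = img > thr
    labels, n = ndi.label(binary, structure=_EIGHT)
    if n == 0:
        return []

    flat = labels.ravel()
    idx = np.flatnonzero(flat)
    lab = flat[idx]
    order = np.argsort(lab, kind="stable")
    idx, lab = idx[order], lab[order]
    starts = np.searchsorted(lab, np.arange(1, n + 1))
    ends = np.append(starts[1:], idx.size)
    rows, cols = np.unravel_index(idx, labels.shape)
    weights = img.ravel()[idx]

    wsum = np.add.reduceat(weights, starts)
    wr = np.add.reduceat(weights * rows, starts) / wsum
    wc = np.add.reduceat(weights * cols, starts) / wsum
    areas = ends - starts

    lo = settings.min_cell_size / settings.um_per_px**2
    hi = settings.max_cell_size / settings.um_per_px**2
    blobs: list[CellBlob] = []
    for i in range(n):
        if not lo <= areas[i] <= hi:
            continue
        sl = slice(starts[i], ends[i])
        blobs.append(
            CellBlob(
                centroid=(float(wc[i]), float(wr[i])),
                area_px=int(areas[i]),
                coords=np.column_stack([rows[sl], cols[sl]]),
            )
        )
    return blobs


def link_frames(detections: list[list[CellBlob]], settings: AnalysisSettings) -> TrackSet:
    """Link per-frame detections into trajectories with the search-radius rule.

    Candidate (track, blob) pairs with centroid distance at most
    ``max_displacement`` (converted to pixels) are matched greedily in
    ascending distance order; ties break deterministically toward the lower
    track then blob index.  Tracks that end up with a single point are
    dropped (a trajectory needs two points to define a displacement).
    """
    if len(detections) < 2:
        raise ValueError("need detections for at least 2 frames")
    max_r = settings.max_displacement_px

    # open tracks: lists of (frame, x, y); position of the last point
    open_pts: list[list[tuple[int, float, float]]] = []
    closed: list[list[tuple[int, float, float]]] = []
    open_pts = [[(0, bx, by)] for (bx, by) in (b.centroid for b in detections[0])]

    for t in range(1, len(detections)):
        cents = np.array([b.centroid for b in detections[t]], dtype=float).reshape(-1, 2)
        last = np.array([trk[-1][1:] for trk in open_pts], dtype=float).reshape(-1, 2)
        n_trk, n_det = last.shape[0], cents.shape[0]
        matched_trk = np.zeros(n_trk, dtype=bool)
        matched_det = np.zeros(n_det, dtype=bool)
        if n_trk and n_det:
            dist = np.linalg.norm(last[:, None, :] - cents[None, :, :], axis=2)
            ti, di = np.nonzero(dist <= max_r)
            dv = dist[ti, di]
            for k in np.lexsort((di, ti, dv)):
                a, b = ti[k], di[k]
                if matched_trk[a] or matched_det[b]:
                    continue
                matched_trk[a] = matched_det[b] = True
                open_pts[a].append((t, float(cents[b, 0]), float(cents[b, 1])))
        # terminate unmatched tracks, start new ones from unmatched blobs
        still_open = []
        for a, trk in enumerate(open_pts):
            (still_open if matched_trk[a] else closed).append(trk)
        open_pts = still_open
        for b in range(n_det):
            if not matched_det[b]:
                open_pts.append([(t, float(cents[b, 0]), float(cents[b, 1]))])
    closed.extend(open_pts)

    trajectories = []
    tid = 0
    for trk in closed:
        if len(trk) < 2:
            continue
        arr = np.array(trk, dtype=float)
        trajectories.append(
            Trajectory(track_id=tid, points=arr[:, 1:], frames=arr[:, 0].astype(int))
        )
        tid += 1
    return TrackSet(trajectories, meta={"source": "tracking", "n_frames": len(detections)})


def filter_tracks(tracks: TrackSet, settings: AnalysisSettings) -> TrackSet:
    """Drop tracks shorter than ``min_track_length`` frames; order is stable."""
    n_frames = tracks.meta.get("n_frames", tracks.n_frames)
    if n_frames and settings.min_track_length > n_frames:
        raise ConfigError(
            f"min_track_length ({settings.min_track_length}) exceeds the video "
            f"length ({n_frames} frames)"
        )
    kept = [t for t in tracks if len(t) >= settings.min_track_length]
    return TrackSet(kept, meta=dict(tracks.meta))
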