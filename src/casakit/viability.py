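"""Membrane-integrity (live/dead) counting on dual-stained fluorescence stills.

With an acridine-orange / propidium-iodide stain, membrane-intact cells
fluoresce green and membrane-damaged cells red.  The red and green channels
are segmented independently; green blobs count as viable, red blobs as
non-viable.  Cells visible in both channels (dual-stained) are detected by
footprint overlap and counted once, assigned to the channel with the higher
mean intensity over the joint footprint.  The blue channel is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisSettings
from .tracking import CellBlob, segment_frame

__all__ = ["ViabilityResult", "classify_viability"]


@dataclass
class ViabilityResult:
    n_viable: int
    n_nonviable: int
    pct_viable: float
    pct_nonviable: float
    cells: list[tuple[float, float, str]] = field(default_factory=list)
    """Per-cell records (x, y, label) with label "viable" or "nonviable"."""


def _overlap_merge(
    green: list[CellBlob],
    red: list[CellBlob],
    g_chan: np.ndarray,
    r_chan: np.ndarray,
) -> tuple[list[tuple[CellBlob, str]], set[int], set[int]]:
    """Resolve dual-stained cells.

    A green/red blob pair whose footprints overlap by more than 50 % of the
    smaller footprint is one cell; it is assigned to the channel whose mean
    intensity over the union footprint is higher.
    """
    shape = g_chan.shape
    red_label = np.zeros(shape, dtype=np.int32)
    for j, blob in enumerate(red, start=1):
        red_label[blob.coords[:, 0], blob.coords[:, 1]] = j

    merged: list[tuple[CellBlob, str]] = []
    used_g: set[int] = set()
    used_r: set[int] = set()
    for i, gb in enumerate(green):
        hits = red_label[gb.coords[:, 0], gb.coords[:, 1]]
        hits = hits[hits > 0]
        if hits.size == 0:
            continue
        labels, counts = np.unique(hits, return_counts=True)
        j = int(labels[np.argmax(counts)]) - 1
        if j in used_r:
            continue
        rb = red[j]
        overlap = counts.max()
        if overlap <= 0.5 * min(gb.area_px, rb.area_px):
            continue
        union = np.unique(np.vstack([gb.coords, rb.coords]), axis=0)
        g_mean = g_chan[union[:, 0], union[:, 1]].mean()
        r_mean = r_chan[union[:, 0], union[:, 1]].mean()
        winner = gb if g_mean >= r_mean else rb
        label = "viable" if g_mean >= r_mean else "nonviable"
        merged.append((winner, label))
        used_g.add(i)
        used_r.add(j)
    return merged, used_g, used_r


def classify_viability(image: np.ndarray, settings: AnalysisSettings) -> ViabilityResult:
    """Count viable (green) and non-viable (red) cells in an RGB still."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("classify_viability needs a 3-channel RGB image")
    r_chan = img[..., 0].astype(float)
    g_chan = img[..., 1].astype(float)

    green = segment_frame(g_chan, settings)
    red = segment_frame(r_chan, settings)
    merged, used_g, used_r = _overlap_merge(green, red, g_chan, r_chan)

    cells: list[tuple[float, float, str]] = []
    for i, blob in enumerate(green):
        if i not in used_g:
            cells.append((*blob.centroid, "viable"))
    for j, blob in enumerate(red):
        if j not in used_r:
            cells.append((*blob.centroid, "nonviable"))
    for blob, label in merged:
        cells.append((*blob.centroid, label))

    n_viable = sum(1 for *_, lab in cells if lab == "viable")
    n_nonviable = len(cells) - n_viable
    total = n_viable + n_nonviable
    pct_v = 100.0 * n_viable / total if total else np.nan
    pct_n = 100.0 * n_nonviable / total if total else np.nan
    return ViabilityResult(
        n_viable=n_viable,
        n_nonviable=n_nonviable,
        pct_viable=pct_v,
        pct_nonviable=pct_n,
        cells=cells,
    )
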