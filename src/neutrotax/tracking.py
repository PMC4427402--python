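"""Automated detection and frame-to-frame linking of cell centroids.

Replaces manual click-tracking: per frame, cells are detected either from a
label image (exact centroids) or from a grayscale image by Otsu thresholding
(the between-class-variance criterion), hole filling, and small-object
removal.  Detections are then linked greedily by globally nearest pairs with
a displacement gate and optional gap tolerance.  Greedy linking is exact
under the simulator's seeding guarantee (centers at least two major axes
apart, per-frame steps much smaller than the separation); it is a documented
limitation for dense scenes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .simulate import Track

__all__ = ["Detection", "detect_cells", "detect_stack", "link_tracks"]


@dataclass(frozen=True)
class Detection:
    """One detected cell: centroid (µm), mask area (µm²), source label."""

    x: float
    y: float
    area: float
    label: int = 0


def detect_cells(
    frame: np.ndarray,
    mode: str = "label",
    min_area: float = 0.0,
    pixel_size: float = 1.0,
) -> list[Detection]:
    """Detect cell centroids in one frame.

    ``label`` mode reads an integer label image and returns exact per-label
    centroids; ``threshold`` mode segments a grayscale image with Otsu's
    criterion, fills holes, and drops components below ``min_area`` (µm²).
    A frame with nothing above threshold yields an empty list.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if mode == "label":
        labeled = frame.astype(np.int64)
    elif mode == "threshold":
        if np.ptp(frame) == 0:
            return []
        binary = frame > threshold_otsu(frame)
        binary = ndi.binary_fill_holes(binary)
        labeled = sk_label(binary)
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    min_px = min_area / pixel_size**2
    out = []
    for rp in regionprops(labeled):
        if rp.area < min_px:
            continue
        cy, cx = rp.centroid  # row, col
        out.append(
            Detection(
                x=float(cx) * pixel_size,
                y=float(cy) * pixel_size,
                area=float(rp.area) * pixel_size**2,
                label=int(rp.label),
            )
        )
    # deterministic order regardless of labeling order
    out.sort(key=lambda d: (d.x, d.y))
    return out


def detect_stack(
    stack: np.ndarray, mode: str = "label", min_area: float = 0.0, pixel_size: float = 1.0
) -> list[list[Detection]]:
    """Run :func:`detect_cells` on every frame of a (T, H, W) stack."""
    return [detect_cells(f, mode=mode, min_area=min_area, pixel_size=pixel_size) for f in stack]


class _OpenTrack:
    __slots__ = ("points", "frames", "last_frame")

    def __init__(self, det: Detection, frame: int):
        self.points = [det]
        self.frames = [frame]
        self.last_frame = frame

    def add(self, det: Detection, frame: int) -> None:
        self.points.append(det)
        self.frames.append(frame)
        self.last_frame = frame


def link_tracks(
    detections: list[list[Detection]],
    max_displacement: float,
    max_gap: int = 0,
    frame_interval: float = 10.0,
    min_length: int = 10,
    condition_label: str = "",
) -> list[Track]:
    """Link per-frame detections into trajectories.

    Frame by frame, all (open track, detection) pairs within the
    displacement gate — scaled by the gap length plus one — are assigned
    greedily in order of increasing distance (ties broken by track age then
    detection position, so the result is independent of input ordering
    within a frame).  Unassigned detections open new tracks; tracks
    unmatched for more than ``max_gap`` frames are closed.  Tracks shorter
    than ``min_length`` frames are discarded.
    """
    if not max_displacement > 0:
        raise ValueError("max_displacement must be > 0")
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []

    for f, dets in enumerate(detections):
        dets = sorted(dets, key=lambda d: (d.x, d.y))
        still_open: list[_OpenTrack] = []
        for tr in open_tracks:
            if f - tr.last_frame > max_gap + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pairs = []
        for ti, tr in enumerate(open_tracks):
            gap = f - tr.last_frame
            gate = max_displacement * gap
            last = tr.points[-1]
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.x - last.x, d.y - last.y))
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            open_tracks[ti].add(dets[di], f)
        for di, d in enumerate(dets):
            if di not in used_d:
                open_tracks.append(_OpenTrack(d, f))

    closed.extend(open_tracks)
    tracks = []
    tid = 0
    for tr in closed:
        if len(tr.points) < min_length:
            continue
        xy = np.array([[p.x, p.y] for p in tr.points])
        t = np.asarray(tr.frames, dtype=float) * frame_interval
        tracks.append(Track(track_id=tid, t=t, xy=xy, condition_label=condition_label))
        tid += 1
    tracks.sort(key=lambda tr: (tr.t[0], tr.xy[0, 0], tr.xy[0, 1]))
    for i, tr in enumerate(tracks):
        tr.track_id = i
    return tracks
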