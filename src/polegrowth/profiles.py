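"""Axial intensity profiles and pole orientation.

The elementary measurement throughout this package is the *axial profile*:
intensity sampled at 1-pixel steps along a cell's medial axis, averaged over
a fixed odd width perpendicular to the axis — the automated equivalent of a
segmented-line measurement drawn from the new pole to the old pole.  Poles
are identified either from lineage geometry (the pole nearest the mother's
septum at birth is the new pole) or, for single-timepoint cohorts where no
lineage exists, by the brightest-pole convention used for demographs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize
from skimage.segmentation import clear_border

logger = logging.getLogger(__name__)

NEW_TO_OLD = "new_to_old"
BRIGHTEST_LEFT = "brightest_left"
UNKNOWN = "unknown"


class OrientationError(ValueError):
    """An operation required a resolved new->old orientation."""


class LineageError(ValueError):
    """Track geometry could not be reconciled with the recorded lineage."""


class ShapeError(ValueError):
    """An object's shape does not admit a medial-axis profile."""


@dataclass
class AxialProfile:
    """Intensity sampled along one cell's medial axis at one frame.

    ``samples[0]`` is the new-pole end when ``orientation == "new_to_old"``.
    ``end0_x`` / ``end1_x`` are the axis coordinates (um, in the lineage
    frame of reference) of the sample-0 and last-sample ends; they are what
    lineage-based orientation operates on and may be ``None`` for profiles
    extracted from images without tracking.
    """

    cell_id: int | str
    frame: int
    samples: np.ndarray
    pixel_size_um: float = 0.1
    orientation: str = UNKNOWN
    background_subtracted: bool = False
    end0_x: float | None = None
    end1_x: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a profile needs >= 2 ordered samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("profile intensities must be finite")

    @property
    def length_px(self) -> int:
        return int(self.samples.size)

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size_um

    def flipped(self, orientation: str | None = None) -> "AxialProfile":
        """Reverse the sample order (and swap the recorded end coordinates)."""
        return replace(
            self,
            samples=self.samples[::-1].copy(),
            end0_x=self.end1_x,
            end1_x=self.end0_x,
            orientation=self.orientation if orientation is None else orientation,
        )


@dataclass
class CellCycleTrack:
    """One cell's profiles from birth to the last frame before division."""

    cell_id: int | str
    profiles: list[AxialProfile]

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("a cell-cycle track needs >= 2 frames")
        orientations = {p.orientation for p in self.profiles}
        if len(orientations) != 1:
            raise ValueError("all profiles of a track must share an orientation")
        frames = [p.frame for p in self.profiles]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing and contiguous")

    @property
    def orientation(self) -> str:
        return self.profiles[0].orientation

    @property
    def n_frames(self) -> int:
        return len(self.profiles)

    def flipped(self, orientation: str | None = None) -> "CellCycleTrack":
        return CellCycleTrack(
            self.cell_id, [p.flipped(orientation) for p in self.profiles]
        )


# ---------------------------------------------------------------------------
# segmentation


def segment_frame(
    image: np.ndarray, method: str = "otsu", min_area: int = 20
) -> np.ndarray:
    """Global-threshold segmentation of a single-channel frame.

    Components touching the image border or smaller than ``min_area`` pixels
    are discarded. A constant image yields an empty (all-zero) mask.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got ndim={image.ndim}")
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    thr = threshold_otsu(image)
    fg = image > thr
    labels = cc_label(fg, connectivity=2)
    n_before = labels.max()
    labels = clear_border(labels)
    if labels.max() < n_before:
        logger.warning("discarded %d border-touching object(s)", n_before - labels.max())
    # area filter, then relabel compactly
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    out = np.zeros(image.shape, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return out


def estimate_background(image: np.ndarray, labels: np.ndarray) -> float:
    """Median intensity of non-object pixels (robust to sparse cells)."""
    outside = np.asarray(image)[np.asarray(labels) == 0]
    if outside.size == 0:
        return 0.0
    return float(np.median(outside))


# ---------------------------------------------------------------------------
# medial-axis profile extraction


def _skeleton_longest_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the morphological skeleton (pixel coords)."""
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:
        raise ShapeError("object too small: empty skeleton")
    pixset = {(int(r), int(c)) for r, c in coords}

    def neighbours(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pixset:
                    yield q

    def bfs(start):
        prev = {start: None}
        dist = {start: 0}
        dq = deque([start])
        far = start
        while dq:
            p = dq.popleft()
            if dist[p] > dist[far]:
                far = p
            for q in neighbours(p):
                if q not in prev:
                    prev[q] = p
                    dist[q] = dist[p] + 1
                    dq.append(q)
        return far, prev

    start = (int(coords[0, 0]), int(coords[0, 1]))
    u, prev = bfs(start)
    if len(prev) != len(pixset):
        raise ShapeError("skeleton is disconnected: no unique medial path")
    v, prev = bfs(u)
    path = []
    p = v
    while p is not None:
        path.append(p)
        p = prev[p]
    if len(path) < 2:
        raise ShapeError("degenerate skeleton: medial path shorter than 2 px")
    return np.asarray(path, dtype=float)


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both path tips tangentially, 1 px at a time, to the object edge."""

    def inside(p):
        r, c = int(round(p[0])), int(round(p[1]))
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])

    def extend(tip, inner):
        t = tip - inner
        n = np.linalg.norm(t)
        if n == 0:
            return []
        t = t / n
        out = []
        p = tip + t
        while inside(p):
            out.append(p.copy())
            p = p + t
        return out

    k = min(3, path.shape[0] - 1)
    head = extend(path[0], path[k])
    tail = extend(path[-1], path[-1 - k])
    pieces = [np.asarray(head[::-1]), path] if head else [path]
    if tail:
        pieces.append(np.asarray(tail))
    return np.vstack(pieces)


def _resample_1px(path: np.ndarray) -> np.ndarray:
    """Re-parameterise the path at 1-px arc-length steps."""
    d = np.sqrt(np.sum(np.diff(path, axis=0) ** 2, axis=1))
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    n = max(2, int(np.floor(total)) + 1)
    si = np.arange(n, dtype=float)
    r = np.interp(si, s, path[:, 0])
    c = np.interp(si, s, path[:, 1])
    return np.column_stack([r, c])


def extract_axial_profile(
    image: np.ndarray,
    mask: np.ndarray,
    width_px: int = 5,
    cell_id: int | str = 0,
    frame: int = 0,
    pixel_size_um: float = 0.1,
) -> AxialProfile:
    """Sample the image along one object's medial axis.

    The skeleton is pruned to its longest geodesic path, extended to the
    object boundary at both tips, and sampled at 1-px steps; at each step the
    intensity is averaged over ``width_px`` samples placed perpendicular to
    the local axis direction (samples falling outside the image or outside
    the object are excluded from the perpendicular average, so background
    pixels never dilute the profile). The returned profile has orientation
    ``unknown``: pole identity is assigned downstream.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError(f"width_px must be an odd integer >= 1, got {width_px}")
    if not mask.any():
        raise ValueError("mask is empty")
    path = _skeleton_longest_path(mask)
    path = _extend_to_boundary(path, mask)
    path = _resample_1px(path)

    # local tangents and unit normals
    tang = np.gradient(path, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang = tang / norms
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    # sample points: (n_steps, width, 2); pixels outside the object (or the
    # image) are NaN so they drop out of the perpendicular average
    masked = np.where(mask, image, np.nan)
    pts = path[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    vals = ndimage.map_coordinates(
        masked,
        [pts[..., 0].ravel(), pts[..., 1].ravel()],
        order=1,
        mode="constant",
        cval=np.nan,
    ).reshape(pts.shape[:2])
    support = np.isfinite(vals).sum(axis=1)
    with np.errstate(invalid="ignore"):
        profile = np.nansum(vals, axis=1)[support > 0] / support[support > 0]
    if profile.size < 2:
        raise ShapeError("medial axis too short after trimming to the object")
    return AxialProfile(
        cell_id=cell_id,
        frame=frame,
        samples=profile,
        pixel_size_um=pixel_size_um,
        orientation=UNKNOWN,
    )


# ---------------------------------------------------------------------------
# orientation


def orient_track_new_to_old(track: CellCycleTrack, lineage: Sequence) -> CellCycleTrack:
    """Resolve a track's pole identity from lineage geometry.

    The daughter pole formed at the mother's septum is the new pole; the
    track is flipped (consistently across all frames) so that sample index 0
    is that pole. Founder cells, whose pole history is unrecorded, keep
    orientation ``unknown``. Matching uses the axis coordinates of the
    track's ends at birth against the mother's recorded septum coordinate,
    with a tolerance of half the mother's division length — this resolves
    daughters even if their rows were swapped in the table, because the
    endpoints themselves carry the spatial continuity.
    """
    by_id = {rec.cell_id: rec for rec in lineage}
    rec = by_id.get(track.cell_id)
    if rec is None:
        raise LineageError(f"cell {track.cell_id!r} not present in lineage")
    if rec.mother_id is None or not rec.orientation_known:
        logger.info("cell %s is a founder: orientation stays unknown", track.cell_id)
        return CellCycleTrack(
            track.cell_id, [replace(p, orientation=UNKNOWN) for p in track.profiles]
        )
    mother = by_id.get(rec.mother_id)
    if mother is None or mother.septum_x is None:
        raise LineageError(
            f"mother {rec.mother_id!r} of cell {track.cell_id!r} has no recorded septum"
        )
    birth = track.profiles[0]
    if birth.end0_x is None or birth.end1_x is None:
        raise LineageError(
            f"track of cell {track.cell_id!r} carries no end coordinates; "
            "cannot orient from lineage"
        )
    d0 = abs(birth.end0_x - mother.septum_x)
    d1 = abs(birth.end1_x - mother.septum_x)
    tol = mother.division_cell_length_um / 2.0
    if min(d0, d1) > tol:
        raise LineageError(
            f"neither end of cell {track.cell_id!r} lies within {tol:.2f} um "
            f"of the mother's septum (d0={d0:.2f}, d1={d1:.2f})"
        )
    if d1 < d0:
        oriented = track.flipped(NEW_TO_OLD)
    else:
        oriented = CellCycleTrack(
            track.cell_id, [replace(p, orientation=NEW_TO_OLD) for p in track.profiles]
        )
    return oriented


def orient_by_brightest_pole(
    profile: AxialProfile, terminal_fraction: float = 0.1
) -> AxialProfile:
    """Flip a profile so its brighter terminal region sits at index 0.

    Compares the mean of the first versus last ``ceil(terminal_fraction * n)``
    samples; an exact tie keeps the original order.
    """
    if not 0.0 < terminal_fraction <= 0.5:
        raise ValueError("terminal_fraction must lie in (0, 0.5]")
    k = int(np.ceil(terminal_fraction * profile.length_px))
    head = float(np.mean(profile.samples[:k]))
    tail = float(np.mean(profile.samples[-k:]))
    if tail > head:
        return profile.flipped(BRIGHTEST_LEFT)
    return replace(profile, orientation=BRIGHTEST_LEFT)


def group_tracks(profiles: Iterable[AxialProfile]) -> list[CellCycleTrack]:
    """Group a flat list of per-frame profiles into per-cell tracks."""
    by_cell: dict = {}
    for p in profiles:
        by_cell.setdefault(p.cell_id, []).append(p)
    tracks = []
    for cid, plist in by_cell.items():
        plist.sort(key=lambda p: p.frame)
        tracks.append(CellCycleTrack(cid, plist))
    return tracks
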