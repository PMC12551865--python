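"""Thoracic-aorta geometry: truncation, landmark detection, centerline.

The thoracic aorta is delimited by the diaphragm, operationalised as the
lowest axial plane containing lung voxels.  Two landmarks bound the
centerline: the *endpoint* (centroid of the aorta cross-section on that
diaphragm plane) and the *startingpoint* (the ventral, i.e. anterior,
centroid on the lowest axial plane where the ascending and descending
aorta appear as two distinct cross-sections).

The centerline between the landmarks is a medialness-weighted shortest
path: Dijkstra over 26-connected in-mask voxels with edge cost
``step_length / (inscribed_radius + eps)``, where the inscribed radius is
the Euclidean distance transform of the mask.  The raw voxel path is then
smoothed with a moving average (window of about one lumen radius) and
resampled at a uniform arc-length step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra

from .volume import SegmentationMask

__all__ = [
    "AortaLandmarks",
    "Centerline",
    "AortaDimensions",
    "truncate_thoracic",
    "find_endpoint",
    "find_startingpoint",
    "detect_landmarks",
    "extract_centerline",
    "measure_dimensions",
]

# 26-neighbourhood offsets, one representative per (offset, -offset) pair.
_OFFSETS = np.array(
    [
        off
        for off in (
            np.array([a, b, c])
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
        )
        if tuple(off) > (0, 0, 0)
    ]
)


@dataclass
class AortaLandmarks:
    startingpoint_vox: tuple[int, int, int]
    endpoint_vox: tuple[int, int, int]
    truncation_plane_index: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "AortaLandmarks":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["startingpoint_vox"]),
            tuple(d["endpoint_vox"]),
            int(d["truncation_plane_index"]),
        )


@dataclass
class Centerline:
    """Ordered world-coordinate points with cumulative arc length (mm)."""

    points: np.ndarray
    arc_length_mm: np.ndarray
    step_mm: float

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "arc_length_mm": self.arc_length_mm,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Centerline":
        df = pd.read_csv(path)
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
        arc = df["arc_length_mm"].to_numpy()
        step = float(np.median(np.diff(arc))) if len(arc) > 1 else 0.0
        return cls(pts, arc, step)


@dataclass
class AortaDimensions:
    length_mm: float
    volume_ml: float
    mean_diameter_mm: float
    lung_volume_l: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)


def truncate_thoracic(
    aorta_mask: SegmentationMask, lung_mask: SegmentationMask
) -> tuple[SegmentationMask, int]:
    """Remove aorta planes inferior to the lowest lung-containing plane."""
    if aorta_mask.shape != lung_mask.shape:
        raise ValueError("aorta and lung masks are not aligned")
    lung_planes = np.flatnonzero(lung_mask.data.any(axis=(0, 1)))
    if lung_planes.size == 0:
        raise ValueError("lung mask is empty")
    k_trunc = int(lung_planes[0])
    out = aorta_mask.data.copy()
    out[:, :, :k_trunc] = False
    if not out.any():
        raise ValueError("no thoracic aorta above the truncation plane")
    return SegmentationMask(out, aorta_mask.affine), k_trunc


def _plane_spacing(mask: SegmentationMask) -> tuple[float, float]:
    sp = mask.spacing
    return sp[0], sp[1]


def _snap_to_mask(plane: np.ndarray, centroid: np.ndarray, spacing: tuple[float, float]):
    """Round a 2D centroid; if it lands outside the mask, take the nearest
    in-mask voxel (Euclidean distance in mm)."""
    ij = np.rint(centroid).astype(int)
    ij = np.clip(ij, 0, np.array(plane.shape) - 1)
    if plane[ij[0], ij[1]]:
        return int(ij[0]), int(ij[1])
    vox = np.argwhere(plane)
    d = ((vox - centroid) * np.array(spacing)) ** 2
    best = vox[np.argmin(d.sum(axis=1))]
    return int(best[0]), int(best[1])


def find_endpoint(
    thoracic_mask: SegmentationMask, truncation_plane_index: int
) -> tuple[int, int, int]:
    """Centroid of the aorta cross-section on the truncation plane."""
    plane = thoracic_mask.data[:, :, truncation_plane_index]
    if not plane.any():
        raise ValueError(
            f"truncation plane {truncation_plane_index} contains no aorta voxels"
        )
    centroid = np.argwhere(plane).mean(axis=0)
    i, j = _snap_to_mask(plane, centroid, _plane_spacing(thoracic_mask))
    return (i, j, int(truncation_plane_index))


def find_startingpoint(
    thoracic_mask: SegmentationMask, min_area_mm2: float = 25.0
) -> tuple[int, int, int]:
    """Ventral centroid on the lowest plane with two distinct cross-sections.

    Scanning axial planes from inferior to superior, the first plane on
    which the aorta splits into exactly two 8-connected components (each of
    at least ``min_area_mm2``, to suppress segmentation specks) marks the
    level of the aortic root; the more anterior component is the ascending
    aorta and its centroid the starting point.
    """
    dx, dy = _plane_spacing(thoracic_mask)
    pixel_area = dx * dy
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity in-plane
    excess_counts: list[int] = []
    for k in range(thoracic_mask.shape[2]):
        plane = thoracic_mask.data[:, :, k]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane, structure=structure)
        if n < 2:
            continue
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        big = [lab for lab, a in zip(range(1, n + 1), areas) if a * pixel_area >= min_area_mm2]
        if len(big) < 2:
            continue
        if len(big) > 2:
            excess_counts.append(len(big))
            continue
        # Ventral = larger anterior (A) world coordinate in the RAS frame.
        cents = [np.argwhere(labels == lab).mean(axis=0) for lab in big]
        worlds = [
            thoracic_mask.voxel_to_world(np.array([c[0], c[1], k]))[0, 1] for c in cents
        ]
        ventral = int(np.argmax(worlds))
        comp = labels == big[ventral]
        i, j = _snap_to_mask(comp, cents[ventral], (dx, dy))
        return (i, j, k)
    if excess_counts:
        raise ValueError(
            "no plane with exactly two aorta cross-sections; planes with "
            f"{sorted(set(excess_counts))} components were seen"
        )
    raise ValueError("arch not resolved: no plane with two aorta cross-sections")


def detect_landmarks(
    aorta_mask: SegmentationMask,
    lung_mask: SegmentationMask,
    min_area_mm2: float = 25.0,
) -> tuple[SegmentationMask, AortaLandmarks]:
    """Truncate to the thoracic aorta and locate both landmarks."""
    thoracic, k_trunc = truncate_thoracic(aorta_mask, lung_mask)
    endpoint = find_endpoint(thoracic, k_trunc)
    startingpoint = find_startingpoint(thoracic, min_area_mm2=min_area_mm2)
    return thoracic, AortaLandmarks(startingpoint, endpoint, k_trunc)


def _medial_path_voxels(
    mask: np.ndarray,
    spacing: np.ndarray,
    dt: np.ndarray,
    start: tuple[int, int, int],
    end: tuple[int, int, int],
    epsilon_mm: float,
) -> np.ndarray:
    """Dijkstra shortest path (voxel indices) weighted towards the medial axis."""
    flat = np.flatnonzero(mask.ravel())
    node_of = np.full(mask.size, -1, dtype=np.int64)
    node_of[flat] = np.arange(flat.size)
    coords = np.stack(np.unravel_index(flat, mask.shape), axis=1)

    rows, cols, weights = [], [], []
    dt_flat = dt.ravel()[flat]
    shape = np.array(mask.shape)
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, mask.shape)
        nb_node = node_of[nb_flat]
        valid = nb_node >= 0
        src = np.flatnonzero(ok)[valid]
        dst = nb_node[valid]
        step_len = float(np.linalg.norm(off * spacing))
        medial = 0.5 * (dt_flat[src] + dt_flat[dst]) + epsilon_mm
        rows.append(src)
        cols.append(dst)
        weights.append(step_len / medial)
    graph = csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(flat.size, flat.size),
    )
    s_node = node_of[np.ravel_multi_index(start, mask.shape)]
    e_node = node_of[np.ravel_multi_index(end, mask.shape)]
    if s_node < 0 or e_node < 0:
        raise ValueError("landmark lies outside the aorta mask")
    dist, pred = _sparse_dijkstra(
        graph, directed=False, indices=s_node, return_predecessors=True
    )
    if not np.isfinite(dist[e_node]):
        raise ValueError("disconnected aorta: landmarks are in different components")
    path = [e_node]
    while path[-1] != s_node:
        path.append(pred[path[-1]])
    return coords[np.array(path[::-1])]


def _resample_polyline(pts: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / step_mm)) + 1, 2)
    s_new = np.linspace(0.0, total, n)
    out = np.stack([np.interp(s_new, arc, pts[:, d]) for d in range(3)], axis=1)
    seg2 = np.linalg.norm(np.diff(out, axis=0), axis=1)
    return out, np.concatenate([[0.0], np.cumsum(seg2)])


def extract_centerline(
    thoracic_mask: SegmentationMask,
    landmarks: AortaLandmarks,
    step_mm: float = 1.0,
    smooth_window_mm: float | None = None,
    epsilon_mm: float = 0.5,
) -> Centerline:
    """Medialness-weighted shortest-path centerline between the landmarks."""
    spacing = np.asarray(thoracic_mask.spacing)
    dt = ndimage.distance_transform_edt(thoracic_mask.data, sampling=spacing)
    path_vox = _medial_path_voxels(
        thoracic_mask.data,
        spacing,
        dt,
        tuple(landmarks.startingpoint_vox),
        tuple(landmarks.endpoint_vox),
        epsilon_mm,
    )
    pts = thoracic_mask.voxel_to_world(path_vox)

    if smooth_window_mm is None:
        # about one lumen radius, from the medial inscribed radius
        smooth_window_mm = float(np.median(dt[tuple(path_vox.T)]))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    mean_step = float(seg.mean()) if seg.size else 1.0
    w = max(int(round(smooth_window_mm / mean_step)), 1)
    if w > 1 and len(pts) > 2:
        kernel = np.ones(w) / w
        padded = np.pad(pts, ((w, w), (0, 0)), mode="edge")
        sm = np.stack(
            [np.convolve(padded[:, d], kernel, mode="same")[w:-w] for d in range(3)],
            axis=1,
        )
        sm[0], sm[-1] = pts[0], pts[-1]  # keep the landmarks anchored
        pts = sm

    pts, arc = _resample_polyline(pts, step_mm)
    return Centerline(pts, arc, step_mm)


def measure_dimensions(
    thoracic_mask: SegmentationMask,
    lung_mask: SegmentationMask,
    centerline: Centerline,
) -> AortaDimensions:
    """Confounder measurements: aorta length/volume/diameter, lung volume.

    The mean diameter is twice the mean inscribed radius (mask distance
    transform) sampled along the centerline.  Near the axial cuts at the
    aortic root and the diaphragm the distance transform measures the
    distance to the cut rather than to the vessel wall, so one median
    radius is trimmed from each end of the centerline before averaging.
    """
    spacing = np.asarray(thoracic_mask.spacing)
    dt = ndimage.distance_transform_edt(thoracic_mask.data, sampling=spacing)
    vox = centerline.points @ np.linalg.inv(thoracic_mask.affine)[:3, :3].T + np.linalg.inv(
        thoracic_mask.affine
    )[:3, 3]
    radii = ndimage.map_coordinates(dt, vox.T, order=1)
    arc = centerline.arc_length_mm
    trim = float(np.median(radii))
    interior = (arc >= trim) & (arc <= arc[-1] - trim)
    if interior.sum() >= 3:
        radii = radii[interior]
    mean_radius = float(radii.mean())
    voxvol = thoracic_mask.voxel_volume_mm3()
    return AortaDimensions(
        length_mm=centerline.length_mm,
        volume_ml=thoracic_mask.count() * voxvol / 1000.0,
        mean_diameter_mm=2.0 * mean_radius,
        lung_volume_l=lung_mask.count() * voxvol / 1.0e6,
    )
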