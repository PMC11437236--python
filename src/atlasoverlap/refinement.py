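"""Marker-based in-plane nonlinear refinement of plate geometry.

Interactive section-alignment tools let an operator nudge an anchored
section with a sparse set of landmark moves; this module reproduces that
step as a deterministic, documented deformation model so refined plates are
exactly reproducible from their marker files.

Model: a piecewise-affine map built on the Delaunay triangulation of the
marker *source* points augmented with the four plate corners, which are
pinned to themselves.  Inside each triangle the map is the affine
interpolant of the vertex displacements, so the warp is continuous
everywhere, exact at every marker, and the identity when the marker set is
empty.  The corner pinning keeps the plate boundary fixed.

Markers describe where a plate pixel's *sampling position* moves: pixel
``p`` of the refined plate is sampled at plate position ``warp(p)`` (forward
warp applied in sampling space), so label images are never resampled or
interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .anchoring import AnchoringSpec, GeometryError, plate_to_voxel, sample_labels
from .atlas_model import LabelVolume

__all__ = [
    "MarkerSet",
    "PlateWarp",
    "warp_point",
    "extract_refined_plate",
    "read_markers",
    "write_markers",
]


@dataclass
class MarkerSet:
    """Landmark moves on one plate: pairs of (source, target) pixel positions.

    Source points must be pairwise distinct.  ``margin_frac`` bounds how far
    (as a fraction of the plate diagonal) points may sit outside the plate.
    """

    pairs: list[tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=list)
    margin_frac: float = 0.5

    def __post_init__(self) -> None:
        src = [tuple(map(float, s)) for s, _ in self.pairs]
        if len(set(src)) != len(src):
            raise ValueError("marker source points must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty((0, 2)), np.empty((0, 2))
        src = np.array([s for s, _ in self.pairs], dtype=float)
        dst = np.array([d for _, d in self.pairs], dtype=float)
        return src, dst

    def check_bounds(self, plate_dims: tuple[int, int]) -> None:
        w, h = plate_dims
        margin = self.margin_frac * float(np.hypot(w, h))
        src, dst = self.arrays()
        for pts in (src, dst):
            if len(pts) and (
                np.any(pts[:, 0] < -margin) or np.any(pts[:, 0] > w + margin)
                or np.any(pts[:, 1] < -margin) or np.any(pts[:, 1] > h + margin)
            ):
                raise ValueError("marker outside plate bounds plus margin")


class PlateWarp:
    """Piecewise-affine plate warp; build once, evaluate on many points.

    :meth:`inverse` returns the exact inverse map, built on the *image* of
    the forward triangulation (same connectivity), so warp-then-unwarp is
    the identity to numerical precision wherever the forward map does not
    fold triangles over each other.
    """

    def __init__(self, markers: MarkerSet, plate_dims: tuple[int, int]):
        self.plate_dims = plate_dims
        self.identity = len(markers) == 0
        if self.identity:
            return
        markers.check_bounds(plate_dims)
        w, h = plate_dims
        corners = np.array([(0.0, 0.0), (w, 0.0), (0.0, h), (w, h)])
        src, dst = markers.arrays()
        for c in corners:
            if np.any(np.all(src == c, axis=1)):
                raise ValueError("marker source coincides with a pinned plate corner")
        self._src = np.vstack([src, corners])
        self._dst = np.vstack([dst, corners])  # corners map to themselves
        try:
            self._tri = Delaunay(self._src)
        except QhullError as exc:  # pragma: no cover - needs near-degenerate input
            raise GeometryError(f"degenerate marker triangulation: {exc}") from exc
        self._simplices = self._tri.simplices

    def _locate_bruteforce(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Point location by testing every triangle (used by inverse warps,
        whose domain triangulation is not Delaunay)."""
        a = self._src[self._simplices[:, 0]]
        b = self._src[self._simplices[:, 1]]
        c = self._src[self._simplices[:, 2]]
        det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
        det = np.where(det == 0, np.finfo(float).eps, det)
        d = flat[:, None, :] - a[None, :, :]
        l1 = (d[..., 0] * (c[:, 1] - a[:, 1]) - d[..., 1] * (c[:, 0] - a[:, 0])) / det
        l2 = (d[..., 1] * (b[:, 0] - a[:, 0]) - d[..., 0] * (b[:, 1] - a[:, 1])) / det
        l0 = 1.0 - l1 - l2
        worst = np.minimum(np.minimum(l0, l1), l2)
        simplex = np.argmax(worst, axis=1)
        rows = np.arange(len(flat))
        bary = np.stack([l0[rows, simplex], l1[rows, simplex], l2[rows, simplex]], axis=1)
        return simplex, bary

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Warp an (..., 2) array of plate coordinates."""
        points = np.asarray(points, dtype=float)
        if self.identity:
            return points.copy()
        flat = points.reshape(-1, 2)
        if self._tri is None:
            simplex, bary = self._locate_bruteforce(flat)
        else:
            simplex = self._tri.find_simplex(flat)
            miss = simplex < 0
            if np.any(miss):
                # numerical edge of the hull: nudge towards the plate centre
                w, h = self.plate_dims
                centre = np.array([w / 2.0, h / 2.0])
                nudged = flat[miss] + 1e-9 * (centre - flat[miss])
                simplex[miss] = self._tri.find_simplex(nudged)
                if np.any(simplex < 0):
                    raise GeometryError("point outside the triangulated plate hull")
            # barycentric coordinates from the stored affine transforms
            trans = self._tri.transform[simplex]
            bary2 = np.einsum("nij,nj->ni", trans[:, :2, :], flat - trans[:, 2, :])
            bary = np.hstack([bary2, 1.0 - bary2.sum(axis=1, keepdims=True)])
        verts = self._simplices[simplex]
        out = np.einsum("nk,nkd->nd", bary, self._dst[verts])
        return out.reshape(points.shape)

    def inverse(self) -> "PlateWarp":
        """Exact inverse warp sharing the forward map's triangulation."""
        inv = object.__new__(PlateWarp)
        inv.plate_dims = self.plate_dims
        inv.identity = self.identity
        if not self.identity:
            inv._src = self._dst
            inv._dst = self._src
            inv._simplices = self._simplices
            inv._tri = None
        return inv


def warp_point(markers: MarkerSet, plate_dims: tuple[int, int], p) -> np.ndarray:
    """Warp a single plate position ``p = (x, y)``; identity for empty markers."""
    return PlateWarp(markers, plate_dims)(np.asarray(p, dtype=float))


def extract_refined_plate(
    volume: LabelVolume, spec: AnchoringSpec, markers: MarkerSet
) -> np.ndarray:
    """Custom-cut label image with marker refinement applied before sampling.

    Pixel ``(i, j)`` is sampled (nearest voxel, never interpolated) at the
    volume coordinate of the warped pixel centre; with empty markers this is
    exactly :func:`atlasoverlap.anchoring.extract_plate`.
    """
    warp = PlateWarp(markers, (spec.width, spec.height))
    ii, jj = np.meshgrid(np.arange(spec.width), np.arange(spec.height), indexing="ij")
    centres = np.stack([ii + 0.5, jj + 0.5], axis=-1)
    warped = warp(centres)
    coords = plate_to_voxel(spec, warped[..., 0], warped[..., 1])
    return sample_labels(volume, coords)


def read_markers(path: str | Path) -> dict[str, MarkerSet]:
    """Read per-plate markers from JSON: {plate_id: [[sx, sy, tx, ty], ...]}."""
    doc = json.loads(Path(path).read_text())
    out: dict[str, MarkerSet] = {}
    for plate_id, rows in doc.items():
        pairs = [((float(sx), float(sy)), (float(tx), float(ty))) for sx, sy, tx, ty in rows]
        out[plate_id] = MarkerSet(pairs)
    return out


def write_markers(markers: dict[str, MarkerSet], path: str | Path) -> None:
    """Write per-plate markers as the flat [sx, sy, tx, ty] JSON dialect."""
    doc = {
        plate_id: [[s[0], s[1], d[0], d[1]] for s, d in ms.pairs]
        for plate_id, ms in markers.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1))
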