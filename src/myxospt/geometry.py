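"""Spherocylinder (capped-rod) cell outlines.

The 2-D projection of a rod-shaped bacterium is modelled as a rectangle of
length ``length - width`` capped by two semicircles of radius ``width / 2``:
the set of points within ``width / 2`` of the central axis segment.  All
coordinates are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidGeometryError(ValueError):
    """Raised for non-positive or inverted cell dimensions."""


@dataclass(frozen=True)
class CellGeometry:
    """A rod cell as a 2-D spherocylinder.

    Parameters
    ----------
    center : (2,) array-like
        Cell centroid in µm.
    axis_angle : float
        Orientation of the long axis in radians (0 = x axis).
    length_um : float
        Pole-to-pole length (including the caps).
    width_um : float
        Cell width, i.e. the diameter of the caps.
    id : int
        Integer label, also used in mask images (0 is background).
    """

    center: np.ndarray
    axis_angle: float
    length_um: float
    width_um: float
    id: int = 0
    _u: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.length_um > self.width_um > 0):
            raise InvalidGeometryError(
                f"need length > width > 0, got length={self.length_um}, "
                f"width={self.width_um}"
            )
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        u = np.array([np.cos(self.axis_angle), np.sin(self.axis_angle)])
        object.__setattr__(self, "_u", u)

    @property
    def radius_um(self) -> float:
        return self.width_um / 2.0

    @property
    def half_axis_um(self) -> float:
        """Half-length of the central axis segment (pole centres at ±this)."""
        return (self.length_um - self.width_um) / 2.0

    def to_axis_frame(self, points_um: np.ndarray) -> np.ndarray:
        """Map absolute points to (u, v): along-axis / across-axis µm."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float)) - self.center
        u = p @ self._u
        v = p @ np.array([-self._u[1], self._u[0]])
        return np.stack([u, v], axis=-1)

    def from_axis_frame(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        n = np.array([-self._u[1], self._u[0]])
        return self.center + uv[:, :1] * self._u + uv[:, 1:] * n

    def axis_distance(self, points_um: np.ndarray) -> np.ndarray:
        """Distance from each point to the central axis segment."""
        uv = self.to_axis_frame(points_um)
        du = np.maximum(np.abs(uv[:, 0]) - self.half_axis_um, 0.0)
        return np.hypot(du, uv[:, 1])

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        """Exact membership test for the spherocylinder outline."""
        return self.axis_distance(points_um) <= self.radius_um

    def reflect_inside(self, points_um: np.ndarray, max_iter: int = 32) -> np.ndarray:
        """Mirror points that fall outside the outline back across the wall.

        Each outside point is reflected about its nearest boundary point
        (radially with respect to the central axis segment); repeated until
        inside.  Used for reflective Brownian dynamics.
        """
        p = np.atleast_2d(np.asarray(points_um, dtype=float)).copy()
        for _ in range(max_iter):
            d = self.axis_distance(p)
            out = d > self.radius_um
            if not out.any():
                break
            uv = self.to_axis_frame(p[out])
            # nearest point on the axis segment, in axis coords
            qu = np.clip(uv[:, 0], -self.half_axis_um, self.half_axis_um)
            rel = uv - np.stack([qu, np.zeros_like(qu)], axis=-1)
            dd = np.linalg.norm(rel, axis=1)
            scale = (2.0 * self.radius_um - dd) / dd
            uv_new = np.stack([qu, np.zeros_like(qu)], axis=-1) + rel * scale[:, None]
            p[out] = self.from_axis_frame(uv_new)
        return p

    def sample_inside(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the outline (rejection from bounding box)."""
        out = np.empty((0, 2))
        half = self.length_um / 2.0
        while len(out) < n:
            uv = rng.uniform(
                [-half, -self.radius_um], [half, self.radius_um], size=(2 * n, 2)
            )
            pts = self.from_axis_frame(uv)
            pts = pts[self.contains(pts)]
            out = np.vstack([out, pts])
        return out[:n]

    def rasterize(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Paint the cell id into a label image (pixel centres at (i+0.5))."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.stack([(xx.ravel() + 0.5), (yy.ravel() + 0.5)], axis=-1) * pixel_size_um
        return self.contains(pts).reshape(h, w)


def make_cell(
    length_um: float,
    width_um: float,
    axis_angle: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    id: int = 0,
) -> CellGeometry:
    """Construct a :class:`CellGeometry`, validating the dimensions."""
    return CellGeometry(
        center=np.asarray(center, dtype=float),
        axis_angle=float(axis_angle),
        length_um=float(length_um),
        width_um=float(width_um),
        id=int(id),
    )
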