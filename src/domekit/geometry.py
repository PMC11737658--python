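"""Dome projection geometry.

Coordinate conventions
----------------------
The dome is a spherical screen of fixed radius centered on the subject's
head.  Directions are expressed in *dome coordinates*: azimuth (degrees,
positive rightward) and elevation (degrees, positive up), with (0, 0) at
the front-center of the dome -- the direction a centered subject looks at.
For such a subject, dome coordinates equal visual angles.

Cartesian axes follow the engine convention used throughout the package:

* +X forward (toward dome center front)
* +Y rightward
* +Z up

The fisheye image is a unit square [0, 1]^2 whose center (0.5, 0.5) is the
forward direction; the radial image distance grows linearly with the polar
angle from forward (equidistant fisheye law), reaching 0.5 at ``theta_max``
(125 deg for a 250 deg dome).  The fisheye u axis points rightward (+Y) and
the v axis upward (+Z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DOME_RADIUS_CM",
    "DOME_COVERAGE_DEG",
    "THETA_MAX_DEG",
    "DomeDirection",
    "FisheyePoint",
    "WarpMesh",
    "dome_to_cartesian",
    "cartesian_to_dome",
    "polar_angle",
    "direction_to_fisheye",
    "fisheye_uv",
    "RIG_FACES",
    "rig_face_for_direction",
    "project_to_face",
    "face_pixel_to_direction",
    "rig_compose_fisheye",
    "load_warp_mesh",
    "save_warp_mesh",
    "identity_warp_mesh",
    "apply_warp_mesh",
]

#: Radius of the physical dome screen, centimetres.
DOME_RADIUS_CM = 60.0
#: Angular extent of the dome (full cone angle), degrees.
DOME_COVERAGE_DEG = 250.0
#: Maximum polar angle from the forward direction that lies on the dome.
THETA_MAX_DEG = DOME_COVERAGE_DEG / 2.0


@dataclass(frozen=True)
class DomeDirection:
    """A direction (and distance) in dome angular coordinates."""

    azimuth: float
    elevation: float
    radius: float = DOME_RADIUS_CM

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class FisheyePoint:
    """Normalized fisheye image coordinates with on-image flag."""

    u: float
    v: float
    inside: bool


def dome_to_cartesian(d: DomeDirection) -> np.ndarray:
    """Convert dome angular coordinates to engine Cartesian coordinates.

    Returns ``[x, y, z]`` with x forward, y rightward, z up, in the same
    length unit as ``d.radius``.
    """
    az = math.radians(d.azimuth)
    el = math.radians(d.elevation)
    return np.array(
        [
            d.radius * math.cos(el) * math.cos(az),
            d.radius * math.cos(el) * math.sin(az),
            d.radius * math.sin(el),
        ]
    )


def cartesian_to_dome(p) -> DomeDirection:
    """Inverse of :func:`dome_to_cartesian`.

    Azimuth is returned in (-180, 180], elevation in [-90, 90].  The zero
    vector has no direction and raises ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    r = float(np.linalg.norm(p))
    if r == 0.0:
        raise ValueError("cannot convert the zero vector to a dome direction")
    el = math.degrees(math.asin(np.clip(p[2] / r, -1.0, 1.0)))
    az = math.degrees(math.atan2(p[1], p[0]))
    if az <= -180.0:  # atan2 returns (-180, 180]; normalize -180 to +180
        az += 360.0
    return DomeDirection(azimuth=az, elevation=el, radius=r)


def polar_angle(direction) -> float:
    """Polar angle (degrees) of a direction from the forward (+X) axis."""
    v = np.asarray(direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero vector has no polar angle")
    return math.degrees(math.acos(np.clip(v[0] / n, -1.0, 1.0)))


def fisheye_uv(directions, theta_max: float = THETA_MAX_DEG):
    """Vectorized equidistant fisheye mapping.

    Parameters
    ----------
    directions : array-like, shape (..., 3)
        Direction vectors (any nonzero length; normalized internally).
    theta_max : float
        Polar angle mapped to the image-circle rim (radius 0.5).

    Returns
    -------
    u, v, inside : ndarrays broadcast over the leading axes.
    """
    d = np.asarray(directions, dtype=float)
    n = np.linalg.norm(d, axis=-1)
    if np.any(n == 0):
        raise ValueError("zero vector in directions")
    x, y, z = d[..., 0] / n, d[..., 1] / n, d[..., 2] / n
    theta = np.degrees(np.arccos(np.clip(x, -1.0, 1.0)))
    rho = np.hypot(y, z)
    # Image azimuth: undefined on-axis, where the radius is zero anyway.
    with np.errstate(invalid="ignore", divide="ignore"):
        cy = np.where(rho > 0, y / rho, 0.0)
        cz = np.where(rho > 0, z / rho, 0.0)
    rad = 0.5 * theta / theta_max
    u = 0.5 + rad * cy
    v = 0.5 + rad * cz
    inside = theta <= theta_max + 1e-9  # rim-inclusive under float round-off
    return u, v, inside


def direction_to_fisheye(direction, theta_max: float = THETA_MAX_DEG) -> FisheyePoint:
    """Map a single direction to fisheye image coordinates."""
    u, v, inside = fisheye_uv(np.asarray(direction, dtype=float), theta_max)
    return FisheyePoint(float(u), float(v), bool(inside))


# --------------------------------------------------------------------------
# Five-camera rig: square 90 deg frusta facing front / left / right / up /
# down.  Together they cover every direction within 125 deg of forward (the
# dome), leaving only a rear gap.

RIG_FACES: dict[str, dict[str, np.ndarray]] = {
    "front": {"forward": np.array([1.0, 0.0, 0.0]), "right": np.array([0.0, 1.0, 0.0]), "up": np.array([0.0, 0.0, 1.0])},
    "right": {"forward": np.array([0.0, 1.0, 0.0]), "right": np.array([-1.0, 0.0, 0.0]), "up": np.array([0.0, 0.0, 1.0])},
    "left": {"forward": np.array([0.0, -1.0, 0.0]), "right": np.array([1.0, 0.0, 0.0]), "up": np.array([0.0, 0.0, 1.0])},
    "up": {"forward": np.array([0.0, 0.0, 1.0]), "right": np.array([0.0, 1.0, 0.0]), "up": np.array([-1.0, 0.0, 0.0])},
    "down": {"forward": np.array([0.0, 0.0, -1.0]), "right": np.array([0.0, 1.0, 0.0]), "up": np.array([1.0, 0.0, 0.0])},
}

_FACE_ORDER = ("front", "right", "left", "up", "down")


def project_to_face(direction, face: str):
    """Project a direction onto a rig face's image plane.

    Returns ``(a, b)`` in [-1, 1]^2 (the face's normalized pixel
    coordinates) or ``None`` when the direction lies outside the face's
    90 deg frustum.
    """
    axes = RIG_FACES[face]
    d = np.asarray(direction, dtype=float)
    f = float(d @ axes["forward"])
    if f <= 0.0:
        return None
    a = float(d @ axes["right"]) / f
    b = float(d @ axes["up"]) / f
    eps = 1e-12
    if abs(a) > 1.0 + eps or abs(b) > 1.0 + eps:
        return None
    return a, b


def face_pixel_to_direction(face: str, a: float, b: float) -> np.ndarray:
    """Unit direction seen by face pixel ``(a, b)`` in [-1, 1]^2."""
    axes = RIG_FACES[face]
    v = axes["forward"] + a * axes["right"] + b * axes["up"]
    return v / np.linalg.norm(v)


def rig_face_for_direction(direction) -> str:
    """Name of the rig face covering ``direction`` (ties broken by a fixed
    face order), or raise if the direction falls in the rear gap."""
    best = None
    best_f = -np.inf
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    for face in _FACE_ORDER:
        if project_to_face(d, face) is not None:
            f = float(d @ RIG_FACES[face]["forward"])
            if f > best_f:
                best, best_f = face, f
    if best is None:
        raise ValueError(
            "direction {} is outside all five rig faces (rear gap behind the "
            "250 deg dome coverage)".format(np.round(d, 4).tolist())
        )
    return best


def rig_compose_fisheye(direction, theta_max: float = THETA_MAX_DEG, face: str | None = None) -> FisheyePoint:
    """Fisheye coordinates of a direction via the five-camera rig.

    The direction is projected onto the covering face's image plane and the
    face pixel is carried through that face's warp onto the fisheye image,
    reproducing the capture-then-warp assembly of the dome pipeline.  The
    result agrees with :func:`direction_to_fisheye` over the full coverage.

    ``face`` forces a particular face (used to check seam consistency).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if face is None:
        face = rig_face_for_direction(d)
    pix = project_to_face(d, face)
    if pix is None:
        raise ValueError(f"direction {np.round(d, 4).tolist()} is outside face {face!r}")
    a, b = pix
    recon = face_pixel_to_direction(face, a, b)
    u, v, inside = fisheye_uv(recon, theta_max)
    return FisheyePoint(float(u), float(v), bool(inside))


# --------------------------------------------------------------------------
# Warp meshes


@dataclass
class WarpMesh:
    """Regular grid mapping screen positions to source texture coordinates.

    All node arrays have shape ``(ny, nx)``.  Screen positions ``x``/``y``
    and texture coordinates ``u``/``v`` are normalized to [0, 1]; nodes with
    texture coordinates outside [0, 1]^2 are invalid and render transparent
    (black).  ``intensity`` is a per-node brightness weight in [0, 1].
    ``projection`` is the projection-type tag carried by warp files
    (2 = fisheye source).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    intensity: np.ndarray
    projection: int = 2

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x, self.y, self.u, self.v, self.intensity)}
        if len(shapes) != 1:
            raise ValueError("warp mesh node arrays must share one shape")
        ny, nx = self.x.shape
        if nx < 2 or ny < 2:
            raise ValueError("warp mesh needs at least a 2x2 node grid")

    @property
    def nx(self) -> int:
        return self.x.shape[1]

    @property
    def ny(self) -> int:
        return self.x.shape[0]

    def valid_nodes(self) -> np.ndarray:
        """Boolean mask of nodes whose texture coordinates are usable."""
        return (
            (self.u >= 0.0) & (self.u <= 1.0) & (self.v >= 0.0) & (self.v <= 1.0)
        )


def identity_warp_mesh(nx: int = 2, ny: int = 2) -> WarpMesh:
    """Mesh that maps the screen straight onto the source image."""
    gx, gy = np.meshgrid(np.linspace(0.0, 1.0, nx), np.linspace(0.0, 1.0, ny))
    return WarpMesh(x=gx, y=gy, u=gx.copy(), v=gy.copy(), intensity=np.ones_like(gx))


def save_warp_mesh(mesh: WarpMesh, path) -> None:
    """Write a mesh as plain text.

    Line 1: projection-type integer.  Line 2: ``nx ny``.  Then ``nx*ny``
    node lines ``x y u v intensity``, row-major (y outer, x inner).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{mesh.projection}\n")
        fh.write(f"{mesh.nx} {mesh.ny}\n")
        for j in range(mesh.ny):
            for i in range(mesh.nx):
                fh.write(
                    "{:.7f} {:.7f} {:.7f} {:.7f} {:.7f}\n".format(
                        mesh.x[j, i], mesh.y[j, i], mesh.u[j, i], mesh.v[j, i], mesh.intensity[j, i]
                    )
                )


def load_warp_mesh(path) -> WarpMesh:
    """Read a warp mesh written by :func:`save_warp_mesh` (or compatible)."""
    with open(path, "r", encoding="utf-8") as fh:
        tokens = fh.read().split()
    if len(tokens) < 3:
        raise ValueError(f"warp mesh file {path!r} is truncated")
    projection = int(tokens[0])
    nx, ny = int(tokens[1]), int(tokens[2])
    vals = np.array(tokens[3:], dtype=float)
    if vals.size != nx * ny * 5:
        raise ValueError(
            f"warp mesh file {path!r}: expected {nx * ny} nodes of 5 values, got {vals.size} values"
        )
    nodes = vals.reshape(ny, nx, 5)
    return WarpMesh(
        x=nodes[..., 0],
        y=nodes[..., 1],
        u=nodes[..., 2],
        v=nodes[..., 3],
        intensity=nodes[..., 4],
        projection=projection,
    )


def _bilinear_grid_interp(axis_vals: np.ndarray, query: np.ndarray):
    """Indices and weights for 1-D linear interpolation on a sorted axis."""
    idx = np.searchsorted(axis_vals, query, side="right") - 1
    idx = np.clip(idx, 0, axis_vals.size - 2)
    span = axis_vals[idx + 1] - axis_vals[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(span > 0, (query - axis_vals[idx]) / span, 0.0)
    return idx, np.clip(w, 0.0, 1.0)


def _sample_image_bilinear(image: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sample image at normalized (u, v); u -> column, v -> row."""
    h, w = image.shape[:2]
    col = np.clip(u, 0.0, 1.0) * (w - 1)
    row = np.clip(v, 0.0, 1.0) * (h - 1)
    c0 = np.clip(np.floor(col).astype(int), 0, w - 2) if w > 1 else np.zeros_like(col, dtype=int)
    r0 = np.clip(np.floor(row).astype(int), 0, h - 2) if h > 1 else np.zeros_like(row, dtype=int)
    fc = col - c0
    fr = row - r0
    if image.ndim == 3:
        fc = fc[..., None]
        fr = fr[..., None]
    p00 = image[r0, c0]
    p01 = image[r0, np.minimum(c0 + 1, w - 1)]
    p10 = image[np.minimum(r0 + 1, h - 1), c0]
    p11 = image[np.minimum(r0 + 1, h - 1), np.minimum(c0 + 1, w - 1)]
    top = p00 * (1 - fc) + p01 * fc
    bot = p10 * (1 - fc) + p11 * fc
    return top * (1 - fr) + bot * fr


def apply_warp_mesh(image: np.ndarray, mesh: WarpMesh, out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Warp an image through a mesh.

    Every output pixel's texture coordinate and intensity weight are
    bilinearly interpolated from the surrounding mesh nodes (the node grid
    must be a tensor-product grid in screen space, the layout warp files
    use); the source image is then sampled bilinearly at that coordinate.
    Cells touching an invalid node (texture coordinate outside [0, 1]^2)
    come out black.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = (image.shape[0], image.shape[1]) if out_shape is None else out_shape
    xs = mesh.x[0, :]
    ys = mesh.y[:, 0]
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
        raise ValueError("warp mesh screen positions must form an increasing grid")
    px = np.linspace(xs[0], xs[-1], w)
    py = np.linspace(ys[0], ys[-1], h)
    ix, wx = _bilinear_grid_interp(xs, px)
    iy, wy = _bilinear_grid_interp(ys, py)
    IX, IY = np.meshgrid(ix, iy)
    WX, WY = np.meshgrid(wx, wy)

    def interp(field: np.ndarray) -> np.ndarray:
        f00 = field[IY, IX]
        f01 = field[IY, IX + 1]
        f10 = field[IY + 1, IX]
        f11 = field[IY + 1, IX + 1]
        return (
            f00 * (1 - WX) * (1 - WY)
            + f01 * WX * (1 - WY)
            + f10 * (1 - WX) * WY
            + f11 * WX * WY
        )

    u = interp(mesh.u)
    v = interp(mesh.v)
    inten = interp(mesh.intensity)
    valid = mesh.valid_nodes()
    cell_ok = valid[IY, IX] & valid[IY, IX + 1] & valid[IY + 1, IX] & valid[IY + 1, IX + 1]
    out = _sample_image_bilinear(image, u, v)
    if image.ndim == 3:
        out = out * inten[..., None]
        out[~cell_ok] = 0.0
    else:
        out = out * inten
        out[~cell_ok] = 0.0
    return out
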