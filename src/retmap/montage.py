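"""Montaging and cross-modality alignment into one µm-scale retinal map.

Registered AOSLO averages are placed on a common canvas from their
fixation coordinates (degrees, converted to µm through the RMF) and
refined by pairwise NCC of overlapping neighbors.  En-face FIR, FAF and
OCT images are brought into the same frame with landmark-based
similarity (default) or affine transforms fitted by least squares in
µm space, so the fit only absorbs residual rotation/translation/small
scale after the RMF has removed the gross magnification differences.

Coordinate conventions (serialized with every transform):

* pixel coordinates are 0-based, pixel-center, x right / y down;
* the common frame is in µm; once the anatomical foveal center has been
  marked on the OCT layer and projected everywhere, eccentricities are
  measured from it;
* meridian labels are laterality-aware: with image x increasing to the
  right, +x is temporal retina for a left eye (OS) and nasal retina for
  a right eye (OD); -y (up) is superior for both.  Importers may flip
  images horizontally (``flip_x``) to put every eye in the same
  anatomical orientation, in which case +x is temporal throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .register import _ncc_surface, _parabolic_peak
from .scale import ModalityScale

__all__ = [
    "Transform2D",
    "LandmarkPair",
    "RetinalMap",
    "MapLayer",
    "estimate_transform",
    "montage_place",
    "set_foveal_center",
    "eccentricity_of",
]


@dataclass
class Transform2D:
    """2x3 affine mapping source px -> target coordinates."""

    matrix: np.ndarray
    kind: str = "affine"  # {"similarity", "affine"}
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        a = self.matrix[:, :2]
        if abs(np.linalg.det(a)) < 1e-12:
            raise ValueError("linear part is singular")
        if self.kind == "similarity":
            # isotropic scale, no shear: A = s R (up to reflection)
            g = a.T @ a
            if not (
                math.isclose(g[0, 0], g[1, 1], rel_tol=0, abs_tol=1e-9 * g[0, 0])
                and abs(g[0, 1]) <= 1e-9 * g[0, 0]
            ):
                raise ValueError("similarity transform has shear/anisotropy")

    @classmethod
    def identity(cls, kind: str = "similarity") -> "Transform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), kind=kind)

    @classmethod
    def from_scale_offset(
        cls, sx: float, sy: float, tx: float, ty: float
    ) -> "Transform2D":
        kind = "similarity" if math.isclose(sx, sy, rel_tol=1e-12) else "affine"
        return cls(np.array([[sx, 0.0, tx], [0.0, sy, ty]]), kind=kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "Transform2D":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        ai = np.linalg.inv(a)
        return Transform2D(
            np.hstack([ai, (-ai @ t)[:, None]]), kind=self.kind,
            residual_rms=self.residual_rms,
        )

    def compose(self, other: "Transform2D") -> "Transform2D":
        """self o other: apply ``other`` first, then ``self``."""
        a1, t1 = self.matrix[:, :2], self.matrix[:, 2]
        a2, t2 = other.matrix[:, :2], other.matrix[:, 2]
        kind = "similarity" if self.kind == other.kind == "similarity" else "affine"
        return Transform2D(
            np.hstack([(a1 @ a2), (a1 @ t2 + t1)[:, None]]), kind=kind
        )


@dataclass(frozen=True)
class LandmarkPair:
    """Matched point in two modalities (e.g., a vessel bifurcation)."""

    point_a: tuple[float, float]
    point_b: tuple[float, float]
    label: str = ""


def estimate_transform(
    pairs: list[LandmarkPair], kind: str = "similarity"
) -> Transform2D:
    """Least-squares transform mapping point_a -> point_b.

    Requires >= 2 distinct pairs for a similarity, >= 3 non-collinear
    for an affine fit.  Points are expected in a common metric (µm)
    space so the fit absorbs only residual rotation/translation/scale.
    """
    src = np.array([p.point_a for p in pairs], dtype=float)
    dst = np.array([p.point_b for p in pairs], dtype=float)
    n = len(pairs)
    if kind == "similarity":
        if n < 2:
            raise ValueError("similarity fit needs >= 2 landmark pairs")
        if np.allclose(src.std(axis=0), 0) or np.allclose(dst.std(axis=0), 0):
            raise ValueError("degenerate landmarks: coincident points")
        # Umeyama closed form (similarity without reflection)
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        sc, dc = src - mu_s, dst - mu_d
        cov = dc.T @ sc / n
        u, s, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u @ vt))
        dsign = np.diag([1.0, d])
        r = u @ dsign @ vt
        var_s = (sc**2).sum() / n
        scale_f = float(np.trace(np.diag(s) @ dsign) / var_s)
        a = scale_f * r
        t = mu_d - a @ mu_s
    elif kind == "affine":
        if n < 3:
            raise ValueError("affine fit needs >= 3 landmark pairs")
        g = np.hstack([src, np.ones((n, 1))])
        if np.linalg.matrix_rank(g) < 3:
            raise ValueError("degenerate landmarks: collinear or coincident")
        sol, *_ = np.linalg.lstsq(g, dst, rcond=None)
        a = sol[:2].T
        t = sol[2]
    else:
        raise ValueError("kind must be 'similarity' or 'affine'")
    m = np.hstack([a, t[:, None]])
    pred = src @ a.T + t
    rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    return Transform2D(m, kind=kind, residual_rms=rms)


@dataclass
class MapLayer:
    image: np.ndarray
    scale: ModalityScale
    to_common: Transform2D  # layer px -> common frame µm
    modality: str = ""


@dataclass
class RetinalMap:
    """Set of co-registered modality layers in one µm coordinate frame."""

    layers: dict[str, MapLayer] = field(default_factory=dict)
    eye: str = "OD"  # {"OD", "OS"}
    rmf: float = 0.291
    foveal_center: np.ndarray | None = None  # common-frame µm
    anatomical_x: bool = False  # True if +x is temporal for either eye

    def add_layer(
        self,
        name: str,
        image: np.ndarray,
        scale: ModalityScale,
        to_common: Transform2D | None = None,
    ) -> None:
        if to_common is None:
            to_common = Transform2D.from_scale_offset(
                scale.microns_per_pixel_x, scale.microns_per_pixel_y, 0.0, 0.0
            )
        self.layers[name] = MapLayer(
            image=np.asarray(image, dtype=float),
            scale=scale,
            to_common=to_common,
            modality=name,
        )

    def to_layer(self, name: str, common_um: np.ndarray) -> np.ndarray:
        return self.layers[name].to_common.inverse().apply(common_um)

    def from_layer(self, name: str, px: np.ndarray) -> np.ndarray:
        return self.layers[name].to_common.apply(px)


def montage_place(
    images: list[np.ndarray],
    fixation_deg: list[tuple[float, float]],
    scale: ModalityScale,
    rmf: float,
    refine: bool = True,
    search_radius: int = 12,
    feather: float = 10.0,
) -> tuple[np.ndarray, list[Transform2D]]:
    """Place registered averages on a canvas from fixation coordinates.

    Each image's nominal center offset is ``fixation_deg * rmf * 1000``
    µm from the montage origin, converted to canvas pixels at the
    modality scale.  With ``refine=True`` each tile after the first is
    nudged by NCC against the partially built canvas, recovering
    mislabeled or drifted fixation within ``search_radius`` px.
    Overlaps are blended with distance-weighted feathering.

    Returns the canvas and one px->canvas-px transform per tile; tiles
    with no overlap are placed by fixation alone (flagged by a NaN
    residual on their transform).
    """
    if len(images) != len(fixation_deg):
        raise ValueError("one fixation coordinate per image required")
    if not images:
        raise ValueError("no images to montage")
    sx, sy = scale.microns_per_pixel_x, scale.microns_per_pixel_y
    um_per_deg = rmf * 1000.0
    # nominal top-left offsets in canvas px
    offsets = []
    for img, (fx, fy) in zip(images, fixation_deg):
        h, w = img.shape
        cx = fx * um_per_deg / sx
        cy = fy * um_per_deg / sy
        offsets.append(np.array([cx - w / 2.0, cy - h / 2.0]))
    offsets = np.asarray(offsets)
    mins = offsets.min(axis=0)
    offsets -= mins  # shift so canvas starts at 0
    pad = search_radius + 2
    offsets += pad
    wc = int(math.ceil(offsets[:, 0].max() + max(i.shape[1] for i in images))) + pad
    hc = int(math.ceil(offsets[:, 1].max() + max(i.shape[0] for i in images))) + pad

    acc = np.zeros((hc, wc))
    wgt = np.zeros((hc, wc))
    transforms: list[Transform2D] = []
    for ti, img in enumerate(images):
        h, w = img.shape
        ox, oy = offsets[ti]
        ix, iy = int(round(ox)), int(round(oy))
        dx = dy = 0.0
        flagged = False
        if refine and ti > 0 and wgt.max() > 0:
            # match against the current blended canvas where covered
            canvas = np.where(wgt > 0, acc / np.maximum(wgt, 1e-12), 0.0)
            r = search_radius
            sub = canvas[
                max(iy - r, 0) : iy + h + r, max(ix - r, 0) : ix + w + r
            ]
            cov = wgt[max(iy - r, 0) : iy + h + r, max(ix - r, 0) : ix + w + r]
            if (cov > 0).mean() > 0.05:
                top = iy - max(iy - r, 0)
                left = ix - max(ix - r, 0)
                surf = _ncc_surface(img, sub, top, left, r)
                ddx, ddy, val = _parabolic_peak(surf)
                if np.isfinite(val) and val > 0.2:
                    dx, dy = ddx, ddy
                else:
                    flagged = True
            else:
                flagged = True
        tx, ty = ox + dx, oy + dy
        transforms.append(
            Transform2D(
                np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]),
                kind="similarity",
                residual_rms=float("nan") if flagged else 0.0,
            )
        )
        # feathered accumulation at integer placement of refined offset
        jx, jy = int(round(tx)), int(round(ty))
        fx_, fy_ = tx - jx, ty - jy
        tile = img
        if abs(fx_) > 1e-9 or abs(fy_) > 1e-9:
            tile = ndimage.shift(img, (fy_, fx_), order=1, mode="nearest")
        d = np.minimum.reduce(
            np.meshgrid(
                np.minimum(np.arange(w) + 1, w - np.arange(w)),
                np.minimum(np.arange(h) + 1, h - np.arange(h)),
                indexing="xy",
            )
        ).astype(float)
        wt = np.clip(d / feather, 0.05, 1.0)
        acc[jy : jy + h, jx : jx + w] += tile * wt
        wgt[jy : jy + h, jx : jx + w] += wt
    canvas = np.full((hc, wc), np.nan)
    good = wgt > 0
    canvas[good] = acc[good] / wgt[good]
    return canvas, transforms


def set_foveal_center(
    rmap: RetinalMap, point_on_oct: tuple[float, float], oct_layer: str = "oct_enface"
) -> RetinalMap:
    """Anchor the map at the anatomical foveal center marked on OCT.

    The pixel marked on the OCT en-face layer is projected into the
    common µm frame and stored; its corresponding location in every
    other modality follows from that layer's transform.
    """
    if oct_layer not in rmap.layers:
        raise KeyError(f"layer {oct_layer!r} not in map")
    layer = rmap.layers[oct_layer]
    h, w = layer.image.shape
    x, y = point_on_oct
    if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
        raise ValueError("foveal mark outside the OCT layer")
    rmap.foveal_center = layer.to_common.apply(np.array([x, y], dtype=float))
    return rmap


_MERIDIANS_TEMPORAL_POS_X = {0: "temporal", 1: "inferior", 2: "nasal", 3: "superior"}


def eccentricity_of(
    rmap: RetinalMap, point_um: tuple[float, float]
) -> tuple[float, float, str]:
    """Eccentricity of a common-frame point: (mm, degrees, meridian).

    Degrees are mm / RMF.  The meridian is the 90° sector around the
    horizontal/vertical axes; nasal/temporal depend on eye laterality
    unless the map was imported in anatomical orientation
    (``anatomical_x=True``, +x temporal for both eyes).
    """
    if rmap.foveal_center is None:
        raise ValueError("foveal center not set")
    v = np.asarray(point_um, dtype=float) - rmap.foveal_center
    mm = float(np.hypot(*v)) / 1000.0
    deg = mm / rmap.rmf
    if mm == 0:
        return 0.0, 0.0, "center"
    ang = math.degrees(math.atan2(v[1], v[0])) % 360.0  # y down
    sector = int(((ang + 45.0) % 360.0) // 90.0)
    x_is_temporal = rmap.anatomical_x or rmap.eye == "OS"
    label = _MERIDIANS_TEMPORAL_POS_X[sector]
    if not x_is_temporal and label in ("temporal", "nasal"):
        label = "nasal" if label == "temporal" else "temporal"
    return mm, deg, label
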