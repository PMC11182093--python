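"""Retinal magnification and per-modality pixel scales from ocular biometry.

The lateral scale of every retinal image depends on the optics of the eye
being imaged.  The retinal magnification factor (RMF, mm of retina per
degree of visual angle) is obtained from a paraxial schematic eye whose
axial length is replaced by the measured value:

* ``four_surface`` — a four-refracting-surface schematic eye (Le Grand
  full theoretical eye defaults: both corneal surfaces and both lens
  surfaces).  The system is traced with 2x2 ray-transfer matrices in the
  reduced-angle convention; the RMF is the posterior nodal distance
  (second nodal point to retina) times pi/180.
* ``reduced`` — Bennett's reduced-eye closed form
  ``RMF = 0.01306 * (AL - 1.82)`` with AL the axial length in mm, used
  as an independent cross-check of the matrix trace.

When imaging is performed through a soft contact lens the magnification
of the composite lens+eye system differs from the bare eye; the RMF is
multiplied by a paraxial lens-correction factor (see
:func:`apply_contact_lens_correction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Biometry",
    "ScaleModel",
    "ModalityScale",
    "LE_GRAND_DEFAULTS",
    "compute_rmf",
    "apply_contact_lens_correction",
    "microns_per_pixel",
]

#: Le Grand full theoretical eye (unaccommodated), distances in mm.
#: Radii are signed (positive = center of curvature to the right).
LE_GRAND_DEFAULTS: dict[str, float] = {
    "corneal_front_radius": 7.8,
    "corneal_back_radius": 6.5,
    "corneal_thickness": 0.55,
    "anterior_chamber_depth": 3.05,
    "lens_front_radius": 10.2,
    "lens_back_radius": -6.0,
    "lens_thickness": 4.0,
    "n_cornea": 1.3771,
    "n_aqueous": 1.3374,
    "n_lens": 1.42,
    "n_vitreous": 1.336,
    "axial_length": 24.197,
}

MODALITIES = (
    "aoslo_confocal",
    "aoslo_split",
    "aoslo_darkfield",
    "fir",
    "faf",
    "oct_enface",
    "cfp",
)


@dataclass(frozen=True)
class Biometry:
    """Ocular biometry; optional fields fall back to Le Grand defaults.

    All lengths/radii in mm; refractive indices are unitless.
    """

    axial_length: float
    corneal_front_radius: float | None = None
    corneal_back_radius: float | None = None
    corneal_thickness: float | None = None
    anterior_chamber_depth: float | None = None
    lens_front_radius: float | None = None
    lens_back_radius: float | None = None
    lens_thickness: float | None = None
    refractive_indices: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (15.0 < self.axial_length < 40.0):
            raise ValueError(
                f"axial_length={self.axial_length} mm is outside the "
                "physiological range (15, 40) mm"
            )
        for name in (
            "corneal_front_radius",
            "corneal_back_radius",
            "lens_front_radius",
            "lens_back_radius",
        ):
            r = getattr(self, name)
            if r is not None and r == 0:
                raise ValueError(f"{name} must be nonzero")
        for name in ("corneal_thickness", "anterior_chamber_depth", "lens_thickness"):
            t = getattr(self, name)
            if t is not None and t < 0:
                raise ValueError(f"{name} must be nonnegative")

    def filled(self) -> dict[str, float]:
        """Biometry with missing fields substituted from the default eye."""
        out = dict(LE_GRAND_DEFAULTS)
        out["axial_length"] = self.axial_length
        for name in (
            "corneal_front_radius",
            "corneal_back_radius",
            "corneal_thickness",
            "anterior_chamber_depth",
            "lens_front_radius",
            "lens_back_radius",
            "lens_thickness",
        ):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        for k, v in self.refractive_indices.items():
            if k not in ("n_cornea", "n_aqueous", "n_lens", "n_vitreous"):
                raise ValueError(f"unknown refractive index key {k!r}")
            out[k] = float(v)
        return out


@dataclass(frozen=True)
class ScaleModel:
    """RMF in mm/deg plus the contact-lens correction multiplier."""

    rmf: float
    model_name: str
    lens_correction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rmf > 0 and math.isfinite(self.rmf)):
            raise ValueError(f"rmf must be positive and finite, got {self.rmf}")
        if not (self.lens_correction > 0 and math.isfinite(self.lens_correction)):
            raise ValueError("lens_correction must be positive and finite")

    @property
    def corrected_rmf(self) -> float:
        return self.rmf * self.lens_correction


@dataclass(frozen=True)
class ModalityScale:
    modality: str
    microns_per_pixel_x: float
    microns_per_pixel_y: float

    def __post_init__(self) -> None:
        for v in (self.microns_per_pixel_x, self.microns_per_pixel_y):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"pixel scale must be positive and finite, got {v}")


# ---------------------------------------------------------------------------
# paraxial machinery

def _refraction(n1: float, n2: float, radius: float) -> np.ndarray:
    """Refraction matrix acting on [y, n*u] (reduced-angle convention)."""
    power = (n2 - n1) / radius  # 1/mm
    return np.array([[1.0, 0.0], [-power, 1.0]])


def _translation(t: float, n: float) -> np.ndarray:
    return np.array([[1.0, t / n], [0.0, 1.0]])


def _eye_matrix(p: dict[str, float]) -> np.ndarray:
    """System matrix from cornea front vertex to lens back vertex."""
    m = _refraction(1.0, p["n_cornea"], p["corneal_front_radius"])
    m = _translation(p["corneal_thickness"], p["n_cornea"]) @ m
    m = _refraction(p["n_cornea"], p["n_aqueous"], p["corneal_back_radius"]) @ m
    m = _translation(p["anterior_chamber_depth"], p["n_aqueous"]) @ m
    m = _refraction(p["n_aqueous"], p["n_lens"], p["lens_front_radius"]) @ m
    m = _translation(p["lens_thickness"], p["n_lens"]) @ m
    m = _refraction(p["n_lens"], p["n_vitreous"], p["lens_back_radius"]) @ m
    return m


def _posterior_nodal_distance(p: dict[str, float]) -> float:
    """Distance from the second nodal point to the retina, mm.

    With system matrix M = [[A, B], [C, D]] (object space air, image
    space vitreous n'), the back focal distance from the last surface is
    -A n'/C, the back focal length n'/F with equivalent power F = -C,
    and N'F' equals the front focal length 1/F; hence the second nodal
    point sits at (1 - A n')/C behind the last surface.
    """
    m = _eye_matrix(p)
    a, c = m[0, 0], m[1, 0]
    if c >= 0:
        raise ValueError("schematic eye has non-positive power; check biometry")
    n_v = p["n_vitreous"]
    z_nodal = (1.0 - a * n_v) / c  # from lens back vertex
    front_to_lens_back = (
        p["corneal_thickness"] + p["anterior_chamber_depth"] + p["lens_thickness"]
    )
    pnd = p["axial_length"] - (front_to_lens_back + z_nodal)
    if pnd <= 0:
        raise ValueError("posterior nodal distance non-positive; check biometry")
    return pnd


def bennett_rmf(axial_length: float) -> float:
    """Bennett's reduced-eye closed form, mm/deg."""
    return 0.01306 * (axial_length - 1.82)


def compute_rmf(biometry: Biometry, model_name: str = "four_surface") -> ScaleModel:
    """Retinal magnification factor from biometry.

    Parameters
    ----------
    biometry
        Measured ocular geometry; unmeasured surfaces default to the
        Le Grand schematic values.
    model_name
        ``"four_surface"`` (matrix trace) or ``"reduced"`` (Bennett).
    """
    if model_name == "reduced":
        rmf = bennett_rmf(biometry.axial_length)
    elif model_name == "four_surface":
        pnd = _posterior_nodal_distance(biometry.filled())
        rmf = pnd * math.pi / 180.0
    else:
        raise ValueError(f"unknown model {model_name!r}")
    return ScaleModel(rmf=rmf, model_name=model_name)


def apply_contact_lens_correction(
    scale: ScaleModel,
    lens_power: float,
    effective_distance: float = 0.0,
    pupil_depth: float = 3.05,
) -> ScaleModel:
    """Scale the RMF for imaging through a contact (or trial) lens.

    The correction is the paraxial magnification of the lens+eye system
    relative to the bare eye, for the chief ray through the eye's
    entrance pupil: a thin lens of power ``lens_power`` (diopters) at
    ``effective_distance`` mm in front of the cornea multiplies the
    chief-ray angle — and hence the retinal image height — by
    ``1 / (1 - K d)`` with ``d`` the lens-to-entrance-pupil distance.
    The entrance-pupil plane defaults to 3.05 mm behind the cornea
    (anterior-chamber depth of the default schematic eye).

    The factor is computed here by an explicit two-element matrix trace
    (thin lens, air gap, pupil plane) rather than the closed form.
    """
    if not math.isfinite(lens_power):
        raise ValueError("lens_power must be finite")
    if effective_distance < 0:
        raise ValueError("effective_distance must be >= 0 mm")
    if lens_power == 0.0:
        return replace(scale, lens_correction=1.0)

    p_lens = lens_power * 1e-3  # diopters -> 1/mm
    d = effective_distance + pupil_depth  # lens to entrance pupil, mm
    # Incoming parallel bundle at unit angle; pick the ray of the bundle
    # that crosses the axis at the pupil plane.  Lens: [y, u]->[y, u-Py];
    # gap d: y -> y + d u.  Solve y_pupil = 0 for the lens-plane height.
    u = 1.0
    denom = 1.0 - d * p_lens
    if denom <= 0:
        raise ValueError(
            "lens power/distance combination is non-paraxial (chief ray lost)"
        )
    y_lens = -d * u / denom
    u_after = u - p_lens * y_lens  # chief-ray angle entering the eye
    correction = u_after / u
    return replace(scale, lens_correction=correction)


def microns_per_pixel(
    scale: ScaleModel,
    field_of_view: float,
    pixels_across: int,
    modality: str = "aoslo_confocal",
    field_of_view_y: float | None = None,
    pixels_down: int | None = None,
) -> ModalityScale:
    """Convert acquisition geometry to µm per pixel for one modality.

    ``µm/px = RMF(corrected) * 1000 * field_of_view / pixels_across``;
    an independent vertical field/pixel count gives anisotropic scales.
    """
    if field_of_view <= 0:
        raise ValueError("field_of_view must be > 0 degrees")
    if pixels_across < 1:
        raise ValueError("pixels_across must be >= 1")
    rmf_um = scale.corrected_rmf * 1000.0
    sx = rmf_um * field_of_view / pixels_across
    fov_y = field_of_view if field_of_view_y is None else field_of_view_y
    py = pixels_across if pixels_down is None else pixels_down
    if fov_y <= 0 or py < 1:
        raise ValueError("vertical field/pixels invalid")
    sy = rmf_um * fov_y / py
    return ModalityScale(
        modality=modality, microns_per_pixel_x=sx, microns_per_pixel_y=sy
    )
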