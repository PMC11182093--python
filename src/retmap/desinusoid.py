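"""Correction of sinusoidal fast-axis scan distortion ("desinusoiding").

A resonant scanner sweeps the imaging beam sinusoidally while pixels are
clocked at a constant rate, so equally spaced image columns correspond
to unequally spaced retinal positions.  Imaging a regular grid of
vertical lines (a Ronchi ruling) of known period reveals the distortion:
the line centers, equally spaced on the target, appear at columns that
follow an arcsine law.  Fitting that law yields a per-column lookup
table (LUT) that resamples each row onto equally spaced positions.

The scan model used here maps source column ``i`` to (normalized) field
position::

    p(i) = [sin(theta * (2 i / (W-1) - 1 - phase)) + sin(theta * (1 + phase))] / s

with ``theta`` the half-sweep angle actually used (``theta -> 0`` is an
undistorted linear scan) and ``phase`` a small centering offset; ``s``
normalizes the covered range.  The correction inverts this map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize, signal

__all__ = ["DesinusoidLUT", "fit_desinusoid", "apply_desinusoid"]


@dataclass
class DesinusoidLUT:
    """Per-output-column fractional source-column positions."""

    source_width: int
    mapping: np.ndarray  # (output_width,) float, strictly increasing
    fit_params: dict = field(default_factory=dict)
    residual: float = float("nan")

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=float)
        if self.mapping.ndim != 1 or self.mapping.size < 2:
            raise ValueError("mapping must be a 1-D array of >= 2 columns")
        if not np.all(np.diff(self.mapping) > 0):
            raise ValueError("LUT mapping must be strictly increasing")
        if self.mapping[0] < -0.5 or self.mapping[-1] > self.source_width - 0.5:
            raise ValueError("LUT endpoints outside the source image")
        if not math.isfinite(float(self.residual)) and not math.isnan(
            float(self.residual)
        ):
            raise ValueError("residual must be finite or NaN")

    @property
    def is_identity(self) -> bool:
        ref = np.arange(self.mapping.size, dtype=float)
        return self.mapping.size == self.source_width and np.allclose(
            self.mapping, ref, atol=1e-12
        )

    def to_json(self, path: str | Path) -> None:
        obj = {
            "source_width": int(self.source_width),
            "mapping": self.mapping.tolist(),
            "fit_params": {k: float(v) for k, v in self.fit_params.items()},
            "residual": float(self.residual),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DesinusoidLUT":
        obj = json.loads(Path(path).read_text())
        return cls(
            source_width=obj["source_width"],
            mapping=np.asarray(obj["mapping"], dtype=float),
            fit_params=obj.get("fit_params", {}),
            residual=obj.get("residual", float("nan")),
        )


def scan_position(cols: np.ndarray, width: int, theta: float, phase: float = 0.0
                  ) -> np.ndarray:
    """Normalized field position in [0, 1] of each source column.

    Shared with the phantom generator so calibration phantoms and the
    fitted model speak the same parameterization.
    """
    cols = np.asarray(cols, dtype=float)
    x = 2.0 * cols / (width - 1) - 1.0  # [-1, 1]
    if abs(theta) < 1e-9:
        lo, hi = -1.0 - phase, 1.0 - phase
        raw = x - phase
    else:
        raw = np.sin(theta * (x - phase))
        lo, hi = math.sin(theta * (-1.0 - phase)), math.sin(theta * (1.0 - phase))
    return (raw - lo) / (hi - lo)


def _line_centers(profile: np.ndarray, template_sigma: float) -> np.ndarray:
    """Subpixel line-center columns from a 1-D intensity profile.

    Cross-correlates with a Gaussian line template and refines each
    local maximum by parabolic interpolation.
    """
    prof = profile - profile.mean()
    if prof.std() == 0:
        return np.empty(0)
    half = max(2, int(round(3 * template_sigma)))
    xs = np.arange(-half, half + 1, dtype=float)
    tmpl = np.exp(-0.5 * (xs / template_sigma) ** 2)
    tmpl -= tmpl.mean()
    score = np.correlate(prof, tmpl, mode="same")
    thr = 0.3 * score.max()
    peaks, _ = signal.find_peaks(score, height=thr, distance=max(3, half))
    centers = []
    for p in peaks:
        if 0 < p < score.size - 1:
            a, b, c = score[p - 1], score[p], score[p + 1]
            denom = a - 2 * b + c
            delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            centers.append(p + delta)
    return np.asarray(centers)


def fit_desinusoid(
    grid_image: np.ndarray,
    line_period: float = 1.0,
    distance: float = 1.0,
    template_sigma: float | None = None,
) -> DesinusoidLUT:
    """Fit the sinusoidal scan model to a Ronchi-ruling calibration image.

    Parameters
    ----------
    grid_image
        2-D grayscale image of approximately vertical lines.
    line_period, distance
        Physical line period of the ruling and its distance from the
        scanner; only their product's constancy matters for the shape of
        the correction, so they are accepted for provenance but the fit
        itself uses the equal-spacing constraint of the target.
    """
    img = np.asarray(grid_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("grid_image must be 2-D")
    h, w = img.shape
    profile = img.mean(axis=0)
    if template_sigma is None:
        # estimate line spacing from the autocorrelation of the profile
        prof0 = profile - profile.mean()
        if prof0.std() == 0:
            raise ValueError("no lines detected: featureless calibration image")
        ac = np.correlate(prof0, prof0, mode="full")[w - 1 :]
        pk, _ = signal.find_peaks(ac)
        est_spacing = float(pk[0]) if pk.size else w / 8.0
        template_sigma = max(1.0, est_spacing / 6.0)
    centers = _line_centers(profile, template_sigma)
    if centers.size < 8:
        raise ValueError(
            f"no usable calibration: {centers.size} line crossings found, need >= 8"
        )
    if np.any(np.diff(centers) <= 0):
        raise ValueError("detected line centers are not monotone")

    k = np.arange(centers.size, dtype=float)  # line index = equal target steps

    def resid(params: np.ndarray) -> np.ndarray:
        theta, phase, p0, dp = params
        pos = scan_position(centers, w, theta, phase)
        return pos - (p0 + dp * k)

    # linear initialization: theta ~ 0, target positions from a line fit
    dp0 = 1.0 / max(centers.size - 1, 1)
    x0 = np.array([0.3, 0.0, 0.05, dp0])
    sol = optimize.least_squares(
        resid,
        x0,
        bounds=([1e-6, -0.5, -1.0, 1e-6], [math.pi / 2 - 1e-6, 0.5, 1.0, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
    )
    theta, phase = float(sol.x[0]), float(sol.x[1])

    # residual in source-pixel units: invert the model at fitted target
    p0, dp = float(sol.x[2]), float(sol.x[3])
    model_cols = _invert_scan(p0 + dp * k, w, theta, phase)
    residual = float(np.sqrt(np.mean((model_cols - centers) ** 2)))

    out_cols = np.arange(w, dtype=float)
    target = out_cols / (w - 1)
    mapping = _invert_scan(target, w, theta, phase)
    mapping = np.clip(mapping, 0.0, w - 1.0)
    # strict monotonicity can be lost to clipping only at the exact ends
    eps = 1e-9
    mapping = np.maximum.accumulate(mapping + eps * out_cols) - eps * out_cols
    if not np.all(np.diff(mapping) > 0):
        raise ValueError("fitted LUT is not strictly increasing")
    return DesinusoidLUT(
        source_width=w,
        mapping=mapping,
        fit_params={
            "theta": theta,
            "phase": phase,
            "line_period": float(line_period),
            "distance": float(distance),
        },
        residual=residual,
    )


def _invert_scan(target: np.ndarray, width: int, theta: float, phase: float
                 ) -> np.ndarray:
    """Source columns whose scan_position equals ``target`` (in [0,1])."""
    target = np.asarray(target, dtype=float)
    if abs(theta) < 1e-9:
        x = target * 2.0 - 1.0  # linear scan limit
        return (x + 1.0) * (width - 1) / 2.0
    lo = math.sin(theta * (-1.0 - phase))
    hi = math.sin(theta * (1.0 - phase))
    raw = target * (hi - lo) + lo
    x = np.arcsin(np.clip(raw, -1.0, 1.0)) / theta + phase
    return (x + 1.0) * (width - 1) / 2.0


def apply_desinusoid(
    image: np.ndarray, lut: DesinusoidLUT, interpolation: str = "cubic"
) -> np.ndarray:
    """Resample each row of ``image`` onto the equally spaced LUT grid.

    Output width equals ``len(lut.mapping)`` (by default the input
    width).  An identity LUT returns the input unchanged, bit-exactly.
    Resampling is not idempotent: applying a non-identity LUT twice
    compounds the warp and is not equivalent to applying it once.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if img.shape[1] != lut.source_width:
        raise ValueError(
            f"image width {img.shape[1]} != LUT source width {lut.source_width}"
        )
    if lut.is_identity:
        return img.copy()
    order = {"cubic": 3, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'cubic' or 'linear'")
    h = img.shape[0]
    cols = np.broadcast_to(lut.mapping, (h, lut.mapping.size))
    rows = np.broadcast_to(np.arange(h, dtype=float)[:, None], cols.shape)
    return ndimage.map_coordinates(
        img, [rows, cols], order=order, mode="nearest"
    )
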