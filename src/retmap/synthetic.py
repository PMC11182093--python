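"""Seeded phantom generators with machine-readable ground truth.

Every pipeline stage can be validated without clinical images: the
generators here emulate the structures the pipeline quantifies —
jittered hexagonal photoreceptor mosaics (with an optional fraction of
non-waveguiding "dark" cones rendered only in the split-detection
channel), multi-channel AOSLO renderings, translation-jittered noisy
frame sequences, sinusoidally distorted Ronchi rulings, layered OCT
B-scans with speckle, and normative tables with plausible magnitudes.

All randomness derives from a single integer seed; each sub-generator
forks its own named stream so ground truth is stable when an unrelated
component's parameters change.  Identical specs (including the seed)
produce bit-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .desinusoid import DesinusoidLUT, scan_position, _invert_scan
from .octlayers import BOUNDARIES, LayerSegmentation, OCTVolume
from .register import FrameStack
from .scale import ModalityScale
from .stats import NormativeTable

__all__ = [
    "PhantomSpec",
    "gen_mosaic",
    "render_channels",
    "gen_frames",
    "gen_oct",
    "gen_ruling",
    "gen_normative",
    "hex_spacing_for_density",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic imaging session.

    Defaults mirror the acquisition this pipeline targets: 150-frame
    AOSLO sequences, 3.5/14 µm-per-px OCT sampling, cone densities
    spanning the healthy foveal range down to severely reduced mosaics.
    """

    seed: int = 0
    # mosaic
    density: float = 15000.0  # cells/mm^2 (local, constant unless profile)
    density_profile: object | None = None  # callable ecc_mm -> cells/mm^2
    jitter_fraction: float = 0.10  # of local spacing
    dark_cone_fraction: float = 0.0
    field_um: float = 200.0
    microns_per_pixel: float = 0.75
    psf_sigma_um: float = 1.0
    snr: float = 10.0
    # frames
    n_frames: int = 150
    motion_amplitude_px: float = 4.0
    motion_period_rows: float = 96.0
    frame_noise_sigma: float = 0.05
    # oct
    oct_shape: tuple[int, int, int] = (5, 256, 256)
    oct_boundaries: tuple[float, float, float, float] = (100.0, 150.0, 170.0, 188.0)
    oct_boundary_wave_px: float = 0.0
    oct_speckle_snr: float = 5.0
    # ruling
    ruling_shape: tuple[int, int] = (64, 512)
    ruling_lines: int = 16
    ruling_theta: float = 0.9  # half-sweep angle, 0 = undistorted
    ruling_phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dark_cone_fraction <= 1.0):
            raise ValueError("dark_cone_fraction must be in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def rng(self, key: str) -> np.random.Generator:
        """Named sub-stream forked deterministically from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), zlib.crc32(key.encode())])
        )


def hex_spacing_for_density(density_mm2: float) -> float:
    """Center spacing s (µm) of a hexagonal lattice: density = 2/(sqrt(3) s^2)."""
    return math.sqrt(2.0 / (math.sqrt(3.0) * density_mm2 * 1e-6))


def gen_mosaic(spec: PhantomSpec) -> dict:
    """Jittered hexagonal cell mosaic with optional dark-cone labels.

    Returns ``{"centers": (n, 2) µm, "dark": (n,) bool, "spacing_um",
    "scale": ModalityScale}``.  With a ``density_profile`` the lattice
    is generated at unit density and radially warped so the local
    density matches the profile at each point's eccentricity (exact
    radially, approximate tangentially for steep profiles).
    """
    rng = spec.rng("mosaic")
    field = spec.field_um
    s = hex_spacing_for_density(spec.density)
    if s / spec.microns_per_pixel < 2.0:
        raise ValueError(
            f"density {spec.density} implies spacing {s:.2f} µm "
            f"< 2 px at {spec.microns_per_pixel} µm/px"
        )
    # hexagonal lattice covering the field with margin
    margin = 4.0 * s
    nx = int(math.ceil((field + 2 * margin) / s)) + 2
    ny = int(math.ceil((field + 2 * margin) / (s * math.sqrt(3) / 2))) + 2
    pts = []
    for j in range(ny):
        y = j * s * math.sqrt(3) / 2 - margin
        x0 = (s / 2 if j % 2 else 0.0) - margin
        for i in range(nx):
            pts.append((x0 + i * s, y))
    pts = np.asarray(pts)
    if spec.density_profile is not None:
        pts = _radial_density_warp(pts, field, spec.density,
                                   spec.density_profile)
    jitter = rng.normal(0.0, spec.jitter_fraction * s, size=pts.shape)
    pts = pts + jitter
    keep = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= field)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= field)
    )
    pts = pts[keep]
    dark = rng.random(len(pts)) < spec.dark_cone_fraction
    scale = ModalityScale(
        modality="aoslo_confocal",
        microns_per_pixel_x=spec.microns_per_pixel,
        microns_per_pixel_y=spec.microns_per_pixel,
    )
    return {"centers": pts, "dark": dark, "spacing_um": s, "scale": scale}


def _radial_density_warp(pts: np.ndarray, field: float, base_density: float,
                         profile) -> np.ndarray:
    """Map a uniform lattice to match a radial density profile.

    Equates cumulative cell counts: a point at virtual radius rho moves
    to radius r with ``integral_0^r 2 pi t d(t) dt = pi rho^2 d0``.
    """
    c = np.array([field / 2.0, field / 2.0])
    v = pts - c
    rho = np.linalg.norm(v, axis=1)
    rmax = max(rho.max(), 1e-9)
    rr = np.linspace(0, 2.0 * rmax, 2048)
    dens = np.asarray([max(float(profile(r / 1000.0)), 1e-12) for r in rr])
    cum = np.concatenate([[0.0], np.cumsum(
        2 * math.pi * 0.5 * (dens[1:] * rr[1:] + dens[:-1] * rr[:-1])
        * np.diff(rr))])
    target = math.pi * rho**2 * base_density
    r_new = np.interp(target, cum, rr)
    scale = np.where(rho > 0, r_new / np.maximum(rho, 1e-12), 1.0)
    return c + v * scale[:, None]


def render_channels(
    centers: np.ndarray,
    dark: np.ndarray,
    spec: PhantomSpec,
    cell_type: str = "cone",
) -> dict:
    """Render confocal / split-detection / dark-field images of a mosaic.

    Confocal: Gaussian spots, omitting dark-labeled cells.
    Split-detection: signed horizontal edge-pair profile (derivative of
    a Gaussian) per cell, dark-labeled cells included.
    Dark-field: broader overlapping blobs (RPE-like).
    Poisson-plus-Gaussian noise at the spec SNR; images in [0, 1]-ish
    range, shape ``(field/µm_per_px)`` square.
    """
    px = spec.microns_per_pixel
    npix = int(round(spec.field_um / px))
    sigma = spec.psf_sigma_um / px
    rng = spec.rng("render")

    def splat(pts_um: np.ndarray, deriv: bool, width: float) -> np.ndarray:
        img = np.zeros((npix, npix))
        if len(pts_um):
            cx = pts_um[:, 0] / px
            cy = pts_um[:, 1] / px
            ix = np.clip(np.round(cx).astype(int), 0, npix - 1)
            iy = np.clip(np.round(cy).astype(int), 0, npix - 1)
            np.add.at(img, (iy, ix), 1.0)
        if deriv:
            out = -ndimage.gaussian_filter(img, width, order=(0, 1))
        else:
            out = ndimage.gaussian_filter(img, width)
        m = np.abs(out).max()
        return out / m if m > 0 else out

    bright = centers[~dark] if len(centers) else centers
    confocal = splat(bright, deriv=False, width=sigma)
    split = splat(centers, deriv=True, width=sigma)
    darkfield = splat(centers, deriv=False, width=2.5 * sigma)

    def noisy(img: np.ndarray, key: str) -> np.ndarray:
        """Poisson shot noise plus Gaussian read noise at the spec SNR."""
        r = spec.rng("noise_" + key)
        ptp = np.ptp(img)
        base = (img - img.min()) / ptp if ptp > 0 else img - img.min()
        gain = spec.snr**2  # photons at unit signal -> shot SD 1/snr at peak
        shot = r.poisson(base * gain) / gain
        return shot + r.normal(0.0, 0.5 / spec.snr, img.shape)

    return {
        "confocal": noisy(confocal, "confocal"),
        "split": noisy(split, "split"),
        "darkfield": noisy(darkfield, "darkfield"),
        "confocal_truth": bright.copy(),
        "split_truth": centers.copy(),
        "scale": ModalityScale("aoslo_confocal", px, px),
    }


def gen_frames(base_image: np.ndarray, spec: PhantomSpec) -> dict:
    """Translation-jittered noisy frame sequence with known motion.

    Each frame gets a global translation plus a row-dependent sinusoidal
    horizontal shift (slow drift of the eye during the raster), then
    iid Gaussian noise.  Returns the stack, the per-frame global
    offsets and the per-frame row-shift waveforms — the ground truth
    the registration stage must recover.
    """
    rng = spec.rng("frames")
    base = np.asarray(base_image, dtype=float)
    h, w = base.shape
    n = spec.n_frames
    amp = spec.motion_amplitude_px
    global_shifts = rng.uniform(-amp, amp, size=(n, 2))
    global_shifts[0] = 0.0
    phases = rng.uniform(0, 2 * math.pi, size=n)
    wave_amp = rng.uniform(0, amp / 2.0, size=n)
    wave_amp[0] = 0.0
    rows = np.arange(h)
    frames = np.empty((n, h, w))
    waveforms = np.empty((n, h))
    for i in range(n):
        gx, gy = global_shifts[i]
        wave = wave_amp[i] * np.sin(
            2 * math.pi * rows / spec.motion_period_rows + phases[i]
        )
        waveforms[i] = wave + gx
        # row r of frame i samples the base at x + (gx + wave[r]), y + gy
        coords_y = np.broadcast_to((rows + gy)[:, None], (h, w)).astype(float)
        coords_x = np.arange(w)[None, :] + (gx + wave)[:, None]
        frames[i] = ndimage.map_coordinates(
            base, [coords_y, coords_x], order=1, mode="nearest"
        )
        if spec.frame_noise_sigma > 0:
            frames[i] += rng.normal(0, spec.frame_noise_sigma, (h, w))
    stack = FrameStack(frames=frames, modality="aoslo_confocal")
    return {
        "stack": stack,
        "global_shifts": global_shifts,
        "row_waveforms": waveforms,  # dx per row incl. global component
        "global_y": global_shifts[:, 1],
    }


def gen_oct(spec: PhantomSpec) -> dict:
    """Layered OCT volume with speckle and known boundary geometry.

    Boundary rows (ILM, OPL, EZ center, RPE-BrM posterior) may carry a
    sinusoidal lateral undulation of amplitude ``oct_boundary_wave_px``.
    Band reflectivities: dark vitreous, bright inner retina, dark outer
    nuclear layer, bright EZ ridge, brightest RPE band, dark choroid.
    Speckle is multiplicative (gamma) at ``oct_speckle_snr``.
    """
    b_ilm, b_opl, b_ez, b_rpe = spec.oct_boundaries
    if not (b_ilm <= b_opl <= b_ez <= b_rpe):
        raise ValueError("boundaries must be ordered ILM <= OPL <= EZ <= RPE-BrM")
    n, rows, cols = spec.oct_shape
    rng = spec.rng("oct")
    x = np.arange(cols)
    r = np.arange(rows, dtype=float)[:, None]
    truth = {b: np.zeros((n, cols)) for b in BOUNDARIES}
    vols = np.empty((n, rows, cols))
    edge = 1.2  # soft transition half-width (px) so gradients peak on-boundary
    for bi in range(n):
        wave = spec.oct_boundary_wave_px * np.sin(
            2 * math.pi * x / cols + 0.7 * bi
        )
        ilm = b_ilm + wave
        opl = b_opl + wave
        ez = b_ez + wave
        rpe = b_rpe + wave
        truth["ILM"][bi] = ilm
        truth["OPL_posterior"][bi] = opl
        truth["EZ_center"][bi] = ez
        truth["RPEBrM_posterior"][bi] = rpe

        def smoothstep(bnd):
            return 0.5 * (1.0 + np.tanh((r - bnd[None, :]) / edge))

        img = 0.02
        img = img + 0.55 * smoothstep(ilm)  # inner retina
        img = img - 0.35 * smoothstep(opl)  # darker outer nuclear layer
        # EZ ridge centered at ez
        img = img + 0.45 * np.exp(-0.5 * ((r - ez[None, :]) / 2.0) ** 2)
        # RPE band: from ez+gap to rpe (posterior edge at rpe)
        rpe_top = ez + 0.55 * (rpe - ez)
        img = img + 0.75 * (smoothstep(rpe_top) - smoothstep(rpe))
        if spec.oct_speckle_snr and spec.oct_speckle_snr > 0:
            k = spec.oct_speckle_snr**2  # gamma shape: mean 1, SD 1/snr
            speck = rng.gamma(k, 1.0 / k, size=(rows, cols))
            img = img * speck
        vols[bi] = img
    volume = OCTVolume(
        bscans=vols,
        axial_scale=3.5,
        lateral_scale=14.0,
        bscan_spacing=120.0,
    )
    seg = LayerSegmentation(boundaries={k: v.copy() for k, v in truth.items()})
    return {"volume": volume, "truth": seg}


def gen_ruling(spec: PhantomSpec) -> dict:
    """Ronchi-ruling calibration image seen through a sinusoidal scan.

    The ruling has ``ruling_lines`` bright lines equally spaced on the
    target; the scan maps source column i to field position
    ``scan_position(i, W, theta, phase)``.  Returns the image, the true
    LUT (the correction the fit should recover) and the generator
    parameters.
    """
    h, w = spec.ruling_shape
    theta, phase = spec.ruling_theta, spec.ruling_phase
    cols = np.arange(w, dtype=float)
    pos = scan_position(cols, w, theta, phase)  # [0, 1]
    nl = spec.ruling_lines
    # bright Gaussian lines at field positions (k + 0.5)/nl
    profile = np.zeros(w)
    line_sigma = 0.25 / nl
    for k in range(nl):
        c = (k + 0.5) / nl
        profile += np.exp(-0.5 * ((pos - c) / line_sigma) ** 2)
    img = np.tile(profile, (h, 1))
    rng = spec.rng("ruling")
    img = img + rng.normal(0, 0.01, img.shape)
    target = cols / (w - 1)
    mapping = np.clip(_invert_scan(target, w, theta, phase), 0, w - 1)
    true_lut = DesinusoidLUT(
        source_width=w,
        mapping=np.maximum.accumulate(mapping + 1e-12 * cols) - 1e-12 * cols,
        fit_params={"theta": theta, "phase": phase},
        residual=0.0,
    )
    return {"image": img, "true_lut": true_lut,
            "theta": theta, "phase": phase}


def gen_normative(
    spec: PhantomSpec,
    measures: tuple[str, ...] = ("cone_density", "rt", "orl"),
    eccentricities_mm: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    meridians: tuple[str, ...] = ("nasal", "temporal", "superior", "inferior"),
    n_controls: int = 10,
) -> NormativeTable:
    """Normative table with plausible healthy-retina magnitudes.

    Foveal cone density is drawn within the healthy range
    104,985-163,797 cells/mm² and falls off with eccentricity; RT and
    ORL span ~250-335 µm and ~100-147 µm respectively.  SDs are a fixed
    fraction of the mean (minimum enforced positive).
    """
    rng = spec.rng("normative")
    rows = []
    fovea = rng.uniform(104985.0, 163797.0)
    for meas in measures:
        for mer in meridians:
            for ecc in eccentricities_mm:
                if meas == "cone_density":
                    mean = fovea * math.exp(-1.1 * ecc) + 8000.0
                    sd = 0.12 * mean
                elif meas == "rt":
                    mean = 335.0 - 20.0 * ecc
                    sd = 12.0
                elif meas == "orl":
                    mean = 147.0 - 10.0 * ecc
                    sd = 7.0
                elif meas == "rpe_density":
                    mean = 7800.0 - 500.0 * ecc
                    sd = 600.0
                else:  # rpe_area
                    mean = 130.0 + 70.0 * ecc
                    sd = 0.2 * mean
                mean = mean * (1.0 + rng.normal(0, 0.01))
                rows.append({
                    "measure": meas,
                    "eccentricity_mm": ecc,
                    "meridian": mer,
                    "mean": round(float(mean), 3),
                    "sd": round(float(max(sd, 1e-6)), 3),
                    "n": n_controls,
                })
    return NormativeTable(pd.DataFrame(rows))
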