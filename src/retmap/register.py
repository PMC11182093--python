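"""Intra-sequence AOSLO frame registration and averaging.

An AOSLO video (150 frames per sequence by default) is reduced to a
single high-SNR image in three steps: frames are ranked by whole-frame
normalized cross correlation (NCC) against a manually chosen reference;
each selected frame is registered to the reference with a horizontal
strip method that estimates one translation per strip, tracking the
intra-frame distortion left by eye motion during the raster scan; and
the accepted, shifted strips are averaged per pixel.

All NCC values are zero-mean normalized correlations in [-1, 1].
Subpixel offsets come from parabolic interpolation of the integer NCC
surface around its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scale import ModalityScale

__all__ = [
    "FrameStack",
    "StripOffsets",
    "rank_frames_by_ncc",
    "strip_register",
    "average_registered",
]

DEFAULT_TOP_N = 50
DEFAULT_STRIP_HEIGHT = 32
DEFAULT_NCC_THRESHOLD = 0.5


@dataclass
class FrameStack:
    frames: np.ndarray  # (n, h, w) float
    modality: str = "aoslo_confocal"
    scale: ModalityScale | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n>=1, h, w) array")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class StripOffsets:
    """Per-strip translations (dx, dy) of one frame relative to a reference."""

    strip_height: int
    strip_rows: np.ndarray  # (n_strips,) top row of each strip
    offsets: np.ndarray  # (n_strips, 2) (dx, dy), px
    ncc_scores: np.ndarray  # (n_strips,) peak NCC
    accepted: np.ndarray  # (n_strips,) bool
    search_radius: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.ncc_scores = np.asarray(self.ncc_scores, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if np.any(self.ncc_scores > 1.0 + 1e-9) or np.any(
            self.ncc_scores < -1.0 - 1e-9
        ):
            raise ValueError("NCC scores must lie in [-1, 1]")

    @property
    def usable(self) -> bool:
        return bool(self.accepted.any())


def _zero_mean_ncc(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:  # constant image: NCC undefined
        return -math.inf
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -math.inf
    return float(np.vdot(a, b) / (na * nb))


def rank_frames_by_ncc(
    stack: FrameStack, reference_index: int
) -> list[tuple[int, float]]:
    """Order frames by whole-frame NCC to the reference, best first.

    The reference frame itself scores exactly 1.0.  Constant-intensity
    frames have undefined NCC and are assigned ``-inf`` so they sort
    last.  Ties are broken by frame index for determinism.
    """
    n = stack.frame_count
    if not (0 <= reference_index < n):
        raise IndexError(f"reference_index {reference_index} out of range [0, {n})")
    ref = stack.frames[reference_index]
    scores = []
    for i in range(n):
        if i == reference_index:
            s = 1.0 if np.ptp(stack.frames[i]) > 0 else -math.inf
        else:
            s = _zero_mean_ncc(stack.frames[i], ref)
        scores.append((i, s))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def _ncc_surface(
    strip: np.ndarray, reference: np.ndarray, top: int, left: int, radius: int
) -> np.ndarray:
    """NCC of ``strip`` against reference windows over a (2r+1)^2 shift grid.

    Shift (dx, dy) means the strip content sits at reference position
    (col + dx, row + dy); out-of-bounds windows score -inf.
    """
    h, w = strip.shape
    rh, rw = reference.shape
    out = np.full((2 * radius + 1, 2 * radius + 1), -np.inf)
    s0 = strip - strip.mean()
    ns = np.linalg.norm(s0)
    if ns == 0:
        return out
    for iy, dy in enumerate(range(-radius, radius + 1)):
        r0 = top + dy
        if r0 < 0 or r0 + h > rh:
            continue
        for ix, dx in enumerate(range(-radius, radius + 1)):
            c0 = left + dx
            if c0 < 0 or c0 + w > rw:
                continue
            win = reference[r0 : r0 + h, c0 : c0 + w]
            w0 = win - win.mean()
            nw = np.linalg.norm(w0)
            if nw == 0:
                continue
            out[iy, ix] = float(np.vdot(s0, w0) / (ns * nw))
    return out


def _parabolic_peak(surface: np.ndarray) -> tuple[float, float, float]:
    """(dx, dy, value) of the subpixel NCC peak on a shift grid."""
    iy, ix = np.unravel_index(np.argmax(surface), surface.shape)
    val = surface[iy, ix]
    radius = (surface.shape[0] - 1) // 2

    def refine(axis_vals: np.ndarray) -> float:
        a, b, c = axis_vals
        denom = a - 2 * b + c
        if denom == 0 or not np.all(np.isfinite(axis_vals)):
            return 0.0
        return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))

    dx = float(ix - radius)
    dy = float(iy - radius)
    if val >= 1.0 - 1e-9:  # exact match: parabola would only add bias
        return dx, dy, float(val)
    if 0 < ix < surface.shape[1] - 1:
        dx += refine(surface[iy, ix - 1 : ix + 2])
    if 0 < iy < surface.shape[0] - 1:
        dy += refine(surface[iy - 1 : iy + 2, ix])
    return dx, dy, float(val)


def strip_register(
    frame: np.ndarray,
    reference: np.ndarray,
    strip_height: int = DEFAULT_STRIP_HEIGHT,
    search_radius: int = 12,
    ncc_threshold: float = DEFAULT_NCC_THRESHOLD,
    overlap: float = 0.5,
) -> StripOffsets:
    """Estimate one (dx, dy) translation per horizontal strip.

    Strips of ``strip_height`` rows (50% overlap by default) are matched
    against the reference by exhaustive NCC over integer shifts within
    ``search_radius``, refined to subpixel by parabolic interpolation.
    Strips whose peak NCC falls below ``ncc_threshold`` are rejected
    (blink / tear-film dropout handling) and excluded from averaging.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference shapes differ")
    if strip_height < 8:
        raise ValueError("strip_height must be >= 8 px")
    h, w = frame.shape
    step = max(1, int(round(strip_height * (1.0 - overlap))))
    # horizontal margin so shifted windows stay in bounds
    mx = search_radius
    tops = list(range(0, max(h - strip_height, 0) + 1, step))
    if not tops:
        tops = [0]
    rows, offs, scores, ok = [], [], [], []
    for top in tops:
        strip = frame[top : top + strip_height, mx : w - mx]
        surf = _ncc_surface(strip, reference, top, mx, search_radius)
        dx, dy, val = _parabolic_peak(surf)
        rows.append(top)
        offs.append((dx, dy))
        scores.append(val if np.isfinite(val) else -1.0)
        ok.append(np.isfinite(val) and val >= ncc_threshold)
    result = StripOffsets(
        strip_height=strip_height,
        strip_rows=np.asarray(rows),
        offsets=np.asarray(offs, dtype=float),
        ncc_scores=np.clip(np.asarray(scores, dtype=float), -1.0, 1.0),
        accepted=np.asarray(ok, dtype=bool),
        search_radius=search_radius,
    )
    return result


def _shift_image(img: np.ndarray, dx: float, dy: float, method: str) -> np.ndarray:
    """Translate content by (+dx, +dy): maps frame pixels onto reference grid.

    Offsets follow the convention frame(x, y) ~ reference(x+dx, y+dy),
    so the registered image is reg(X, Y) = frame(X-dx, Y-dy).
    """
    if dx == 0 and dy == 0:
        return img
    if method == "fourier":
        return np.real(
            np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (dy, dx)))
        )
    return ndimage.shift(img, (dy, dx), order=1, mode="nearest")


def average_registered(
    stack: FrameStack,
    offsets: list[StripOffsets],
    top_n: int = DEFAULT_TOP_N,
    order: list[int] | None = None,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Average the best ``top_n`` frames after per-strip alignment.

    Each accepted strip is shifted onto the reference grid (bilinear by
    default, Fourier shift optional) and accumulated; the per-pixel mean
    over contributing strips is returned together with a coverage map
    counting contributions.  Pixels with zero coverage are NaN.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n = stack.frame_count
    if top_n > n:
        raise ValueError(f"top_n={top_n} exceeds frame_count={n}")
    if len(offsets) != n:
        raise ValueError("need one StripOffsets per frame")
    idx = list(range(n)) if order is None else list(order)
    idx = idx[:top_n]
    h, w = stack.frames.shape[1:]
    acc = np.zeros((h, w))
    cov = np.zeros((h, w))
    method = "fourier" if interpolation == "fourier" else "bilinear"
    for i in idx:
        so = offsets[i]
        frame = stack.frames[i]
        for k, top in enumerate(so.strip_rows):
            if not so.accepted[k]:
                continue
            dx, dy = so.offsets[k]
            # weight mask limits the shifted strip to its own rows
            mask = np.zeros((h, w))
            mask[top : top + so.strip_height, :] = 1.0
            shifted = _shift_image(frame * mask, dx, dy, method)
            wmask = _shift_image(mask, dx, dy, method)
            acc += shifted
            cov += wmask
    out = np.full((h, w), np.nan)
    good = cov > 1e-9
    out[good] = acc[good] / cov[good]
    return out, cov
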