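"""OCT B-scan layer segmentation and retinal thickness extraction.

Four axial boundaries are segmented on each B-scan:

* ILM — inner boundary of the inner limiting membrane (first
  dark-to-bright transition below the vitreous),
* OPL — posterior boundary of the outer plexiform layer
  (bright-to-dark transition into the outer nuclear layer),
* EZ — center of the ellipsoid zone (intensity ridge between OPL and
  the RPE complex),
* RPE-BrM — posterior boundary of the RPE-Bruch's membrane band
  (bright-to-dark transition into the choroid).

Initial estimates come from signed axial-gradient extrema in
polarity-appropriate search windows; each boundary is then refined by a
1-D active contour (per-column energy from the smoothed gradient or
ridge feature, second-difference curvature smoothing, optional seed
points as hard constraints).  Thickness definitions:
``RT = (RPE-BrM - ILM) * axial_scale`` and
``ORL = (RPE-BrM - OPL) * axial_scale``, both in µm with fractional
row positions (no rounding before subtraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .montage import RetinalMap, Transform2D

__all__ = [
    "OCTVolume",
    "LayerSegmentation",
    "ThicknessProfile",
    "BOUNDARIES",
    "segment_layers",
    "thickness_profile",
    "extract_thickness_at",
]

BOUNDARIES = ("ILM", "OPL_posterior", "EZ_center", "RPEBrM_posterior")


@dataclass
class OCTVolume:
    """OCT volume: list of B-scans plus physical sampling.

    Defaults follow the acquisition this pipeline targets: 3.5 µm/px
    axial and 14 µm/px lateral sampling in tissue.
    """

    bscans: np.ndarray  # (n_bscans, rows, ascans)
    axial_scale: float = 3.5  # µm per px
    lateral_scale: float = 14.0  # µm per px
    bscan_spacing: float = 120.0  # µm between B-scans
    enface_transform: Transform2D | None = None

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans, dtype=float)
        if self.bscans.ndim == 2:
            self.bscans = self.bscans[None]
        if self.bscans.ndim != 3:
            raise ValueError("bscans must be (n, rows, ascans)")
        for v in (self.axial_scale, self.lateral_scale, self.bscan_spacing):
            if v <= 0:
                raise ValueError("scales must be positive")


@dataclass
class LayerSegmentation:
    """Fractional boundary rows per A-scan per B-scan, NaN = undefined."""

    boundaries: dict[str, np.ndarray]  # each (n_bscans, n_ascans)
    quality: np.ndarray | None = None  # per-A-scan contrast flag

    def __post_init__(self) -> None:
        for name in BOUNDARIES:
            if name not in self.boundaries:
                raise ValueError(f"missing boundary {name}")
        shapes = {b.shape for b in self.boundaries.values()}
        if len(shapes) != 1:
            raise ValueError("boundary arrays must share one shape")
        self._enforce_ordering()

    def _enforce_ordering(self) -> None:
        """ILM <= OPL <= EZ <= RPE-BrM wherever all are defined."""
        arrs = [self.boundaries[n] for n in BOUNDARIES]
        stack = np.stack(arrs)
        defined = np.all(np.isfinite(stack), axis=0)
        ordered = np.sort(stack[:, defined], axis=0)
        for k, name in enumerate(BOUNDARIES):
            a = self.boundaries[name]
            a[defined] = ordered[k]


@dataclass
class ThicknessProfile:
    rt: np.ndarray  # (n_bscans, n_ascans) µm
    orl: np.ndarray
    lateral_scale: float
    bscan_spacing: float


# ---------------------------------------------------------------------------
# segmentation

def _active_contour_1d(
    feature: np.ndarray,
    init: np.ndarray,
    alpha: float = 0.5,
    gradient_weight: float = 1.0,
    iterations: int = 60,
    step: float = 1.0,
    seeds: dict[int, float] | None = None,
) -> np.ndarray:
    """Refine a boundary row profile on a per-column feature image.

    Classic discrete snake on an open curve y(x): at each iteration the
    curve moves up the feature's axial derivative (external force,
    weight ``gradient_weight``) and is smoothed implicitly by a
    second-difference penalty of weight ``alpha``.  Seed columns are
    hard constraints re-imposed every iteration.
    """
    rows, cols = feature.shape
    y = init.astype(float).copy()
    x_idx = np.arange(cols)
    # implicit smoothing operator (I + step*alpha*L)^-1 via tridiagonal solve
    from scipy.linalg import solveh_banded

    ab = np.zeros((2, cols))
    ab[0, 1:] = -step * alpha
    ab[1, :] = 1.0 + 2.0 * step * alpha
    ab[1, 0] = 1.0 + step * alpha
    ab[1, -1] = 1.0 + step * alpha
    dfdr = np.gradient(feature, axis=0)
    fmax = float(np.abs(dfdr).max())
    if fmax > 0:  # normalize so the external force is O(1) px per step
        dfdr = dfdr / fmax
    for _ in range(iterations):
        yc = np.clip(y, 0, rows - 1)
        f = ndimage.map_coordinates(dfdr, [yc, x_idx.astype(float)], order=1)
        y = solveh_banded(ab, y + step * gradient_weight * f)
        if seeds:
            for c, r in seeds.items():
                y[c] = r
        y = np.clip(y, 0.0, rows - 1.0)
    if seeds:
        for c, r in seeds.items():
            y[c] = r
    return y


def _profile_boundaries(profile: np.ndarray) -> dict[str, float] | None:
    """Boundary rows on a single (usually lateral-mean) A-scan profile."""
    g = np.gradient(profile)
    if g.max() <= 0 or g.min() >= 0:
        return None
    # ILM: first strong positive gradient from the top
    gpos = np.where(g > 0.25 * g.max())[0]
    if gpos.size == 0:
        return None
    ilm = float(gpos[0])
    # RPE-BrM posterior: strongest negative gradient below the brightest band
    bright = int(np.argmax(profile))
    lower = g[bright:]
    if lower.size < 2 or lower.min() >= 0:
        return None
    rpe = float(bright + int(np.argmin(lower)))
    if rpe <= ilm + 3:
        return None
    # EZ: most anterior intensity ridge in the outer half (the ridge
    # below it is the RPE band itself)
    lo = int(ilm + 0.5 * (rpe - ilm))
    hi = int(rpe) - 1
    ez = float("nan")
    if hi - lo >= 3:
        from scipy.signal import find_peaks

        seg_col = profile[lo:hi]
        prom = 0.1 * (seg_col.max() - seg_col.min())
        peaks, _ = find_peaks(seg_col, prominence=prom)
        ez = float(lo + peaks[0]) if peaks.size else float(
            lo + int(np.argmax(seg_col)))
    # OPL posterior: strongest negative gradient between ILM and EZ
    lo2 = int(ilm) + 2
    hi2 = int(ez) - 2 if math.isfinite(ez) else int(rpe)
    opl = float("nan")
    if hi2 - lo2 >= 2 and np.any(g[lo2:hi2] < 0):
        opl = float(lo2 + int(np.argmin(g[lo2:hi2])))
    return {"ILM": ilm, "OPL_posterior": opl, "EZ_center": ez,
            "RPEBrM_posterior": rpe}


def _initial_boundaries(bscan: np.ndarray, smooth_sigma: float = 1.5,
                        track_halfwidth: int = 12) -> dict[str, np.ndarray]:
    """Per-A-scan boundary initialization, NaN where no structure.

    Boundaries are first located on the lateral-mean profile (robust to
    speckle), then tracked per column by restricting each feature's
    extremum search to a window around the global row.
    """
    img = ndimage.gaussian_filter(bscan, (smooth_sigma, smooth_sigma * 2))
    rows, cols = img.shape
    out = {b: np.full(cols, np.nan) for b in BOUNDARIES}
    contrast = img.max(axis=0) - img.min(axis=0)
    thr = 0.05 * max(float(contrast.max()), 1e-12)
    glob = _profile_boundaries(img.mean(axis=1))
    if glob is None:
        return out
    # heavier lateral smoothing for tracking only: speckle-robust, the
    # active contour refines on the lightly smoothed feature afterwards
    wide = ndimage.gaussian_filter(bscan, (smooth_sigma, 6.0 * smooth_sigma))
    gwide = np.gradient(wide, axis=0)
    features = {"ILM": gwide, "OPL_posterior": -gwide, "EZ_center": wide,
                "RPEBrM_posterior": -gwide}
    order = [glob.get(b, float("nan")) for b in BOUNDARIES]
    for bi, name in enumerate(BOUNDARIES):
        if name == "EZ_center":
            continue  # located per column from OPL/RPE tracks below
        r0 = glob.get(name, float("nan"))
        if not math.isfinite(r0):
            continue
        # clamp the search window at the midpoint to adjacent boundaries
        # so tracking cannot jump to a neighboring (brighter) feature
        lo = int(r0) - track_halfwidth
        hi = int(r0) + track_halfwidth + 1
        prev = [v for v in order[:bi] if math.isfinite(v)]
        nxt = [v for v in order[bi + 1:] if math.isfinite(v)]
        if prev:
            lo = max(lo, int(math.ceil((r0 + prev[-1]) / 2.0)))
        if nxt:
            hi = min(hi, int(math.floor((r0 + nxt[0]) / 2.0)) + 1)
        lo = max(lo, 0)
        hi = min(hi, rows)
        if hi - lo < 1:
            continue
        win = features[name][lo:hi]
        best = lo + np.argmax(win, axis=0).astype(float)
        best[contrast <= thr] = np.nan
        out[name] = best
    # EZ: most anterior prominent ridge between each column's OPL and
    # RPE estimates (a global row fails when boundary undulation smears
    # the lateral-mean ridge into the RPE shoulder)
    from scipy.signal import find_peaks

    ez = np.full(cols, np.nan)
    for c in range(cols):
        o, rp = out["OPL_posterior"][c], out["RPEBrM_posterior"][c]
        if not (math.isfinite(o) and math.isfinite(rp)):
            continue
        lo = int(o + 0.3 * (rp - o))
        hi = int(rp) - 2
        if hi - lo < 3:
            continue
        prof = wide[lo:hi, c]
        prom = 0.1 * max(float(prof.max() - prof.min()), 1e-12)
        peaks, _ = find_peaks(prof, prominence=prom)
        ez[c] = float(lo + peaks[0]) if peaks.size else float(
            lo + int(np.argmax(prof)))
    out["EZ_center"] = ez
    return out


def _interp_nan(y: np.ndarray) -> np.ndarray:
    out = y.copy()
    bad = ~np.isfinite(out)
    if bad.all():
        return out
    x = np.arange(out.size)
    out[bad] = np.interp(x[bad], x[~bad], out[~bad])
    return out


def segment_layers(
    volume: OCTVolume,
    seeds: dict[str, dict[int, dict[int, float]]] | None = None,
    alpha: float = 0.5,
    gradient_weight: float = 1.0,
    smooth_sigma: float = 1.5,
) -> LayerSegmentation:
    """Segment the four boundaries on every B-scan of a volume.

    ``seeds`` optionally gives hard constraints as
    ``{boundary: {bscan_index: {ascan: row, ...}}}``; the refined
    contour interpolates seed points exactly.  A-scans without
    detectable gradient structure are left NaN (undefined).
    """
    n, rows, cols = volume.bscans.shape
    out = {b: np.full((n, cols), np.nan) for b in BOUNDARIES}
    quality = np.zeros((n, cols), dtype=bool)
    for bi in range(n):
        bscan = volume.bscans[bi]
        img = ndimage.gaussian_filter(bscan, (smooth_sigma, smooth_sigma * 2))
        grad = np.gradient(img, axis=0)
        init = _initial_boundaries(bscan, smooth_sigma)
        defined = np.isfinite(init["ILM"]) & np.isfinite(init["RPEBrM_posterior"])
        if not defined.any():
            continue
        quality[bi] = defined
        features = {
            "ILM": grad,
            "OPL_posterior": -grad,
            "EZ_center": img,  # ridge, not edge
            "RPEBrM_posterior": -grad,
        }
        for name in BOUNDARIES:
            y0 = _interp_nan(init[name])
            if not np.isfinite(y0).any():
                continue
            s = None
            if seeds and name in seeds and bi in seeds[name]:
                s = {int(c): float(r) for c, r in seeds[name][bi].items()}
            y = _active_contour_1d(
                features[name], y0, alpha=alpha,
                gradient_weight=gradient_weight, seeds=s,
            )
            y[~defined] = np.nan
            if s:
                for c, r in s.items():
                    y[c] = r
            out[name][bi] = y
    return LayerSegmentation(boundaries=out, quality=quality)


def thickness_profile(seg: LayerSegmentation, volume: OCTVolume
                      ) -> ThicknessProfile:
    """RT and ORL in µm per A-scan from fractional boundary rows."""
    ilm = seg.boundaries["ILM"]
    opl = seg.boundaries["OPL_posterior"]
    rpe = seg.boundaries["RPEBrM_posterior"]
    rt = (rpe - ilm) * volume.axial_scale
    orl = (rpe - opl) * volume.axial_scale
    return ThicknessProfile(
        rt=rt, orl=orl,
        lateral_scale=volume.lateral_scale,
        bscan_spacing=volume.bscan_spacing,
    )


def extract_thickness_at(
    profile: ThicknessProfile,
    rmap: RetinalMap,
    volume: OCTVolume,
    offsets_nasal_mm: tuple[float, ...] = (2.5, 3.0, 3.5),
    window: int = 10,
    oct_layer: str = "oct_enface",
) -> list[dict]:
    """Mean RT/ORL over a window of A-scans at nasal offsets from the fovea.

    For each offset the foveal center is displaced along the nasal
    meridian in the common frame, projected into en-face OCT
    coordinates (x = A-scan, y = B-scan index), and RT/ORL are averaged
    over ``window`` A-scans centered there.  Partial windows (at the
    scan edge) are flagged.
    """
    if rmap.foveal_center is None:
        raise ValueError("foveal center not set")
    if window < 1:
        raise ValueError("window must be >= 1")
    # unit vector toward nasal retina in the common frame
    x_is_temporal = rmap.anatomical_x or rmap.eye == "OS"
    nasal = np.array([-1.0, 0.0]) if x_is_temporal else np.array([1.0, 0.0])
    layer = rmap.layers[oct_layer]
    inv = layer.to_common.inverse()
    n_b, n_a = profile.rt.shape
    results = []
    for off in offsets_nasal_mm:
        p_um = rmap.foveal_center + nasal * off * 1000.0
        px = inv.apply(p_um)
        ascan = int(round(px[0]))
        bscan = int(round(px[1]))
        if not (0 <= bscan < n_b):
            results.append({"offset_mm": off, "rt": float("nan"),
                            "orl": float("nan"), "n_defined": 0,
                            "partial": True})
            continue
        lo = ascan - window // 2
        hi = lo + window
        partial = lo < 0 or hi > n_a
        lo, hi = max(lo, 0), min(hi, n_a)
        rt_w = profile.rt[bscan, lo:hi]
        orl_w = profile.orl[bscan, lo:hi]
        n_def = int(np.isfinite(rt_w).sum())
        results.append({
            "offset_mm": float(off),
            "rt": float(np.nanmean(rt_w)) if n_def else float("nan"),
            "orl": float(np.nanmean(orl_w)) if np.isfinite(orl_w).any()
            else float("nan"),
            "n_defined": n_def,
            "partial": bool(partial),
        })
    return results
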