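"""Interchange formats, the phantom session, and pipeline orchestration.

Images travel as single- or multi-page TIFF (or PNG), held internally
as float arrays in [0, 1] with the original dtype recorded for
round-trip fidelity.  A *session* is a directory of input files plus a
``session.yaml`` manifest; :func:`run_pipeline` executes the stages in
method order — desinusoid, register, montage/align, foveal anchoring,
mosaic metrics, OCT thickness, normative z-scores — echoing every
parameter to a line-delimited JSON log, and writes diff-stable CSVs
(µm quantities at 3 decimals).

:func:`create_phantom_session` materializes a fully synthetic session
(known ground truth, fixed seed) so the complete pipeline can run and
be verified without clinical images.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import desinusoid as dsn
from . import mosaic as mos
from . import octlayers as octl
from . import register as reg
from . import stats as st
from . import synthetic as syn
from .montage import RetinalMap, Transform2D
from .scale import Biometry, ModalityScale, compute_rmf, microns_per_pixel

__all__ = [
    "load_image",
    "save_image",
    "load_stack",
    "save_stack",
    "SessionManifest",
    "create_phantom_session",
    "run_pipeline",
]

_DTYPE_MAX = {"uint8": 255.0, "uint16": 65535.0}


def load_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a grayscale image as float in [0, 1] plus dtype metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> grayscale
        arr = arr[..., :3].mean(axis=-1)
    meta = {"dtype": str(arr.dtype), "path": str(path)}
    if str(arr.dtype) in _DTYPE_MAX:
        out = arr.astype(float) / _DTYPE_MAX[str(arr.dtype)]
    else:
        out = arr.astype(float)
    return out, meta


def save_image(path: str | Path, image: np.ndarray, dtype: str = "float32") -> None:
    path = Path(path)
    img = np.asarray(image)
    if dtype in _DTYPE_MAX:
        img = np.clip(img, 0.0, 1.0)
        img = np.round(img * _DTYPE_MAX[dtype]).astype(dtype)
    else:
        img = img.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a multi-page TIFF as an (n, h, w) float stack in [0, 1]."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    meta = {"dtype": str(arr.dtype), "path": str(path), "frame_count": len(arr)}
    if str(arr.dtype) in _DTYPE_MAX:
        return arr.astype(float) / _DTYPE_MAX[str(arr.dtype)], meta
    return arr.astype(float), meta


def save_stack(path: str | Path, stack: np.ndarray, dtype: str = "float32") -> None:
    img = np.asarray(stack)
    if dtype in _DTYPE_MAX:
        img = np.round(np.clip(img, 0, 1) * _DTYPE_MAX[dtype]).astype(dtype)
    else:
        img = img.astype(dtype)
    tifffile.imwrite(Path(path), img)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class SessionManifest:
    """Subject/eye identifiers, file references and the processing log."""

    root: Path
    subject: str = "phantom"
    eye: str = "OD"
    seed: int = 0
    files: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    @classmethod
    def load(cls, root: str | Path) -> "SessionManifest":
        root = Path(root)
        obj = yaml.safe_load((root / "session.yaml").read_text())
        m = cls(
            root=root,
            subject=obj.get("subject", "phantom"),
            eye=obj.get("eye", "OD"),
            seed=int(obj.get("seed", 0)),
            files=obj.get("files", {}),
            params=obj.get("params", {}),
        )
        for key, rel in m.files.items():
            if not (root / rel).exists():
                raise FileNotFoundError(f"manifest file {key!r} missing: {rel}")
        return m

    def save(self) -> None:
        obj = {
            "subject": self.subject,
            "eye": self.eye,
            "seed": self.seed,
            "files": self.files,
            "params": self.params,
        }
        (self.root / "session.yaml").write_text(yaml.safe_dump(obj, sort_keys=True))

    def log_step(self, operation: str, **params) -> None:
        self.log.append({"operation": operation, **params})
        with (self.root / "processing_log.jsonl").open("a") as fh:
            fh.write(json.dumps({"operation": operation, **params},
                                sort_keys=True, default=str) + "\n")


def create_phantom_session(root: str | Path, seed: int = 0) -> SessionManifest:
    """Write a complete synthetic session to ``root``.

    Contents: a distorted Ronchi ruling, an AOSLO frame sequence (the
    mosaic rendering passed through eye motion, the sinusoidal scan map
    and noise), an OCT volume with sidecar scales, a normative table,
    biometry config and ground-truth files.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    spec = syn.PhantomSpec(
        seed=seed,
        density=15000.0,
        field_um=150.0,
        microns_per_pixel=0.6,
        dark_cone_fraction=0.2,
        n_frames=24,
        motion_amplitude_px=3.0,
        snr=10.0,
        oct_shape=(5, 224, 256),
        oct_boundary_wave_px=2.0,
        oct_speckle_snr=6.0,
        ruling_shape=(48, 250),
        ruling_lines=12,
        ruling_theta=0.8,
    )
    truth = syn.gen_mosaic(spec)
    channels = syn.render_channels(truth["centers"], truth["dark"], spec)
    frames = syn.gen_frames(channels["confocal"], spec)

    # pass every frame through the sinusoidal scan map so the
    # desinusoid stage has real work to do
    stack = frames["stack"].frames
    h, w = stack.shape[1:]
    cols = np.arange(w, dtype=float)
    pos_px = syn.scan_position(cols, w, spec.ruling_theta, 0.0) * (w - 1)
    from scipy import ndimage as ndi

    distorted = np.stack([
        ndi.map_coordinates(
            f,
            [np.broadcast_to(np.arange(h, dtype=float)[:, None], (h, w)),
             np.broadcast_to(pos_px[None, :], (h, w))],
            order=1, mode="nearest",
        )
        for f in stack
    ])

    ruling = syn.gen_ruling(syn.PhantomSpec(
        seed=seed, ruling_shape=(48, w), ruling_lines=12,
        ruling_theta=spec.ruling_theta,
    ))
    oct_ph = syn.gen_oct(spec)
    normative = syn.gen_normative(spec)

    save_stack(root / "frames.tif", np.clip(distorted, 0, 1), dtype="uint16")
    save_image(root / "ruling.tif", np.clip(ruling["image"], 0, 1), dtype="uint16")
    save_stack(root / "oct.tif", np.clip(oct_ph["volume"].bscans / 2.0, 0, 1),
               dtype="uint16")
    (root / "oct.json").write_text(json.dumps({
        "axial_um_per_px": oct_ph["volume"].axial_scale,
        "lateral_um_per_px": oct_ph["volume"].lateral_scale,
        "bscan_spacing_um": oct_ph["volume"].bscan_spacing,
    }, indent=1))
    normative.table.to_csv(root / "normative.csv", index=False)
    np.savetxt(root / "truth_centers.csv",
               np.column_stack([truth["centers"], truth["dark"]]),
               delimiter=",", header="x_um,y_um,dark", comments="", fmt="%.3f")

    m = SessionManifest(
        root=root, subject="phantom", eye="OD", seed=seed,
        files={
            "frames": "frames.tif",
            "ruling": "ruling.tif",
            "oct": "oct.tif",
            "oct_sidecar": "oct.json",
            "normative": "normative.csv",
        },
        params={
            "axial_length_mm": 24.0,
            "fov_deg": None,  # scale given directly for the phantom
            "microns_per_pixel": spec.microns_per_pixel,
            "reference_frame": 0,
            "top_n": 12,
            "strip_height": 16,
            "search_radius": 6,
            "expected_spacing_um": truth["spacing_um"],
            "roi_um": 100.0,
            "fovea_oct_px": [128.0, 2.0],
            "thickness_offsets_mm": [0.5, 1.0],
            "thickness_window": 10,
        },
    )
    m.save()
    return m


def run_pipeline(manifest: SessionManifest, out_dir: str | Path | None = None
                 ) -> dict:
    """Run the full phantom-session pipeline; returns result paths.

    Stages: desinusoid fit+apply -> frame ranking + strip registration +
    averaging -> map assembly (AOSLO layer + OCT en-face layer) ->
    foveal anchoring -> OCT layer segmentation and nasal thickness
    extraction -> mosaic detection and Voronoi metrics in the central
    ROI -> z-scores against the session's normative table.  Every stage
    logs its parameters; outputs are deterministic for a fixed session.
    """
    p = manifest.params
    root = manifest.root
    out = Path(out_dir) if out_dir else root / "results"
    out.mkdir(parents=True, exist_ok=True)

    # --- scale
    bio = Biometry(axial_length=float(p.get("axial_length_mm", 24.0)))
    model = compute_rmf(bio, "four_surface")
    um_px = float(p["microns_per_pixel"])
    scale = ModalityScale("aoslo_confocal", um_px, um_px)
    manifest.log_step("scale", rmf=model.rmf, microns_per_pixel=um_px)

    # --- desinusoid
    ruling, _ = load_image(root / manifest.files["ruling"])
    lut = dsn.fit_desinusoid(ruling)
    lut.to_json(out / "desinusoid_lut.json")
    frames, _ = load_stack(root / manifest.files["frames"])
    frames = np.stack([dsn.apply_desinusoid(f, lut) for f in frames])
    manifest.log_step("desinusoid", residual_px=lut.residual,
                      **{k: v for k, v in lut.fit_params.items()})

    # --- register
    stack = reg.FrameStack(frames=frames, scale=scale)
    ranked = reg.rank_frames_by_ncc(stack, int(p.get("reference_frame", 0)))
    top_n = min(int(p.get("top_n", 50)), stack.frame_count)
    order = [i for i, _ in ranked]
    ref = stack.frames[int(p.get("reference_frame", 0))]
    offsets = [
        reg.strip_register(
            f, ref,
            strip_height=int(p.get("strip_height", 32)),
            search_radius=int(p.get("search_radius", 12)),
        )
        for f in stack.frames
    ]
    avg, cov = reg.average_registered(stack, offsets, top_n=top_n, order=order)
    filled = np.nan_to_num(avg, nan=float(np.nanmean(avg)))
    save_image(out / "registered.tif", np.clip(filled, 0, 1), dtype="uint16")
    manifest.log_step("register", top_n=top_n,
                      mean_score=float(np.mean([s for _, s in ranked[:top_n]])))

    # --- map assembly
    oct_stack, _ = load_stack(root / manifest.files["oct"])
    sidecar = json.loads((root / manifest.files["oct_sidecar"]).read_text())
    volume = octl.OCTVolume(
        bscans=oct_stack,
        axial_scale=float(sidecar["axial_um_per_px"]),
        lateral_scale=float(sidecar["lateral_um_per_px"]),
        bscan_spacing=float(sidecar["bscan_spacing_um"]),
    )
    enface = volume.bscans.mean(axis=1)  # (n_bscans, n_ascans)
    rmap = RetinalMap(eye=manifest.eye, rmf=model.rmf)
    rmap.add_layer("aoslo_confocal", filled, scale)
    oct_scale = ModalityScale("oct_enface", volume.lateral_scale,
                              volume.bscan_spacing)
    rmap.add_layer("oct_enface", enface, oct_scale)
    fx, fy = p.get("fovea_oct_px", [enface.shape[1] / 2, enface.shape[0] / 2])
    from .montage import set_foveal_center

    set_foveal_center(rmap, (float(fx), float(fy)), "oct_enface")
    manifest.log_step("map", foveal_center_um=list(map(float,
                                                       rmap.foveal_center)))

    # --- OCT thickness
    seg = octl.segment_layers(volume)
    profile = octl.thickness_profile(seg, volume)
    volume.enface_transform = rmap.layers["oct_enface"].to_common
    offs = tuple(float(v) for v in p.get("thickness_offsets_mm", (2.5, 3.0, 3.5)))
    thick = octl.extract_thickness_at(
        profile, rmap, volume, offsets_nasal_mm=offs,
        window=int(p.get("thickness_window", 10)),
    )
    tdf = pd.DataFrame(thick)
    tdf.insert(0, "subject", manifest.subject)
    tdf.insert(1, "eye", manifest.eye)
    tdf.to_csv(out / "thickness.csv", index=False, float_format="%.3f")
    manifest.log_step("oct", offsets_mm=list(offs))

    # --- mosaic metrics in the central ROI
    exp_sp = float(p.get("expected_spacing_um", 8.0))
    cones = mos.detect_cells(filled, "cone", exp_sp, scale)
    cones.to_common = rmap.layers["aoslo_confocal"].to_common
    roi_w = float(p.get("roi_um", 100.0))
    h, w = filled.shape
    center_um = rmap.from_layer("aoslo_confocal",
                                np.array([w / 2.0, h / 2.0]))
    ecc_mm, ecc_deg, meridian = (0.0, 0.0, "temporal")
    try:
        from .montage import eccentricity_of

        ecc_mm, ecc_deg, meridian = eccentricity_of(rmap, center_um)
    except ValueError:
        pass
    roi = mos.ROI(center=tuple(center_um), width=roi_w, height=roi_w,
                  eccentricity_mm=ecc_mm, meridian=meridian)
    vm = mos.voronoi_metrics(cones, roi, expected_spacing=exp_sp)
    mdf = pd.DataFrame([{
        "subject": manifest.subject,
        "eye": manifest.eye,
        "cell_type": "cone",
        "eccentricity_mm": ecc_mm,
        "meridian": meridian,
        "n_marked": vm.n_marked,
        "n_bounded": vm.n_bounded,
        "bounded_density_mm2": vm.bounded_density,
        "mean_cell_area_um2": vm.mean_cell_area,
        "mean_spacing_um": vm.mean_spacing,
        "low_quality": vm.low_quality,
    }])
    mdf.to_csv(out / "metrics.csv", index=False, float_format="%.3f")
    manifest.log_step("mosaic", n_cells=cones.n_cells,
                      bounded_density=vm.bounded_density)

    # --- z-scores
    table = st.NormativeTable.from_csv(root / manifest.files["normative"])
    zrows = []
    if not vm.low_quality:
        zr = st.zscore(vm.bounded_density, table, "cone_density",
                       round(ecc_mm * 2) / 2.0, meridian
                       if meridian != "center" else "temporal",
                       tolerance_mm=0.3)
        zrows.append({"measure": "cone_density", "value": zr.value,
                      "z": zr.z, "abnormal": zr.abnormal})
    for row in thick:
        for meas in ("rt", "orl"):
            v = row[meas]
            if math.isfinite(v):
                zr = st.zscore(v, table, meas,
                               round(row["offset_mm"] * 2) / 2.0, "nasal",
                               tolerance_mm=0.3)
                zrows.append({"measure": meas, "value": zr.value,
                              "z": zr.z, "abnormal": zr.abnormal})
    zdf = pd.DataFrame(zrows)
    zdf.to_csv(out / "zscores.csv", index=False, float_format="%.3f")
    manifest.log_step("stats", n_zscores=len(zrows))

    return {
        "registered": out / "registered.tif",
        "thickness": out / "thickness.csv",
        "metrics": out / "metrics.csv",
        "zscores": out / "zscores.csv",
        "lut": out / "desinusoid_lut.json",
    }
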