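"""Synthetic en-face OCTA angiograms with known FAZ ground truth.

Real OCTA exports carry no ground truth: the FAZ has no marked boundary,
and method validation in the clinic rests on cross-method agreement.  This
module generates angiogram-like images in which the foveal avascular zone
is known exactly, so both segmentation paths can be scored against truth
and the agreement/longitudinal statistics can be exercised on cohorts with
a controlled effect structure.

An image is built in the 768×768 source frame (so the 512×512 foveal crop
is exercised as in real exports): a star-convex avascular polygon around
the frame center whose rasterized pixel area matches a requested mm² area
under the magnification-corrected scale; a capillary mesh of biased random
walks outside it, plus ring capillaries terminating at the boundary;
a perifoveal *flow-signal falloff* — terminal capillary loops carry slow
flow, so their decorrelation signal fades over ~15 px just outside the
anatomic boundary, which is why binarized angiograms show a dark zone
slightly larger than the true avascular area; Gaussian blur; multiplicative
speckle; 8-bit quantization.

Ground truth is the vessel-free polygon interior, reported in crop
coordinates as a :class:`~fazkit.script_segmenter.FazRegion`.

Cohorts follow a longitudinal design: n eyes × 4 visits × 3 plexuses with
per-plexus visit-mean trajectories, a between-eye random effect, and
within-eye visit noise.  Default trajectories encode a post-intervention
FAZ shrinkage in the superficial plexus at visits 3–4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import AngiogramImage, BinaryMask, MeasurementTable, ScanMetadata, write_metadata_csv
from .scaling import ScalingConfig, corrected_scale
from .script_segmenter import FazRegion, ScriptPipelineConfig, _region_boundary

__all__ = [
    "SyntheticSpec",
    "CohortSpec",
    "simulate_angiogram",
    "simulate_cohort_areas",
    "simulate_cohort",
    "training_annotations",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic angiogram.

    ``faz_area_mm2`` is the true avascular area; the default is the
    baseline superficial-plexus cohort mean.  ``vessel_density`` scales the
    total capillary path length; ``boundary_irregularity`` is the radial
    perturbation amplitude of the FAZ outline as a fraction of its radius;
    ``flow_falloff_px`` is the width (in source-frame pixels) of the
    perifoveal band over which terminal-capillary flow signal fades to
    full strength.
    """

    faz_area_mm2: float = 0.49
    plexus: str = "SVP"
    vessel_density: float = 0.35
    boundary_irregularity: float = 0.15
    noise_sigma: float = 0.30
    blur_sigma: float = 1.0
    al_mm: float = 23.79
    flow_falloff_px: float = 12.0
    image_size: int = 768
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_area_mm2 <= 0:
            raise ValueError("faz_area_mm2 must be positive")
        if not (0 < self.vessel_density <= 1):
            raise ValueError("vessel_density must be in (0, 1]")
        if self.boundary_irregularity < 0 or self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("irregularity/noise/blur must be nonnegative")


# default per-plexus visit-mean trajectories (mm²) and dispersion components
DEFAULT_TRAJECTORIES: dict[str, tuple[float, float, float, float]] = {
    "SVP": (0.49, 0.45, 0.41, 0.41),
    "IVP": (0.15, 0.14, 0.14, 0.17),
    "DVP": (0.41, 0.39, 0.37, 0.38),
}
DEFAULT_BETWEEN_SD = {"SVP": 0.20, "IVP": 0.10, "DVP": 0.18}
DEFAULT_WITHIN_SD = 0.06
MIN_TRUE_AREA_MM2 = 0.02


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic longitudinal cohort (one eye per subject)."""

    n_eyes: int = 59
    trajectories: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    between_eye_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    within_eye_sd: float = DEFAULT_WITHIN_SD
    al_mean_mm: float = 23.79
    al_sd_mm: float = 1.7
    al_bounds_mm: tuple[float, float] = (21.0, 26.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        for plexus, traj in self.trajectories.items():
            if len(traj) != 4 or any(m <= 0 for m in traj):
                raise ValueError(f"trajectory for {plexus} must be 4 positive means")
        if self.within_eye_sd < 0 or any(s < 0 for s in self.between_eye_sd.values()):
            raise ValueError("dispersion components must be nonnegative")


# ---------------------------------------------------------------------------
# single image


def _boundary_radius_fn(rng: np.random.Generator, irregularity: float):
    """Smooth periodic radial modulation r(θ)/r0 = 1 + irregularity·s(θ),
    with s a low-order random-phase harmonic sum normalized to max |s| = 1."""
    orders = np.arange(2, 6)
    amps = rng.uniform(0.2, 1.0, size=orders.size) / orders
    phases = rng.uniform(0, 2 * np.pi, size=orders.size)

    def s(theta: np.ndarray) -> np.ndarray:
        th = np.atleast_1d(np.asarray(theta, dtype=float)).ravel()
        out = np.sum(
            amps[:, None] * np.cos(orders[:, None] * th[None, :] + phases[:, None]), axis=0
        )
        return out.reshape(np.shape(theta))

    grid = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    peak = np.max(np.abs(s(grid)))
    scale = irregularity / peak if peak > 0 else 0.0

    def radius_mod(theta: np.ndarray) -> np.ndarray:
        return 1.0 + scale * s(theta)

    return radius_mod


def _walk_paths(
    rng: np.random.Generator,
    n_walkers: int,
    start_xy: np.ndarray,
    start_heading: np.ndarray,
    n_steps: int,
    heading_sd: float,
    inside_faz,
    size: int,
) -> np.ndarray:
    """Simulate biased random-walk capillary paths; each path is truncated
    at the first point inside the FAZ or outside the frame.  Returns the
    concatenated (N, 2) float array of path points, densely sampled."""
    turns = rng.normal(0.0, heading_sd, size=(n_walkers, n_steps))
    headings = start_heading[:, None] + np.cumsum(turns, axis=1)
    steps = np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    pos = start_xy[:, None, :] + np.cumsum(steps, axis=1)
    bad = (
        inside_faz(pos[..., 0], pos[..., 1])
        | (pos[..., 0] < 1)
        | (pos[..., 0] > size - 2)
        | (pos[..., 1] < 1)
        | (pos[..., 1] > size - 2)
    )
    keep = []
    for w in range(n_walkers):
        stop = np.argmax(bad[w]) if bad[w].any() else n_steps
        if stop >= 2:
            p = pos[w, :stop]
            # densify to half-pixel sampling so rounding leaves no gaps
            dense = np.empty((2 * len(p) - 1, 2))
            dense[0::2] = p
            dense[1::2] = 0.5 * (p[:-1] + p[1:])
            keep.append(dense)
    if not keep:
        return np.empty((0, 2))
    return np.concatenate(keep)


def simulate_angiogram(spec: SyntheticSpec) -> tuple[AngiogramImage, FazRegion]:
    """Generate one synthetic angiogram and its ground-truth FAZ.

    Deterministic given ``spec.seed``.  The rasterized truth area matches
    ``faz_area_mm2 / scale²`` to within 2%.  Ground truth is returned in
    the coordinates of the 512×512 foveal crop.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    cx = cy = (size - 1) / 2.0
    scale = corrected_scale(spec.al_mm, ScalingConfig())
    target_px = spec.faz_area_mm2 / scale**2

    radius_mod = _boundary_radius_fn(rng, spec.boundary_irregularity)
    r0 = float(np.sqrt(target_px / np.pi))

    # solve r0 so the rasterized star-convex interior hits the target area
    half = int(np.ceil(r0 * (1 + spec.boundary_irregularity) * 1.8 + spec.flow_falloff_px + 8))
    cfg = ScriptPipelineConfig()
    max_half = min(cx - cfg.crop_x, (cfg.crop_x + cfg.crop_w - 1) - cx) - 2
    if half > max_half:
        raise ValueError(
            f"FAZ of {spec.faz_area_mm2} mm² (radius ~{r0:.0f} px) does not fit the foveal crop"
        )
    win = np.arange(int(cx) - half, int(cx) + half + 1)
    wx, wy = np.meshgrid(win, win)
    d = np.hypot(wx - cx, wy - cy)
    theta = np.arctan2(wy - cy, wx - cx)
    mod = radius_mod(theta)
    for _ in range(12):
        area = np.count_nonzero(d <= r0 * mod)
        if abs(area - target_px) <= 0.005 * target_px:
            break
        r0 *= np.sqrt(target_px / max(area, 1))
    truth_win = d <= r0 * mod

    def inside_faz(x, y):
        dd = np.hypot(x - cx, y - cy)
        th = np.arctan2(y - cy, x - cx)
        return dd <= r0 * radius_mod(th)

    # --- capillary mesh -------------------------------------------------
    canvas = np.zeros((size, size), dtype=np.float64)
    widths = np.zeros((size, size), dtype=np.float64)

    n_bg = int(round(250 * spec.vessel_density / 0.35))
    start = rng.uniform(2, size - 3, size=(n_bg, 2))
    retry = inside_faz(start[:, 0], start[:, 1])
    while retry.any():
        start[retry] = rng.uniform(2, size - 3, size=(int(retry.sum()), 2))
        retry = inside_faz(start[:, 0], start[:, 1])
    bg_pts = _walk_paths(
        rng, n_bg, start, rng.uniform(0, 2 * np.pi, n_bg), 180, 0.30, inside_faz, size
    )

    # ring capillaries: seeded on an annulus outside the FAZ, biased inward,
    # terminating at the anatomic boundary; one terminal loop per ~7 px of
    # boundary circumference so the perifoveal mesh stays lace-like
    n_ring = max(40, int(round(2 * np.pi * r0 / 7.0)))
    ring_theta = rng.uniform(0, 2 * np.pi, n_ring)
    ring_r = r0 * radius_mod(ring_theta) * rng.uniform(1.25, 1.9, n_ring)
    ring_start = np.stack([cx + ring_r * np.cos(ring_theta), cy + ring_r * np.sin(ring_theta)], axis=1)
    inward = np.arctan2(cy - ring_start[:, 1], cx - ring_start[:, 0])
    ring_pts = _walk_paths(
        rng, n_ring, ring_start, inward + rng.normal(0, 0.3, n_ring), 80, 0.25, inside_faz, size
    )

    for pts in (bg_pts, ring_pts):
        if len(pts) == 0:
            continue
        xi = np.clip(np.rint(pts[:, 0]).astype(int), 0, size - 1)
        yi = np.clip(np.rint(pts[:, 1]).astype(int), 0, size - 1)
        inten = rng.uniform(150, 255, size=len(pts))
        np.maximum.at(canvas, (yi, xi), inten)
        wsel = rng.random(len(pts))
        np.maximum.at(widths, (yi, xi), np.where(wsel < 0.70, 1.0, np.where(wsel < 0.95, 2.0, 3.0)))

    # widen vessels: grayscale dilation applied where the drawn width asks for it
    wide2 = ndimage.maximum_filter(np.where(widths >= 2, canvas, 0.0), size=3)
    wide3 = ndimage.maximum_filter(np.where(widths >= 3, canvas, 0.0), size=5)
    canvas = np.maximum(canvas, np.maximum(wide2 * (wide2 > 0), wide3 * (wide3 > 0)))

    # --- perifoveal flow-signal falloff ---------------------------------
    g = np.ones((size, size))
    t = np.clip((d - r0 * mod) / max(spec.flow_falloff_px, 1e-9), 0.0, 1.0)
    g[np.ix_(win, win)] = t * t * (3 - 2 * t)  # smoothstep, 0 at boundary
    canvas *= g

    # --- background floor, blur, speckle, quantization ------------------
    img = canvas + np.clip(rng.normal(22.0, 7.0, canvas.shape), 0, None)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img *= np.exp(rng.normal(0.0, spec.noise_sigma, img.shape))
    img8 = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    meta = ScanMetadata(
        subject_id="SYN",
        eye="OD",
        visit=1,
        plexus=spec.plexus,
        axial_length_mm=spec.al_mm,
        quality_index=30,
    )
    angiogram = AngiogramImage(pixels=img8, metadata=meta)

    # ground truth in crop coordinates
    truth_src = np.zeros((size, size), dtype=bool)
    truth_src[np.ix_(win, win)] = truth_win
    truth_crop = truth_src[cfg.crop_y : cfg.crop_y + cfg.crop_h, cfg.crop_x : cfg.crop_x + cfg.crop_w]
    mask = BinaryMask.from_bool(truth_crop)
    truth = FazRegion(
        mask=mask,
        pixel_count=mask.foreground_count,
        boundary=_region_boundary(truth_crop),
        method="truth",
        area_mm2=mask.foreground_count * scale**2,
    )
    return angiogram, truth


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort_areas(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the latent cohort structure without rendering images.

    Returns ``(eyes, areas)``: one row per eye (subject, eye, axial length,
    quality index) and one row per eye × visit × plexus with the true FAZ
    area in mm² (trajectory mean + between-eye effect + within-eye visit
    noise, floored at a small positive area).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.al_bounds_mm
    a, b = (lo - spec.al_mean_mm) / spec.al_sd_mm, (hi - spec.al_mean_mm) / spec.al_sd_mm
    als = stats.truncnorm.rvs(a, b, loc=spec.al_mean_mm, scale=spec.al_sd_mm,
                              size=spec.n_eyes, random_state=rng)
    eyes = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(spec.n_eyes)],
            "eye": ["OD" if i % 2 == 0 else "OS" for i in range(spec.n_eyes)],
            "axial_length_mm": als,
            "quality_index": rng.integers(16, 41, size=spec.n_eyes),
        }
    )
    rows = []
    for i in range(spec.n_eyes):
        for plexus, traj in spec.trajectories.items():
            eye_effect = rng.normal(0.0, spec.between_eye_sd.get(plexus, 0.0))
            noise = rng.normal(0.0, spec.within_eye_sd, size=4)
            for v in range(4):
                true_area = max(MIN_TRUE_AREA_MM2, traj[v] + eye_effect + noise[v])
                rows.append(
                    {
                        "subject_id": eyes.loc[i, "subject_id"],
                        "eye": eyes.loc[i, "eye"],
                        "visit": v + 1,
                        "plexus": plexus,
                        "true_area_mm2": true_area,
                    }
                )
    return eyes, pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    render_images: bool = True,
    image_kwargs: dict | None = None,
) -> dict:
    """Simulate a full longitudinal cohort.

    With ``render_images`` an angiogram TIFF is written per scan together
    with the metadata sidecar (``meta.csv``) and the ground-truth area
    table (``truth.csv``); without, only the tables are produced (fast path
    for statistical simulations).  Returns a dict with ``eyes``, ``truth``
    (DataFrame with true areas and, when rendered, file names) and
    ``n_scans``.
    """
    import tifffile

    eyes, areas = simulate_cohort_areas(spec)
    rng = np.random.default_rng(spec.seed + 1)
    kwargs = dict(image_kwargs or {})
    meta_entries: dict[str, ScanMetadata] = {}
    files = []
    if render_images:
        if out_dir is None:
            raise ValueError("out_dir is required when rendering images")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for _, row in areas.iterrows():
            eye_row = eyes[eyes["subject_id"] == row["subject_id"]].iloc[0]
            img_seed = int(rng.integers(0, 2**31 - 1))
            sspec = SyntheticSpec(
                faz_area_mm2=float(row["true_area_mm2"]),
                plexus=row["plexus"],
                al_mm=float(eye_row["axial_length_mm"]),
                seed=img_seed,
                **kwargs,
            )
            angio, _truth = simulate_angiogram(sspec)
            fname = f"{row['subject_id']}_{row['eye']}_v{row['visit']}_{row['plexus']}.tif"
            tifffile.imwrite(out_dir / fname, angio.pixels)
            meta_entries[fname] = ScanMetadata(
                subject_id=row["subject_id"],
                eye=row["eye"],
                visit=int(row["visit"]),
                plexus=row["plexus"],
                axial_length_mm=float(eye_row["axial_length_mm"]),
                quality_index=int(eye_row["quality_index"]),
            )
            files.append(fname)
        areas = areas.assign(file=files)
        write_metadata_csv(meta_entries, out_dir / "meta.csv")
        areas.to_csv(out_dir / "truth.csv", index=False, float_format="%.17g")
    return {"eyes": eyes, "truth": areas, "n_scans": len(areas)}


# ---------------------------------------------------------------------------
# classifier training strokes


def training_annotations(truth: FazRegion, image_id: str = "train", n_per_class: int = 3):
    """Linear training strokes derived from a ground-truth FAZ.

    Emulates the interactive training workflow: a few line segments drawn
    in representative areas — inside the avascular zone and across the
    surrounding vascular mesh — labelled accordingly.  Strokes are
    horizontal chords at fixed fractions of the FAZ radius, in crop
    coordinates.
    """
    from .io import TrainingAnnotation

    fg = truth.mask.as_bool()
    ys, xs = np.nonzero(fg)
    cx, cy = float(xs.mean()), float(ys.mean())
    r_eq = float(np.sqrt(len(xs) / np.pi))
    h, w = fg.shape

    def clamp_pt(x, y):
        return (float(np.clip(x, 0, w - 1)), float(np.clip(y, 0, h - 1)))

    # per-angle boundary radius by radial scan of the truth mask
    angles = np.linspace(0, 2 * np.pi, 28, endpoint=False)
    rmax_scan = int(min(h, w) / 2) - 1
    radii = np.arange(1, rmax_scan)

    def boundary_radius(theta: float) -> float:
        px = np.clip(np.rint(cx + radii * np.cos(theta)).astype(int), 0, w - 1)
        py = np.clip(np.rint(cy + radii * np.sin(theta)).astype(int), 0, h - 1)
        inside = fg[py, px]
        return float(radii[np.nonzero(inside)[0].max()]) if inside.any() else r_eq

    b_rad = np.array([boundary_radius(t) for t in angles])

    def ring(offset_px: float, label: str) -> TrainingAnnotation:
        pts = [
            clamp_pt(cx + f * np.cos(t), cy + f * np.sin(t))
            for t, f in zip(angles, b_rad + offset_px)
        ]
        pts.append(pts[0])
        return TrainingAnnotation(polyline=tuple(pts), label=label, source_image_id=image_id)

    def chord(dy: float, half: float, label: str) -> TrainingAnnotation:
        y = float(np.clip(cy + dy, 0, h - 1))
        return TrainingAnnotation(
            polyline=(clamp_pt(cx - half, y), clamp_pt(cx + half, y)),
            label=label,
            source_image_id=image_id,
        )

    def interior_chord(dy: float, margin: float = 0.92) -> TrainingAnnotation:
        """Horizontal chord spanning ``margin`` of the truth extent in its row."""
        y = int(np.clip(round(cy + dy), 0, h - 1))
        cols = np.nonzero(fg[y])[0]
        x0, x1 = float(cols.min()), float(cols.max())
        mid, half = (x0 + x1) / 2.0, (x1 - x0) / 2.0 * margin
        return TrainingAnnotation(
            polyline=(clamp_pt(mid - half, y), clamp_pt(mid + half, y)),
            label="avascular",
            source_image_id=image_id,
        )

    anns = [
        # avascular: a freehand ring tracing the boundary from just inside,
        # plus chords spanning the zone, so boundary-adjacent avascular
        # texture is represented in every direction
        ring(-2.0, "avascular"),
        interior_chord(0.0),
        interior_chord(-0.45 * r_eq),
        # vascular: a freehand ring just past the perifoveal signal falloff,
        # one through the dense mesh, and a far chord
        ring(18.0, "vascular"),
        ring(45.0, "vascular"),
        chord(2.4 * r_eq + 30.0, 1.8 * r_eq, "vascular"),
    ]
    return anns
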