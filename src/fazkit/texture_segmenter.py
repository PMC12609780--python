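"""Trainable pixel-classification FAZ segmentation.

A supervised alternative to the morphological script: each pixel of the
512×512 foveal crop is described by local texture statistics (mean, median,
variance and Shannon entropy over square neighborhoods at several radii,
plus the raw intensity), a random-forest classifier is trained from a few
labelled polylines drawn on one training image — vascular strokes over
vessels, avascular strokes inside the FAZ — and the saved model is applied
unchanged to every image in the dataset.  The FAZ is the connected
avascular component at the image center.

Feature statistics are computed exactly: means and variances from integer
integral images, medians and entropies from per-intensity integral
histograms, all with edge-replicated borders so every window has the full
(2r+1)² support.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.draw import line as _bresenham_line
from sklearn.ensemble import RandomForestClassifier

from .io import BinaryMask, TrainingAnnotation
from .script_segmenter import FazRegion, FazSeedFailure, _region_boundary

__all__ = [
    "FeatureStack",
    "PixelClassifierModel",
    "DEFAULT_RADII",
    "compute_features",
    "rasterize_annotations",
    "train_classifier",
    "classify_image",
    "extract_faz",
    "save_model",
    "load_model",
]

DEFAULT_RADII = (1, 2, 4, 8, 16)
STAT_NAMES = ("mean", "median", "variance", "entropy")
MODEL_FORMAT_VERSION = 1


@dataclass
class FeatureStack:
    """Per-pixel feature vectors over one image.

    ``data`` has shape (H, W, n_features); ``feature_names`` gives the
    ordered feature labels ("intensity", then the four statistics per
    radius).
    """

    data: np.ndarray
    feature_names: list[str]
    radii: tuple[int, ...]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def matrix(self) -> np.ndarray:
        """Flatten to (H·W, n_features) row-major."""
        return self.data.reshape(-1, self.n_features)


def _integral(a: np.ndarray) -> np.ndarray:
    """2-D integral image with a leading zero row/column."""
    out = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(a, axis=0, dtype=np.int64), axis=1, out=out[1:, 1:])
    return out


def _box_sum(integral: np.ndarray, h: int, w: int, pad: int, r: int) -> np.ndarray:
    """(2r+1)² window sums for every pixel of the h×w image, given the
    integral image of the version padded by ``pad`` on each side."""
    o = pad - r
    k = 2 * r + 1
    return (
        integral[o + k : o + k + h, o + k : o + k + w]
        - integral[o : o + h, o + k : o + k + w]
        - integral[o + k : o + k + h, o : o + w]
        + integral[o : o + h, o : o + w]
    )


def compute_features(image: np.ndarray, radii: tuple[int, ...] = DEFAULT_RADII) -> FeatureStack:
    """Compute the texture feature stack of an 8-bit image.

    For each radius r the statistics are taken over the (2r+1)×(2r+1)
    window centered on the pixel, with edge replication at the borders.
    Variance is the population variance of the window; entropy is the
    Shannon entropy (base 2, in bits) of the window's 256-bin intensity
    histogram.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("compute_features expects an 8-bit image")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    h, w = arr.shape
    rmax = max(radii)
    padded = np.pad(arr, rmax, mode="edge").astype(np.int64)

    i1 = _integral(padded)
    i2 = _integral(padded * padded)

    n_feat = 1 + len(STAT_NAMES) * len(radii)
    data = np.empty((h, w, n_feat), dtype=np.float64)
    names = ["intensity"]
    data[:, :, 0] = arr

    counts = {r: (2 * r + 1) ** 2 for r in radii}
    col = 1
    cols: dict[tuple[int, str], int] = {}
    for r in radii:
        n = counts[r]
        s1 = _box_sum(i1, h, w, rmax, r)
        s2 = _box_sum(i2, h, w, rmax, r)
        mean = s1 / n
        var = s2 / n - mean**2
        for stat in STAT_NAMES:
            cols[(r, stat)] = col
            names.append(f"{stat}_r{r}")
            col += 1
        data[:, :, cols[(r, "mean")]] = mean
        data[:, :, cols[(r, "variance")]] = np.maximum(var, 0.0)

    # median and entropy via per-intensity integral histograms: one pass
    # over the occupied intensity levels serves every radius
    ent = {r: np.zeros((h, w)) for r in radii}
    cum = {r: np.zeros((h, w), dtype=np.int64) for r in radii}
    med = {r: np.zeros((h, w), dtype=np.int16) for r in radii}
    found = {r: np.zeros((h, w), dtype=bool) for r in radii}
    # entropy lookup: contribution of a count c out of n
    ent_lut = {}
    for r in radii:
        n = counts[r]
        c = np.arange(n + 1, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            lut = -(c / n) * np.log2(c / n)
        lut[0] = 0.0
        ent_lut[r] = lut
    for b in np.unique(arr):
        ib = _integral((padded == b).astype(np.int64))
        for r in radii:
            cb = _box_sum(ib, h, w, rmax, r)
            ent[r] += ent_lut[r][cb]
            cum[r] += cb
            newly = ~found[r] & (cum[r] * 2 >= counts[r] + 1)
            med[r][newly] = b
            found[r] |= newly
    for r in radii:
        data[:, :, cols[(r, "median")]] = med[r]
        data[:, :, cols[(r, "entropy")]] = ent[r]

    return FeatureStack(data=data, feature_names=names, radii=tuple(radii))


# ---------------------------------------------------------------------------
# annotations -> labelled pixels


def rasterize_annotations(
    annotations: list[TrainingAnnotation], dims: tuple[int, int]
) -> list[tuple[tuple[int, int], str]]:
    """Rasterize labelled polylines to ((x, y), label) pixel samples.

    Each polyline segment is drawn with Bresenham's algorithm.  Duplicate
    pixels keep their first label; the same pixel carrying *different*
    labels is a validation error.
    """
    h, w = dims
    seen: dict[tuple[int, int], str] = {}
    order: list[tuple[int, int]] = []
    for ann in annotations:
        verts = [(int(round(x)), int(round(y))) for x, y in ann.polyline]
        for (x, y) in verts:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"annotation vertex ({x}, {y}) outside image {w}x{h}")
        for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
            rr, cc = _bresenham_line(y0, x0, y1, x1)
            for y, x in zip(rr, cc):
                px = (int(x), int(y))
                if px in seen:
                    if seen[px] != ann.label:
                        raise ValueError(
                            f"conflicting labels at pixel {px}: "
                            f"{seen[px]!r} vs {ann.label!r}"
                        )
                else:
                    seen[px] = ann.label
                    order.append(px)
    return [(px, seen[px]) for px in order]


# ---------------------------------------------------------------------------
# model


@dataclass
class PixelClassifierModel:
    """A trained texture pixel classifier plus its feature recipe.

    The recipe (radii, feature names, expected frame) makes application
    reproducible: classification recomputes exactly the features the
    model was trained on, and a saved model refuses to run against a
    mismatching recipe.
    """

    classifier: RandomForestClassifier
    radii: tuple[int, ...]
    feature_names: list[str]
    frame_shape: tuple[int, int]
    class_order: tuple[str, str]
    n_trees: int
    seed: int
    training_accuracy: float
    provenance: dict = field(default_factory=dict)

    def fingerprint(self) -> str:
        """Hash of the model's trees and recipe; stable across classify calls."""
        payload = joblib.hash((self.classifier, self.radii, self.feature_names))
        return hashlib.sha256(str(payload).encode()).hexdigest()


def train_classifier(
    stack: FeatureStack,
    labeled: list[tuple[tuple[int, int], str]],
    n_trees: int = 100,
    seed: int = 0,
    provenance: dict | None = None,
) -> PixelClassifierModel:
    """Train the pixel classifier from labelled pixels of one feature stack.

    Both classes must be present.  Training is deterministic given
    ``seed``.  If the classifier cannot reproduce its own training labels
    with accuracy ≥ 0.95 a warning is raised: the annotations are probably
    inconsistent with the image content.
    """
    labels = {lab for _, lab in labeled}
    if labels != {"vascular", "avascular"}:
        raise ValueError(
            "need both vascular and avascular examples; got labels " + repr(sorted(labels))
        )
    xs = np.array([stack.data[y, x] for (x, y), _ in labeled])
    ys = np.array([1 if lab == "avascular" else 0 for _, lab in labeled])
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, oob_score=True
    )
    with warnings.catch_warnings():
        # small training sets can leave a few samples without OOB trees
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        clf.fit(xs, ys)
    acc = float(np.mean(clf.predict(xs) == ys))
    # resubstitution accuracy of a full-depth forest is ~1 even on shuffled
    # labels; the out-of-bag score is the honest sanity check
    oob = float(getattr(clf, "oob_score_", np.nan))
    if not np.isnan(oob) and oob < 0.95:
        warnings.warn(
            f"out-of-bag accuracy {oob:.3f} below the 0.95 sanity bound; "
            "annotations may be inconsistent",
            stacklevel=2,
        )
    return PixelClassifierModel(
        classifier=clf,
        radii=stack.radii,
        feature_names=list(stack.feature_names),
        frame_shape=stack.data.shape[:2],
        class_order=("vascular", "avascular"),
        n_trees=n_trees,
        seed=seed,
        training_accuracy=acc,
        provenance=dict(provenance or {}),
    )


def classify_image(
    image: np.ndarray, model: PixelClassifierModel
) -> tuple[np.ndarray, BinaryMask]:
    """Classify every pixel of an image with a trained model.

    Returns the probability map of the avascular class and the binary
    avascular mask at p ≥ 0.5.  The image must match the frame the model
    was trained for; features are recomputed from the model's recipe.
    """
    arr = np.asarray(image)
    if arr.shape != model.frame_shape:
        raise ValueError(
            f"image frame {arr.shape} does not match model frame {model.frame_shape}"
        )
    stack = compute_features(arr, model.radii)
    if stack.feature_names != model.feature_names:
        raise ValueError("feature recipe mismatch between model and computed stack")
    prob = model.classifier.predict_proba(stack.matrix())[:, 1].reshape(arr.shape)
    return prob, BinaryMask.from_bool(prob >= 0.5)


def extract_faz(
    avascular_mask: BinaryMask,
    center: tuple[int, int] = (255, 255),
    rescue_radius: int = 10,
    hole_fill_px: int = 50,
) -> FazRegion:
    """Select the central avascular component as the FAZ.

    Takes the 4-connected avascular component containing ``center`` (or
    the nearest avascular pixel within ``rescue_radius`` if the center
    pixel was classed vascular), fills interior holes smaller than
    ``hole_fill_px`` pixels (capillary-dropout speckle), and returns the
    region with method ``"ml"``.
    """
    fg = avascular_mask.as_bool()
    h, w = fg.shape
    cx, cy = center
    warnings_list: list[str] = []
    labels, _ = ndimage.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    # candidate components: all that intersect the rescue disc around the
    # center; take the largest, so a speckle-sized fragment sitting exactly
    # on the center pixel cannot shadow the actual avascular zone
    yy, xx = np.ogrid[:h, :w]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= rescue_radius**2
    cand = np.unique(labels[disc & fg])
    cand = cand[cand != 0]
    if len(cand) == 0:
        raise FazSeedFailure(
            f"FAZ seed failure: no avascular pixel within {rescue_radius} px of {center}"
        )
    sizes = ndimage.sum_labels(fg, labels, index=cand)
    chosen = int(cand[int(np.argmax(sizes))])
    if not fg[cy, cx]:
        warnings_list.append(f"center {center} classed vascular; rescued within {rescue_radius} px")
    elif labels[cy, cx] != chosen:
        warnings_list.append(
            f"center {center} sits on a {int(sizes.min())}-px fragment; "
            "took the largest nearby avascular component"
        )
    comp = labels == chosen
    # fill small interior holes
    filled = ndimage.binary_fill_holes(comp)
    holes, n_holes = ndimage.label(filled & ~comp)
    if n_holes:
        sizes = ndimage.sum_labels(np.ones_like(holes), holes, index=np.arange(1, n_holes + 1))
        for i, size in enumerate(sizes, start=1):
            if size < hole_fill_px:
                comp |= holes == i
    mask = BinaryMask.from_bool(comp)
    return FazRegion(
        mask=mask,
        pixel_count=mask.foreground_count,
        boundary=_region_boundary(comp),
        method="ml",
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: PixelClassifierModel, path: str | Path) -> None:
    """Serialize a model (recipe + trees + provenance) to one archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "radii": model.radii,
        "feature_names": model.feature_names,
        "frame_shape": model.frame_shape,
        "class_order": model.class_order,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "training_accuracy": model.training_accuracy,
        "provenance": model.provenance,
        "classifier": model.classifier,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> PixelClassifierModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version in {path}")
    expected = 1 + len(STAT_NAMES) * len(payload["radii"])
    if len(payload["feature_names"]) != expected:
        raise ValueError(
            f"recipe mismatch in {path}: {len(payload['feature_names'])} feature names "
            f"for radii {payload['radii']} (expected {expected})"
        )
    clf = payload["classifier"]
    if getattr(clf, "n_features_in_", expected) != expected:
        raise ValueError(f"recipe mismatch in {path}: classifier expects {clf.n_features_in_} features")
    return PixelClassifierModel(
        classifier=clf,
        radii=tuple(payload["radii"]),
        feature_names=list(payload["feature_names"]),
        frame_shape=tuple(payload["frame_shape"]),
        class_order=tuple(payload["class_order"]),
        n_trees=payload["n_trees"],
        seed=payload["seed"],
        training_accuracy=payload["training_accuracy"],
        provenance=payload["provenance"],
    )
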