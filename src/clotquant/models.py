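"""SVM pixel classifiers: training, prediction, serialization, composition.

Two model kinds mirror the slide-analysis workflow: an *exclusion* model
separating background / tissue / artefact (only tissue is analyzable), and a
*classification* model assigning tissue pixels to RBC / WBC / fibrin. Their
composition is the *main* model applied in batch (see :mod:`clotquant.quantify`).

Training fits a kernel SVM (RBF, one-vs-one) on standardized window
features. Prediction is computed from the model's own serialized state —
support vectors, dual coefficients, intercepts — with an explicit pairwise
vote and a deterministic tie-break by label order, so a saved model file
fully determines its predictions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from clotquant.features import FeatureConfig, feature_map, features_at
from clotquant.imaging import AnnotationRegion, LabelMap, RasterImage, UNCLASSIFIED, rasterize_region

logger = logging.getLogger(__name__)

MODEL_MAGIC = b"CLOTQUANT-MODEL"
MAIN_MAGIC = b"CLOTQUANT-MAIN"
FORMAT_VERSION = "1"

EXCLUSION_LABELS = ("background", "tissue", "artefact")
CLASSIFICATION_LABELS = ("RBC", "WBC", "fibrin")

#: Default per-class training sample size: bounds training cost and
#: prevents class-imbalance bias from unequal annotation areas.
DEFAULT_PER_CLASS = 5000


@dataclass(frozen=True)
class SVMHyperParams:
    """RBF-SVM settings. ``gamma`` defaults to 1/n_features on standardized data."""

    C: float = 1.0
    gamma: float | None = None  # None -> 1 / feature dimension
    cache_size_mb: float = 512.0

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass
class PixelModel:
    """A trained pixel classifier with everything needed for deterministic prediction."""

    label_set: tuple[str, ...]
    feature_config: FeatureConfig
    scaler_mean: np.ndarray  # (n_features,)
    scaler_sd: np.ndarray  # (n_features,) zero-variance features recorded with sd 1
    degenerate_features: tuple[int, ...]
    support_vectors: np.ndarray  # (n_sv, n_features), standardized
    dual_coef: np.ndarray  # (n_classes - 1, n_sv), libsvm one-vs-one layout
    intercept: np.ndarray  # (n_classes * (n_classes - 1) / 2,)
    n_support: np.ndarray  # (n_classes,) support vectors per class, label order
    gamma: float
    training_meta: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.label_set)

    # -- prediction -------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """One-vs-one decision values for raw (unstandardized) feature rows.

        Column ``p`` corresponds to the class pair (i, j), i < j, enumerated
        in label order; positive values favor class i.
        """
        Xs = self._standardize(np.asarray(X, dtype=np.float64)).astype(np.float32)
        k = self.n_classes
        starts = np.concatenate([[0], np.cumsum(self.n_support)])
        # Single-precision kernel with a preallocated chunk buffer and
        # in-place updates: the decision is a sign/vote, so float32 is ample,
        # and avoiding large temporaries keeps whole-slide prediction fast.
        sv = self.support_vectors.astype(np.float32)
        sv_sq = np.einsum("ij,ij->i", sv, sv)
        gamma = np.float32(self.gamma)
        n = Xs.shape[0]
        n_pairs = k * (k - 1) // 2
        dec = np.empty((n, n_pairs), dtype=np.float64)
        chunk = 8192
        K = np.empty((min(chunk, n), len(sv)), dtype=np.float32)
        for lo in range(0, n, chunk):
            xs = Xs[lo : lo + chunk]
            Km = K[: len(xs)]
            np.matmul(xs, sv.T, out=Km)
            Km *= np.float32(-2.0)
            Km += sv_sq[None, :]
            Km += np.einsum("ij,ij->i", xs, xs)[:, None]
            Km *= -gamma
            np.exp(Km, out=Km)
            p = 0
            for i in range(k):
                for j in range(i + 1, k):
                    si = slice(starts[i], starts[i + 1])
                    sj = slice(starts[j], starts[j + 1])
                    dec[lo : lo + chunk, p] = (
                        Km[:, si] @ self.dual_coef[j - 1, si].astype(np.float32)
                        + Km[:, sj] @ self.dual_coef[i, sj].astype(np.float32)
                        + self.intercept[p]
                    )
                    p += 1
        return dec

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        """Class indices (into ``label_set``) by one-vs-one vote.

        Vote ties are broken by label_set order: argmax picks the first
        maximal vote count.
        """
        dec = self.decision_values(X)
        k = self.n_classes
        votes = np.zeros((dec.shape[0], k), dtype=np.int32)
        p = 0
        for i in range(k):
            for j in range(i + 1, k):
                win_i = dec[:, p] > 0
                votes[win_i, i] += 1
                votes[~win_i, j] += 1
                p += 1
        return np.argmax(votes, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class names for raw feature rows."""
        labels = np.asarray(self.label_set, dtype=object)
        return labels[self.predict_indices(X)]


@dataclass
class MainModel:
    """Exclusion-then-classification pipeline.

    Only pixels the exclusion stage marks as tissue are passed to the
    classification stage; background and artefact are final.
    """

    exclusion: PixelModel
    classification: PixelModel

    def __post_init__(self) -> None:
        if tuple(self.exclusion.label_set) != EXCLUSION_LABELS:
            raise ValueError(
                f"exclusion model must have label set {EXCLUSION_LABELS}, got {self.exclusion.label_set}"
            )
        if tuple(self.classification.label_set) != CLASSIFICATION_LABELS:
            raise ValueError(
                f"classification model must have label set {CLASSIFICATION_LABELS}, "
                f"got {self.classification.label_set}"
            )


def combine_models(exclusion: PixelModel, classification: PixelModel) -> MainModel:
    """Compose validated exclusion and classification models into a main model."""
    return MainModel(exclusion=exclusion, classification=classification)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def sample_training_pixels(
    images: list[RasterImage],
    regions: list[AnnotationRegion],
    per_class: int = DEFAULT_PER_CLASS,
    seed: int = 0,
    label_set: tuple[str, ...] | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], list[str]]:
    """Sample labeled feature vectors from annotated regions.

    For each class, up to ``per_class`` pixel locations are drawn uniformly
    without replacement (seeded) from the union of that class's rasterized
    regions across all images; classes with fewer annotated pixels
    contribute all of them and a warning is recorded.

    Returns ``(X, y, label_set, warnings)`` with ``y`` holding indices into
    ``label_set``.
    """
    config = feature_config or FeatureConfig()
    by_id = {im.id: im for im in images}
    if label_set is None:
        label_set = tuple(dict.fromkeys(reg.label for reg in regions))
    # Collect per-class pixel locations: (image_id, row, col)
    class_pixels: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {lab: [] for lab in label_set}
    for reg in regions:
        if reg.label not in class_pixels:
            raise ValueError(f"region label {reg.label!r} not in label set {label_set}")
        if reg.image_id not in by_id:
            raise ValueError(f"region references unknown image {reg.image_id!r}")
        im = by_id[reg.image_id]
        mask = rasterize_region(reg, im.shape)
        rows, cols = np.nonzero(mask)
        class_pixels[reg.label].append((reg.image_id, rows, cols))
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    X_parts, y_parts = [], []
    fm_cache: dict[str, np.ndarray] = {}
    for ci, lab in enumerate(label_set):
        chunks = class_pixels[lab]
        total = sum(len(r) for _, r, _ in chunks)
        if total == 0:
            raise ValueError(f"class {lab!r} has zero annotated pixels")
        if total <= per_class:
            take = np.arange(total)
            if total < per_class:
                msg = f"class {lab!r}: only {total} annotated pixels available (requested {per_class})"
                warnings.append(msg)
                logger.warning(msg)
        else:
            take = rng.choice(total, size=per_class, replace=False)
            take.sort()
        # map flat indices back to (image, row, col)
        offsets = np.cumsum([0] + [len(r) for _, r, _ in chunks])
        for k, (img_id, rows, cols) in enumerate(chunks):
            sel = take[(take >= offsets[k]) & (take < offsets[k + 1])] - offsets[k]
            if len(sel) == 0:
                continue
            if img_id not in fm_cache:
                fm_cache[img_id] = feature_map(by_id[img_id], config)
            X_parts.append(fm_cache[img_id][rows[sel], cols[sel], :])
            y_parts.append(np.full(len(sel), ci, dtype=np.int64))
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)
    return X, y, label_set, warnings


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    label_set: tuple[str, ...],
    hyperparams: SVMHyperParams | None = None,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    training_meta: dict | None = None,
) -> PixelModel:
    """Fit an RBF SVM pixel classifier on labeled feature vectors.

    Features are standardized by their training mean/SD (zero-variance
    features get SD 1 and are recorded); multi-class is one-vs-one.
    Identical inputs give an identical model.
    """
    hp = hyperparams or SVMHyperParams()
    config = feature_config or FeatureConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    present = np.unique(y)
    if len(label_set) < 2 or len(present) < 2:
        raise ValueError("training needs >= 2 classes present")
    if not np.array_equal(present, np.arange(len(label_set))):
        raise ValueError("every class in label_set must have training vectors")
    counts = np.bincount(y)
    if counts.min() < 50:
        raise ValueError(f"need >= 50 vectors per class, got counts {counts.tolist()}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    degenerate = tuple(int(i) for i in np.nonzero(sd == 0.0)[0])
    sd = np.where(sd == 0.0, 1.0, sd)
    Xs = (X - mean) / sd
    if np.all(Xs == Xs[0]):
        raise ValueError("degenerate training data: all feature vectors identical")
    gamma = hp.resolved_gamma(X.shape[1])
    svc = SVC(C=hp.C, kernel="rbf", gamma=gamma, cache_size=hp.cache_size_mb)
    svc.fit(Xs, y)
    # libsvm groups support vectors by class in sorted class order, which is
    # label_set order because y holds indices 0..k-1.
    dual_coef = svc.dual_coef_.astype(np.float64)
    intercept = svc.intercept_.astype(np.float64)
    if len(label_set) == 2:
        # sklearn flips the binary decision so positive means the second
        # class; undo it so stored state follows the uniform one-vs-one
        # convention (positive favors the first class of the pair).
        dual_coef = -dual_coef
        intercept = -intercept
    meta = dict(training_meta or {})
    meta.setdefault("seed", seed)
    meta.setdefault("n_vectors_per_class", counts.tolist())
    meta.setdefault("version", FORMAT_VERSION)
    return PixelModel(
        label_set=tuple(label_set),
        feature_config=config,
        scaler_mean=mean,
        scaler_sd=sd,
        degenerate_features=degenerate,
        support_vectors=svc.support_vectors_.astype(np.float64),
        dual_coef=dual_coef,
        intercept=intercept,
        n_support=svc.n_support_.astype(np.int64),
        gamma=float(gamma),
        training_meta=meta,
    )


def train_from_annotations(
    images: list[RasterImage],
    regions: list[AnnotationRegion],
    label_set: tuple[str, ...],
    per_class: int = DEFAULT_PER_CLASS,
    seed: int = 0,
    hyperparams: SVMHyperParams | None = None,
    feature_config: FeatureConfig | None = None,
) -> PixelModel:
    """Convenience: sample annotated pixels then fit (the usual training path)."""
    X, y, label_set, warnings = sample_training_pixels(
        images, regions, per_class=per_class, seed=seed, label_set=label_set,
        feature_config=feature_config,
    )
    meta = {
        "images": sorted({im.id for im in images}),
        "per_class": per_class,
        "seed": seed,
        "warnings": warnings,
    }
    return train_model(
        X, y, label_set, hyperparams=hyperparams, seed=seed,
        feature_config=feature_config, training_meta=meta,
    )


# ---------------------------------------------------------------------------
# Prediction on images
# ---------------------------------------------------------------------------

#: Images with a longer edge than this are predicted tile-wise; tiles carry a
#: margin of real pixels equal to the window diameter, so the stitched result
#: is identical to the untiled computation.
DEFAULT_TILE_EDGE = 8192


def _predict_tile(
    model: PixelModel,
    image: RasterImage,
    legend_values: np.ndarray,
    mask: np.ndarray | None,
    stride: int,
) -> np.ndarray:
    h, w = image.shape
    fm = feature_map(image, model.feature_config)
    out = np.full((h, w), UNCLASSIFIED, dtype=np.uint8)
    if stride == 1:
        if mask is None:
            idx = model.predict_indices(fm.reshape(-1, fm.shape[2]))
            out[:] = legend_values[idx].reshape(h, w)
        else:
            rows, cols = np.nonzero(mask)
            if len(rows):
                idx = model.predict_indices(fm[rows, cols, :])
                out[rows, cols] = legend_values[idx]
    else:
        # classify every stride-th pixel, nearest-neighbor fill in between
        rs = np.arange(0, h, stride)
        cs = np.arange(0, w, stride)
        sub = fm[np.ix_(rs, cs)].reshape(-1, fm.shape[2])
        idx = model.predict_indices(sub).reshape(len(rs), len(cs))
        full_r = np.clip(np.round(np.arange(h) / stride).astype(int), 0, len(rs) - 1)
        full_c = np.clip(np.round(np.arange(w) / stride).astype(int), 0, len(cs) - 1)
        filled = legend_values[idx[np.ix_(full_r, full_c)]]
        if mask is None:
            out[:] = filled
        else:
            out[mask] = filled[mask]
    return out


def predict_labels(
    model: PixelModel,
    image: RasterImage,
    mask: np.ndarray | None = None,
    stride: int = 1,
    tile_edge: int = DEFAULT_TILE_EDGE,
) -> LabelMap:
    """Classify pixels of an image into the model's label set.

    If ``mask`` is given, only masked pixels are classified; the rest get the
    reserved ``UNCLASSIFIED`` value. ``stride`` > 1 classifies every
    stride-th pixel and fills by nearest neighbor (speed option; the default
    stride 1 is the reference behavior). Images longer than ``tile_edge`` on
    a side are processed as overlapping tiles and stitched exactly.
    """
    h, w = image.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError("mask shape must match image")
    legend_values = np.arange(len(model.label_set), dtype=np.uint8)
    legend = {int(i): lab for i, lab in enumerate(model.label_set)}
    if max(h, w) <= tile_edge:
        labels = _predict_tile(model, image, legend_values, mask, stride)
        return LabelMap(labels=labels, legend=legend, image_id=image.id)
    # tiled path: margin of real context pixels makes stitching exact
    margin = 2 * model.feature_config.window_radius + 1
    labels = np.full((h, w), UNCLASSIFIED, dtype=np.uint8)
    for r0 in range(0, h, tile_edge):
        for c0 in range(0, w, tile_edge):
            r1, c1 = min(r0 + tile_edge, h), min(c0 + tile_edge, w)
            rr0, cc0 = max(r0 - margin, 0), max(c0 - margin, 0)
            rr1, cc1 = min(r1 + margin, h), min(c1 + margin, w)
            tile = RasterImage(pixels=image.pixels[rr0:rr1, cc0:cc1], id=f"{image.id}#tile")
            tmask = None if mask is None else mask[rr0:rr1, cc0:cc1]
            tl = _predict_tile(model, tile, legend_values, tmask, stride)
            labels[r0:r1, c0:c1] = tl[r0 - rr0 : r1 - rr0, c0 - cc0 : c1 - cc0]
    return LabelMap(labels=labels, legend=legend, image_id=image.id)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
# Single-file container: a text header (magic + version line, one JSON line
# describing label set, feature config, scaler, training metadata and the
# binary layout with a SHA-256 checksum), followed by the raw little-endian
# binary block of classifier state. Saves are byte-deterministic.

_ARRAY_FIELDS = ("scaler_mean", "scaler_sd", "support_vectors", "dual_coef", "intercept", "n_support")


def _model_payload(model: PixelModel) -> tuple[bytes, list[dict]]:
    manifest = []
    blobs = []
    for name in _ARRAY_FIELDS:
        arr = np.ascontiguousarray(getattr(model, name))
        if arr.dtype not in (np.float64, np.int64):
            arr = arr.astype(np.float64)
        raw = arr.astype(arr.dtype.newbyteorder("<")).tobytes()
        manifest.append({"name": name, "dtype": str(arr.dtype), "shape": list(arr.shape)})
        blobs.append(raw)
    return b"".join(blobs), manifest


def _model_bytes(model: PixelModel) -> bytes:
    payload, manifest = _model_payload(model)
    header = {
        "format_version": FORMAT_VERSION,
        "label_set": list(model.label_set),
        "feature_config": model.feature_config.to_dict(),
        "degenerate_features": list(model.degenerate_features),
        "gamma": model.gamma,
        "training_meta": model.training_meta,
        "arrays": manifest,
        "payload_sha256": hashlib.sha256(payload).hexdigest(),
        "payload_bytes": len(payload),
    }
    head = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    return MODEL_MAGIC + b" v" + FORMAT_VERSION.encode() + b"\n" + head + b"\n" + payload


def _model_from_bytes(data: bytes, source: str = "<bytes>") -> PixelModel:
    try:
        first_nl = data.index(b"\n")
        second_nl = data.index(b"\n", first_nl + 1)
    except ValueError:
        raise IOError(f"{source}: truncated model file (missing header)")
    magic = data[:first_nl]
    if not magic.startswith(MODEL_MAGIC):
        raise IOError(f"{source}: not a model file (bad magic line {magic!r})")
    version = magic.split(b" v")[-1].decode()
    if version != FORMAT_VERSION:
        raise IOError(f"{source}: unsupported model format version {version!r}")
    try:
        header = json.loads(data[first_nl + 1 : second_nl].decode())
    except json.JSONDecodeError as exc:
        raise IOError(f"{source}: corrupt header: {exc}")
    payload = data[second_nl + 1 :]
    if len(payload) != header["payload_bytes"]:
        raise IOError(
            f"{source}: truncated payload ({len(payload)} bytes, expected {header['payload_bytes']})"
        )
    if hashlib.sha256(payload).hexdigest() != header["payload_sha256"]:
        raise IOError(f"{source}: classifier_state checksum mismatch (corrupt payload)")
    arrays = {}
    off = 0
    for spec in header["arrays"]:
        dtype = np.dtype(spec["dtype"]).newbyteorder("<")
        count = int(np.prod(spec["shape"])) if spec["shape"] else 1
        nbytes = dtype.itemsize * count
        arrays[spec["name"]] = (
            np.frombuffer(payload[off : off + nbytes], dtype=dtype)
            .reshape(spec["shape"])
            .astype(dtype.newbyteorder("="))
        )
        off += nbytes
    return PixelModel(
        label_set=tuple(header["label_set"]),
        feature_config=FeatureConfig.from_dict(header["feature_config"]),
        scaler_mean=arrays["scaler_mean"],
        scaler_sd=arrays["scaler_sd"],
        degenerate_features=tuple(header["degenerate_features"]),
        support_vectors=arrays["support_vectors"],
        dual_coef=arrays["dual_coef"],
        intercept=arrays["intercept"],
        n_support=arrays["n_support"].astype(np.int64),
        gamma=float(header["gamma"]),
        training_meta=header["training_meta"],
    )


def save_model(model: PixelModel | MainModel, path: str) -> None:
    """Write a model container; two saves of the same model are byte-identical."""
    if isinstance(model, MainModel):
        exc = _model_bytes(model.exclusion)
        cls = _model_bytes(model.classification)
        head = json.dumps(
            {"format_version": FORMAT_VERSION, "exclusion_bytes": len(exc), "classification_bytes": len(cls)},
            sort_keys=True,
            separators=(",", ":"),
        ).encode()
        data = MAIN_MAGIC + b" v" + FORMAT_VERSION.encode() + b"\n" + head + b"\n" + exc + cls
    else:
        data = _model_bytes(model)
    with open(path, "wb") as fh:
        fh.write(data)


def load_model(path: str) -> PixelModel | MainModel:
    """Load a model container; round trip preserves predictions exactly."""
    if not os.path.exists(path):
        raise IOError(f"model file not found: {path}")
    with open(path, "rb") as fh:
        data = fh.read()
    if data.startswith(MAIN_MAGIC):
        first_nl = data.index(b"\n")
        second_nl = data.index(b"\n", first_nl + 1)
        header = json.loads(data[first_nl + 1 : second_nl].decode())
        body = data[second_nl + 1 :]
        n_exc = header["exclusion_bytes"]
        exc = _model_from_bytes(body[:n_exc], source=f"{path}[exclusion]")
        cls = _model_from_bytes(body[n_exc : n_exc + header["classification_bytes"]], source=f"{path}[classification]")
        return MainModel(exclusion=exc, classification=cls)
    return _model_from_bytes(data, source=path)
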