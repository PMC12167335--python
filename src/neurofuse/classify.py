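"""Tissue classification for both modalities.

Hyperspectral cubes are segmented pixel-wise from the per-pixel reflectance
spectrum into background / healthy / tumor with either an RBF-kernel SVM
(C = 1) or a two-hidden-layer MLP (128 and 64 units, cross-entropy loss,
Adam, learning rate 0.001).  Endomicroscopy frames are classified
healthy/tumor with a compact convolutional network: three stride-2
convolutional blocks (16/32/64 channels, He-initialised seeded filter
banks, ReLU) with global average pooling, feeding a dense softmax head
trained with the same loss, optimizer and learning rate.

Class imbalance is handled by undersampling every class to the minority
count, and evaluation uses leave-one-specimen-out folds so no specimen
contributes to both training and testing.  Probe scans from tumor-margin
regions are test-only; attempting to train on one raises
:class:`ContaminationError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .calibration import ReflectanceCube
from .fusion import BG, HEALTHY, TUMOR

CLASS_NAMES = ("BG", "healthy", "tumor")
PCLE_CLASSES = ("healthy", "tumor")


class ContaminationError(ValueError):
    """A margin-region probe scan appeared in a training set."""


class ArchitectureUnavailable(RuntimeError):
    """The requested backbone family ships no weights in this package."""


# --- domain types -----------------------------------------------------------

@dataclass
class SpectrumSample:
    reflectance: np.ndarray          # restricted-band reflectance vector
    label: str                       # one of CLASS_NAMES
    specimen_id: int | str = 0

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float).ravel()
        if self.label not in CLASS_NAMES:
            raise ValueError(f"label must be one of {CLASS_NAMES}")


@dataclass
class LabeledPCLEImage:
    image: np.ndarray
    label: str                       # {"healthy", "tumor"}
    region: str = "healthy"          # {"healthy", "core", "margin"}
    specimen_id: int | str = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.label not in PCLE_CLASSES:
            raise ValueError("label must be 'healthy' or 'tumor'")
        if self.region not in ("healthy", "core", "margin"):
            raise ValueError("region must be healthy/core/margin")


@dataclass
class ClassifierSpec:
    family: str = "mlp"              # svm_rbf | mlp | cnn_small | mobilenet_v2 | efficientnet
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    _FAMILIES = ("svm_rbf", "mlp", "cnn_small", "mobilenet_v2", "efficientnet")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"family must be one of {self._FAMILIES}")


@dataclass
class SegmentationResult:
    """Per-pixel class labels plus per-class confidence maps.

    Confidences sum to 1 per pixel and the label map is their argmax.
    """

    labels: np.ndarray               # (H, W) int in {BG, HEALTHY, TUMOR}
    confidence: np.ndarray           # (3, H, W), sums to 1 per pixel

    def __post_init__(self) -> None:
        if self.confidence.shape != (3, *self.labels.shape):
            raise ValueError("confidence must be (3, H, W)")
        if not np.allclose(self.confidence.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("confidences must sum to 1 per pixel")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == TUMOR


# --- sampling and folds -----------------------------------------------------

def undersample_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a class-balanced subset: every class downsampled without
    replacement to the minority-class count.  Deterministic per seed and
    independent of input order (selection happens within sorted per-class
    index lists)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty sample set")
    classes, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    picked = []
    for cls in classes:   # np.unique sorts, so the stream order is stable
        idx = np.flatnonzero(labels == cls)
        picked.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(picked))


def undersample(samples: list, seed: int) -> list:
    """Balance a list of labelled items (anything with a ``.label``)."""
    labels = np.asarray([s.label for s in samples])
    keep = undersample_indices(labels, seed)
    return [samples[i] for i in keep]


def make_loso_folds(specimen_ids) -> list[tuple[list, object]]:
    """Leave-one-specimen-out folds: one (train_ids, test_id) per specimen."""
    ids = list(specimen_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate specimen ids")
    if len(ids) < 2:
        raise ValueError("need >= 2 specimens for held-out folds")
    ids = sorted(ids)
    return [([s for s in ids if s != test], test) for test in ids]


# --- spectral classifiers ---------------------------------------------------

class SpectralModel:
    """Fitted spectral classifier exposing 3-class probabilities."""

    def __init__(self, estimator, spec: ClassifierSpec, n_bands: int):
        self.estimator = estimator
        self.spec = spec
        self.n_bands = n_bands

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(N, 3) probabilities in canonical BG/healthy/tumor order."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_bands:
            raise ValueError(
                f"band count {X.shape[1]} differs from training ({self.n_bands})")
        raw = self.estimator.predict_proba(X)
        out = np.zeros((X.shape[0], 3))
        for j, cls in enumerate(self.estimator.classes_):
            out[:, int(cls)] = raw[:, j]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.argmax(proba, axis=1)

    @property
    def n_parameters(self) -> int | None:
        est = self.estimator
        if hasattr(est, "coefs_"):
            return int(sum(c.size for c in est.coefs_)
                       + sum(b.size for b in est.intercepts_))
        return None


def _label_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iuf":
        return labels.astype(int)
    lut = {name: i for i, name in enumerate(CLASS_NAMES)}
    return np.asarray([lut[str(v)] for v in labels], dtype=int)


def train_spectral_classifier(X: np.ndarray, y, spec: ClassifierSpec
                              ) -> SpectralModel:
    """Fit an SVM or MLP spectral classifier; training is seeded.

    ``X`` is (N, bands) reflectance; ``y`` class names or codes.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN/inf in features")
    y = _label_codes(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    hp = dict(spec.hyperparameters)
    if spec.family == "svm_rbf":
        est = SVC(C=hp.pop("C", 1.0), kernel="rbf", gamma=hp.pop("gamma", "scale"),
                  probability=True, random_state=spec.seed, **hp)
    elif spec.family == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (128, 64)),
            activation=hp.pop("activation", "relu"),
            solver="adam",
            learning_rate_init=hp.pop("learning_rate_init", 1e-3),
            batch_size=hp.pop("batch_size", 256),
            max_iter=hp.pop("max_iter", 50),
            alpha=hp.pop("alpha", 0.0),
            random_state=spec.seed, **hp)
    else:
        raise ValueError(f"{spec.family!r} is not a spectral classifier family")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return SpectralModel(est, spec, X.shape[1])


def classify_cube(cube: ReflectanceCube, model: SpectralModel,
                  bg_mask: np.ndarray | None = None) -> SegmentationResult:
    """Pixel-wise segmentation of a calibrated cube.

    Pixels flagged invalid by radiometric calibration (and any in
    ``bg_mask``) are labelled background with confidence 1.
    """
    h, w, b = cube.data.shape
    if b != model.n_bands:
        raise ValueError(f"cube has {b} bands, model expects {model.n_bands}")
    skip = ~cube.valid_mask
    if bg_mask is not None:
        skip |= np.asarray(bg_mask, dtype=bool)
    X = cube.data[~skip]
    conf = np.zeros((3, h, w))
    conf[BG][skip] = 1.0
    if X.shape[0]:
        proba = model.predict_proba(X)
        flat = conf.reshape(3, -1)
        flat[:, (~skip).ravel()] = proba.T
    labels = np.argmax(conf, axis=0)
    return SegmentationResult(labels=labels, confidence=conf)


# --- pCLE classifiers -------------------------------------------------------

def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


class ConvFeatureBank:
    """Three stride-2 convolutional blocks with seeded He-initialised
    filters, ReLU, and global average pooling; purely feed-forward."""

    CHANNELS = (16, 32, 64)

    def __init__(self, seed: int, input_size: int = 64):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.filters = []
        c_in = 1
        for c_out in self.CHANNELS:
            std = np.sqrt(2.0 / (c_in * 9))
            self.filters.append(rng.normal(0.0, std, size=(c_out, c_in, 3, 3)))
            c_in = c_out

    @staticmethod
    def _conv_stride2(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
        return np.einsum("nchwij,ocij->nohw", win, w, optimize=True)

    def transform(self, images: list[np.ndarray]) -> np.ndarray:
        """(N, 64) pooled activations from per-image min-max-scaled inputs."""
        from skimage.transform import resize
        batch = np.empty((len(images), 1, self.input_size, self.input_size))
        for i, img in enumerate(images):
            img = _minmax(np.asarray(img, dtype=float))
            if img.shape != (self.input_size, self.input_size):
                img = resize(img, (self.input_size, self.input_size),
                             anti_aliasing=True)
            batch[i, 0] = img
        x = batch
        for w in self.filters:
            x = np.maximum(self._conv_stride2(x, w), 0.0)
        return x.mean(axis=(2, 3))


class PCLEModel:
    """Binary healthy/tumor classifier over probe frames."""

    def __init__(self, bank: ConvFeatureBank, head, spec: ClassifierSpec):
        self.bank = bank
        self.head = head
        self.spec = spec

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        """(N, 2) probabilities ordered (healthy, tumor)."""
        feats = self.bank.transform(images)
        raw = self.head.predict_proba(feats)
        out = np.zeros((len(images), 2))
        for j, cls in enumerate(self.head.classes_):
            out[:, int(cls)] = raw[:, j]
        return out

    def predict(self, images: list[np.ndarray]) -> list[str]:
        proba = self.predict_proba(images)
        return [PCLE_CLASSES[i] for i in np.argmax(proba, axis=1)]


def train_pcle_classifier(train: list[LabeledPCLEImage], spec: ClassifierSpec
                          ) -> PCLEModel:
    """Train the probe-frame classifier on healthy-region and tumor-core
    scans; margin scans are rejected (they are reserved for testing)."""
    if spec.family in ("mobilenet_v2", "efficientnet"):
        raise ArchitectureUnavailable(
            f"{spec.family} requires pretrained backbone weights that this "
            "package does not ship; use 'cnn_small'")
    if spec.family != "cnn_small":
        raise ValueError(f"{spec.family!r} is not a pCLE classifier family")
    for im in train:
        if im.region == "margin":
            raise ContaminationError(
                f"margin scan from specimen {im.specimen_id} in training set")
    labels = np.asarray([PCLE_CLASSES.index(im.label) for im in train])
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in training")

    hp = dict(spec.hyperparameters)
    bank = ConvFeatureBank(seed=spec.seed, input_size=hp.pop("input_size", 64))
    head = MLPClassifier(
        hidden_layer_sizes=hp.pop("hidden_layer_sizes", (32,)),
        activation="relu", solver="adam",
        learning_rate_init=hp.pop("learning_rate_init", 1e-3),
        batch_size=min(hp.pop("batch_size", 256), len(train)),
        max_iter=hp.pop("max_iter", 300),
        alpha=hp.pop("alpha", 0.0), random_state=spec.seed, **hp)
    feats = bank.transform([im.image for im in train])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        head.fit(feats, labels)
    return PCLEModel(bank, head, spec)


def classify_pcle(images: list[np.ndarray] | list[LabeledPCLEImage],
                  model: PCLEModel) -> tuple[list[str], np.ndarray]:
    """Labels and (N, 2) healthy/tumor probabilities for a batch of frames."""
    arrs = [im.image if isinstance(im, LabeledPCLEImage) else im for im in images]
    proba = model.predict_proba(arrs)
    labels = [PCLE_CLASSES[i] for i in np.argmax(proba, axis=1)]
    return labels, proba
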