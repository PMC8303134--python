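"""Trainable two-stage detector behind the same detection contract.

The training protocol mirrors the screening system's recipe: a first
training maps grayscale images to the white-on-black stage-1 composite of
the three structures; a secondary training maps the first stage's output
images to the five keypoints.  SGD with the protocol's hyperparameters
(learning rate 0.01, weight decay 0.0001, batch size 10, validation every
``validation_interval`` steps with best-checkpoint selection) and the
protocol's augmentation ranges (shift +/-5%, scale 80-100%, rotation
+/-15 degrees, brightness 75-100%, optional Gaussian noise).

The networks are deliberately small fully-convolutional models — a 5x5
conv + ReLU + 1x1 conv pixel classifier for stage 1, and a 9x9 conv +
ReLU + 1x1 conv heatmap regressor for stage 2 — implemented directly in
numpy (im2col + manual backprop) so training is exactly reproducible from
a seed on any machine.  Keypoints are decoded from the regressed heatmaps
by argmax plus 3x3 centroid refinement.  What is exercised here is the
two-stage protocol and its data plumbing at desk scale, not a large
backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktransform

from .detection import DetectionResult, StructureMaskSet, segment_structures
from .errors import ValidationError
from .geometry import LandmarkSet, Point2D
from .phantom import PhantomTruth

__all__ = [
    "NeuralTrainingConfig",
    "augment",
    "train_two_stage",
    "NeuralDetector",
    "untrained_detector",
    "mean_landmark_error",
]

_LANDMARK_ORDER = ("check_upper", "triradiate", "lower_ilium", "bone_edge", "labrum_end")


@dataclass(frozen=True)
class NeuralTrainingConfig:
    """Training protocol hyperparameters; defaults are the full-scale recipe.

    Toy runs shrink ``total_steps`` / ``validation_interval`` but keep the
    optimizer settings and augmentation ranges.
    """

    total_steps: int = 40_000
    validation_interval: int = 1_000
    learning_rate: float = 0.01
    weight_decay: float = 0.0001
    batch_size: int = 10
    shift_range: float = 0.05          # fraction of image size, +/-
    scale_range: Tuple[float, float] = (0.80, 1.00)
    rotation_range: float = 15.0       # degrees, +/-
    brightness_range: Tuple[float, float] = (0.75, 1.00)
    gaussian_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_steps < self.validation_interval:
            raise ValidationError("total_steps must be >= validation_interval")
        if self.validation_interval < 1 or self.batch_size < 1:
            raise ValidationError("validation_interval and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValidationError("learning_rate must be > 0 and weight_decay >= 0")
        if not (0.0 <= self.shift_range <= 0.5):
            raise ValidationError("shift_range must lie in [0, 0.5]")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValidationError("scale_range must satisfy 0 < low <= high")
        if self.rotation_range < 0:
            raise ValidationError("rotation_range must be >= 0")
        blo, bhi = self.brightness_range
        if not (0.0 < blo <= bhi <= 1.5):
            raise ValidationError("brightness_range must satisfy 0 < low <= high <= 1.5")


def augment(
    image: np.ndarray,
    truth: PhantomTruth,
    cfg: NeuralTrainingConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, PhantomTruth]:
    """One seeded random augmentation of an (image, truth) pair.

    A single similarity transform (scale, rotation about the image centre,
    shift) is sampled within the config ranges and applied identically to
    the image, the structure masks and the landmark coordinates; brightness
    scaling and optional additive Gaussian noise apply to the image only.
    With all ranges collapsed to the identity the input is returned
    unchanged (as copies).  Passing no ``rng`` seeds one from ``cfg.seed``,
    so the call is reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = image.shape
    theta = math.radians(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    s = rng.uniform(*cfg.scale_range)
    tx = rng.uniform(-cfg.shift_range, cfg.shift_range) * w
    ty = rng.uniform(-cfg.shift_range, cfg.shift_range) * h
    bright = rng.uniform(*cfg.brightness_range)

    identity = theta == 0.0 and s == 1.0 and tx == 0.0 and ty == 0.0 and bright == 1.0
    if identity and not cfg.gaussian_noise:
        return image.copy(), PhantomTruth(
            landmarks=truth.landmarks,
            masks={k: v.copy() for k, v in truth.masks.items()},
            spec=truth.spec,
        )

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # In the y-down raster frame this sign convention makes a positive
    # rotation tilt the distal iliac wing toward +x, i.e. it adds to the
    # check angle.
    A = s * np.array([[math.cos(theta), math.sin(theta)],
                      [-math.sin(theta), math.cos(theta)]])
    offset = np.array([cx + tx, cy + ty]) - A @ np.array([cx, cy])
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = offset
    tf = sktransform.AffineTransform(matrix=M)

    img = sktransform.warp(
        np.asarray(image, dtype=float), tf.inverse, order=1, preserve_range=True
    )
    img *= bright
    if cfg.gaussian_noise:
        img += rng.normal(0.0, 2.0, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    masks = {
        k: sktransform.warp(v.astype(float), tf.inverse, order=0, preserve_range=True) > 0.5
        for k, v in truth.masks.items()
    }
    pts = {}
    for name, p in truth.landmarks.points().items():
        q = A @ np.array([p.x, p.y]) + offset
        pts[name] = Point2D(float(q[0]), float(q[1]))
    return img, PhantomTruth(landmarks=LandmarkSet(**pts), masks=masks, spec=truth.spec)


# ---------------------------------------------------------------------------
# numpy fully-convolutional nets


def _im2col(img: np.ndarray, k: int) -> np.ndarray:
    """(H*W, k*k) patch matrix with zero padding, float32."""
    pad = k // 2
    padded = np.pad(img, pad, mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(padded, (k, k))
    return win.reshape(-1, k * k).astype(np.float32)


class _ConvNet:
    """k x k conv -> ReLU -> 1x1 conv, trained by SGD on flattened patches."""

    def __init__(self, k: int, hidden: int, out: int, rng: np.random.Generator):
        self.k = k
        fan_in = k * k
        self.W1 = (rng.standard_normal((fan_in, hidden)) / math.sqrt(fan_in)).astype(np.float32)
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.W2 = (rng.standard_normal((hidden, out)) / math.sqrt(hidden)).astype(np.float32)
        self.b2 = np.zeros(out, dtype=np.float32)
        self._vel = [np.zeros_like(t) for t in (self.W1, self.b1, self.W2, self.b2)]
        self.momentum = 0.9

    def forward(self, X: np.ndarray):
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        return H, H @ self.W2 + self.b2

    def sgd_step(self, X: np.ndarray, dY: np.ndarray, H: np.ndarray, lr: float, wd: float):
        """dY: gradient of the loss w.r.t. the pre-output activations."""
        gW2 = H.T @ dY
        gb2 = dY.sum(axis=0)
        dH = dY @ self.W2.T
        dH[H <= 0] = 0.0
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        params = (self.W1, self.b1, self.W2, self.b2)
        grads = (gW1 + wd * self.W1, gb1, gW2 + wd * self.W2, gb2)
        for v, p, g in zip(self._vel, params, grads):
            v *= self.momentum
            v += g
            p -= lr * v

    def state(self):
        return [self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()]

    def load(self, state):
        self.W1, self.b1, self.W2, self.b2 = (s.copy() for s in state)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _heatmaps(landmarks: LandmarkSet, shape: Tuple[int, int], sigma: float = 2.5) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.empty((len(_LANDMARK_ORDER), h, w), dtype=np.float32)
    pts = landmarks.points()
    for i, name in enumerate(_LANDMARK_ORDER):
        p = pts[name]
        out[i] = np.exp(-((xx - p.x) ** 2 + (yy - p.y) ** 2) / (2 * sigma**2))
    return out


def _decode_heatmap(hm: np.ndarray) -> Point2D:
    """Argmax + 3x3 positive-mass centroid refinement."""
    h, w = hm.shape
    iy, ix = np.unravel_index(int(np.argmax(hm)), hm.shape)
    y0, y1 = max(iy - 1, 0), min(iy + 2, h)
    x0, x1 = max(ix - 1, 0), min(ix + 2, w)
    win = np.clip(hm[y0:y1, x0:x1], 0.0, None)
    tot = win.sum()
    if tot <= 0:
        return Point2D(float(ix), float(iy))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return Point2D(float((xx * win).sum() / tot), float((yy * win).sum() / tot))


class NeuralDetector:
    """Two small convolutional stages satisfying the detect() contract."""

    STAGE1_K = 5
    STAGE2_K = 9
    HIDDEN = 16

    def __init__(self, rng: np.random.Generator):
        self.stage1 = _ConvNet(self.STAGE1_K, self.HIDDEN, 1, rng)
        self.stage2 = _ConvNet(self.STAGE2_K, self.HIDDEN, len(_LANDMARK_ORDER), rng)
        self.history: list[dict] = []

    # -- inference ---------------------------------------------------------
    def stage1_prob(self, image: np.ndarray) -> np.ndarray:
        X = _im2col(np.asarray(image, dtype=np.float32) / 255.0 - 0.5, self.STAGE1_K)
        _, logits = self.stage1.forward(X)
        return _sigmoid(logits[:, 0]).reshape(image.shape)

    def stage2_heatmaps(self, stage1_img: np.ndarray) -> np.ndarray:
        X = _im2col(np.asarray(stage1_img, dtype=np.float32) - 0.5, self.STAGE2_K)
        _, out = self.stage2.forward(X)
        return out.T.reshape((len(_LANDMARK_ORDER),) + stage1_img.shape)

    def keypoints(self, image: np.ndarray) -> LandmarkSet:
        hms = self.stage2_heatmaps(self.stage1_prob(image))
        pts = {n: _decode_heatmap(hms[i]) for i, n in enumerate(_LANDMARK_ORDER)}
        return LandmarkSet(**pts)

    def detect(self, image: np.ndarray) -> DetectionResult:
        """DetectionResult from the two trained stages.

        Per-structure masks are recovered from the thresholded stage-1
        output with the same geometric assignment the classical detector
        uses, so both detectors are drop-in interchangeable downstream.
        """
        prob = self.stage1_prob(image)
        stage1_img = np.where(prob > 0.5, 255, 0).astype(np.uint8)
        masks = segment_structures(stage1_img)
        try:
            landmarks = self.keypoints(image)
        except ValidationError:
            return DetectionResult(masks=masks, landmarks=None, detectable=False)
        if not masks.is_complete:
            return DetectionResult(masks=masks, landmarks=None, detectable=False)
        return DetectionResult(masks=masks, landmarks=landmarks, detectable=True)


def untrained_detector(seed: int = 0) -> NeuralDetector:
    """A randomly initialised detector — the no-training baseline."""
    return NeuralDetector(np.random.default_rng(seed))


def _as_pairs(cohort: Iterable) -> list[Tuple[np.ndarray, PhantomTruth]]:
    pairs = []
    for item in cohort:
        if isinstance(item, tuple):
            pairs.append(item)
        else:  # CohortItem
            pairs.append((item.image, item.truth))
    return pairs


def train_two_stage(cohort: Iterable, cfg: NeuralTrainingConfig) -> NeuralDetector:
    """Train the two stages sequentially on a phantom cohort.

    Stage 1 fits the pixelwise structure classifier (binary cross-entropy
    against the white-on-black union of the truth masks); stage 2 fits the
    keypoint heatmap regressor (mean squared error) on the *predicted*
    stage-1 output of the best stage-1 checkpoint, matching the protocol in
    which the secondary training consumes the first training's resulting
    images.  20% of the cohort (at least one item) is held out for
    validation; every ``validation_interval`` steps the validation loss is
    logged and the best checkpoint retained.  Each stage runs
    ``cfg.total_steps`` SGD steps.  Fully deterministic given ``cfg.seed``.
    """
    pairs = _as_pairs(cohort)
    if len(pairs) < cfg.batch_size:
        raise ValidationError(
            f"cohort size {len(pairs)} is smaller than batch_size {cfg.batch_size}"
        )
    rng = np.random.default_rng(cfg.seed)
    det = NeuralDetector(rng)
    n_val = max(1, int(round(0.2 * len(pairs))))
    order = rng.permutation(len(pairs))
    val = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]]
    if not train:
        raise ValidationError("cohort too small to split into train and validation")
    lr, wd = cfg.learning_rate, cfg.weight_decay

    # ---- stage 1: image -> union mask ------------------------------------
    val_X = [_im2col(np.asarray(im, np.float32) / 255.0 - 0.5, det.STAGE1_K) for im, _ in val]
    val_y = [
        (t.masks["ilium"] | t.masks["acetabulum"] | t.masks["labrum"]).astype(np.float32).ravel()
        for _, t in val
    ]

    def _balanced_bce(p, y):
        frac = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        w = np.where(y > 0.5, 0.5 / frac, 0.5 / (1.0 - frac)).astype(np.float32)
        loss = float(np.mean(-w * (y * np.log(p + 1e-7) + (1 - y) * np.log(1 - p + 1e-7))))
        return loss, w

    def stage1_val_loss() -> float:
        tot = 0.0
        for X, y in zip(val_X, val_y):
            _, logits = det.stage1.forward(X)
            p = _sigmoid(logits[:, 0])
            tot += _balanced_bce(p, y)[0]
        return tot / len(val)

    best = (np.inf, det.stage1.state())
    for step in range(1, cfg.total_steps + 1):
        idx = rng.integers(0, len(train), cfg.batch_size)
        Xs, ys = [], []
        for i in idx:
            im, tr = augment(train[i][0], train[i][1], cfg, rng)
            Xs.append(_im2col(np.asarray(im, np.float32) / 255.0 - 0.5, det.STAGE1_K))
            union = tr.masks["ilium"] | tr.masks["acetabulum"] | tr.masks["labrum"]
            ys.append(union.astype(np.float32).ravel())
        X = np.concatenate(Xs)
        y = np.concatenate(ys)
        H, logits = det.stage1.forward(X)
        p = _sigmoid(logits[:, 0])
        train_loss, wgt = _balanced_bce(p, y)
        dY = (wgt * (p - y) / len(y)).astype(np.float32)[:, None]
        det.stage1.sgd_step(X, dY, H, lr, wd)
        if step % cfg.validation_interval == 0 or step == cfg.total_steps:
            vl = stage1_val_loss()
            det.history.append({"stage": 1, "step": step, "train_loss": train_loss,
                                "val_loss": vl})
            if vl < best[0]:
                best = (vl, det.stage1.state())
    det.stage1.load(best[1])

    # ---- stage 2: predicted stage-1 output -> keypoint heatmaps ----------
    val_X2 = [_im2col(det.stage1_prob(im).astype(np.float32) - 0.5, det.STAGE2_K)
              for im, _ in val]
    val_h = [_heatmaps(t.landmarks, im.shape).reshape(len(_LANDMARK_ORDER), -1).T
             for im, t in val]

    def _peak_mse(out, hm):
        w = 1.0 + 50.0 * hm  # keypoint neighbourhoods dominate the loss
        return float(np.mean(w * (out - hm) ** 2)), w

    def stage2_val_loss() -> float:
        tot = 0.0
        for X, hm in zip(val_X2, val_h):
            _, out = det.stage2.forward(X)
            tot += _peak_mse(out, hm)[0]
        return tot / len(val)

    best2 = (np.inf, det.stage2.state())
    for step in range(1, cfg.total_steps + 1):
        idx = rng.integers(0, len(train), cfg.batch_size)
        Xs, hs = [], []
        for i in idx:
            im, tr = augment(train[i][0], train[i][1], cfg, rng)
            prob = det.stage1_prob(im)
            Xs.append(_im2col(prob.astype(np.float32) - 0.5, det.STAGE2_K))
            hs.append(_heatmaps(tr.landmarks, im.shape).reshape(len(_LANDMARK_ORDER), -1).T)
        X = np.concatenate(Xs)
        hm = np.concatenate(hs)
        H, out = det.stage2.forward(X)
        train_loss, wgt = _peak_mse(out, hm)
        dY = (2.0 * wgt * (out - hm) / out.size).astype(np.float32)
        det.stage2.sgd_step(X, dY, H, lr, wd)
        if step % cfg.validation_interval == 0 or step == cfg.total_steps:
            vl = stage2_val_loss()
            det.history.append({"stage": 2, "step": step, "train_loss": train_loss,
                                "val_loss": vl})
            if vl < best2[0]:
                best2 = (vl, det.stage2.state())
    det.stage2.load(best2[1])
    return det


def mean_landmark_error(
    detector: NeuralDetector, items: Sequence[Tuple[np.ndarray, PhantomTruth]]
) -> float:
    """Mean Euclidean keypoint error (pixels) of a detector over phantoms."""
    pairs = _as_pairs(items)
    errs = []
    for im, truth in pairs:
        pred = detector.keypoints(im).points()
        true = truth.landmarks.points()
        for name in _LANDMARK_ORDER:
            errs.append(math.hypot(pred[name].x - true[name].x, pred[name].y - true[name].y))
    return float(np.mean(errs))
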