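"""Single-plane 2D attention U-Net: architecture, augmentation and training.

One network per orthogonal plane maps a preprocessed 2D slice (HU window
affinely rescaled to [0, 1]) to three per-class probability maps — background,
aortic root, coronary artery — through a final per-channel sigmoid.  The
multi-class problem is treated as three independent binary ones (binary
cross-entropy averaged over channels), matching the downstream per-class
thresholding: the maps need not sum to one.

Training uses Adam (default learning rate 1e-4), mini-batches of 10 slices
sampled uniformly at random from the training pool, and early stopping on
validation loss with a patience of 15 epochs; the parameters returned are
those of the best validation epoch.  Augmentation draws one rotation
(default ±7°), shift (±22 px in width; ±22 px in height for axial planes,
±72 px for sagittal/coronal, both at clinical 320-px scale) and zoom
(0.85–1.15) per sample and applies them identically to image and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import TrainingError
from .nn import Adam, AttentionGate, Conv2d, ConvBlock, MaxPool2, UpNearest2, bce_with_logits, sigmoid

PLANES = ("axial", "sagittal", "coronal")
N_CLASSES = 3


@dataclass
class ModelConfig:
    """Architecture hyper-parameters (not dictated by the clinical protocol;
    defaults chosen for desk-scale trainability)."""

    depth: int = 4
    base_filters: int = 16
    in_channels: int = 1
    out_channels: int = N_CLASSES

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.out_channels != N_CLASSES:
            raise ValueError("out_channels must be 3 (background, aorta, coronary)")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 10
    patience: int = 15
    max_epochs: int = 100
    steps_per_epoch: int | None = None  # None: one pass over the training pool
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


@dataclass
class AugmentConfig:
    """Sampling intervals for the per-slice random affine augmentation.

    ``shift_h_px`` defaults per plane: ±22 px axial, ±72 px sagittal/coronal
    (clinical 320-px scale); use :meth:`for_plane` to resolve it, and
    :meth:`scaled` to adapt the pixel ranges to another slice size.
    """

    rotation_deg: tuple[float, float] = (-7.0, 7.0)
    shift_w_px: tuple[float, float] = (-22.0, 22.0)
    shift_h_px: tuple[float, float] | None = None
    shift_h_px_axial: tuple[float, float] = (-22.0, 22.0)
    shift_h_px_lateral: tuple[float, float] = (-72.0, 72.0)
    zoom: tuple[float, float] = (0.85, 1.15)

    def __post_init__(self):
        for iv in (self.rotation_deg, self.shift_w_px, self.shift_h_px_axial,
                   self.shift_h_px_lateral, self.zoom):
            if iv[0] > iv[1]:
                raise ValueError(f"interval lower bound exceeds upper: {iv}")
        if self.zoom[0] <= 0:
            raise ValueError("zoom interval must be strictly positive")

    def for_plane(self, plane: str) -> "AugmentConfig":
        """Resolve the height-shift interval for the named plane."""
        if plane not in PLANES:
            raise ValueError(f"unknown plane {plane!r}; one of {PLANES}")
        h = self.shift_h_px_axial if plane == "axial" else self.shift_h_px_lateral
        return replace(self, shift_h_px=self.shift_h_px if self.shift_h_px is not None else h)

    def scaled(self, factor: float) -> "AugmentConfig":
        """Scale the pixel-shift ranges, e.g. by 64/320 for desk-scale slices."""
        s = lambda iv: (iv[0] * factor, iv[1] * factor)
        return replace(
            self,
            shift_w_px=s(self.shift_w_px),
            shift_h_px=None if self.shift_h_px is None else s(self.shift_h_px),
            shift_h_px_axial=s(self.shift_h_px_axial),
            shift_h_px_lateral=s(self.shift_h_px_lateral),
        )


class AttentionUNet:
    """Encoder–decoder with attention-gated skip connections.

    ``depth`` encoder blocks (channels ``base * 2**i``) each followed by 2x2
    max pooling, a bottleneck block at ``base * 2**depth`` channels, then a
    mirrored decoder: 2x nearest upsampling + 3x3 conv, an additive attention
    gate on the skip, concatenation and a conv block.  A 1x1 conv emits the
    three class channels; ``predict`` applies the element-wise sigmoid.
    Input sides must be divisible by (and at least) ``2**depth``.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, base = cfg.depth, cfg.base_filters
        ch = [base * 2**i for i in range(d + 1)]
        self.enc = []
        c_in = cfg.in_channels
        for i in range(d):
            self.enc.append(ConvBlock(c_in, ch[i], rng))
            c_in = ch[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(ch[d - 1], ch[d], rng)
        self.ups, self.up_convs, self.up_relus, self.atts, self.dec = [], [], [], [], []
        from .nn import ReLU  # local import to keep the layer list together

        for i in reversed(range(d)):
            self.ups.append(UpNearest2())
            self.up_convs.append(Conv2d(ch[i + 1], ch[i], 3, rng))
            self.up_relus.append(ReLU())
            self.atts.append(AttentionGate(ch[i], rng))
            self.dec.append(ConvBlock(2 * ch[i], ch[i], rng))
        self.out_conv = Conv2d(ch[0], cfg.out_channels, 1, rng)
        self._layers = (
            self.enc + self.pools + [self.bottleneck] + self.ups + self.up_convs
            + self.up_relus + self.atts + self.dec + [self.out_conv]
        )

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        return [p for layer in self._layers for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.v.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for i, p in enumerate(params):
            p.v[...] = state[f"p{i}"]

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x):
        side = 2**self.cfg.depth
        if x.shape[2] < side or x.shape[3] < side or x.shape[2] % side or x.shape[3] % side:
            raise ValueError(
                f"input sides must be multiples of 2^depth = {side}, got {x.shape[2:]}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) float32 -> (N, 3, H, W) logits."""
        self._check_input(x)
        h = x
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._concat_channels = []
        for j, i in enumerate(reversed(range(self.cfg.depth))):
            g = self.up_relus[j].forward(self.up_convs[j].forward(self.ups[j].forward(h)))
            s = self.atts[j].forward(skips[i], g)
            self._concat_channels.append(s.shape[1])
            h = np.concatenate([s, g], axis=1)
            h = self.dec[j].forward(h)
        return self.out_conv.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.out_conv.backward(dlogits)
        dskips = [None] * self.cfg.depth
        for j in reversed(range(self.cfg.depth)):
            i = self.cfg.depth - 1 - j
            dcat = self.dec[j].backward(dh)
            csplit = self._concat_channels[j]
            ds, dg = dcat[:, :csplit], dcat[:, csplit:]
            ds_att, dg_att = self.atts[j].backward(ds)
            dskips[i] = ds_att
            dg = dg + dg_att
            dh = self.ups[j].backward(self.up_convs[j].backward(self.up_relus[j].backward(dg)))
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(self.cfg.depth)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)

    # -- inference ---------------------------------------------------------
    def predict_batch(self, images: np.ndarray, chunk: int = 16) -> np.ndarray:
        """(N, H, W) in [0,1] -> (N, 3, H, W) per-class probabilities."""
        images = np.asarray(images, dtype=np.float32)
        outs = []
        for start in range(0, images.shape[0], chunk):
            x = images[start : start + chunk][:, None]
            outs.append(sigmoid(self.forward(x)))
        return np.concatenate(outs, axis=0)


def build_model(cfg: ModelConfig, seed: int = 0) -> AttentionUNet:
    """Construct an attention U-Net with deterministic initialisation."""
    return AttentionUNet(cfg, seed=seed)


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form parameter count of :class:`AttentionUNet` for ``cfg``."""
    d, base = cfg.depth, cfg.base_filters
    ch = [base * 2**i for i in range(d + 1)]

    def convblock(ci, co):
        return 9 * ci * co + co + 9 * co * co + co

    total = 0
    c_in = cfg.in_channels
    for i in range(d):
        total += convblock(c_in, ch[i])
        c_in = ch[i]
    total += convblock(ch[d - 1], ch[d])
    for i in reversed(range(d)):
        total += 9 * ch[i + 1] * ch[i] + ch[i]  # up-conv
        c_int = max(ch[i] // 2, 1)
        total += ch[i] * c_int + (ch[i] * c_int + c_int) + (c_int + 1)  # gate
        total += convblock(2 * ch[i], ch[i])
    total += ch[0] * cfg.out_channels + cfg.out_channels
    return total


# ---------------------------------------------------------------------------
# augmentation


def augment_pair(image: np.ndarray, labels: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator):
    """Apply one random rotation/shift/zoom identically to image and labels.

    The image is resampled bilinearly, the labels nearest-neighbour (so label
    values stay in {0, 1, 2}); out-of-frame regions are filled with the image
    minimum (the HU-window floor for windowed slices) and label 0.
    """
    if image.shape != labels.shape:
        raise ValueError("image and labels must share a shape")
    if cfg.shift_h_px is None:
        cfg = cfg.for_plane("axial")
    angle = rng.uniform(*cfg.rotation_deg)
    shift_w = rng.uniform(*cfg.shift_w_px)
    shift_h = rng.uniform(*cfg.shift_h_px)
    zoom = rng.uniform(*cfg.zoom)
    if angle == 0.0 and shift_w == 0.0 and shift_h == 0.0 and zoom == 1.0:
        return image.copy(), labels.copy()

    # Axis 0 is height, axis 1 width.  output(o) = input(A (o - c) + c - s):
    # rotation and zoom about the slice centre, then translation by s.
    th = np.deg2rad(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mat = rot / zoom
    centre = (np.array(image.shape, dtype=float) - 1.0) / 2.0
    shift = np.array([shift_h, shift_w])
    # input_coord = mat @ (output - shift - centre) + centre
    offset = centre - mat @ (centre + shift)
    img_out = ndimage.affine_transform(
        image.astype(np.float32), mat, offset=offset, order=1,
        mode="constant", cval=float(image.min()),
    )
    lab_out = ndimage.affine_transform(
        labels, mat, offset=offset, order=0, mode="constant", cval=0
    )
    return img_out, lab_out


# ---------------------------------------------------------------------------
# training


def one_hot(labels: np.ndarray) -> np.ndarray:
    """(H, W) int labels -> (3, H, W) float32 one-hot target."""
    return np.stack([(labels == c) for c in range(N_CLASSES)]).astype(np.float32)


def _mean_loss(model: AttentionUNet, slices, batch: int = 16) -> float:
    total, count = 0.0, 0
    for start in range(0, len(slices), batch):
        chunk = slices[start : start + batch]
        x = np.stack([im for im, _ in chunk])[:, None].astype(np.float32)
        t = np.stack([one_hot(lab) for _, lab in chunk])
        loss, _ = bce_with_logits(model.forward(x), t)
        total += loss * len(chunk)
        count += len(chunk)
    return total / count


def train_plane_model(
    train_slices,
    val_slices,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    acfg: AugmentConfig | None = None,
    plane_axis: str = "axial",
    init_seed: int | None = None,
):
    """Train one single-plane model; returns ``(model, history)``.

    ``train_slices``/``val_slices`` are sequences of ``(image, labels)`` 2D
    pairs with images already windowed and scaled to [0, 1].  Mini-batches of
    ``tcfg.batch_size`` slices are sampled uniformly from the training pool,
    each slice independently augmented.  Training stops when the validation
    loss has not improved for ``tcfg.patience`` consecutive epochs, and the
    best-validation parameters are restored.  History is a DataFrame with
    per-epoch mean train loss and validation loss.
    """
    if not train_slices:
        raise TrainingError("empty training set")
    if not val_slices:
        raise TrainingError("empty validation set")
    acfg_resolved = acfg.for_plane(plane_axis) if acfg is not None else None
    rng = np.random.default_rng(tcfg.seed)
    model = build_model(mcfg, seed=tcfg.seed if init_seed is None else init_seed)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    n = len(train_slices)
    steps = tcfg.steps_per_epoch or max(1, int(np.ceil(n / tcfg.batch_size)))

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    rows = []
    for epoch in range(tcfg.max_epochs):
        losses = []
        for _ in range(steps):
            idx = rng.integers(0, n, size=tcfg.batch_size)
            imgs, labs = [], []
            for i in idx:
                im, lab = train_slices[i]
                if acfg_resolved is not None:
                    im, lab = augment_pair(im, lab, acfg_resolved, rng)
                imgs.append(im)
                labs.append(one_hot(lab))
            x = np.stack(imgs)[:, None].astype(np.float32)
            t = np.stack(labs)
            logits = model.forward(x)
            loss, dlogits = bce_with_logits(logits, t)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss = _mean_loss(model, val_slices)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= tcfg.patience:
            break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


def predict_slice(model: AttentionUNet, image: np.ndarray) -> np.ndarray:
    """One preprocessed 2D slice -> (3, H, W) probabilities in [0, 1]."""
    return model.predict_batch(np.asarray(image)[None])[0]


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: AttentionUNet, path) -> None:
    """Write parameters as .npz plus a sidecar YAML of the ModelConfig."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = model.cfg
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "depth": cfg.depth,
                "base_filters": cfg.base_filters,
                "in_channels": cfg.in_channels,
                "out_channels": cfg.out_channels,
            }
        )
    )


def load_model(path) -> AttentionUNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = ModelConfig(**yaml.safe_load(path.with_suffix(".yaml").read_text()))
    model = build_model(cfg, seed=0)
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
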