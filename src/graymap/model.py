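"""Multitask residual CNN on slide-level gray value maps.

A GrayValueMap (per-patch A/F/L triples) is normalized, centered on a fixed
square canvas, and fed to a residual convolutional network with PReLU
activations and two sigmoid heads trained jointly with sigmoid
cross-entropy: a 3-class head for the IHC level (0/1+, 2+, 3+) and a binary
head for FISH amplification status.  Training uses Adam with a cosine
learning-rate schedule and heavy augmentation — random rotation, flips,
random crop, and "paste synthesis", which copies a lower-expression donor
slide of the same FISH status into the blank canvas space of a target slide
to enlarge the training set.

The reference configuration mirrors a ResNet18 backbone (base width 64,
stages 2-2-2-2, 680x680 canvas, 512 crop); :func:`desk_config` gives a
reduced geometry used for fast CPU experiments — same model family, same
training procedure, smaller canvas/width/depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import _nn
from .maps import GrayValueMap

__all__ = [
    "TrainConfig",
    "desk_config",
    "SlideSample",
    "Prediction",
    "canvas_embed",
    "paste_synthesize",
    "MultitaskCNN",
]

IHC_CLASS_NAMES = ("0/1+", "2+", "3+")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Channel normalization divides A and L by the 99th-percentile constants
    ``a_p99``/``l_p99`` (F is already a fraction).  ``base_width`` and
    ``stage_blocks`` set the backbone size; the reference values follow
    ResNet18 (64, (2, 2, 2, 2)).
    """

    base_lr: float = 0.001
    min_lr: float = 1e-8
    epochs: int = 150
    batch_size: int = 8
    dropout_p: float = 0.5
    canvas: int = 680
    crop: int = 512
    rotation_deg: float = 180.0
    hflip: bool = True
    vflip: bool = True
    paste_prob: float = 0.5
    base_width: int = 64
    stage_blocks: tuple[int, ...] = (2, 2, 2, 2)
    a_p99: float = 2.0
    l_p99: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not self.min_lr < self.base_lr:
            raise ValueError("min_lr must be < base_lr")
        if self.crop > self.canvas:
            raise ValueError("crop must be <= canvas")


def desk_config(**overrides) -> TrainConfig:
    """Reduced-geometry config for CPU-scale experiments (same crop ratio)."""
    base = dict(
        canvas=64,
        crop=48,
        base_width=8,
        stage_blocks=(1, 1),
        epochs=40,
        batch_size=8,
    )
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class SlideSample:
    """A canvas-embedded slide with its labels and CV fold."""

    canvas: np.ndarray  # (H, W, 3) float32, zero outside the map
    ihc_label: int | None  # 0 = 0/1+, 1 = 2+, 2 = 3+
    fish_label: int | None  # 0/1, None = missing (masked in the FISH head)
    fold_id: int = 0
    slide_id: str = ""
    pasted: bool = False


@dataclass
class Prediction:
    """Sigmoid head outputs for one slide."""

    ihc_scores: np.ndarray  # (3,) in (0,1), one-vs-rest
    fish_score: float  # in (0,1)

    @property
    def ihc_class(self) -> int:
        return int(np.argmax(self.ihc_scores))

    @property
    def fish_class(self) -> int:
        return int(self.fish_score >= 0.5)


def canvas_embed(gmap: GrayValueMap, cfg: TrainConfig) -> np.ndarray:
    """Normalize a gray value map and center it on a zero square canvas.

    A and L are divided by ``cfg.a_p99``/``cfg.l_p99``; F stays a fraction.
    Maps larger than the canvas are downscaled by area averaging, preserving
    aspect ratio.
    """
    grid = np.asarray(gmap.grid, dtype=np.float64).copy()
    if grid.size == 0:
        raise ValueError("empty gray value map")
    grid[..., 0] /= cfg.a_p99
    grid[..., 2] /= cfg.l_p99
    h, w = grid.shape[:2]
    if h > cfg.canvas or w > cfg.canvas:
        scale = min(cfg.canvas / h, cfg.canvas / w)
        new_h, new_w = max(1, int(h * scale)), max(1, int(w * scale))
        grid = resize(grid, (new_h, new_w), order=1, anti_aliasing=True, preserve_range=True)
        h, w = new_h, new_w
    canvas = np.zeros((cfg.canvas, cfg.canvas, 3), dtype=np.float32)
    top = (cfg.canvas - h) // 2
    left = (cfg.canvas - w) // 2
    canvas[top : top + h, left : left + w] = grid
    return canvas


def paste_synthesize(target: SlideSample, donor: SlideSample, seed: int, max_tries: int = 20) -> SlideSample:
    """Paste a lower-expression donor into the blank space of a target canvas.

    Preconditions (training-set hygiene): same FISH status, same CV fold,
    donor IHC level strictly below the target's.  The donor's nonzero cells
    are translated by a random seeded offset; a placement is accepted only
    where it covers exclusively zero cells of the target.  After
    ``max_tries`` failures the target is returned unchanged (``pasted``
    False).  The result always carries the target's labels.
    """
    if donor.fish_label != target.fish_label:
        raise ValueError("paste synthesis requires matching FISH status")
    if donor.fold_id != target.fold_id:
        raise ValueError("paste synthesis requires matching CV fold")
    if donor.ihc_label is None or target.ihc_label is None or donor.ihc_label >= target.ihc_label:
        raise ValueError("donor IHC level must be strictly below the target's")

    rng = np.random.default_rng(seed)
    dmask = np.any(donor.canvas != 0, axis=2)
    if not dmask.any():
        return replace(target, pasted=False)
    rows = np.flatnonzero(dmask.any(axis=1))
    cols = np.flatnonzero(dmask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    block = donor.canvas[r0:r1, c0:c1]
    bmask = dmask[r0:r1, c0:c1]
    bh, bw = bmask.shape
    H, W = target.canvas.shape[:2]
    tmask = np.any(target.canvas != 0, axis=2)
    if bh > H or bw > W:
        return replace(target, pasted=False)
    for _ in range(max_tries):
        top = int(rng.integers(0, H - bh + 1))
        left = int(rng.integers(0, W - bw + 1))
        if not (tmask[top : top + bh, left : left + bw] & bmask).any():
            out = target.canvas.copy()
            region = out[top : top + bh, left : left + bw]
            region[bmask] = block[bmask]
            return replace(target, canvas=out, pasted=True)
    return replace(target, pasted=False)


def _augment(canvas: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    out = canvas
    if cfg.rotation_deg:
        angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0)
    if cfg.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    h, w = out.shape[:2]
    top = int(rng.integers(0, h - cfg.crop + 1))
    left = int(rng.integers(0, w - cfg.crop + 1))
    return np.ascontiguousarray(out[top : top + cfg.crop, left : left + cfg.crop])


def _center_crop(canvas: np.ndarray, crop: int) -> np.ndarray:
    h, w = canvas.shape[:2]
    top = (h - crop) // 2
    left = (w - crop) // 2
    return np.ascontiguousarray(canvas[top : top + crop, left : left + crop])


def _build_net(cfg: TrainConfig, rng: np.random.Generator):
    layers = [
        _nn.Conv2d(3, cfg.base_width, 3, stride=1, rng=rng, bias=False),
        _nn.BatchNorm2d(cfg.base_width),
        _nn.PReLU(cfg.base_width),
    ]
    cin = cfg.base_width
    for stage, n_blocks in enumerate(cfg.stage_blocks):
        cout = cfg.base_width * (2**stage)
        for b in range(n_blocks):
            stride = 2 if (b == 0 and stage > 0) else 1
            layers.append(_nn.ResidualBlock(cin, cout, stride=stride, rng=rng))
            cin = cout
    backbone = _nn.Sequential(*layers)
    pool = _nn.GlobalAvgPool()
    drop_ihc = _nn.Dropout(cfg.dropout_p)
    drop_fish = _nn.Dropout(cfg.dropout_p)
    head_ihc = _nn.Linear(cin, 3, rng=rng)
    head_fish = _nn.Linear(cin, 1, rng=rng)
    return backbone, pool, drop_ihc, drop_fish, head_ihc, head_fish


class MultitaskCNN:
    """Joint IHC-level / FISH-status classifier over gray value maps.

    Use :meth:`fit` on a list of :class:`SlideSample`; :meth:`predict` and
    :meth:`predict_sample` run deterministically (center crop, no dropout,
    batch-norm running statistics).
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        (
            self.backbone,
            self.pool,
            self.drop_ihc,
            self.drop_fish,
            self.head_ihc,
            self.head_fish,
        ) = _build_net(cfg, rng)
        self.history: list[dict] = []
        self._fitted = False

    # -- internals ---------------------------------------------------------
    def _params(self):
        return (
            self.backbone.params()
            + self.head_ihc.params()
            + self.head_fish.params()
        )

    def _forward(self, x_nchw: np.ndarray, train: bool, rng=None):
        feat = self.pool.forward(self.backbone.forward(x_nchw, train, rng), train, rng)
        zi = self.head_ihc.forward(self.drop_ihc.forward(feat, train, rng), train, rng)
        zf = self.head_fish.forward(self.drop_fish.forward(feat, train, rng), train, rng)
        return zi, zf

    def _backward(self, dzi: np.ndarray, dzf: np.ndarray):
        dfeat = self.drop_ihc.backward(self.head_ihc.backward(dzi))
        dfeat = dfeat + self.drop_fish.backward(self.head_fish.backward(dzf))
        self.backbone.backward(self.pool.backward(dfeat))

    @staticmethod
    def _targets(batch: list[SlideSample]):
        n = len(batch)
        t_ihc = np.zeros((n, 3))
        m_ihc = np.zeros((n, 3))
        t_fish = np.zeros((n, 1))
        m_fish = np.zeros((n, 1))
        for i, s in enumerate(batch):
            if s.ihc_label is not None:
                t_ihc[i, s.ihc_label] = 1.0
                m_ihc[i] = 1.0
            if s.fish_label is not None:
                t_fish[i, 0] = float(s.fish_label)
                m_fish[i, 0] = 1.0
        return t_ihc, m_ihc, t_fish, m_fish

    # -- public API --------------------------------------------------------
    def fit(self, samples: list[SlideSample]) -> "MultitaskCNN":
        """Train on canvas-embedded samples; returns self.

        Per-epoch: shuffle, optional paste synthesis per sample, rotation/
        flip/crop augmentation, Adam step per mini-batch at the cosine LR for
        the epoch.  The loss is the equal-weight sum of the two heads'
        sigmoid cross-entropies; per-epoch averages land in ``history``.
        """
        cfg = self.cfg
        ihc_present = {s.ihc_label for s in samples if s.ihc_label is not None}
        fish_present = {s.fish_label for s in samples if s.fish_label is not None}
        if len(ihc_present) < 2 or len(fish_present) < 2:
            raise ValueError("each head needs at least two label values present")
        rng = np.random.default_rng(cfg.seed)
        opt = _nn.Adam(self._params(), lr=cfg.base_lr)
        n = len(samples)
        # Donor pool for paste synthesis, keyed by (fish, fold).
        donors: dict[tuple, list[SlideSample]] = {}
        for s in samples:
            donors.setdefault((s.fish_label, s.fold_id), []).append(s)

        for epoch in range(cfg.epochs):
            lr = _nn.cosine_lr(epoch, cfg.epochs, cfg.base_lr, cfg.min_lr)
            opt.lr = lr
            order = rng.permutation(n)
            losses_i, losses_f = [], []
            for start in range(0, n, cfg.batch_size):
                batch = [samples[i] for i in order[start : start + cfg.batch_size]]
                arrs = []
                for s in batch:
                    s_use = s
                    if cfg.paste_prob and rng.random() < cfg.paste_prob and s.ihc_label:
                        pool = [
                            d
                            for d in donors.get((s.fish_label, s.fold_id), [])
                            if d.ihc_label is not None and d.ihc_label < s.ihc_label
                        ]
                        if pool:
                            donor = pool[int(rng.integers(len(pool)))]
                            s_use = paste_synthesize(s, donor, seed=int(rng.integers(2**31)))
                    arrs.append(_augment(s_use.canvas.astype(np.float64), cfg, rng))
                x = np.stack(arrs).transpose(0, 3, 1, 2)
                t_ihc, m_ihc, t_fish, m_fish = self._targets(batch)
                zi, zf = self._forward(x, train=True, rng=rng)
                li, dzi = _nn.bce_with_logits(zi, t_ihc, m_ihc)
                lf, dzf = _nn.bce_with_logits(zf, t_fish, m_fish)
                opt.zero_grad()
                self._backward(dzi, dzf)
                opt.step()
                losses_i.append(li)
                losses_f.append(lf)
            self.history.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "loss_ihc": float(np.mean(losses_i)),
                    "loss_fish": float(np.mean(losses_f)),
                    "loss": float(np.mean(losses_i) + np.mean(losses_f)),
                }
            )
        self._fitted = True
        return self

    def predict_sample(self, sample: SlideSample) -> Prediction:
        if not self._fitted:
            raise RuntimeError("model is not trained; call fit() first")
        x = _center_crop(sample.canvas.astype(np.float64), self.cfg.crop)
        x = x.transpose(2, 0, 1)[None]
        zi, zf = self._forward(x, train=False)
        return Prediction(ihc_scores=_nn.sigmoid(zi[0]), fish_score=float(_nn.sigmoid(zf)[0, 0]))

    def predict(self, gmap: GrayValueMap) -> Prediction:
        """Predict from a raw gray value map (embeds it on the canvas)."""
        sample = SlideSample(canvas=canvas_embed(gmap, self.cfg), ihc_label=None, fish_label=None)
        return self.predict_sample(sample)

    # -- checkpoints -------------------------------------------------------
    def _bn_layers(self):
        found = []

        def walk(layer):
            if isinstance(layer, _nn.Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, _nn.ResidualBlock):
                walk(layer.bn1)
                walk(layer.bn2)
                if layer.proj is not None:
                    walk(layer.proj_bn)
            elif isinstance(layer, _nn.BatchNorm2d):
                found.append(layer)

        walk(self.backbone)
        return found

    def save(self, path) -> None:
        """Serialize weights, batch-norm statistics, and config to ``.npz``."""
        import json as _json

        arrays = {f"param_{i}": p.value for i, p in enumerate(self._params())}
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        cfg = dataclass_to_dict(self.cfg)
        arrays["config_json"] = np.array(_json.dumps(cfg))
        arrays["fitted"] = np.array(self._fitted)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MultitaskCNN":
        import json as _json

        with np.load(path, allow_pickle=False) as data:
            cfg_d = _json.loads(str(data["config_json"]))
            cfg_d["stage_blocks"] = tuple(cfg_d["stage_blocks"])
            net = cls(TrainConfig(**cfg_d))
            for i, p in enumerate(net._params()):
                p.value[...] = data[f"param_{i}"]
            for i, bn in enumerate(net._bn_layers()):
                bn.running_mean = data[f"bn_mean_{i}"]
                bn.running_var = data[f"bn_var_{i}"]
            net._fitted = bool(data["fitted"])
        return net


def dataclass_to_dict(cfg: TrainConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)
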