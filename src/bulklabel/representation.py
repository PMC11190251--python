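"""Use-case-specific patch representation learning.

The feature space is learned in two phases, mirroring the labeling loop it
serves:

1. *Self-supervised pre-training*: two stochastic augmented views of every
   patch are pulled together and pushed away from all other patches in the
   batch with the normalized-temperature cross-entropy (NT-Xent) contrastive
   loss, giving a task-agnostic feature space before a single label exists.
2. *Semi-supervised fine-tuning*: as confirmed labels accumulate, a
   cross-entropy term over the labeled subset (weight ``ce_weight``) is added
   to the contrastive loss, sharpening class separation while unlabeled
   patches keep contributing the contrastive term.

The default backbone is a small residual multi-layer perceptron over the
flattened patch (optionally pooled down to ``encoder_size``), implemented in
NumPy with explicit backpropagation and Adam.  The trainer is deliberately
seed-deterministic: identical (seed, data, config) triples produce
bit-identical model states, which makes every downstream embedding and
efficiency experiment reproducible.  Alternative self-supervised back ends
can be registered via :data:`BACKENDS`; only the contrastive one ships.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "EncoderSpec",
    "TrainConfig",
    "ModelState",
    "BACKENDS",
    "init_model",
    "augment_pair",
    "nt_xent_loss",
    "train_selfsupervised",
    "finetune_semisupervised",
    "compute_features",
    "predict_labels",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the patch encoder.

    ``encoder_size`` is the square input resolution actually fed to the
    network; by default it equals ``patch_size`` so the full patch content is
    used.  ``n_blocks`` residual blocks of width ``hidden_dim`` sit between
    the input projection and the ``feature_dim`` output.
    """

    patch_size: int
    encoder_size: int | None = None
    feature_dim: int = 64
    projection_dim: int = 32
    hidden_dim: int = 128
    n_blocks: int = 1
    backbone: str = "residual_mlp"

    @property
    def input_size(self) -> int:
        return self.patch_size if self.encoder_size is None else self.encoder_size

    @property
    def input_dim(self) -> int:
        return 3 * self.input_size * self.input_size


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and augmentation hyperparameters.

    temperature : NT-Xent temperature τ (> 0).
    ce_weight : λ, weight of the supervised cross-entropy term during
        fine-tuning (λ = 0 disables supervision entirely).
    crop_scale : area range of the random resized crop; ``(1, 1)`` together
        with ``flip=False``, ``color_jitter=0`` and ``aug_noise_sd=0`` makes
        augmentation the identity (up to the encoder resize).
    """

    temperature: float = 0.5
    batch_size: int = 64
    epochs_pretrain: int = 20
    epochs_finetune: int = 10
    ce_weight: float = 1.0
    learning_rate: float = 1e-3
    seed: int = 0
    crop_scale: tuple[float, float] = (0.6, 1.0)
    flip: bool = True
    color_jitter: float = 0.15
    aug_noise_sd: float = 0.02
    cosine_decay: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.ce_weight < 0:
            raise ValueError("ce_weight must be >= 0")


@dataclass
class ModelState:
    """Encoder + projection-head + classification-head weights and the Adam
    moments, serializable bit-exactly."""

    spec: EncoderSpec
    n_classes: int
    params: dict[str, np.ndarray]
    opt_m: dict[str, np.ndarray]
    opt_v: dict[str, np.ndarray]
    step: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            spec=self.spec,
            n_classes=self.n_classes,
            params={k: v.copy() for k, v in self.params.items()},
            opt_m={k: v.copy() for k, v in self.opt_m.items()},
            opt_v={k: v.copy() for k, v in self.opt_v.items()},
            step=self.step,
        )

    def to_bytes(self) -> bytes:
        buf = io.BytesIO()
        arrays = {f"p_{k}": v for k, v in self.params.items()}
        arrays |= {f"m_{k}": v for k, v in self.opt_m.items()}
        arrays |= {f"v_{k}": v for k, v in self.opt_v.items()}
        meta = {"spec": asdict(self.spec), "n_classes": self.n_classes,
                "step": self.step}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(buf, **arrays)
        return buf.getvalue()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "ModelState":
        with np.load(io.BytesIO(blob)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = EncoderSpec(**meta["spec"])
            params = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
            opt_m = {k[2:]: data[k] for k in data.files if k.startswith("m_")}
            opt_v = {k[2:]: data[k] for k in data.files if k.startswith("v_")}
        return cls(spec, int(meta["n_classes"]), params, opt_m, opt_v,
                   int(meta["step"]))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_model(spec: EncoderSpec, n_classes: int, seed: int) -> ModelState:
    """He-initialized encoder/projection weights; near-zero heads so that an
    untrained classifier outputs ~uniform confidences."""
    rng = np.random.default_rng(seed)
    d, h, f, p = spec.input_dim, spec.hidden_dim, spec.feature_dim, spec.projection_dim

    def he(shape):
        return rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)

    params: dict[str, np.ndarray] = {"W0": he((d, h)), "b0": np.zeros(h)}
    for i in range(spec.n_blocks):
        params[f"Wb{i}"] = he((h, h))
        params[f"bb{i}"] = np.zeros(h)
    params["Wf"] = he((h, f))
    params["bf"] = np.zeros(f)
    params["Wp1"] = he((f, f))
    params["bp1"] = np.zeros(f)
    params["Wp2"] = he((f, p))
    params["bp2"] = np.zeros(p)
    params["Wc"] = 1e-3 * rng.normal(size=(f, n_classes))
    params["bc"] = np.zeros(n_classes)
    zeros = {k: np.zeros_like(v) for k, v in params.items()}
    return ModelState(spec, n_classes, params,
                      {k: v.copy() for k, v in zeros.items()},
                      {k: v.copy() for k, v in zeros.items()})


# ---------------------------------------------------------------------------
# preprocessing & augmentation
# ---------------------------------------------------------------------------

def _resize_square(img: np.ndarray, size: int) -> np.ndarray:
    """Deterministic resize of a square float image to (size, size)."""
    side = img.shape[0]
    if side == size:
        return img
    if side % size == 0:
        k = side // size
        return img.reshape(size, k, size, k, 3).mean(axis=(1, 3))
    return _sk_resize(img, (size, size, 3), order=1, preserve_range=True,
                      anti_aliasing=side > size)


def preprocess(patches, encoder_size: int) -> np.ndarray:
    """uint8 patches -> float64 array (n, encoder_size, encoder_size, 3) in [0, 1]."""
    out = np.empty((len(patches), encoder_size, encoder_size, 3))
    for i, patch in enumerate(patches):
        img = np.asarray(patch, dtype=np.float64)
        if img.max() > 1.0:
            img = img / 255.0
        out[i] = _resize_square(img, encoder_size)
    return out


def _one_view(patch: np.ndarray, rng: np.random.Generator, cfg: TrainConfig,
              encoder_size: int) -> np.ndarray:
    ps = patch.shape[0]
    scale = rng.uniform(*cfg.crop_scale)
    side = int(np.clip(round(ps * np.sqrt(scale)), 1, ps))
    top = int(rng.integers(0, ps - side + 1))
    left = int(rng.integers(0, ps - side + 1))
    view = patch[top:top + side, left:left + side]
    if cfg.flip:
        if rng.random() < 0.5:
            view = view[:, ::-1]
        if rng.random() < 0.5:
            view = view[::-1]
    if cfg.color_jitter > 0:
        gains = 1.0 + rng.uniform(-cfg.color_jitter, cfg.color_jitter, size=3)
        view = view * gains
    view = _resize_square(np.ascontiguousarray(view, dtype=np.float64),
                          encoder_size)
    if cfg.aug_noise_sd > 0:
        view = view + rng.normal(0.0, cfg.aug_noise_sd, size=view.shape)
    return np.clip(view, 0.0, 1.0)


def augment_pair(patch: np.ndarray, rng: np.random.Generator,
                 cfg: TrainConfig | None = None,
                 encoder_size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two stochastic views of one patch: random resized crop, flips, color
    jitter and Gaussian noise, both resized to ``encoder_size``.

    With all augmentation strengths zero the two views are identical and
    equal the (resized) patch.
    """
    cfg = cfg or TrainConfig()
    img = np.asarray(patch, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    es = encoder_size if encoder_size is not None else img.shape[0]
    return _one_view(img, rng, cfg, es), _one_view(img, rng, cfg, es)


# ---------------------------------------------------------------------------
# forward / backward primitives
# ---------------------------------------------------------------------------

def _encoder_forward(params, spec: EncoderSpec, x: np.ndarray):
    pre0 = x @ params["W0"] + params["b0"]
    h = np.maximum(pre0, 0.0)
    block_cache = []
    for i in range(spec.n_blocks):
        pre = h @ params[f"Wb{i}"] + params[f"bb{i}"]
        act = np.maximum(pre, 0.0)
        block_cache.append((h, pre))
        h = h + act
    f = h @ params["Wf"] + params["bf"]
    return f, (x, pre0, block_cache, h)


def _encoder_backward(params, spec: EncoderSpec, cache, df, grads):
    x, pre0, block_cache, h_last = cache
    grads["Wf"] += h_last.T @ df
    grads["bf"] += df.sum(axis=0)
    dh = df @ params["Wf"].T
    for i in reversed(range(spec.n_blocks)):
        h_in, pre = block_cache[i]
        dact = dh * (pre > 0)
        grads[f"Wb{i}"] += h_in.T @ dact
        grads[f"bb{i}"] += dact.sum(axis=0)
        dh = dh + dact @ params[f"Wb{i}"].T
    dpre0 = dh * (pre0 > 0)
    grads["W0"] += x.T @ dpre0
    grads["b0"] += dpre0.sum(axis=0)


def _projection_forward(params, f: np.ndarray):
    pre = f @ params["Wp1"] + params["bp1"]
    a = np.maximum(pre, 0.0)
    u = a @ params["Wp2"] + params["bp2"]
    return u, (f, pre, a)


def _projection_backward(params, cache, du, grads):
    f, pre, a = cache
    grads["Wp2"] += a.T @ du
    grads["bp2"] += du.sum(axis=0)
    da = du @ params["Wp2"].T
    dpre = da * (pre > 0)
    grads["Wp1"] += f.T @ dpre
    grads["bp1"] += dpre.sum(axis=0)
    return dpre @ params["Wp1"].T  # gradient w.r.t. features


def _nt_xent_with_grad(u: np.ndarray, temperature: float):
    """NT-Xent loss and its gradient w.r.t. the *unnormalized* projections.

    ``u`` holds 2N rows laid out [a_1..a_N, b_1..b_N]; view i's positive is
    i+N (mod 2N).  Cosine similarities are divided by the temperature; each
    view's loss is the softmax cross-entropy of its positive among the other
    2N-1 views, and the result is averaged over all 2N views.
    """
    n2 = u.shape[0]
    n = n2 // 2
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    z = u / norms
    s = (z @ z.T) / temperature
    np.fill_diagonal(s, -np.inf)
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    row_max = s.max(axis=1, keepdims=True)
    exps = np.exp(s - row_max)
    sums = exps.sum(axis=1, keepdims=True)
    logsum = np.log(sums) + row_max
    loss = float(np.mean(logsum[:, 0] - s[np.arange(n2), pos]))
    # gradient w.r.t. the similarity matrix
    g = exps / sums
    g[np.arange(n2), pos] -= 1.0
    g /= n2
    dz = ((g + g.T) @ z) / temperature
    du = (dz - (dz * z).sum(axis=1, keepdims=True) * z) / norms
    return loss, du


def nt_xent_loss(projections: np.ndarray, temperature: float) -> float:
    """Mean NT-Xent loss over 2N projection vectors (pairs ``(i, i+N)``).

    Inputs are L2-normalized internally, so pre-normalized vectors pass
    through unchanged.  Requires at least N = 2 pairs (otherwise a view has
    no negatives) and τ > 0.
    """
    z = np.asarray(projections, dtype=np.float64)
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if z.ndim != 2 or z.shape[0] % 2 != 0 or z.shape[0] < 4:
        raise ValueError("need an even number 2N >= 4 of projection vectors")
    loss, _ = _nt_xent_with_grad(z, temperature)
    return loss


def _cross_entropy_with_grad(logits: np.ndarray, labels0: np.ndarray):
    """Mean softmax cross-entropy; ``labels0`` are 0-based class indices."""
    m = logits.max(axis=1, keepdims=True)
    expl = np.exp(logits - m)
    probs = expl / expl.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels0] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels0] -= 1.0
    dlogits /= n
    return loss, dlogits


def _adam_step(state: ModelState, grads: dict[str, np.ndarray], lr: float,
               beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    state.step += 1
    t = state.step
    for k, g in grads.items():
        m = state.opt_m[k] = beta1 * state.opt_m[k] + (1 - beta1) * g
        v = state.opt_v[k] = beta2 * state.opt_v[k] + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        state.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_label_array(labels, n: int, n_classes: int) -> np.ndarray:
    """Normalize labels to an int array of length n; 0 marks unlabeled.
    Accepts None, a dict {index: class}, or a sequence (None = unlabeled)."""
    arr = np.zeros(n, dtype=np.int64)
    if labels is None:
        return arr
    if isinstance(labels, dict):
        for i, c in labels.items():
            arr[int(i)] = int(c)
    else:
        for i, c in enumerate(labels):
            if c is not None:
                arr[i] = int(c)
    if arr.max(initial=0) > n_classes or arr.min(initial=0) < 0:
        raise ValueError("labels must be class ids in 1..n_classes")
    return arr


def _train(state: ModelState, patches, labels, cfg: TrainConfig,
           epochs: int) -> ModelState:
    state = state.copy()
    spec = state.spec
    n = len(patches)
    imgs = np.stack([np.asarray(p, dtype=np.float64) for p in patches])
    if imgs.max() > 1.0:
        imgs = imgs / 255.0
    label_arr = _as_label_array(labels, n, state.n_classes)
    # Seeding from (config seed, optimizer step) makes a fine-tune call a
    # reproducible *continuation* distinct from a fresh run.
    rng = np.random.default_rng([cfg.seed, state.step])
    steps_per_epoch = max(1, n // cfg.batch_size + (n % cfg.batch_size >= 2))
    total_steps = max(1, epochs * steps_per_epoch)
    done = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            views_a, views_b = [], []
            for i in idx:
                va = _one_view(imgs[i], rng, cfg, spec.input_size)
                vb = _one_view(imgs[i], rng, cfg, spec.input_size)
                views_a.append(va)
                views_b.append(vb)
            x = np.stack(views_a + views_b).reshape(2 * len(idx), -1)
            feats, enc_cache = _encoder_forward(state.params, spec, x)
            u, proj_cache = _projection_forward(state.params, feats)
            _, du = _nt_xent_with_grad(u, cfg.temperature)
            grads = {k: np.zeros_like(v) for k, v in state.params.items()}
            df = _projection_backward(state.params, proj_cache, du, grads)
            batch_labels = np.concatenate([label_arr[idx], label_arr[idx]])
            labeled = batch_labels > 0
            if cfg.ce_weight > 0 and labeled.any():
                f_lab = feats[labeled]
                logits = f_lab @ state.params["Wc"] + state.params["bc"]
                _, dlogits = _cross_entropy_with_grad(
                    logits, batch_labels[labeled] - 1)
                dlogits *= cfg.ce_weight
                grads["Wc"] += f_lab.T @ dlogits
                grads["bc"] += dlogits.sum(axis=0)
                df[labeled] += dlogits @ state.params["Wc"].T
            _encoder_backward(state.params, spec, enc_cache, df, grads)
            lr = cfg.learning_rate
            if cfg.cosine_decay:
                lr *= 0.5 * (1.0 + np.cos(np.pi * done / total_steps))
            _adam_step(state, grads, lr)
            done += 1
    return state


def train_selfsupervised(patches, spec: EncoderSpec, cfg: TrainConfig,
                         n_classes: int = 2) -> ModelState:
    """Contrastive pre-training from a seeded random initialization.

    With ``epochs_pretrain=0`` the returned state is exactly the seeded
    initialization.  Requires at least 4 patches (a contrastive batch needs
    negatives).
    """
    if len(patches) < 4:
        raise ValueError("self-supervised training requires >= 4 patches")
    state = init_model(spec, n_classes, cfg.seed)
    return _train(state, patches, None, cfg, cfg.epochs_pretrain)


def finetune_semisupervised(state: ModelState, patches, labels,
                            cfg: TrainConfig) -> ModelState:
    """Continue training with contrastive loss + λ·cross-entropy on the
    labeled subset.

    ``labels`` maps patch index -> class id (1..K), or is a per-patch
    sequence with ``None`` for unlabeled; an empty label set degrades to pure
    self-supervised continuation.
    """
    return _train(state, patches, labels, cfg, cfg.epochs_finetune)


BACKENDS = {"contrastive": train_selfsupervised}
"""Registry of self-supervised training back ends (pluggable contract:
``fn(patches, spec, cfg, n_classes) -> ModelState``)."""


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def compute_features(state: ModelState, patches) -> np.ndarray:
    """Deterministic forward pass (no augmentation): one ``feature_dim`` row
    per patch, in patch order."""
    x = preprocess(patches, state.spec.input_size).reshape(len(patches), -1)
    feats, _ = _encoder_forward(state.params, state.spec, x)
    return feats


def predict_labels(state: ModelState, patches) -> tuple[np.ndarray, np.ndarray]:
    """Classification-head predictions: (class ids 1..K, softmax confidence)."""
    feats = compute_features(state, patches)
    logits = feats @ state.params["Wc"] + state.params["bc"]
    m = logits.max(axis=1, keepdims=True)
    expl = np.exp(logits - m)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return probs.argmax(axis=1) + 1, probs.max(axis=1)
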