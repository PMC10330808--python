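"""A small trainable vessel segmenter with explicit gradients.

The adaptation method is architecture-agnostic: it needs K parameterized
functions mapping an image to a per-pixel foreground probability in (0, 1),
trainable by gradient descent.  Here that function is a pixelwise two-layer
perceptron on top of a fixed multiscale filter bank — per scale sigma, the
Gaussian-smoothed luminance, the Gaussian gradient magnitude, and the
scale-normalized leading Hessian eigenvalue (a classic ridge detector that
lights up on dark curvilinear vessels) — plus the raw normalized channels.
Only the MLP weights train; the filter bank is fixed, which keeps the
parameter count tiny and the forward/backward pass pure numpy.

Gradients are written out by hand (the network is two affine layers and two
pointwise nonlinearities) and optimized with Adam.  Checkpoints are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    sigmas are the filter-bank scales in pixels; hidden the MLP width.
    """

    hidden: int = 128
    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)

    @property
    def n_features(self) -> int:
        return 3 + 3 * len(self.sigmas)


def extract_features(image: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Fixed per-pixel feature stack, standardized per image.

    Returns an (H, W, D) float array with D = 3 raw channels + 3 filter
    responses per scale.  Each feature map is z-scored over the image so the
    trainable head sees comparable scales regardless of the input's
    photometry.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) image")
    lum = img.mean(axis=-1)
    feats = [img[..., 0], img[..., 1], img[..., 2]]
    for s in config.sigmas:
        feats.append(ndimage.gaussian_filter(lum, s))
        gy = ndimage.gaussian_filter(lum, s, order=(1, 0))
        gx = ndimage.gaussian_filter(lum, s, order=(0, 1))
        feats.append(np.hypot(gy, gx))
        hyy = ndimage.gaussian_filter(lum, s, order=(2, 0))
        hxx = ndimage.gaussian_filter(lum, s, order=(0, 2))
        hxy = ndimage.gaussian_filter(lum, s, order=(1, 1))
        # leading Hessian eigenvalue, scale-normalized: > 0 on dark ridges
        tr = hyy + hxx
        det_part = np.sqrt((hyy - hxx) ** 2 + 4.0 * hxy**2)
        feats.append(0.5 * (tr + det_part) * s**2)
    stack = np.stack(feats, axis=-1)
    mean = stack.reshape(-1, stack.shape[-1]).mean(axis=0)
    std = stack.reshape(-1, stack.shape[-1]).std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return (stack - mean) / std


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


class SegmentationModel:
    """Pixelwise MLP segmenter: features -> tanh hidden layer -> sigmoid.

    Outputs are strictly inside (0, 1) (logits clipped to +-30 before the
    sigmoid).  ``forward`` caches activations for ``backward``, which maps
    d(loss)/d(logit) to parameter gradients.
    """

    PARAM_NAMES = ("W1", "b1", "w2", "b2")

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0,
                 domain_id: str = ""):
        self.config = config
        self.domain_id = domain_id
        rng = np.random.default_rng(seed)
        d, h = config.n_features, config.hidden
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h)),
            "b1": np.zeros(h),
            "w2": rng.normal(0.0, 1.0 / np.sqrt(h), size=h),
            "b2": np.zeros(1),
        }

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, dict]:
        """Probability map plus the activation cache needed for backward."""
        shape = image.shape[:2]
        F = extract_features(image, self.config).reshape(-1, self.config.n_features)
        z1 = F @ self.params["W1"] + self.params["b1"]
        h = np.tanh(z1)
        z2 = h @ self.params["w2"] + self.params["b2"][0]
        p = _sigmoid(z2)
        cache = {"F": F, "h": h, "shape": shape}
        return p.reshape(shape), cache

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map only (inference)."""
        return self.forward(image)[0]

    def backward(self, cache: dict, dloss_dz2: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients from d(loss)/d(logit), shape (H, W) or flat."""
        dz2 = np.asarray(dloss_dz2, dtype=np.float64).ravel()
        F, h = cache["F"], cache["h"]
        grads = {
            "w2": h.T @ dz2,
            "b2": np.array([dz2.sum()]),
        }
        dh = np.outer(dz2, self.params["w2"])
        dz1 = dh * (1.0 - h**2)
        grads["W1"] = F.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "config": {"hidden": self.config.hidden, "sigmas": list(self.config.sigmas)},
            "domain_id": self.domain_id,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()))

    @classmethod
    def from_state_dict(cls, state: dict) -> "SegmentationModel":
        cfg = ModelConfig(hidden=int(state["config"]["hidden"]),
                          sigmas=tuple(state["config"]["sigmas"]))
        model = cls(cfg, seed=0, domain_id=state.get("domain_id", ""))
        for k in cls.PARAM_NAMES:
            model.params[k] = np.asarray(state["params"][k], dtype=np.float64)
        return model

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        return cls.from_state_dict(json.loads(Path(path).read_text()))

    def copy(self) -> "SegmentationModel":
        return SegmentationModel.from_state_dict(self.state_dict())


class Adam:
    """Standard Adam on a model's parameter dict (beta1=0.9, beta2=0.999)."""

    def __init__(self, model: SegmentationModel, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            self.model.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
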