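"""Small trainable default networks fulfilling the model contracts.

The pipeline only requires a *contract*: the detection model maps a 3D patch
to per-voxel spine probabilities, the identification model maps a patch to a
continuous per-pixel vertebra value on the sagittal plane.  Reproducing any
particular U-Net architecture is a non-goal, so the defaults here are
deliberately small: a fixed multi-scale intensity/coordinate featurizer
followed by a trainable pixelwise MLP, optimized with Adam.  Everything is
plain numpy, seeded, and bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

HU_SCALE = 1000.0  # brings CT intensities to O(1) features


class Adam:
    """Standard Adam optimizer over a dict of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m.setdefault(k, np.zeros_like(g))
            self.v.setdefault(k, np.zeros_like(g))
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _PixelMLP:
    """One-hidden-layer tanh MLP applied independently to every pixel/voxel."""

    def __init__(self, n_features: int, n_hidden: int, rng: np.random.Generator,
                 out_scale: float = 1.0):
        self.out_scale = out_scale
        self.params = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(n_features), (n_features, n_hidden)),
            "b1": np.zeros(n_hidden),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(n_hidden), (n_hidden, 1)),
            "b2": np.zeros(1),
        }

    def forward(self, X: np.ndarray):
        h = np.tanh(X @ self.params["W1"] + self.params["b1"])
        z = (h @ self.params["W2"])[:, 0] + self.params["b2"][0]
        return self.out_scale * z, (X, h)

    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        X, h = cache
        dz = self.out_scale * dout
        dW2 = h.T @ dz[:, None]
        db2 = np.array([dz.sum()])
        dh = dz[:, None] @ self.params["W2"].T
        dpre = dh * (1.0 - h * h)
        return {
            "W1": X.T @ dpre,
            "b1": dpre.sum(axis=0),
            "W2": dW2,
            "b2": db2,
        }


def _state_dict(mlp: _PixelMLP) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in mlp.params.items()}


class DetectionNet:
    """Default binary spine segmenter: multi-scale intensity features ->
    pixelwise MLP -> sigmoid probability per voxel.

    The larger box-filter scales provide the context a 3D CNN would learn:
    they separate dim voxels *surrounded* by bone (inter-vertebral bridges,
    which must stay spine so the spine remains one connected component) from
    bright but isolated structures such as the scanner bed.
    """

    n_features = 4

    def __init__(self, n_hidden: int = 8, seed: int = 0, learning_rate: float = 1e-3):
        self.mlp = _PixelMLP(self.n_features, n_hidden,
                             np.random.default_rng(seed))
        self.optimizer = Adam(learning_rate)
        self.history: list[float] = []

    @staticmethod
    def features(patch: np.ndarray) -> np.ndarray:
        p = np.asarray(patch, dtype=np.float64)
        feats = np.stack(
            [p, uniform_filter(p, 3), uniform_filter(p, 7), uniform_filter(p, 13)],
            axis=-1,
        ) / HU_SCALE
        return feats.reshape(-1, DetectionNet.n_features)

    def forward_features(self, X: np.ndarray):
        z, cache = self.mlp.forward(X)
        return 1.0 / (1.0 + np.exp(-z)), cache

    def backward_logits(self, cache, dz: np.ndarray) -> dict[str, np.ndarray]:
        return self.mlp.backward(cache, dz)

    def apply_gradients(self, grads: dict[str, np.ndarray]):
        self.optimizer.step(self.mlp.params, grads)

    def predict_proba(self, patch: np.ndarray) -> np.ndarray:
        prob, _ = self.forward_features(self.features(patch))
        return prob.reshape(np.asarray(patch).shape)

    def state_dict(self):
        return _state_dict(self.mlp)


class IdentificationNet:
    """Default per-pixel vertebra-value regressor on the sagittal plane.

    The patch's thin sagittal-slab axis is collapsed by maximum intensity;
    features are multi-scale intensities plus the absolute row/column mm
    coordinate of each pixel (patch origin + index), which gives the tiny
    pixelwise model the spatial context a large-receptive-field CNN would
    learn.  The output is a continuous vertebra value (rounded downstream).
    """

    n_features = 5

    def __init__(self, n_hidden: int = 32, seed: int = 0,
                 learning_rate: float = 5e-4, out_scale: float = 10.0):
        self.mlp = _PixelMLP(self.n_features, n_hidden,
                             np.random.default_rng(seed), out_scale=out_scale)
        self.optimizer = Adam(learning_rate)
        self.history: list[tuple[int, str, float]] = []

    @staticmethod
    def features(patch: np.ndarray, origin=(0, 0, 0),
                 spacing=(1.0, 1.0, 1.0)) -> tuple[np.ndarray, tuple[int, int]]:
        """Pixelwise features for the sagittal max projection of a 3D patch.
        Returns (features, plane_shape)."""
        img = np.asarray(patch, dtype=np.float64).max(axis=0)
        rr, cc = np.indices(img.shape)
        feats = np.stack(
            [
                img / HU_SCALE,
                gaussian_filter(img, 1.0) / HU_SCALE,
                gaussian_filter(img, 3.0) / HU_SCALE,
                (origin[1] + rr) * spacing[1] / 100.0,
                (origin[2] + cc) * spacing[2] / 100.0,
            ],
            axis=-1,
        )
        return feats.reshape(-1, IdentificationNet.n_features), img.shape

    def forward_features(self, X: np.ndarray):
        return self.mlp.forward(X)

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        return self.mlp.backward(cache, dy)

    def apply_gradients(self, grads: dict[str, np.ndarray]):
        self.optimizer.step(self.mlp.params, grads)

    def predict_plane(self, patch: np.ndarray, origin=(0, 0, 0),
                      spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
        X, shape = self.features(patch, origin, spacing)
        y, _ = self.forward_features(X)
        return y.reshape(shape)

    def state_dict(self):
        return _state_dict(self.mlp)


def save_model(model, path):
    """Persist a model's trainable parameters plus its class name."""
    np.savez(path, __class__=type(model).__name__, **model.mlp.params)


def load_model(path, learning_rate: float | None = None):
    data = np.load(path, allow_pickle=False)
    name = str(data["__class__"])
    cls = {"DetectionNet": DetectionNet, "IdentificationNet": IdentificationNet}[name]
    kwargs = {} if learning_rate is None else {"learning_rate": learning_rate}
    model = cls(**kwargs)
    for k in model.mlp.params:
        model.mlp.params[k] = data[k]
    return model
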