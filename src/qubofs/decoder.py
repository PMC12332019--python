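"""Convolutional decoder for reconstructing images from selected pixels.

Architecture: a linear layer mapping the k input values to a
``c1 x (side/4) x (side/4)`` feature map, followed by two transposed
convolutions (kernel 4, stride 2, padding 1, so the spatial size doubles
twice: side/4 -> side/2 -> side), with a ReLU after the linear layer and the
first transposed convolution and a sigmoid after the last.  Trained with
Adam on mean-squared-error loss.

Implemented directly on NumPy with hand-written backprop so the evaluation
stack has no deep-learning framework dependency; training is deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .solvers import SelectionMask

__all__ = [
    "DecoderConfig",
    "Decoder",
    "Autoencoder",
    "build_decoder",
    "train_decoder",
    "train_on_codes",
    "evaluate_mse",
    "evaluate_mse_on_codes",
    "mask_to_codes",
]


@dataclass(frozen=True)
class DecoderConfig:
    k: int
    side: int
    c1: int = 32
    c2: int = 16
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side % 4 != 0:
            raise ConfigError(
                f"image side must be divisible by 4 (two stride-2 upsamplings); "
                f"got side={self.side}"
            )
        # each transposed conv must exactly double the spatial size
        if (1 * self.stride - 2 * self.padding + self.kernel) != 2 * self.stride:
            raise ConfigError(
                "kernel/stride/padding must satisfy k - 2p == s so each layer "
                "doubles the spatial size"
            )
        if self.k < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("k >= 1, epochs >= 0 and batch_size >= 1 required")


# ---------------------------------------------------------------------------
# functional layers


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _convt_spans(hi: int, ho: int, kpos: int, stride: int, pad: int):
    """Input/output index spans hit by kernel offset ``kpos`` (1-D)."""
    i0 = max(0, -((kpos - pad) // stride))
    i1 = min(hi - 1, (ho - 1 + pad - kpos) // stride)
    if i0 > i1:
        return None
    o0 = i0 * stride - pad + kpos
    count = i1 - i0 + 1
    return slice(i0, i1 + 1), slice(o0, o0 + count * stride, stride)


def convt_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int
) -> np.ndarray:
    """Transposed 2-D convolution. ``x``: (B, Cin, H, H); ``w``:
    (Cin, Cout, K, K); output: (B, Cout, (H-1)*s - 2p + K, same)."""
    batch, cin, hi, wi = x.shape
    k = w.shape[2]
    ho = (hi - 1) * stride - 2 * pad + k
    wo = (wi - 1) * stride - 2 * pad + k
    y = np.zeros((batch, w.shape[1], ho, wo))
    for ki in range(k):
        rows = _convt_spans(hi, ho, ki, stride, pad)
        if rows is None:
            continue
        for kj in range(k):
            cols = _convt_spans(wi, wo, kj, stride, pad)
            if cols is None:
                continue
            y[:, :, rows[1], cols[1]] += np.einsum(
                "bcij,cd->bdij", x[:, :, rows[0], cols[0]], w[:, :, ki, kj]
            )
    return y + b[None, :, None, None]


def convt_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray, stride: int, pad: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of :func:`convt_forward`."""
    batch, cin, hi, wi = x.shape
    k = w.shape[2]
    ho, wo = dy.shape[2], dy.shape[3]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for ki in range(k):
        rows = _convt_spans(hi, ho, ki, stride, pad)
        if rows is None:
            continue
        for kj in range(k):
            cols = _convt_spans(wi, wo, kj, stride, pad)
            if cols is None:
                continue
            dy_sub = dy[:, :, rows[1], cols[1]]
            dx[:, :, rows[0], cols[0]] += np.einsum(
                "bdij,cd->bcij", dy_sub, w[:, :, ki, kj]
            )
            dw[:, :, ki, kj] = np.einsum(
                "bcij,bdij->cd", x[:, :, rows[0], cols[0]], dy_sub
            )
    return dx, dw, dy.sum(axis=(0, 2, 3))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class Decoder:
    """k-vector -> (side, side) image decoder with hand-written backprop."""

    def __init__(self, cfg: DecoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        s4 = cfg.side // 4
        self.s4 = s4
        flat1 = cfg.c1 * s4 * s4
        self.params: dict[str, np.ndarray] = {
            "w1": rng.normal(0.0, np.sqrt(2.0 / cfg.k), size=(cfg.k, flat1)),
            "b1": np.zeros(flat1),
            "w2": rng.normal(
                0.0, np.sqrt(2.0 / (cfg.c1 * cfg.kernel**2)),
                size=(cfg.c1, cfg.c2, cfg.kernel, cfg.kernel),
            ),
            "b2": np.zeros(cfg.c2),
            "w3": rng.normal(
                0.0, np.sqrt(1.0 / (cfg.c2 * cfg.kernel**2)),
                size=(cfg.c2, 1, cfg.kernel, cfg.kernel),
            ),
            "b3": np.zeros(1),
        }

    def forward(self, codes: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Map (B, k) codes to (B, side, side) reconstructions in (0, 1)."""
        p, cfg = self.params, self.cfg
        z1 = codes @ p["w1"] + p["b1"]
        a1 = _relu(z1).reshape(codes.shape[0], cfg.c1, self.s4, self.s4)
        z2 = convt_forward(a1, p["w2"], p["b2"], cfg.stride, cfg.padding)
        a2 = _relu(z2)
        z3 = convt_forward(a2, p["w3"], p["b3"], cfg.stride, cfg.padding)
        out = _sigmoid(z3)
        if cache is not None:
            cache.update(codes=codes, z1=z1, a1=a1, z2=z2, a2=a2, out=out)
        return out[:, 0]

    def backward(self, cache: dict, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss given d(loss)/d(output image)."""
        p, cfg = self.params, self.cfg
        out = cache["out"]
        dz3 = d_out[:, None] * out * (1.0 - out)
        da2, dw3, db3 = convt_backward(cache["a2"], p["w3"], dz3, cfg.stride, cfg.padding)
        dz2 = da2 * (cache["z2"] > 0)
        da1, dw2, db2 = convt_backward(cache["a1"], p["w2"], dz2, cfg.stride, cfg.padding)
        dz1 = da1.reshape(da1.shape[0], -1) * (cache["z1"] > 0)
        return {
            "w1": cache["codes"].T @ dz1,
            "b1": dz1.sum(axis=0),
            "w2": dw2,
            "b2": db2,
            "w3": dw3,
            "b3": db3,
            "_d_codes": dz1 @ p["w1"].T,  # consumed by the autoencoder wrapper
        }

    def predict(self, codes: np.ndarray, batch_size: int = 512) -> np.ndarray:
        chunks = [
            self.forward(codes[start : start + batch_size])
            for start in range(0, codes.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def save(self, path) -> None:
        np.savez(path, **self.params)

    def load(self, path) -> "Decoder":
        with np.load(path) as archive:
            for key in self.params:
                self.params[key] = archive[key]
        return self


def build_decoder(cfg: DecoderConfig) -> Decoder:
    return Decoder(cfg)


def mask_to_codes(images: np.ndarray, mask: SelectionMask) -> np.ndarray:
    """Extract the selected pixel values (fixed row-major coordinate order)."""
    flat = images.reshape(images.shape[0], -1)
    return flat[:, mask.indices()]


def train_on_codes(
    dec: Decoder,
    codes: np.ndarray,
    images: np.ndarray,
    cfg: DecoderConfig | None = None,
    *,
    encoder: "Autoencoder | None" = None,
) -> list[float]:
    """Train the decoder to map codes to full images; returns per-epoch mean
    training MSE (length == epochs)."""
    cfg = cfg or dec.cfg
    if encoder is None and codes.shape[1] != dec.cfg.k:
        raise ValueError(f"codes have width {codes.shape[1]}, expected k={dec.cfg.k}")
    n = codes.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    opt_params = dict(dec.params)
    if encoder is not None:
        opt_params.update(encoder.enc_params)
    opt = _Adam(opt_params, cfg.learning_rate)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_sse = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_codes = codes[idx]
            if encoder is not None:
                batch_codes = encoder.encode(batch_codes)
            target = images[idx]
            cache: dict = {}
            out = dec.forward(batch_codes, cache)
            err = out - target
            epoch_sse += float((err**2).sum())
            d_out = 2.0 * err / err.size
            grads = dec.backward(cache, d_out)
            d_codes = grads.pop("_d_codes")
            if encoder is not None:
                grads.update(encoder.backward(codes[idx], d_codes))
            opt.step(opt_params, grads)
        history.append(epoch_sse / (n * images.shape[1] * images.shape[2]))
    return history


def train_decoder(
    dec: Decoder,
    images: np.ndarray,
    mask: SelectionMask,
    cfg: DecoderConfig | None = None,
) -> list[float]:
    """Train on masked pixel values as inputs and full images as targets."""
    cfg = cfg or dec.cfg
    if mask.hamming_weight != cfg.k:
        raise ValueError(
            f"mask selects {mask.hamming_weight} pixels but config expects k={cfg.k}"
        )
    return train_on_codes(dec, mask_to_codes(images, mask), images, cfg)


def evaluate_mse_on_codes(dec: Decoder, codes: np.ndarray, images: np.ndarray) -> float:
    """Pooled mean squared error over all pixels of all images."""
    out = dec.predict(codes)
    return float(np.mean((out - images) ** 2))


def evaluate_mse(dec: Decoder, images: np.ndarray, mask: SelectionMask) -> float:
    return evaluate_mse_on_codes(dec, mask_to_codes(images, mask), images)


class Autoencoder:
    """Linear bottleneck encoder (n -> k) sharing the decoder architecture.

    A thin learned-representation comparator: the encoder output replaces
    the masked-pixel code vector and is trained jointly with the decoder.
    """

    def __init__(self, n_features: int, cfg: DecoderConfig):
        self.decoder = Decoder(cfg)
        rng = np.random.default_rng(cfg.seed + 2)
        self.enc_params = {
            "we": rng.normal(0.0, np.sqrt(1.0 / n_features), size=(n_features, cfg.k)),
            "be": np.zeros(cfg.k),
        }

    def encode(self, features: np.ndarray) -> np.ndarray:
        return features @ self.enc_params["we"] + self.enc_params["be"]

    def backward(self, features: np.ndarray, d_codes: np.ndarray) -> dict[str, np.ndarray]:
        return {"we": features.T @ d_codes, "be": d_codes.sum(axis=0)}

    def fit(self, images: np.ndarray) -> list[float]:
        flat = images.reshape(images.shape[0], -1)
        return train_on_codes(self.decoder, flat, images, encoder=self)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.decoder.predict(self.encode(images.reshape(images.shape[0], -1)))

    def mse(self, images: np.ndarray) -> float:
        return float(np.mean((self.reconstruct(images) - images) ** 2))
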