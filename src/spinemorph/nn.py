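"""Minimal NumPy implementation of the segmentation U-net.

Pure-NumPy layers (3x3 same-padded convolution via im2col, batch
normalization, ReLU, 2x2 max pooling, nearest-neighbor upsampling, channel
concatenation) with hand-written backward passes, a soft-Dice loss and an
Adam optimizer.  This keeps the trainable segmenter runnable without a
tensor framework; it is intended for desk-scale experiments on phantoms,
not for clinical-scale training.

Architecture: five encoder blocks of two (conv-BN-ReLU) stacks followed by
2x2 max pooling, filter counts doubling along ``filters`` (default 32 ->
512); the first four encoder blocks are concatenated to their mirrored
decoder blocks (exactly four skip connections); a final 1x1 convolution
with sigmoid yields a probability map, thresholded at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNetSpec", "NumpyUNet", "build_unet", "dice_loss"]

_EPS = 1e-6
_BN_EPS = 1e-5


@dataclass(frozen=True)
class UNetSpec:
    """Architecture and training hyper-parameters of the segmenter."""

    encoder_blocks: int = 5
    filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    skip_connections: int = 4
    loss: str = "dice"
    optimizer: str = "adam"
    learning_rate: float = 0.05
    batch_size: int = 16
    epochs: int = 100

    def __post_init__(self) -> None:
        if len(self.filters) != self.encoder_blocks:
            raise ValueError("one filter count per encoder block required")
        for a, b in zip(self.filters, self.filters[1:]):
            if b != 2 * a:
                raise ValueError("filter counts must double per block")
        if self.skip_connections != self.encoder_blocks - 1:
            raise ValueError("expected one skip per encoder block except the deepest")
        if self.loss != "dice":
            raise ValueError("only the Dice loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


# ---------------------------------------------------------------------------
# layers (forward + backward); all tensors are (N, C, H, W) float32
# ---------------------------------------------------------------------------


def _conv3_forward(x, W, b):
    n, c, h, w = x.shape
    f = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9)
    out = cols @ W.reshape(f, c * 9).T + b
    out = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (cols, x.shape, W)


def _conv3_backward(dout, cache):
    cols, xshape, W = cache
    n, c, h, w = xshape
    f = W.shape[0]
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, f)
    dW = (dflat.T @ cols).reshape(f, c, 3, 3)
    db = dflat.sum(axis=0)
    dcols = dflat @ W.reshape(f, c * 9)
    d6 = dcols.reshape(n, h, w, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dout.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + w] += d6[:, :, :, :, i, j]
    return dxp[:, :, 1:h + 1, 1:w + 1], dW, db


def _conv1_forward(x, W, b):
    # 1x1 convolution == per-pixel linear map
    n, c, h, w = x.shape
    f = W.shape[0]
    flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
    out = flat @ W.reshape(f, c).T + b
    return out.reshape(n, h, w, f).transpose(0, 3, 1, 2), (flat, x.shape, W)


def _conv1_backward(dout, cache):
    flat, xshape, W = cache
    n, c, h, w = xshape
    f = W.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
    dW = (dflat.T @ flat).reshape(f, c, 1, 1)
    db = dflat.sum(axis=0)
    dx = (dflat @ W.reshape(f, c)).reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return dx, dW, db


def _bn_forward(x, gamma, beta, running, train):
    mean_r, var_r, momentum = running
    if train:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        mean_r *= momentum
        mean_r += (1 - momentum) * mu
        var_r *= momentum
        var_r += (1 - momentum) * var
    else:
        mu, var = mean_r, var_r
    ivstd = 1.0 / np.sqrt(var + _BN_EPS)
    xc = x - mu[None, :, None, None]
    xhat = xc * ivstd[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xc, ivstd, xhat, gamma)


def _bn_backward(dout, cache):
    xc, ivstd, xhat, gamma = cache
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    iv = ivstd[None, :, None, None]
    dvar = (dxhat * xc * -0.5 * iv ** 3).sum(axis=(0, 2, 3))
    dmu = (-(dxhat * iv).sum(axis=(0, 2, 3))
           + dvar * (-2.0 / m) * xc.sum(axis=(0, 2, 3)))
    dx = (dxhat * iv
          + (2.0 / m) * dvar[None, :, None, None] * xc
          + dmu[None, :, None, None] / m)
    return dx, dgamma, dbeta


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _relu_backward(dout, mask):
    return dout * mask


def _pool2_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool2_backward(dout, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, w)


def _up2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_loss(probs: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Soft-Dice loss over the whole batch; returns (loss, dL/dprobs)."""
    p = probs.astype(np.float64)
    g = target.astype(np.float64)
    num = 2.0 * (p * g).sum() + _EPS
    den = p.sum() + g.sum() + _EPS
    loss = 1.0 - num / den
    dp = -(2.0 * g * den - num) / den ** 2
    return float(loss), dp.astype(probs.dtype)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class NumpyUNet:
    """U-net built from the NumPy layers above.  See module docstring."""

    def __init__(self, spec: UNetSpec, in_channels: int = 1, seed: int = 0):
        self.spec = spec
        self.in_channels = in_channels
        self.params: dict[str, np.ndarray] = {}
        self.bn_running: dict[str, list] = {}
        rng = np.random.default_rng(seed)
        self._momentum = 0.9

        def add_conv(name: str, cin: int, cout: int, k: int = 3) -> None:
            fan_in = cin * k * k
            self.params[f"{name}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        def add_bn(name: str, c: int) -> None:
            self.params[f"{name}.gamma"] = np.ones(c, dtype=np.float32)
            self.params[f"{name}.beta"] = np.zeros(c, dtype=np.float32)
            self.bn_running[name] = [np.zeros(c, dtype=np.float32),
                                     np.ones(c, dtype=np.float32),
                                     self._momentum]

        f = spec.filters
        cin = in_channels
        for k in range(spec.encoder_blocks):
            for sub in "ab":
                add_conv(f"enc{k}.{sub}", cin, f[k])
                add_bn(f"enc{k}.{sub}.bn", f[k])
                cin = f[k]
        # decoder stage k works at encoder level k's resolution and mirrors
        # its filter count; the deepest stage has no skip connection
        cin = f[-1]
        for k in reversed(range(spec.encoder_blocks)):
            skip = f[k] if k < spec.encoder_blocks - 1 else 0
            cout = f[k]
            c = cin + skip
            for sub in "ab":
                add_conv(f"dec{k}.{sub}", c, cout)
                add_bn(f"dec{k}.{sub}.bn", cout)
                c = cout
            cin = cout
        add_conv("head", f[0], 1, k=1)

    # -- shape bookkeeping ----------------------------------------------
    def check_input_shape(self, shape: tuple[int, int]) -> None:
        d = 2 ** self.spec.encoder_blocks
        if shape[0] % d or shape[1] % d:
            raise ValueError(
                f"input shape {shape} must be divisible by {d} for "
                f"{self.spec.encoder_blocks} pooling stages"
            )

    def feature_map_sizes(self, shape: tuple[int, int]) -> list[tuple[int, int]]:
        """Spatial size after each pooling stage (last entry = bottleneck)."""
        self.check_input_shape(shape)
        sizes = []
        h, w = shape
        for _ in range(self.spec.encoder_blocks):
            h, w = h // 2, w // 2
            sizes.append((h, w))
        return sizes

    # -- forward / backward ----------------------------------------------
    def _block(self, x, name, train, caches):
        for sub in "ab":
            x, c_conv = _conv3_forward(x, self.params[f"{name}.{sub}.W"],
                                       self.params[f"{name}.{sub}.b"])
            x, c_bn = _bn_forward(x, self.params[f"{name}.{sub}.bn.gamma"],
                                  self.params[f"{name}.{sub}.bn.beta"],
                                  self.bn_running[f"{name}.{sub}.bn"], train)
            x, c_relu = _relu_forward(x)
            caches[f"{name}.{sub}"] = (c_conv, c_bn, c_relu)
        return x

    def _block_backward(self, dx, name, caches, grads):
        for sub in "ba":
            c_conv, c_bn, c_relu = caches[f"{name}.{sub}"]
            dx = _relu_backward(dx, c_relu)
            dx, dgamma, dbeta = _bn_backward(dx, c_bn)
            grads[f"{name}.{sub}.bn.gamma"] = dgamma
            grads[f"{name}.{sub}.bn.beta"] = dbeta
            dx, dW, db = _conv3_backward(dx, c_conv)
            grads[f"{name}.{sub}.W"] = dW
            grads[f"{name}.{sub}.b"] = db
        return dx

    def forward(self, x: np.ndarray, train: bool = False,
                _caches: dict | None = None) -> np.ndarray:
        """Map (N, 1, H, W) [or (H, W)] input to a probability map."""
        squeeze = False
        if x.ndim == 2:
            x = x[None, None]
            squeeze = True
        x = np.asarray(x, dtype=np.float32)
        self.check_input_shape(x.shape[2:])
        caches = _caches if _caches is not None else {}
        nb = self.spec.encoder_blocks

        skips = []
        for k in range(nb):
            x = self._block(x, f"enc{k}", train, caches)
            skips.append(x)
            x, cp = _pool2_forward(x)
            caches[f"pool{k}"] = cp

        for k in reversed(range(nb)):
            x = _up2_forward(x)
            if k < nb - 1:
                caches[f"cat{k}"] = x.shape[1]
                x = np.concatenate([x, skips[k]], axis=1)
            x = self._block(x, f"dec{k}", train, caches)

        z, ch = _conv1_forward(x, self.params["head.W"], self.params["head.b"])
        caches["head"] = ch
        probs = _sigmoid(z)
        caches["probs"] = probs
        out = probs[:, 0] if not squeeze else probs[0, 0]
        return out

    def loss_and_grads(self, x: np.ndarray, target: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        caches: dict = {}
        self.forward(x, train=True, _caches=caches)
        probs = caches["probs"]
        if target.ndim == 3:
            target = target[:, None]
        loss, dprobs = dice_loss(probs, target.astype(np.float32))
        dz = dprobs * probs * (1.0 - probs)

        grads: dict[str, np.ndarray] = {}
        dx, dW, db = _conv1_backward(dz, caches["head"])
        grads["head.W"] = dW
        grads["head.b"] = db

        nb = self.spec.encoder_blocks
        dskips: dict[int, np.ndarray] = {}
        for k in range(nb):
            dx = self._block_backward(dx, f"dec{k}", caches, grads)
            if k < nb - 1:
                n_up = caches[f"cat{k}"]
                dskips[k] = dx[:, n_up:]
                dx = dx[:, :n_up]
            dx = _up2_backward(dx)
        for k in reversed(range(nb)):
            dx = _pool2_backward(dx, caches[f"pool{k}"])
            if k in dskips:
                dx = dx + dskips[k]
            dx = self._block_backward(dx, f"enc{k}", caches, grads)
        return loss, grads

    # -- training ---------------------------------------------------------
    def train(
        self,
        images: np.ndarray,
        masks: np.ndarray,
        *,
        epochs: int | None = None,
        batch_size: int | None = None,
        learning_rate: float | None = None,
        seed: int = 0,
        verbose: bool = False,
    ) -> list[float]:
        """Adam + Dice-loss training loop; returns per-step losses."""
        epochs = self.spec.epochs if epochs is None else epochs
        batch_size = self.spec.batch_size if batch_size is None else batch_size
        lr = self.spec.learning_rate if learning_rate is None else learning_rate

        images = np.asarray(images, dtype=np.float32)
        masks = np.asarray(masks, dtype=np.float32)
        if images.ndim == 3:
            images = images[:, None]
        if masks.ndim == 3:
            masks = masks[:, None]

        rng = np.random.default_rng(seed)
        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        losses = []
        for epoch in range(epochs):
            order = rng.permutation(len(images))
            for start in range(0, len(images), batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(images[idx], masks[idx])
                t += 1
                for k, g in grads.items():
                    m_state[k] = b1 * m_state[k] + (1 - b1) * g
                    v_state[k] = b2 * v_state[k] + (1 - b2) * g * g
                    mhat = m_state[k] / (1 - b1 ** t)
                    vhat = v_state[k] / (1 - b2 ** t)
                    self.params[k] -= (lr * mhat /
                                       (np.sqrt(vhat) + eps)).astype(np.float32)
                losses.append(loss)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}: loss {losses[-1]:.4f}")
        return losses

    def predict_mask(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.forward(x, train=False) > threshold)


def build_unet(spec: UNetSpec | None = None, *, in_channels: int = 1,
               input_shape: tuple[int, int] | None = None,
               seed: int = 0) -> NumpyUNet:
    """Construct the segmenter; validates pooling-divisibility eagerly."""
    spec = spec or UNetSpec()
    net = NumpyUNet(spec, in_channels=in_channels, seed=seed)
    if input_shape is not None:
        net.check_input_shape(input_shape)
    return net
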