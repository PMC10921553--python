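"""The 3D residual U-Net segmentation model and the Tversky loss.

The network is a standard 3D U-Net whose convolution stacks are residual
blocks: ``depth`` encoder levels with channel doubling and 2x max-pooling,
a mirror decoder with trilinear upsampling + 1x1x1 channel reduction and
skip concatenation, instance normalisation, ReLU activations and a single
sigmoid output channel.

The Tversky index generalises the Dice overlap with asymmetric penalties:

    T(alpha, beta) = sum(p*g) / (sum(p*g) + alpha*sum(p*(1-g)) + beta*sum((1-p)*g))

with ``p`` the voxelwise tumor probability and ``g`` the binary target; the
training loss is ``1 - T``.  ``alpha`` weights false positives, ``beta``
false negatives; ``alpha = beta = 0.5`` recovers the soft Dice loss.  Defaults
``alpha=0.3, beta=0.7`` follow the established recommendation for small,
imbalanced lesions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .volumes import MaskVolume, Volume

__all__ = [
    "NetworkConfig",
    "TverskyParams",
    "UNet3D",
    "build_network",
    "tversky_index",
    "tversky_loss",
    "tversky_loss_grad",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    The default is the scaled CPU profile (depth 3, base width 8, 48^3
    inputs); the full-scale profile (depth 4, base 16, 256x256x128) is a
    config choice.  ``input_window`` is the HU window used to scale network
    inputs to [0, 1].
    """

    depth: int = 3
    base_channels: int = 8
    input_window: tuple[float, float] = (-200.0, 300.0)
    #: per-level downsampling factors (depth-1 triples); None = 2x2x2
    #: everywhere.  Anisotropic factors such as ((2,2,1),(2,2,2)) keep
    #: slice-axis resolution at the top level of thick-slice volumes.
    pool_factors: tuple | None = None

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.pool_factors is not None:
            pf = tuple(tuple(int(f) for f in lvl) for lvl in self.pool_factors)
            if len(pf) != self.depth - 1 or any(len(lvl) != 3 for lvl in pf):
                raise ValueError(
                    f"pool_factors needs {self.depth - 1} triples, got {pf}"
                )
            if any(f not in (1, 2) for lvl in pf for f in lvl):
                raise ValueError("pool factors must be 1 or 2")
            self.pool_factors = pf

    @property
    def level_factors(self) -> tuple:
        if self.pool_factors is None:
            return tuple((2, 2, 2) for _ in range(self.depth - 1))
        return self.pool_factors

    @property
    def divisors(self) -> tuple[int, int, int]:
        div = [1, 1, 1]
        for lvl in self.level_factors:
            for k in range(3):
                div[k] *= lvl[k]
        return tuple(div)


@dataclass
class TverskyParams:
    alpha: float = 0.3
    beta: float = 0.7
    eps: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


class UNet3D:
    """Residual 3D U-Net mapping a 1-channel volume to a probability map."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        D, B = cfg.depth, cfg.base_channels
        ch = [B * 2**i for i in range(D)]
        factors = cfg.level_factors
        self.enc = [nn.ResidualBlock(1, ch[0], rng)]
        self.pools = []
        for i in range(1, D):
            self.pools.append(nn.MaxPool2(factors[i - 1]))
            self.enc.append(nn.ResidualBlock(ch[i - 1], ch[i], rng))
        self.ups = []
        self.reduces = []
        self.merges = []
        self.dec = []
        for i in range(D - 2, -1, -1):
            self.ups.append(nn.TrilinearUp2(factors[i]))
            self.reduces.append(nn.Conv1(ch[i + 1], ch[i], rng))
            # skip fusion: the concatenation is merged back to the level width
            # by a 1x1x1 convolution so the 3x3x3 stack runs at base cost
            self.merges.append(nn.Conv1(2 * ch[i], ch[i], rng))
            self.dec.append(nn.ResidualBlock(ch[i], ch[i], rng))
        self.head = nn.Conv1(ch[0], 1, rng, bias=True)
        self.sigmoid = nn.Sigmoid()
        self._skip_channels = ch

    # -- parameters --------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = []
        for b in self.enc + self.dec:
            ps += b.params()
        for r in self.reduces + self.merges:
            ps += r.params()
        ps += self.head.params()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_shape(self, shape):
        divs = self.cfg.divisors
        if any(s % d for s, d in zip(shape, divs)):
            raise ValueError(
                f"input shape {shape} must be divisible per-axis by {divs} "
                f"(depth {self.cfg.depth})"
            )

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, N, X, Y, Z) float32 in [0, 1] -> probabilities, same shape."""
        self._check_shape(x.shape[2:])
        feats = []
        h = self.enc[0].forward(np.ascontiguousarray(x, dtype=nn.F32))
        feats.append(h)
        for pool, block in zip(self.pools, self.enc[1:]):
            h = block.forward(pool.forward(h))
            feats.append(h)
        for k, (up, red, merge, block) in enumerate(
            zip(self.ups, self.reduces, self.merges, self.dec)
        ):
            skip = feats[self.cfg.depth - 2 - k]
            h = red.forward(up.forward(h))
            h = block.forward(merge.forward(np.concatenate([skip, h], axis=0)))
        return self.sigmoid.forward(self.head.forward(h))

    def backward(self, dprob: np.ndarray) -> None:
        d = self.head.backward(self.sigmoid.backward(dprob))
        dskips = [None] * (self.cfg.depth - 1)
        for k in range(len(self.dec) - 1, -1, -1):
            d = self.merges[k].backward(self.dec[k].backward(d))
            c = self._skip_channels[self.cfg.depth - 2 - k]
            dskips[self.cfg.depth - 2 - k] = d[:c]
            d = self.ups[k].backward(self.reduces[k].backward(d[c:]))
        for i in range(self.cfg.depth - 1, 0, -1):
            if i < self.cfg.depth - 1:
                d = d + dskips[i]
            d = self.pools[i - 1].backward(self.enc[i].backward(d))
        self.enc[0].backward(d + dskips[0])

    # -- weights I/O -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(ps, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shapes do not match architecture")
            p.value[...] = w


def build_network(cfg: NetworkConfig, seed: int = 0) -> UNet3D:
    """Instantiate a randomly initialised residual U-Net."""
    return UNet3D(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Tversky loss
# ---------------------------------------------------------------------------

def _check_pg(p, g):
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    return p, g


def tversky_index(p, g, params: TverskyParams = TverskyParams()) -> float:
    """T(alpha, beta) of a probability map against a binary target."""
    p, g = _check_pg(p, g)
    tp = float((p * g).sum())
    fp = float((p * (1 - g)).sum())
    fn = float(((1 - p) * g).sum())
    return (tp + params.eps) / (tp + params.alpha * fp + params.beta * fn + params.eps)


def tversky_loss(p, g, params: TverskyParams = TverskyParams()) -> float:
    """1 - T(alpha, beta); zero for a perfect prediction (up to eps)."""
    return 1.0 - tversky_index(p, g, params)


def tversky_loss_grad(p, g, params: TverskyParams = TverskyParams()) -> np.ndarray:
    """d(loss)/dp, same shape as ``p`` (for the training backward pass)."""
    p, g = _check_pg(p, g)
    tp = (p * g).sum()
    fp = (p * (1 - g)).sum()
    fn = ((1 - p) * g).sum()
    num = tp + params.eps
    den = tp + params.alpha * fp + params.beta * fn + params.eps
    # dT/dp_i = [g_i * den - num * (g_i + alpha*(1-g_i) - beta*g_i)] / den^2
    dT = (g * den - num * (g + params.alpha * (1 - g) - params.beta * g)) / den**2
    return -dT


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def volume_to_input(v: Volume, window: tuple[float, float]) -> np.ndarray:
    """Scale a (windowed) volume into the [0, 1] network input tensor."""
    lo, hi = window
    u = (np.clip(np.asarray(v.data, dtype=np.float64), lo, hi) - lo) / (hi - lo)
    return np.ascontiguousarray(u[None, None], dtype=nn.F32)


def predict_mask(
    network: UNet3D, v: Volume, threshold: float = 0.5
) -> tuple[Volume, MaskVolume]:
    """Forward pass returning the probability volume and thresholded mask.

    The binary mask is ``probability >= threshold``; both outputs carry the
    input geometry.
    """
    x = volume_to_input(v, network.cfg.input_window)
    prob = network.forward(x)[0, 0]
    pv = Volume(data=prob, spacing=v.spacing, origin=v.origin, modality=v.modality)
    mask = MaskVolume(
        data=(prob >= threshold).astype(np.uint8), spacing=v.spacing, origin=v.origin
    )
    return pv, mask


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: UNet3D, path, extra: dict | None = None) -> None:
    """Single-file checkpoint with the architecture config embedded."""
    meta = {"config": asdict(network.cfg), "extra": extra or {}}
    arrays = {f"w{i}": w for i, w in enumerate(network.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> UNet3D:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg_d = meta["config"]
        cfg_d["input_window"] = tuple(cfg_d["input_window"])
        cfg = NetworkConfig(**cfg_d)
        net = UNet3D(cfg)
        weights = [z[f"w{i}"] for i in range(len(net.params()))]
    net.set_weights(weights)
    return net
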