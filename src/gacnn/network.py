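"""The GACNN model: CNN branch, attention graph-convolution branch, fusion.

The CNN branch is a modified VGG-19: the 16 convolutional layers are kept
(block plan 2,2,4,4,4 convolutions with 64,128,256,512,512 channels, all
3x3 stride 1), the max-pool after the last block is removed, and the three
fully connected layers are replaced by a global max-pool, so a 224x224x3
input produces a 14x14x512 final map and a length-512 feature vector f_k.
A ``width_multiplier`` scales every channel count for desk-scale training.

The graph branch applies stacked graph convolutions

    H^(j+1) = f(A_hat H^(j) W_j),    H^(0) = X,

and aggregates the per-hop node features with attention weights a_i on the
probability simplex:

    gamma_v = sum_i a_i H_v^(i).

A permutation-invariant readout (mean || max over nodes) produces the
graph vector h_k. The two branches are fused per

    z_k = rho(f_k) + mu * sigma(h_k)

with linear projections rho, sigma to a common dimension and fusion ratio
mu (default 1), and a linear classifier maps z_k to the 5 severity grades.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graphbuild import ImageGraph

__all__ = ["BackboneConfig", "GCNConfig", "FusionConfig", "VGGBackbone",
           "GACNN", "cnn_forward", "gcn_layer", "attention_aggregate",
           "graph_readout", "HopStack"]

_ACTIVATIONS = {
    "relu": (ad.relu, lambda x: np.maximum(x, 0.0)),
    "identity": (lambda t: t, lambda x: x),
}


@dataclass(frozen=True)
class BackboneConfig:
    input_side: int = 224
    conv_plan: tuple = ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512))
    width_multiplier: float = 1.0

    def channels(self) -> list[tuple[int, int]]:
        return [(n, max(1, int(round(c * self.width_multiplier))))
                for n, c in self.conv_plan]

    @property
    def feature_length(self) -> int:
        return self.channels()[-1][1]

    @property
    def final_map_side(self) -> int:
        # max-pool after every block except the last
        return self.input_side // (2 ** (len(self.conv_plan) - 1))


@dataclass(frozen=True)
class GCNConfig:
    in_dim: int = 18            # node-feature width (stats + geometry + density)
    hidden: int = 64            # k, the per-hop embedding width
    depth: int = 2              # j, number of hops
    activation: str = "relu"
    attention: str = "global"   # "global" or "per_node"
    leaky_slope: float = 0.2    # negative slope of the per-node scorer


@dataclass(frozen=True)
class FusionConfig:
    mu: float = 1.0
    fused_dim: int = 512
    n_classes: int = 5

    def __post_init__(self):
        if self.fused_dim <= 0:
            raise ValueError("fused_dim must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")


class HopStack:
    """The sequence of per-hop GCN node-feature matrices H^(1)..H^(j)."""

    def __init__(self, hops):
        hops = list(hops)
        if not hops:
            raise ValueError("empty hop stack")
        shapes = {np.shape(h.data if isinstance(h, Tensor) else h) for h in hops}
        if len(shapes) != 1:
            raise ValueError("all hops must share node count and width")
        self.hops = hops

    @property
    def depth(self) -> int:
        return len(self.hops)


# ---------------------------------------------------------------------------
# functional reference operations (plain NumPy)
# ---------------------------------------------------------------------------

def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray,
              activation: str = "relu") -> np.ndarray:
    """One graph convolution: f(A_hat @ H @ W)."""
    H, A_hat, W = (np.asarray(m, dtype=np.float64) for m in (H, A_hat, W))
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[1] != H.shape[0] \
            or H.shape[1] != W.shape[0]:
        raise ValueError("dimension mismatch in gcn_layer")
    return _ACTIVATIONS[activation][1](A_hat @ H @ W)


def attention_aggregate(stack: HopStack, a: np.ndarray) -> np.ndarray:
    """Convex combination over hops: gamma = sum_i a_i H^(i)."""
    a = np.asarray(a, dtype=np.float64)
    if len(a) != stack.depth:
        raise ValueError("attention weight count must equal stack depth")
    hops = [np.asarray(h.data if isinstance(h, Tensor) else h) for h in stack.hops]
    return sum(ai * Hi for ai, Hi in zip(a, hops))


def graph_readout(gammas: np.ndarray) -> np.ndarray:
    """Permutation-invariant pooling: concat(mean over nodes, max over nodes)."""
    gammas = np.asarray(gammas, dtype=np.float64)
    if gammas.ndim != 2 or gammas.shape[0] < 1:
        raise ValueError("need at least one node")
    return np.concatenate([gammas.mean(axis=0), gammas.max(axis=0)])


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class VGGBackbone:
    """Modified VGG-19 feature extractor with a global max-pool head."""

    def __init__(self, cfg: BackboneConfig = BackboneConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0)))
        self.params: dict[str, Tensor] = {}
        in_ch = 3
        for b, (n_convs, out_ch) in enumerate(cfg.channels()):
            for c in range(n_convs):
                w = Tensor(_he(rng, (out_ch, in_ch, 3, 3), in_ch * 9),
                           requires_grad=True)
                bias = Tensor(np.zeros(out_ch), requires_grad=True)
                self.params[f"b{b}c{c}.w"] = w
                self.params[f"b{b}c{c}.b"] = bias
                in_ch = out_ch

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(N,3,S,S) -> (feature vectors (N,C), final conv map (N,C,s,s))."""
        if x.data.ndim != 4 or x.data.shape[1] != 3 \
                or x.data.shape[2] != self.cfg.input_side \
                or x.data.shape[3] != self.cfg.input_side:
            raise ValueError(
                f"expected (N,3,{self.cfg.input_side},{self.cfg.input_side}), "
                f"got {x.data.shape}")
        n_blocks = len(self.cfg.conv_plan)
        for b, (n_convs, _) in enumerate(self.cfg.channels()):
            for c in range(n_convs):
                x = ad.relu(ad.conv2d_3x3(
                    x, self.params[f"b{b}c{c}.w"], self.params[f"b{b}c{c}.b"]))
            if b < n_blocks - 1:   # no pool after the last conv block
                x = ad.maxpool2x2(x)
        return ad.global_maxpool(x), x


def cnn_forward(images: np.ndarray, cfg: BackboneConfig = BackboneConfig(),
                backbone: VGGBackbone | None = None, seed: int = 0) -> np.ndarray:
    """Run a (possibly fresh) backbone on a uint8/float image batch.

    ``images``: (N, S, S, 3) channel-last array; returns (N, C) features.
    """
    if backbone is None:
        backbone = VGGBackbone(cfg, seed=seed)
    x = _to_input_tensor(images, backbone.cfg.input_side)
    feats, _ = backbone.forward(x)
    return feats.data


def _to_input_tensor(images: np.ndarray, side: int) -> Tensor:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != (side, side, 3):
        raise ValueError(f"expected (N,{side},{side},3), got {images.shape}")
    x = images.astype(np.float64) / 255.0 - 0.5
    return Tensor(x.transpose(0, 3, 1, 2))


class GACNN:
    """Full hybrid classifier over (image, region graph) pairs."""

    def __init__(self, backbone_cfg: BackboneConfig = BackboneConfig(),
                 gcn_cfg: GCNConfig = GCNConfig(),
                 fusion_cfg: FusionConfig = FusionConfig(), seed: int = 0):
        self.backbone_cfg = backbone_cfg
        self.gcn_cfg = gcn_cfg
        self.fusion_cfg = fusion_cfg
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA1)))
        self.backbone = VGGBackbone(backbone_cfg, seed=seed)
        k, d, j = gcn_cfg.hidden, gcn_cfg.in_dim, gcn_cfg.depth
        self.gcn_W = [Tensor(_he(rng, (d if i == 0 else k, k), d if i == 0 else k),
                             requires_grad=True) for i in range(j)]
        self.att_logits = Tensor(np.zeros(j), requires_grad=True)
        self.att_scorer = Tensor(_he(rng, (k,), k), requires_grad=True)
        fd = fusion_cfg.fused_dim
        c = backbone_cfg.feature_length
        self.W_rho = Tensor(_he(rng, (c, fd), c), requires_grad=True)
        self.W_sigma = Tensor(_he(rng, (2 * k, fd), 2 * k), requires_grad=True)
        self.b_fuse = Tensor(np.zeros(fd), requires_grad=True)
        self.W_cls = Tensor(_he(rng, (fd, fusion_cfg.n_classes), fd),
                            requires_grad=True)
        self.b_cls = Tensor(np.zeros(fusion_cfg.n_classes), requires_grad=True)
        # node-feature standardisation buffers, calibrated on the train set
        self.x_mu = np.zeros(d)
        self.x_sd = np.ones(d)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        params = dict(self.backbone.params)
        for i, w in enumerate(self.gcn_W):
            params[f"gcn.W{i}"] = w
        params["att.logits"] = self.att_logits
        params["att.scorer"] = self.att_scorer
        params.update({"fuse.rho": self.W_rho, "fuse.sigma": self.W_sigma,
                       "fuse.b": self.b_fuse, "cls.W": self.W_cls,
                       "cls.b": self.b_cls})
        return params

    def attention_weights(self) -> np.ndarray:
        """Global per-hop attention weights (softmax of the logits)."""
        z = self.att_logits.data.astype(np.float64)
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    # -- forward pieces ----------------------------------------------------
    def calibrate(self, graphs: list[ImageGraph]):
        """Fit the node-feature standardisation buffers on a training set.

        Records per-column mean/sd over all nodes of all training graphs
        so the graph branch sees well-conditioned inputs; near-constant
        columns keep unit scale.
        """
        Xall = np.vstack([g.X for g in graphs])
        self.x_mu = Xall.mean(axis=0)
        sd = Xall.std(axis=0)
        self.x_sd = np.where(sd > 1e-8, sd, 1.0)

    def hop_stack(self, graph: ImageGraph) -> HopStack:
        """Run the stacked graph convolutions for one image graph."""
        act = _ACTIVATIONS[self.gcn_cfg.activation][0]
        H = Tensor((graph.X - self.x_mu) / self.x_sd)
        A_hat = Tensor(graph.A_hat)
        hops = []
        for W in self.gcn_W:
            H = act(ad.matmul(ad.matmul(A_hat, H), W))
            hops.append(H)
        return HopStack(hops)

    def _aggregate(self, stack: HopStack) -> Tensor:
        if self.gcn_cfg.attention == "per_node":
            # score each hop per node; softmax over hops, per node
            scores = ad.stack([ad.leaky_relu(ad.matmul(H, self.att_scorer),
                                             self.gcn_cfg.leaky_slope)
                               for H in stack.hops], axis=0)       # (j, n)
            a = ad.softmax(scores, axis=0)
            terms = [ad.mul(ad.reshape(_take_row(a, i), (-1, 1)), stack.hops[i])
                     for i in range(stack.depth)]
        else:
            a = ad.softmax(self.att_logits, axis=-1)               # (j,)
            terms = [ad.mul(_take_scalar(a, i), stack.hops[i])
                     for i in range(stack.depth)]
        out = terms[0]
        for t in terms[1:]:
            out = ad.add(out, t)
        return out

    def graph_branch(self, graph: ImageGraph) -> Tensor:
        """Per-image graph vector h_k = readout(attention(hop stack))."""
        gamma = self._aggregate(self.hop_stack(graph))             # (n, k)
        mean_part = ad.mean_(gamma, axis=0)
        max_part = ad.max_(gamma, axis=0)
        return ad.concat([mean_part, max_part], axis=0)            # (2k,)

    def fused(self, images: np.ndarray, graphs: list[ImageGraph]) -> Tensor:
        """Fused vectors z_k = rho(f_k) + mu * sigma(h_k), (N, fused_dim)."""
        x = _to_input_tensor(images, self.backbone_cfg.input_side)
        if x.data.shape[0] != len(graphs):
            raise ValueError("batch size mismatch between images and graphs")
        f_k, _ = self.backbone.forward(x)                          # (N, C)
        h_k = ad.stack([self.graph_branch(g) for g in graphs], axis=0)  # (N, 2k)
        return ad.add(ad.add(ad.matmul(f_k, self.W_rho),
                             ad.mul(float(self.fusion_cfg.mu),
                                    ad.matmul(h_k, self.W_sigma))),
                      self.b_fuse)

    def forward(self, images: np.ndarray, graphs: list[ImageGraph]) -> Tensor:
        """Logits (N, n_classes) for a batch of images with their graphs."""
        z = self.fused(images, graphs)
        return ad.add(ad.matmul(ad.leaky_relu(z, self.gcn_cfg.leaky_slope),
                                self.W_cls), self.b_cls)

    def predict_proba(self, images: np.ndarray, graphs: list[ImageGraph]) -> np.ndarray:
        return ad.softmax(self.forward(images, graphs), axis=-1).data

    def predict(self, images: np.ndarray, graphs: list[ImageGraph]) -> np.ndarray:
        return np.argmax(self.predict_proba(images, graphs), axis=-1)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | os.PathLike):
        """Checkpoint the weights with the configuration embedded."""
        cfg = {"backbone": asdict(self.backbone_cfg),
               "gcn": asdict(self.gcn_cfg),
               "fusion": asdict(self.fusion_cfg), "seed": self.seed}
        arrays = {k: v.data for k, v in self.parameters().items()}
        arrays.update({"buf.x_mu": self.x_mu, "buf.x_sd": self.x_sd})
        np.savez(os.fspath(path), __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GACNN":
        with np.load(os.fspath(path), allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            bb = dict(cfg["backbone"])
            bb["conv_plan"] = tuple(tuple(p) for p in bb["conv_plan"])
            model = cls(BackboneConfig(**bb), GCNConfig(**cfg["gcn"]),
                        FusionConfig(**cfg["fusion"]), seed=cfg["seed"])
            for k, p in model.parameters().items():
                p.data = z[k]
            model.x_mu, model.x_sd = z["buf.x_mu"], z["buf.x_sd"]
        return model


def _take_scalar(t: Tensor, i: int) -> Tensor:
    """Differentiable selection of element i from a vector tensor."""
    mask = np.zeros_like(t.data)
    mask[i] = 1.0
    return ad.sum_(ad.mul(t, mask))


def _take_row(t: Tensor, i: int) -> Tensor:
    """Differentiable selection of row i from a matrix tensor."""
    mask = np.zeros((t.data.shape[0], 1))
    mask[i, 0] = 1.0
    return ad.sum_(ad.mul(t, mask), axis=0)
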