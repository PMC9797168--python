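"""Region graphs over fundus images.

A preprocessed image is turned into a graph whose nodes are detector-
proposed candidate-lesion regions. Each region is a box {m, n, w, h}
(upper-left corner, width, height) with centre y_i = (m + w/2, n + h/2).
Nodes i and j are connected only when each is among the other's K nearest
neighbours (mutual KNN, Euclidean distance), and a connected pair gets the
Gaussian weight

    w_ij = exp(-||y_i - y_j||^2 / (2 * omega^2))

with bandwidth omega = 1.6 px by default and K = 8. The weighted symmetric
adjacency A, its degree matrix D, and the renormalised propagation operator
A_hat = D~^(-1/2) (A + I) D~^(-1/2) feed the graph-convolution branch.

Detectors are pluggable: determinant-of-Hessian blob detection (the
interest-point principle behind fast Hessian/SURF-style detectors),
Laplacian-of-Gaussian blobs, ORB keypoints, or a deterministic uniform
grid used both as an explicit choice and as the fallback when a detector
finds too few regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse
from skimage.color import rgb2gray
from skimage.feature import blob_doh, blob_log, ORB

__all__ = ["InterestRegion", "ImageGraph", "GraphBuildConfig",
           "detect_regions", "region_center", "edge_weight",
           "build_mutual_knn", "node_features", "normalize_adjacency",
           "build_graph", "save_graph", "load_graph"]

_DETECTORS = ("hessian", "log", "orb", "grid")


@dataclass(frozen=True)
class InterestRegion:
    """A candidate-lesion box: upper-left (m, n), size (w, h), descriptor."""

    m: float
    n: float
    w: float
    h: float
    descriptor: np.ndarray | None = None
    response: float = 0.0

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("region width and height must be positive")


@dataclass
class ImageGraph:
    """Node features X, weighted adjacency A and its normalised form."""

    centers: np.ndarray     # (n, 2) region centres (x, y)
    X: np.ndarray           # (n, m) node features
    A: np.ndarray           # (n, n) weighted adjacency, zero diagonal
    D: np.ndarray           # (n, n) diagonal degree matrix of A
    A_hat: np.ndarray       # normalised propagation operator
    regions: list[InterestRegion] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class GraphBuildConfig:
    K: int = 8
    omega: float = 1.6
    detector: str = "log"
    max_nodes: int = 64
    min_nodes: int = 4
    grid_size: int = 4          # fallback grid is grid_size x grid_size
    self_loops: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.detector not in _DETECTORS:
            raise ValueError(
                f"unknown detector {self.detector!r}; choose from {_DETECTORS}")


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def _grid_regions(shape: tuple, cfg: GraphBuildConfig) -> list[InterestRegion]:
    h, w = shape[:2]
    g = cfg.grid_size
    regions = []
    for gy in range(g):
        for gx in range(g):
            regions.append(InterestRegion(
                m=gx * w / g, n=gy * h / g, w=w / g, h=h / g, response=0.0))
    return regions


def _blob_regions(gray: np.ndarray, method: str) -> list[InterestRegion]:
    if method == "hessian":
        blobs = blob_doh(gray, min_sigma=2, max_sigma=16, num_sigma=8,
                         threshold=0.002)
    else:
        # detect both bright and dark blobs with multiscale LoG
        bright = blob_log(gray, min_sigma=1, max_sigma=6, num_sigma=6,
                          threshold=0.15)
        dark = blob_log(1.0 - gray, min_sigma=1, max_sigma=6, num_sigma=6,
                        threshold=0.15)
        blobs = np.vstack([b for b in (bright, dark) if len(b)]) \
            if (len(bright) or len(dark)) else np.empty((0, 3))
    regions = []
    for row, col, sigma in blobs:
        diam = max(2.0 * np.sqrt(2.0) * sigma, 2.0)
        resp = float(_blob_response(gray, row, col, sigma))
        regions.append(InterestRegion(m=col - diam / 2, n=row - diam / 2,
                                      w=diam, h=diam, response=resp))
    return regions


def _blob_response(gray: np.ndarray, row: float, col: float, sigma: float) -> float:
    """Local contrast at the blob, used to rank detections."""
    h, w = gray.shape
    r = max(int(round(sigma)), 1)
    y0, y1 = max(0, int(row) - r), min(h, int(row) + r + 1)
    x0, x1 = max(0, int(col) - r), min(w, int(col) + r + 1)
    patch = gray[y0:y1, x0:x1]
    return abs(float(patch.mean()) - float(gray.mean()))


def _orb_regions(gray: np.ndarray, cfg: GraphBuildConfig) -> list[InterestRegion]:
    orb = ORB(n_keypoints=cfg.max_nodes, fast_threshold=0.05)
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return []
    regions = []
    for (row, col), scale, resp, desc in zip(
            orb.keypoints, orb.scales, orb.responses,
            orb.descriptors.astype(np.float64)):
        diam = max(31.0 * scale, 2.0)  # ORB patch diameter at this scale
        regions.append(InterestRegion(m=col - diam / 2, n=row - diam / 2,
                                      w=diam, h=diam, descriptor=desc,
                                      response=float(resp)))
    return regions


def detect_regions(image: np.ndarray,
                   cfg: GraphBuildConfig = GraphBuildConfig()) -> list[InterestRegion]:
    """Detect candidate-lesion regions, strongest response first.

    Falls back to a uniform grid of patches when the detector proposes
    fewer than ``cfg.min_nodes`` regions, so every image yields a graph.
    """
    image = np.asarray(image)
    gray = rgb2gray(image) if image.ndim == 3 else image.astype(np.float64)
    if cfg.detector == "grid":
        regions = _grid_regions(image.shape, cfg)
    elif cfg.detector == "orb":
        regions = _orb_regions(gray, cfg)
    else:
        regions = _blob_regions(gray, cfg.detector)
    if len(regions) < cfg.min_nodes:
        regions = _grid_regions(image.shape, cfg)
    h, w = gray.shape
    regions = [_clip_region(r, w, h) for r in regions]
    regions.sort(key=lambda r: -r.response)
    return regions[:cfg.max_nodes]


def _clip_region(r: InterestRegion, img_w: int, img_h: int) -> InterestRegion:
    m = min(max(r.m, 0.0), img_w - 1.0)
    n = min(max(r.n, 0.0), img_h - 1.0)
    w = min(r.w, img_w - m)
    h = min(r.h, img_h - n)
    return InterestRegion(m=m, n=n, w=max(w, 1.0), h=max(h, 1.0),
                          descriptor=r.descriptor, response=r.response)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def region_center(r: InterestRegion) -> tuple[float, float]:
    """Centre of the region box: (m + w/2, n + h/2)."""
    return (r.m + r.w / 2.0, r.n + r.h / 2.0)


def edge_weight(yi, yj, omega: float) -> float:
    """Gaussian kernel exp(-||yi - yj||^2 / (2 omega^2)); in (0, 1]."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    d2 = float(np.sum((np.asarray(yi, dtype=float) - np.asarray(yj, dtype=float)) ** 2))
    return float(np.exp(-d2 / (2.0 * omega * omega)))


def build_mutual_knn(centers: np.ndarray,
                     cfg: GraphBuildConfig = GraphBuildConfig()) -> set[frozenset]:
    """Undirected edges {i, j} with i in N_K(j) and j in N_K(i).

    Distance ties are broken by lower node index, which also makes the
    neighbour lists deterministic. When n - 1 <= K the mutual condition
    is vacuous and the graph is complete.
    """
    centers = np.asarray(centers, dtype=np.float64)
    n = len(centers)
    if n <= 1:
        return set()
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    neighbors: list[set[int]] = []
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))   # distance, then index
        order = [j for j in order if j != i][:cfg.K]
        neighbors.append(set(order))
    edges: set[frozenset] = set()
    for i in range(n):
        for j in neighbors[i]:
            if i in neighbors[j]:
                edges.add(frozenset((i, j)))
    return edges


def _patch_stats(image: np.ndarray, r: InterestRegion) -> np.ndarray:
    """12 intensity statistics of the region patch (descriptor fallback).

    Per-channel mean and spread plus bright/dark pixel fractions, which
    separate exudate-like from hemorrhage-like from vessel-like regions.
    """
    x0, x1 = int(r.m), int(np.ceil(r.m + r.w))
    y0, y1 = int(r.n), int(np.ceil(r.n + r.h))
    patch = np.asarray(image, dtype=np.float64)[max(y0, 0):y1, max(x0, 0):x1]
    if patch.size == 0:
        return np.zeros(12)
    if patch.ndim == 2:
        patch = patch[..., None].repeat(3, axis=-1)
    flat = patch.reshape(-1, 3) / 255.0
    lum = flat.mean(axis=1)
    grad = np.abs(np.diff(patch.mean(-1) / 255.0, axis=0)).mean() \
        if patch.shape[0] > 1 else 0.0
    bright_frac = float((lum > 0.8).mean())
    dark_frac = float(((lum > 0.05) & (lum < 0.3)).mean())
    return np.concatenate([
        flat.mean(axis=0), flat.std(axis=0),
        [flat.max() - flat.min(), grad, bright_frac, dark_frac,
         lum.max(), lum.min()]])


def node_features(image: np.ndarray, regions: list[InterestRegion],
                  cfg: GraphBuildConfig = GraphBuildConfig()) -> np.ndarray:
    """Node-feature matrix X: descriptor + geometry + local-density block.

    Row i holds the detector descriptor of region i (patch intensity
    statistics when the detector provides none), the centre and size
    normalised by the image dimensions, and two spatial-arrangement cues:
    the fraction of other regions within a 1/6-image radius and the
    normalised distance to the nearest other region. The density block is
    what lets a size-invariant readout see how crowded the lesion field
    is.
    """
    if not regions:
        raise ValueError("regions must be nonempty")
    img_h, img_w = np.asarray(image).shape[:2]
    centers = np.array([region_center(r) for r in regions])
    scale = float(max(img_h, img_w))
    if len(regions) > 1:
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        nn_dist = dist.min(axis=1) / scale
        density = (dist < scale / 6.0).sum(axis=1) / (len(regions) - 1.0)
    else:
        nn_dist = np.array([1.0])
        density = np.array([0.0])
    rows = []
    for i, r in enumerate(regions):
        desc = r.descriptor if r.descriptor is not None else _patch_stats(image, r)
        cx, cy = centers[i]
        geom = np.array([cx / img_w, cy / img_h, r.w / img_w, r.h / img_h,
                         density[i], min(nn_dist[i], 1.0)])
        rows.append(np.concatenate([np.asarray(desc, dtype=np.float64), geom]))
    widths = {len(row) for row in rows}
    if len(widths) != 1:
        raise ValueError("inconsistent descriptor widths across regions")
    return np.vstack(rows)


def normalize_adjacency(A: np.ndarray, self_loops: bool = True) -> np.ndarray:
    """Symmetric normalisation D^(-1/2) A D^(-1/2).

    With ``self_loops`` (default) the renormalisation trick is applied:
    A~ = A + I, D~ from A~. Without self-loops, zero-degree nodes get
    D^(-1/2) = 0 by convention.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("A must be symmetric")
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    if self_loops:
        A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]


def build_graph(image: np.ndarray,
                cfg: GraphBuildConfig = GraphBuildConfig()) -> ImageGraph:
    """Full pipeline: detect -> centres -> mutual KNN -> Gaussian A -> A_hat."""
    regions = detect_regions(image, cfg)
    centers = np.array([region_center(r) for r in regions])
    edges = build_mutual_knn(centers, cfg)
    n = len(regions)
    A = np.zeros((n, n))
    for e in edges:
        i, j = sorted(e)
        w = edge_weight(centers[i], centers[j], cfg.omega)
        A[i, j] = A[j, i] = w
    D = np.diag(A.sum(axis=1))
    A_hat = normalize_adjacency(A, self_loops=cfg.self_loops)
    X = node_features(image, regions, cfg)
    return ImageGraph(centers=centers, X=X, A=A, D=D, A_hat=A_hat,
                      regions=regions)


# ---------------------------------------------------------------------------
# serialization: MTX adjacency + CSV sidecars
# ---------------------------------------------------------------------------

def save_graph(graph: ImageGraph, prefix: str | os.PathLike):
    """Write ``<prefix>.adj.mtx``, ``<prefix>.regions.csv``, ``<prefix>.X.csv``."""
    prefix = os.fspath(prefix)
    sio.mmwrite(prefix + ".adj.mtx", sparse.coo_matrix(graph.A))
    pd.DataFrame({
        "m": [r.m for r in graph.regions],
        "n": [r.n for r in graph.regions],
        "w": [r.w for r in graph.regions],
        "h": [r.h for r in graph.regions],
        "cx": graph.centers[:, 0],
        "cy": graph.centers[:, 1],
    }).to_csv(prefix + ".regions.csv", index=False)
    pd.DataFrame(graph.X).to_csv(prefix + ".X.csv", index=False)


def load_graph(prefix: str | os.PathLike, self_loops: bool = True) -> ImageGraph:
    prefix = os.fspath(prefix)
    A = np.asarray(sio.mmread(prefix + ".adj.mtx").todense())
    A = (A + A.T) / 2.0  # exact symmetry after text round-trip
    tab = pd.read_csv(prefix + ".regions.csv")
    regions = [InterestRegion(m=row.m, n=row.n, w=row.w, h=row.h)
               for row in tab.itertuples()]
    centers = tab[["cx", "cy"]].to_numpy()
    X = pd.read_csv(prefix + ".X.csv").to_numpy()
    D = np.diag(A.sum(axis=1))
    return ImageGraph(centers=centers, X=X, A=A, D=D,
                      A_hat=normalize_adjacency(A, self_loops=self_loops),
                      regions=regions)
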