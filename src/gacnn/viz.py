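"""Optional qualitative visualisation hooks: embeddings and saliency.

These return arrays rather than figures so callers can plot with whatever
backend they like; nothing downstream depends on them.
"""

from __future__ import annotations

import numpy as np

from .network import GACNN, _to_input_tensor


def tsne_embed(features: np.ndarray, seed: int = 0,
               perplexity: float = 15.0) -> np.ndarray:
    """2-D t-SNE embedding of fused feature vectors (one row per image)."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    perplexity = min(perplexity, max(2.0, (len(features) - 1) / 3.0))
    return TSNE(n_components=2, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(features)


def input_saliency(model: GACNN, image: np.ndarray, graph,
                   class_id: int | None = None) -> np.ndarray:
    """Gradient saliency map |d logit / d pixel|, summed over channels.

    Highlights the image regions the CNN branch uses for the (predicted
    or given) class, in the spirit of class-activation mapping.
    """
    x = _to_input_tensor(image, model.backbone_cfg.input_side)
    x.requires_grad = True
    f_k, _ = model.backbone.forward(x)
    import gacnn.autodiff as ad
    h_k = ad.stack([model.graph_branch(graph)], axis=0)
    z = ad.add(ad.add(ad.matmul(f_k, model.W_rho),
                      ad.mul(float(model.fusion_cfg.mu),
                             ad.matmul(h_k, model.W_sigma))), model.b_fuse)
    logits = ad.add(ad.matmul(z, model.W_cls), model.b_cls)
    if class_id is None:
        class_id = int(np.argmax(logits.data[0]))
    seed_grad = np.zeros_like(logits.data)
    seed_grad[0, class_id] = 1.0
    logits.backward(seed_grad)
    return np.abs(x.grad[0]).sum(axis=0)
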