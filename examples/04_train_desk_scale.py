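"""Train the hybrid CNN + attention-GCN classifier at desk scale.

A width-1/8 backbone on 64x64 synthetic images, fully supervised, a few
minutes on one CPU. Prints the learning curve and final metrics.
"""

import numpy as np

from gacnn import (BackboneConfig, FusionConfig, GCNConfig,
                   GraphBuildConfig, SyntheticSpec, TrainConfig, fit,
                   generate_dataset)
from gacnn.graphbuild import build_graph

train = generate_dataset(SyntheticSpec(image_side=64, n_per_class=20, seed=1))
graphs = [build_graph(im, GraphBuildConfig(max_nodes=32))
          for im in train.images]

result = fit(
    train,
    TrainConfig.desk_scale(labeling_rate=1.0, epochs=12, seed=0,
                           eval_every=4),
    backbone_cfg=BackboneConfig(input_side=64, width_multiplier=1 / 8),
    gcn_cfg=GCNConfig(hidden=16),
    fusion_cfg=FusionConfig(fused_dim=64),
    graphs=graphs,
)
print(result.history[["epoch", "lr", "train_loss", "train_accuracy",
                      "train_kappa"]].dropna().to_string(index=False))
print("attention weights over hops:", result.model.attention_weights())
# Train accuracy climbs well above chance (0.2) within a dozen epochs;
# the attention weights stay on the probability simplex throughout.
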